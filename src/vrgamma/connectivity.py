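"""Phase-locking-value functional connectivity.

The instantaneous phase of each channel is the angle of its analytic
signal (FFT construction of the Hilbert transform), taken after a
zero-phase 53-80 Hz band-pass -- phase is only interpretable for a
narrowband signal. The PLV between two channels is the modulus of the
time-averaged unit phasor of their phase difference:

    PLV = | mean_t exp(j (theta_1(t) - theta_2(t))) |

computed per trial over the post-stimulus window with 250 ms trimmed at
each end so filter/Hilbert edge transients do not corrupt the estimate.
All 59 * 58 / 2 channel pairs yield a symmetric matrix per trial with a
unit diagonal by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epochs import EpochSet
from .preprocess import bandpass_array

__all__ = ["PLVStack", "instantaneous_phase", "plv", "plv_matrix"]

GAMMA_BAND = (53.0, 80.0)


@dataclass
class PLVStack:
    """Per-trial symmetric PLV matrices with labels carried along."""

    values: np.ndarray  # (trials, channels, channels) in [0, 1]
    labels: np.ndarray
    band: tuple[float, float]
    n_samples: int  # samples entering each per-trial average
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise ValueError("values must be (trials, channels, channels)")
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("PLV entries must lie in [0, 1]")


def instantaneous_phase(
    x: np.ndarray,
    band: tuple[float, float] = GAMMA_BAND,
    fs: float = 1000.0,
    prefilter: bool = True,
) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) along the last axis.

    A zero-phase band-pass restricted to ``band`` is applied first unless
    the input is already narrowband (``prefilter=False``). All-zero input
    has no defined phase and raises.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        raise ValueError("phase is undefined for an all-zero signal")
    if prefilter:
        x = bandpass_array(x, band[0], band[1], fs)
    return np.angle(signal.hilbert(x, axis=-1))


def plv(theta1: np.ndarray, theta2: np.ndarray) -> float:
    """Phase-locking value of two phase time series of equal length."""
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    if theta1.shape != theta2.shape:
        raise ValueError(f"phase vectors differ in shape: {theta1.shape} vs {theta2.shape}")
    if theta1.size == 0:
        raise ValueError("phase vectors must have length >= 1")
    return float(np.abs(np.mean(np.exp(1j * (theta1 - theta2)))))


def plv_matrix(
    epochs: EpochSet,
    band: tuple[float, float] = GAMMA_BAND,
    window_ms: tuple[float, float] = (0.0, 4000.0),
    trim_ms: float = 250.0,
    emotional_only: bool = True,
) -> PLVStack:
    """Per-trial PLV between all channel pairs on kept trials.

    The analysis window is ``window_ms`` shrunk by ``trim_ms`` at both
    ends. Matrices are exactly symmetric with diagonal 1.
    """
    kept = epochs.kept()
    if emotional_only:
        m = np.isin(kept.labels, ["positive", "negative"])
        kept = EpochSet(kept.subject_id, kept.fs, kept.t0_ms, kept.data[m],
                        kept.labels[m], kept.channel_names)
    lo = kept.sample_at(window_ms[0] + trim_ms)
    hi = kept.sample_at(window_ms[1] - trim_ms)
    if hi - lo < 2:
        raise ValueError("analysis window is empty after edge trimming")
    xb = bandpass_array(kept.data, band[0], band[1], kept.fs)
    analytic = signal.hilbert(xb, axis=-1)[:, :, lo:hi]
    z = analytic / np.abs(analytic)
    n = z.shape[-1]
    out = np.empty((kept.n_trials, kept.n_channels, kept.n_channels))
    for t in range(kept.n_trials):
        g = np.abs(z[t] @ z[t].conj().T) / n  # |mean phasor| for every pair at once
        g = 0.5 * (g + g.T)  # exact symmetry against rounding
        np.fill_diagonal(g, 1.0)
        out[t] = np.clip(g, 0.0, 1.0)
    return PLVStack(values=out, labels=kept.labels, band=band, n_samples=n,
                    subject_id=kept.subject_id)
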