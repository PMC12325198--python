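"""Welch power spectral density and high-gamma band power.

Band power per trial and channel is the trapezoidal integral of the
Welch PSD over the 53-80 Hz bins (both edges inclusive), computed on the
post-stimulus 0-4000 ms window. The PSD uses the variance-consistent
one-sided density convention (window power compensated, non-DC bins
doubled), so that the integral of the PSD over frequency recovers the
signal variance for a stationary detrended input; a flat emotional
contrast therefore survives any global scale convention.

Default segmentation: 0.5 s Hann windows with 50% overlap, i.e. 500
samples at the 1 kHz acquisition rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet, FeatureTable
from .montage import Montage, REGIONS

__all__ = [
    "WelchConfig",
    "PSDEstimate",
    "welch_psd",
    "psd_epochs",
    "band_power",
    "aggregate_regions",
    "band_power_table",
]

GAMMA_BAND = (53.0, 80.0)


@dataclass(frozen=True)
class WelchConfig:
    """Welch segmentation parameters.

    ``seg_len_samples`` is the per-segment sample count K; the default
    500 corresponds to 0.5 s at 1 kHz.
    """

    seg_len_samples: int = 500
    overlap_fraction: float = 0.5
    window: str = "hann"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.seg_len_samples < 2:
            raise ValueError("seg_len_samples must be >= 2")

    @classmethod
    def for_fs(cls, fs: float, window_s: float = 0.5) -> "WelchConfig":
        """Segment length for a ``window_s``-second window at rate ``fs``."""
        return cls(seg_len_samples=int(round(window_s * fs)))

    @property
    def noverlap(self) -> int:
        return int(self.seg_len_samples * self.overlap_fraction)

    def n_segments(self, n_samples: int) -> int:
        step = self.seg_len_samples - self.noverlap
        return 1 + (n_samples - self.seg_len_samples) // step


@dataclass
class PSDEstimate:
    """One-sided Welch PSD per trial and channel (values in uV^2/Hz)."""

    freqs: np.ndarray
    values: np.ndarray  # (trials, channels, freqs)
    n_segments: int

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("PSD values must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be ascending")


def welch_psd(x: np.ndarray, fs: float, cfg: WelchConfig = WelchConfig()):
    """Welch averaged-periodogram PSD along the last axis.

    Returns ``(freqs, psd)`` with the one-sided density scaling. Raises
    if the signal is shorter than one segment.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < cfg.seg_len_samples:
        raise ValueError(
            f"signal length {x.shape[-1]} is shorter than the segment length "
            f"{cfg.seg_len_samples}"
        )
    freqs, psd = signal.welch(
        x, fs=fs, window=cfg.window, nperseg=cfg.seg_len_samples,
        noverlap=cfg.noverlap, detrend="constant", scaling="density", axis=-1,
    )
    return freqs, psd


def psd_epochs(
    epochs: EpochSet,
    cfg: WelchConfig | None = None,
    window_ms: tuple[float, float] = (0.0, 4000.0),
) -> PSDEstimate:
    """Welch PSD of every kept trial and channel on the feature window.

    The default window is the post-stimulus 0-4000 ms segment; the
    pre-stimulus baseline is excluded and no baseline correction is
    applied.
    """
    cfg = cfg or WelchConfig.for_fs(epochs.fs)
    kept = epochs.kept()
    lo, hi = kept.sample_at(window_ms[0]), kept.sample_at(window_ms[1])
    seg = kept.data[:, :, lo:hi]
    freqs, psd = welch_psd(seg, kept.fs, cfg)
    return PSDEstimate(freqs=freqs, values=psd, n_segments=cfg.n_segments(seg.shape[-1]))


def band_power(psd: PSDEstimate, band: tuple[float, float] = GAMMA_BAND) -> np.ndarray:
    """Trapezoidal integral of the PSD over ``band`` (edges inclusive), in uV^2."""
    lo, hi = band
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ValueError(f"band {band} outside PSD frequency range")
    sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    if sel.sum() < 2:
        raise ValueError(f"band {band} covers fewer than 2 PSD bins")
    return np.trapezoid(psd.values[..., sel], psd.freqs[sel], axis=-1)


def aggregate_regions(bp: np.ndarray, montage: Montage) -> pd.DataFrame:
    """Unweighted per-region and prefrontal-subset means of channel band power.

    ``bp`` is (trials, channels) in montage channel order. Returns one
    row per trial with columns F, P, O, LT, RT, LF, RF.
    """
    bp = np.asarray(bp)
    if bp.shape[1] != montage.n_channels:
        raise ValueError("band-power channel axis does not match montage")
    cols = {r: bp[:, montage.region_indices(r)].mean(axis=1) for r in REGIONS}
    cols["LF"] = bp[:, montage.subset_indices(montage.lf_set)].mean(axis=1)
    cols["RF"] = bp[:, montage.subset_indices(montage.rf_set)].mean(axis=1)
    return pd.DataFrame(cols)


def band_power_table(
    epochs: EpochSet,
    montage: Montage,
    cfg: WelchConfig | None = None,
    band: tuple[float, float] = GAMMA_BAND,
    emotional_only: bool = True,
) -> FeatureTable:
    """Per-trial channel band powers plus region/hemisphere means.

    One row per kept trial; columns are ``pow_<channel>`` for the 59
    channels, the five region means, LF/RF, ``subject`` and ``label``.
    By default neutral trials are dropped, matching the binary
    positive/negative analysis.
    """
    psd = psd_epochs(epochs, cfg)
    bp = band_power(psd, band)
    kept = epochs.kept()
    frame = pd.DataFrame(bp, columns=[f"pow_{c}" for c in montage.channel_names])
    frame = pd.concat([frame, aggregate_regions(bp, montage)], axis=1)
    frame["subject"] = kept.subject_id
    frame["label"] = list(kept.labels)
    if emotional_only:
        frame = frame[frame["label"].isin(["positive", "negative"])].reset_index(drop=True)
    return FeatureTable(frame)
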