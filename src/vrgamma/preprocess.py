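"""Signal conditioning: band-pass, notch, epoching, rejection, re-referencing.

The fixed pipeline order is band-pass (2-80 Hz) -> notch (50 and 100 Hz)
-> epoch extraction (for continuous input) -> +/-100 microvolt trial
rejection -> average reference. All filtering is zero-phase
(forward-backward), so no group delay is introduced and downstream phase
estimates are protected.

Filter choices (the recordings themselves do not pin them): a 5th-order
Butterworth band-pass applied with ``sosfiltfilt`` and a Q = 30 IIR notch
per line frequency. The amplitude-rejection rule is strict: a trial is
dropped only when ``max |x| > threshold``, screening the full epoch
window. Average reference stands in for reference-electrode
standardization techniques that would require a head model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = [
    "PreprocessConfig",
    "bandpass",
    "notch",
    "extract_epochs",
    "reject_by_amplitude",
    "average_reference",
    "preprocess",
]

log = logging.getLogger("vrgamma.preprocess")


@dataclass(frozen=True)
class PreprocessConfig:
    bp_low: float = 2.0
    bp_high: float = 80.0
    notch_freqs: tuple[float, ...] = (50.0, 100.0)
    reject_uV: float = 100.0
    epoch_window_ms: tuple[float, float] = (-1000.0, 4000.0)
    bp_order: int = 5
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        if not 0 < self.bp_low < self.bp_high:
            raise ValueError("need 0 < bp_low < bp_high")
        if self.bp_high >= fs / 2:
            raise ValueError(f"bp_high={self.bp_high} must be below Nyquist ({fs / 2})")
        if self.reject_uV <= 0:
            raise ValueError("reject_uV must be positive")
        for f0 in self.notch_freqs:
            if f0 >= fs / 2:
                raise ValueError(f"notch frequency {f0} must be below Nyquist ({fs / 2})")


def _bandpass_sos(low: float, high: float, fs: float, order: int) -> np.ndarray:
    sos = signal.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    # poles of every biquad must sit inside the unit circle
    _, poles, _ = signal.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError(
            f"unstable band-pass design (order={order}, band=({low}, {high}), fs={fs}): "
            f"max pole modulus {np.abs(poles).max():.6f}"
        )
    return sos


def bandpass_array(x: np.ndarray, low: float, high: float, fs: float, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if high >= fs / 2:
        raise ValueError(f"band edge {high} Hz not below Nyquist {fs / 2} Hz")
    return signal.sosfiltfilt(_bandpass_sos(low, high, fs, order), x, axis=-1)


def notch_array(x: np.ndarray, freqs, fs: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at each frequency, applied in sequence."""
    y = x
    for f0 in freqs:
        if f0 >= fs / 2:
            raise ValueError(f"notch frequency {f0} Hz not below Nyquist {fs / 2} Hz")
        b, a = signal.iirnotch(f0, q, fs=fs)
        y = signal.filtfilt(b, a, y, axis=-1)
    return y


def bandpass(epochs: EpochSet, low: float = 2.0, high: float = 80.0, order: int = 5) -> EpochSet:
    """Zero-phase band-pass of every trial and channel."""
    return epochs.with_data(bandpass_array(epochs.data, low, high, epochs.fs, order))


def notch(epochs: EpochSet, freqs=(50.0, 100.0), q: float = 30.0) -> EpochSet:
    """Zero-phase narrowband rejection at the line frequency and harmonics."""
    return epochs.with_data(notch_array(epochs.data, freqs, epochs.fs, q))


def extract_epochs(
    continuous: np.ndarray,
    events: np.ndarray,
    fs: float,
    channel_names,
    window_ms: tuple[float, float] = (-1000.0, 4000.0),
    labels=None,
    subject_id: str = "unknown",
) -> EpochSet:
    """Cut stimulus-locked epochs out of a continuous recording.

    ``events`` are stimulus-onset sample indices. Each epoch spans
    ``[onset + window_ms[0], onset + window_ms[1])`` (start-inclusive,
    end-exclusive), so the sample at t = 0 is the event sample. Events
    whose window would leave the recording are skipped with a warning.
    """
    continuous = np.asarray(continuous)
    if continuous.ndim != 2:
        raise ValueError("continuous data must be (channels, samples)")
    n_total = continuous.shape[1]
    start_off = int(round(window_ms[0] * fs / 1000.0))
    stop_off = int(round(window_ms[1] * fs / 1000.0))
    events = np.asarray(events, dtype=int)
    if labels is None:
        labels = np.array(["neutral"] * len(events), dtype=object)
    out, out_labels = [], []
    for ev, lab in zip(events, labels):
        lo, hi = ev + start_off, ev + stop_off
        if lo < 0 or hi > n_total:
            msg = f"event at sample {ev}: window [{lo}, {hi}) outside recording, skipped"
            warnings.warn(msg)
            log.warning(msg)
            continue
        out.append(continuous[:, lo:hi])
        out_labels.append(lab)
    data = (np.stack(out) if out
            else np.empty((0, continuous.shape[0], stop_off - start_off), dtype=continuous.dtype))
    return EpochSet(subject_id=subject_id, fs=fs, t0_ms=window_ms[0], data=data,
                    labels=np.array(out_labels, dtype=object),
                    channel_names=tuple(channel_names))


def reject_by_amplitude(epochs: EpochSet, threshold_uV: float = 100.0) -> EpochSet:
    """Flag trials whose absolute amplitude strictly exceeds the threshold.

    Data are untouched; only ``kept_mask`` is updated (a trial already
    rejected stays rejected).
    """
    peak = np.abs(epochs.data).max(axis=(1, 2))
    ok = peak <= threshold_uV
    out = epochs.with_data(epochs.data)
    out.kept_mask = epochs.kept_mask & ok
    n_new = int((~ok & epochs.kept_mask).sum())
    log.info("amplitude rejection at +/-%g uV: %d trial(s) rejected", threshold_uV, n_new)
    return out


def average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (plain average reference)."""
    if epochs.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return epochs.with_data(epochs.data - epochs.data.mean(axis=1, keepdims=True))


def preprocess(epochs: EpochSet, cfg: PreprocessConfig = PreprocessConfig()) -> EpochSet:
    """Full conditioning chain on already-epoched data.

    Order: band-pass -> notch -> amplitude rejection -> average reference.
    """
    cfg.validate(epochs.fs)
    log.info("preprocess start: bp=(%g, %g) Hz order %d, notch=%s Q=%g, reject=+/-%g uV",
             cfg.bp_low, cfg.bp_high, cfg.bp_order, cfg.notch_freqs, cfg.notch_q, cfg.reject_uV)
    out = bandpass(epochs, cfg.bp_low, cfg.bp_high, cfg.bp_order)
    out = notch(out, cfg.notch_freqs, cfg.notch_q)
    out = reject_by_amplitude(out, cfg.reject_uV)
    out = average_reference(out)
    log.info("preprocess done: %d/%d trials kept", int(out.kept_mask.sum()), out.n_trials)
    return out
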