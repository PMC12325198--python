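"""Synthetic VR-EEG session generator.

Each synthetic subject reproduces the experimental design of the VR
emotion study: two video groups (one pairing emotional-positive with
neutral clips, the other emotional-negative with neutral), each
presented twice, 4 s stimulus epochs with a 1 s pre-stimulus baseline,
59 channels at 1 kHz. At the defaults this yields 120 trials per
subject: 40 positive, 40 negative, 40 neutral.

Signal model per trial and channel::

    x(t) = background(t) + A * g(condition, region, t) * gamma(t)

* ``background`` is 1/f^exponent coloured Gaussian noise (canonical EEG
  spectrum), scaled to ``bg_rms_uV`` microvolts RMS.
* ``gamma`` is a unit-power spectrally flat band-limited (53-80 Hz)
  Gaussian process, i.e. ideally band-pass filtered white noise. Its
  amplitude ``A`` is set so the gamma-to-background power ratio inside
  the band equals ``snr_db``.
* ``g`` injects the valence effects: post-stimulus gamma amplitude is
  multiplied by ``frontal_pos_gain`` on frontal channels in positive
  trials and by ``rt_neg_gain`` on right-temporal channels in negative
  trials; the pre-stimulus baseline always has gain 1.

Inter-channel phase locking is imposed by a shared-driver construction:
all channels of a coupled region pair receive the same analytic
narrowband driver, each rotated by its own piecewise-constant (125 ms
blocks) von Mises phase jitter. The concentration is chosen with
:func:`calibrate_plv_jitter` so that the expected pairwise resultant
length -- hence the realized PLV -- matches the requested target
(each of the two channels contributes sqrt(target)).

Generation is bit-reproducible: the stream for subject ``i`` is derived
from ``SeedSequence(cfg.seed, spawn_key=(i,))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .epochs import EpochSet
from .montage import Montage, default_montage

__all__ = [
    "SynthConfig",
    "calibrate_plv_jitter",
    "generate_session",
    "generate_dataset",
    "inject_spikes",
]

#: Seconds of phase-jitter coherence; one independent von Mises draw per block.
JITTER_BLOCK_S = 0.125


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults emulate the study design.

    ``trials_per_group`` counts videos per group (two thirds emotional,
    one third neutral -- 20 + 10 at the default 30). ``plv_targets``
    maps condition -> {(region, region): target PLV}; channels of the
    two regions share a narrowband driver in trials of that condition.
    """

    n_subjects: int = 19
    trials_per_group: int = 30
    n_groups: int = 2
    repetitions: int = 2
    fs: float = 1000.0
    epoch_ms: tuple[float, float] = (-1000.0, 4000.0)
    gamma_band: tuple[float, float] = (53.0, 80.0)
    frontal_pos_gain: float = 1.3
    rt_neg_gain: float = 1.3
    plv_targets: dict = field(default_factory=dict)
    noise_exponent: float = 1.0
    snr_db: float = 20.0
    bg_rms_uV: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frontal_pos_gain <= 0 or self.rt_neg_gain <= 0:
            raise ValueError("condition gains must be positive")
        if self.fs <= 2 * self.gamma_band[1]:
            raise ValueError(
                f"fs={self.fs} too low for the {self.gamma_band} Hz band "
                f"(need fs > {2 * self.gamma_band[1]})"
            )
        if self.trials_per_group % 3:
            raise ValueError("trials_per_group must be divisible by 3 (2:1 emotional:neutral)")
        for cond, pairs in self.plv_targets.items():
            seen: set[str] = set()
            for (ra, rb), v in pairs.items():
                if not 0 <= v < 1:
                    raise ValueError(f"plv target {v} for {cond}/{(ra, rb)} not in [0, 1)")
                for r in {ra, rb}:
                    if r in seen:
                        raise ValueError(
                            f"region {r} appears in more than one coupling group for {cond}"
                        )
                    seen.add(r)

    @property
    def n_trials(self) -> int:
        return self.n_groups * self.trials_per_group * self.repetitions

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_ms[1] - self.epoch_ms[0]) / 1000.0 * self.fs))


def calibrate_plv_jitter(target_plv: float) -> float:
    """Von Mises concentration whose mean resultant length equals ``target_plv``.

    The mean resultant length of a von Mises(0, kappa) sample is
    R(kappa) = I1(kappa) / I0(kappa), which increases monotonically from
    0 (uniform phase) toward 1. ``target_plv = 1`` would require zero
    jitter and raises.
    """
    if not 0 <= target_plv < 1:
        raise ValueError(f"target PLV must be in [0, 1), got {target_plv}")
    if target_plv == 0:
        return 0.0

    def gap(kappa: float) -> float:
        return i1e(kappa) / i0e(kappa) - target_plv

    return float(brentq(gap, 1e-12, 1e7, xtol=1e-12, rtol=1e-12))


def _trial_labels(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomized trial order with the two-group, two-repetition block design."""
    n_emo = 2 * cfg.trials_per_group // 3
    n_neu = cfg.trials_per_group - n_emo
    block = lambda emo: [emo] * n_emo + ["neutral"] * n_neu
    labels: list[str] = []
    for _ in range(cfg.repetitions):
        labels += block("positive") + block("negative")
    labels_arr = np.array(labels, dtype=object)
    return labels_arr[rng.permutation(len(labels_arr))]


def _background(cfg: SynthConfig, rng: np.random.Generator, n_trials: int,
                n_ch: int) -> tuple[np.ndarray, float]:
    """1/f^exponent Gaussian noise at bg_rms_uV, plus its in-band power (uV^2)."""
    n = cfg.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-cfg.noise_exponent / 2.0)
    # unit-variance normalization: each rfft bin of white noise has E|X|^2 = n,
    # and irfft weighs interior bins twice
    w = np.full_like(freqs, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    total = (w * shape**2).sum() / n
    shape /= np.sqrt(total)
    spec = np.fft.rfft(rng.standard_normal((n_trials, n_ch, n)), axis=-1) * shape
    bg = np.fft.irfft(spec, n, axis=-1) * cfg.bg_rms_uV
    band = (freqs >= cfg.gamma_band[0]) & (freqs <= cfg.gamma_band[1])
    inband_power = cfg.bg_rms_uV**2 * (w[band] * shape[band] ** 2).sum() / n
    return bg, inband_power


def _band_bins(cfg: SynthConfig) -> np.ndarray:
    freqs = np.fft.fftfreq(cfg.n_samples, 1.0 / cfg.fs)
    return np.flatnonzero((freqs >= cfg.gamma_band[0]) & (freqs <= cfg.gamma_band[1]))


def _analytic_noise(cfg: SynthConfig, rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Unit-real-power analytic (positive-frequency) band-limited Gaussian noise."""
    n = cfg.n_samples
    bins = _band_bins(cfg)
    coef = (rng.standard_normal(shape + (bins.size,))
            + 1j * rng.standard_normal(shape + (bins.size,))) / np.sqrt(2.0)
    spec = np.zeros(shape + (n,), dtype=complex)
    spec[..., bins] = coef
    a = np.fft.ifft(spec, axis=-1) * n
    return a * np.sqrt(2.0 / bins.size)


def _condition_gains(cfg: SynthConfig, montage: Montage, labels: np.ndarray) -> np.ndarray:
    """Post-stimulus gamma amplitude gain per (trial, channel)."""
    gains = np.ones((len(labels), montage.n_channels))
    f_idx = montage.region_indices("F")
    rt_idx = montage.region_indices("RT")
    gains[np.ix_(labels == "positive", f_idx)] = cfg.frontal_pos_gain
    gains[np.ix_(labels == "negative", rt_idx)] = cfg.rt_neg_gain
    return gains


def generate_session(cfg: SynthConfig, subject_index: int,
                     montage: Montage | None = None) -> EpochSet:
    """Generate one subject's full synthetic session as an :class:`EpochSet`."""
    montage = montage or default_montage()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(subject_index,)))
    n, n_ch = cfg.n_samples, montage.n_channels
    labels = _trial_labels(cfg, rng)
    n_trials = len(labels)

    bg, inband_bg_power = _background(cfg, rng, n_trials, n_ch)
    gamma_amp = np.sqrt(10.0 ** (cfg.snr_db / 10.0) * inband_bg_power)

    # independent narrowband gamma everywhere, then overwrite coupled groups
    analytic = _analytic_noise(cfg, rng, (n_trials, n_ch))
    block = max(1, int(round(JITTER_BLOCK_S * cfg.fs)))
    n_blocks = -(-n // block)
    for cond in sorted(cfg.plv_targets):
        trials = np.flatnonzero(labels == cond)
        if trials.size == 0:
            continue
        for (ra, rb) in sorted(cfg.plv_targets[cond]):
            target = cfg.plv_targets[cond][(ra, rb)]
            chans = np.unique(np.concatenate([montage.region_indices(ra),
                                              montage.region_indices(rb)]))
            driver = _analytic_noise(cfg, rng, (trials.size,))
            kappa = calibrate_plv_jitter(np.sqrt(target))
            jit = rng.vonmises(0.0, kappa, (trials.size, chans.size, n_blocks)) \
                if kappa > 0 else \
                rng.uniform(-np.pi, np.pi, (trials.size, chans.size, n_blocks))
            jit = np.repeat(jit, block, axis=-1)[..., :n]
            analytic[np.ix_(trials, chans)] = driver[:, None, :] * np.exp(1j * jit)

    gamma = np.real(analytic)
    del analytic

    # stimulus-locked effect injection: baseline second keeps gain 1
    env = np.ones((n_trials, n_ch, n))
    onset = int(round(-cfg.epoch_ms[0] / 1000.0 * cfg.fs))
    env[:, :, onset:] = _condition_gains(cfg, montage, labels)[:, :, None]

    data = (bg + gamma_amp * env * gamma).astype(np.float32)
    return EpochSet(subject_id=f"S{subject_index + 1:02d}", fs=cfg.fs,
                    t0_ms=cfg.epoch_ms[0], data=data, labels=labels,
                    channel_names=montage.channel_names)


def generate_dataset(cfg: SynthConfig, montage: Montage | None = None) -> list[EpochSet]:
    """All subjects of one synthetic study, ``cfg.n_subjects`` sessions."""
    montage = montage or default_montage()
    return [generate_session(cfg, i, montage) for i in range(cfg.n_subjects)]


def inject_spikes(epochs: EpochSet, trial_indices, amplitude_uV: float = 150.0,
                  seed: int = 0) -> EpochSet:
    """Plant a single-sample amplitude spike in the listed trials.

    Exists solely to exercise the +/-100 microvolt rejection rule; no
    physiological artifact model is attempted.
    """
    rng = np.random.default_rng(seed)
    data = epochs.data.copy()
    for t in np.asarray(trial_indices, dtype=int):
        ch = rng.integers(0, epochs.n_channels)
        s = rng.integers(0, epochs.n_samples)
        data[t, ch, s] = amplitude_uV * rng.choice([-1.0, 1.0])
    return epochs.with_data(data)
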