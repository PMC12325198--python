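# Methods

`vrgamma` re-implements, as a tested and reusable pipeline, a
high-gamma (53–80 Hz) EEG analysis of emotional states evoked by
immersive VR video stimuli: Welch band power, phase-locking-value (PLV)
brain networks with graph-efficiency metrics, repeated-measures
statistics, and an SVM / random-forest classification protocol. Because
the VR-EEG recordings the design emulates are not publicly deposited,
the package ships a synthetic session generator that reproduces the
experimental structure with known ground truth, so every stage can be
verified by parameter recovery rather than by comparison with private
data.

## The emulated design

Nineteen subjects each undergo 120 trials: two video groups — one
pairing 20 emotionally positive clips with 10 neutral ones, the other
20 negative with 10 neutral — each presented twice. Every trial is a
4 s stimulus epoch preceded by a 1 s baseline, sampled at 1 kHz on 59
electrodes of an extended 10–10 montage (a 64-channel cap minus one
cardiac and four ocular channels). The montage is grouped into five
regions — frontal (F, 22 channels: Fp/AF/F/FC rows), central-parietal
(P, 21: C/CP/P rows), occipital (O, 10: PO/O rows), left temporal
(LT: FT7, T7, TP7) and right temporal (RT: FT8, T8, TP8) — plus two
prefrontal subsets for asymmetry contrasts (LF = Fp1, AF3, AF7;
RF = Fp2, AF4, AF8). The exact membership of the regions is not fully
determined by the montage figure the design follows; the assignment
above is pinned in a versioned CSV (`vrgamma/data/montage59.csv`) and
can be overridden through `Montage.from_csv`. Channel positions use a
simple square-to-disk head-circle projection and matter only for
plotting.

## Synthetic signal model

Per trial and channel,

    x(t) = b(t) + A · g(condition, region, t) · γ(t)

- **Background** `b(t)` is 1/f^β coloured Gaussian noise (β = 1 by
  default), scaled to 5 μV RMS — the canonical broadband EEG spectrum.
- **Gamma** `γ(t)` is unit-power, spectrally flat, band-limited
  (53–80 Hz) Gaussian noise, generated in the frequency domain so its
  analytic signal is exact. A narrowband *process* rather than a
  sinusoid avoids the degenerate PLV ≡ 1 of deterministic tones.
- **Amplitude** `A` fixes the in-band gamma-to-background power ratio
  at `snr_db` (default 20 dB). The default is deliberately generous:
  the generator is a testbed for recovery, not a forward model of
  scalp SNR.
- **Effects** `g` multiplies the post-stimulus gamma amplitude by
  `frontal_pos_gain` on frontal channels in positive trials and by
  `rt_neg_gain` on right-temporal channels in negative trials
  (default 1.3; recovery experiments use 1.5 ≙ 2.25× power). The
  baseline second always has gain 1, making the effects
  stimulus-locked.

**Phase coupling.** Channels of a coupled region pair share one
analytic narrowband driver per trial; each channel is rotated by its
own phase jitter, piecewise-constant over 125 ms blocks, drawn from a
von Mises(0, κ) distribution. `calibrate_plv_jitter` inverts the mean
resultant length R(κ) = I₁(κ)/I₀(κ); each channel uses
κ = R⁻¹(√target), so the pairwise PLV — the product of two independent
resultants — matches the target. Block-wise jitter is essential: a
constant per-trial offset would leave PLV at 1 regardless of κ, while
per-sample jitter would destroy the narrowband structure that makes
phase meaningful. With ~28 blocks per analysis window the per-trial
resultant has a sampling floor of about √(1/28) ≈ 0.19, so weak targets
(≲ 0.3) are realized biased high; calibration is accurate in the
moderate-to-strong regime used here (verified at 0.8 within ±0.05).

Determinism: subject *i*'s stream is `SeedSequence(seed, spawn_key=(i,))`;
identical configuration and seed reproduce bit-identical sessions.

What the generator does **not** emulate: volume conduction and field
spread (no leadfield), ocular/muscle artifacts (only an optional
single-sample spike injector to exercise the rejection rule),
non-stationarity, inter-subject amplitude variability beyond the noise,
and realistic effect magnitudes (the source design reports no effect
sizes in generator-usable μV² units). Passing recovery tests therefore
demonstrates correctness of the analysis machinery, not real-data
performance.

## Preprocessing

Zero-phase (forward–backward) filtering throughout: Butterworth
band-pass 2–80 Hz (order 5 — chosen so the stopband at 100 Hz is
attenuated by more than 20 dB after the two passes) and Q = 30 IIR
notches at 50 and 100 Hz. Trials whose absolute amplitude strictly
exceeds 100 μV anywhere in the −1000…4000 ms epoch are flagged (data
untouched, mask updated); "exceeding" is read as a strict inequality so
the boundary is pinned. Re-referencing is a plain average reference —
reference standardization via a head model is out of scope for
artifact-free synthetic data, and the recovery results do not depend on
the reference choice. Pipeline order is fixed and logged: band-pass →
notch → (epoching for continuous input) → rejection → average
reference.

## Spectral features

Welch PSD with 0.5 s Hann segments and 50% overlap (K = 500 samples at
1 kHz, K = 125 at the desk-scale 250 Hz), `detrend='constant'`, in the
one-sided variance-consistent density convention: window power is
compensated and non-DC bins doubled, so ∫PSD df equals the signal
variance — which makes Parseval-style checks meaningful, while leaving
the positive-vs-negative contrasts untouched (they are invariant to any
global scale factor). Band power is the trapezoidal integral over bins
with 53 ≤ f ≤ 80 (both edges inclusive), computed on the post-stimulus
0–4000 ms window only; no baseline normalization is applied. Region
features are unweighted means over member channels.

## Connectivity and networks

Phases come from the analytic signal (FFT Hilbert construction) after a
zero-phase 53–80 Hz band-pass; PLV is the modulus of the time-averaged
unit phasor of the phase difference, computed per trial on the
post-stimulus window with 250 ms trimmed at each edge (filter/Hilbert
transients corrupt boundary phases). All 1711 channel pairs are
computed at once via a unit-phasor Gram matrix; matrices are exactly
symmetric with unit diagonal.

Networks are binarized at a fixed 14% connection density:
E = round-half-up(p·N(N−1)/2) = 240 edges for N = 59, selected as the E
strongest upper-triangle weights with ties broken by ascending
(row, column) index — fixed density per trial rather than a fixed
absolute threshold, because a constant density is what makes efficiency
comparable across trials. Nodal efficiency is the mean reciprocal hop
count to all other nodes (disconnected pairs contribute 0); global
efficiency is exactly the mean of nodal efficiencies; local efficiency
is the same quantity inside each node's neighbour-induced subgraph,
with the degree-< 2 convention of 0 (the normalizer is undefined
there). Shortest paths use breadth-first search; the test suite checks
all three metrics against an independent Floyd–Warshall brute force
(200 random graphs, 1e−12) and against networkx.

## Statistics

Trial-level features are reduced to per-subject condition means before
inference (the emulated design's degrees of freedom imply
subject-level analysis, n = 19). The two-way within-subject ANOVA
(Region × Emotion; Hemisphere × Emotion) is computed from orthonormal
contrast scores; the Greenhouse–Geisser epsilon of each effect comes
from the covariance of its contrast scores, ε = tr(S)²/(q·tr(S²)),
clipped to [1/q, 1], and the corrected p uses ε-scaled degrees of
freedom. Partial eta squared is SS_effect/(SS_effect+SS_error). Simple
effects are paired t-tests of Emotion within each level of the other
factor, Bonferroni-corrected over levels; signs are reported as
positive-minus-negative. Cohen's d defaults to the within-subject
d_z = mean(diff)/SD(diff) convention (the average-variance variant is
available); the source design does not state its variant, so no claim
of numeric equivalence is made. Network contrasts (global efficiency
and mean local efficiency, positive vs negative) are paired t-tests on
subject means.

## Classification

Each kept emotional trial is a sample. Per repetition: a fresh 70/30
split stratified independently within every (subject, class) stratum
(round-half-up train counts, never empty on either side), pooled
training of one RBF-kernel SVM (C = 1, gamma = 'scale', no tuning — a
single-model protocol keeps the three feature families comparable) on
per-feature z-scores whose parameters are estimated from training rows
only, then accuracy, a 2×2 confusion matrix and ROC/AUC from the
decision score on the pooled test rows. Ten repetitions yield
mean ± SD. The three feature families — 59 channel band powers, 59
nodal efficiencies, 59 local efficiencies — are always evaluated
separately, never concatenated. Feature importance: 500-tree random
forests on 70% training splits, Gini importance (mean decrease
impurity) averaged over trees then over 5 repetitions, descending
ranking (ties by column order), and a top-n accuracy curve for
n = 5…55 in steps of 5 under the same repeated SVM protocol with the
same seeds (so n = all reproduces the full-table result). A leakage
check verifies that scrambling test-row labels leaves the fitted
model's decision scores bit-for-bit unchanged.

## Desk-scale verification conditions

The repeated-dataset experiments in `vrgamma.experiments` (used by the
test suite and `scripts/acceptance.py`) run the full pipeline on
reduced studies so that hundreds of regenerated datasets complete in
minutes on one CPU:

- **Detection / type-I**: 19 subjects, 250 Hz, 12 trials per subject
  (4 per valence); only subject condition means enter these tests, so
  trial count trades power against runtime. Recovery gain 1.5.
- **Classification comparison**: 24 trials per subject (8 per valence),
  giving 304 pooled emotional trials. The recovery scenario adds an
  occipital within-region coupling contrast (PLV 0.35 positive vs
  0.25 negative) so the network features carry a genuine but weaker
  signal than band power.
- **Null calibration**: all gains 1, no condition-dependent coupling;
  the Region × Emotion interaction's GG-corrected rejection rate is
  compared with the binomial band around α = 0.05 over 200 datasets.
  Note that sphericity is genuinely violated under this null (region
  means average different channel counts, so difference variances are
  unequal), which is exactly the regime the GG correction addresses.

## Numerical choices and degenerate inputs

- Zero-variance ANOVA cells: contrast residue at machine precision is
  truncated to an exact F = 0 rather than reported as 0/0 noise.
- Zero-SD paired differences: t and d are flagged degenerate instead of
  propagating infinities silently.
- Degenerate (all-tied) classifier scores: ROC reported as the chance
  diagonal, AUC 0.5.
- All-zero signals: instantaneous phase raises (undefined) rather than
  returning angle(0).
- Tie-breaks (density thresholding, importance ranking) are
  deterministic and documented above.
- Epoch stores hold float32 data (full round-trip fidelity at the
  generator's output precision); internal computation is float64.

## Known limitations

- The synthetic generator's effect magnitudes and SNR are chosen for
  testability, not fidelity to real VR-EEG recordings; absolute
  accuracies and F statistics obtained here do not predict real-data
  values.
- PLV calibration is biased high for weak targets (sampling floor of
  the per-trial resultant; see above).
- Plain average reference, no ICA, no channel interpolation: the
  conditioning chain assumes artifact-free input apart from the
  amplitude-spike rejection rule.
- The classification protocol pools subjects (as in the emulated
  design); no subject-wise leave-one-out generalization is attempted.
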