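"""Repeated-measures inference on subject-level feature summaries.

Trial-level features are first reduced to per-subject condition means
(n = 19 subjects in the emulated design); all tests below operate on
those means. The two-way within-subject ANOVA (Region x Emotion and
Hemisphere x Emotion) is computed from orthonormal contrast scores:

    for effect contrast C (q columns), Z = Y C with Y the n x (a*b)
    cell-mean matrix; F = [n |mean(Z)|^2 / q] / [tr(S_Z resid) / (q(n-1))]

which reproduces the classical sums-of-squares partition. Sphericity
violations are handled with the Greenhouse-Geisser epsilon estimated
from the covariance of the contrast scores,
eps = tr(S)^2 / (q tr(S^2)), and the corrected p-value uses
epsilon-scaled degrees of freedom. Effect size is partial eta squared.

Simple effects are paired t-tests of Emotion within each level of the
other factor, Bonferroni-corrected over levels. Cohen's d uses the
within-subject convention d_z = mean(diff) / SD(diff) (sample SD); the
average-variance variant is available for comparison with
between-subject conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .epochs import FeatureTable
from .montage import REGIONS

__all__ = [
    "RMAnovaResult",
    "PairedComparison",
    "rm_anova_2way",
    "simple_effects",
    "paired_ttest",
    "cohens_d_paired",
    "subject_condition_means",
    "region_emotion_cells",
    "hemisphere_emotion_cells",
]

EMOTIONS = ("negative", "positive")


@dataclass(frozen=True)
class RMAnovaResult:
    """One within-subject effect of a repeated-measures ANOVA."""

    effect: str
    F: float
    df1: int
    df2: int
    epsilon: float
    p_uncorrected: float
    p_gg: float
    partial_eta_sq: float


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test with Bonferroni adjustment and Cohen's d."""

    name: str
    t: float
    df: int
    p: float
    p_bonferroni: float
    cohens_d: float
    mean_diff: float
    degenerate: bool = False


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """Orthonormal basis of the (k-1)-dimensional contrast space."""
    q, r = np.linalg.qr(np.eye(k) - 1.0 / k)
    return q[:, np.abs(np.diag(r)) > 1e-10]


def _effect_from_contrast(y_flat: np.ndarray, C: np.ndarray, name: str) -> RMAnovaResult:
    n = y_flat.shape[0]
    Z = y_flat @ C
    q = Z.shape[1]
    zbar = Z.mean(axis=0)
    ss_eff = n * float(zbar @ zbar)
    resid = Z - zbar
    ss_err = float((resid**2).sum())
    # contrast residue of order eps * |y| is numerically zero variance
    tol = (np.finfo(float).eps * max(1.0, float(np.abs(y_flat).max()))) ** 2 * y_flat.size
    ss_eff = 0.0 if ss_eff < tol else ss_eff
    ss_err = 0.0 if ss_err < tol else ss_err
    df1, df2 = q, q * (n - 1)
    if ss_err == 0.0:
        F = 0.0 if ss_eff == 0.0 else np.inf
    else:
        F = (ss_eff / df1) / (ss_err / df2)
    S = np.atleast_2d(np.cov(Z, rowvar=False))
    tr2 = float(np.trace(S @ S))
    eps = 1.0 if (q == 1 or tr2 == 0.0) else float(np.trace(S)) ** 2 / (q * tr2)
    eps = float(np.clip(eps, 1.0 / q, 1.0))
    p_unc = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    denom = ss_eff + ss_err
    eta = ss_eff / denom if denom > 0 else 0.0
    return RMAnovaResult(name, float(F), df1, df2, eps, p_unc, p_gg, float(eta))


def rm_anova_2way(cells: np.ndarray, factor_names: tuple[str, str] = ("A", "B"),
                  ) -> dict[str, RMAnovaResult]:
    """Two-way fully within-subject ANOVA on a complete balanced design.

    ``cells`` is (subjects, a_levels, b_levels) of cell means; missing
    values are fatal (no imputation). Returns results keyed by the two
    main effects and their interaction.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3:
        raise ValueError("cells must be (subjects, a_levels, b_levels)")
    if np.isnan(cells).any():
        raise ValueError("design is incomplete: missing cells")
    n, a, b = cells.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    y = cells.reshape(n, a * b)
    CA, CB = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    IA = np.ones((a, 1)) / np.sqrt(a)
    IB = np.ones((b, 1)) / np.sqrt(b)
    na, nb = factor_names
    return {
        na: _effect_from_contrast(y, np.kron(CA, IB), na),
        nb: _effect_from_contrast(y, np.kron(IA, CB), nb),
        f"{na}x{nb}": _effect_from_contrast(y, np.kron(CA, CB), f"{na}x{nb}"),
    }


def cohens_d_paired(x: np.ndarray, y: np.ndarray, variant: str = "dz") -> float:
    """Cohen's d for paired samples; sign follows mean(x - y).

    ``variant='dz'`` divides by the SD of the differences (within-subject
    convention); ``variant='av'`` divides by the average of the two
    condition SDs. A zero denominator yields a signed infinity, flagged
    as degenerate by the callers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = x - y
    if variant == "dz":
        sd = diff.std(ddof=1)
    elif variant == "av":
        sd = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    else:
        raise ValueError(f"unknown Cohen's d variant {variant!r}")
    if sd == 0.0:
        return float(np.sign(diff.mean()) * np.inf) if diff.mean() != 0 else 0.0
    return float(diff.mean() / sd)


def paired_ttest(x: np.ndarray, y: np.ndarray, name: str = "", m_comparisons: int = 1,
                 d_variant: str = "dz") -> PairedComparison:
    """Two-sided paired t-test with Bonferroni adjustment over ``m_comparisons``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = x - y
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if diff.mean() == 0 else float(np.sign(diff.mean()) * np.inf)
        p = 1.0 if diff.mean() == 0 else 0.0
        degenerate = diff.mean() != 0
    else:
        t, p = sps.ttest_rel(x, y)
        t, p = float(t), float(p)
        degenerate = False
    d = cohens_d_paired(x, y, d_variant)
    return PairedComparison(name=name, t=t, df=n - 1, p=p,
                            p_bonferroni=min(1.0, m_comparisons * p),
                            cohens_d=d, mean_diff=float(diff.mean()),
                            degenerate=degenerate or not np.isfinite(d))


def simple_effects(cells: np.ndarray, level_names, contrast_names=EMOTIONS,
                   d_variant: str = "dz") -> list[PairedComparison]:
    """Emotion contrast within each level of the other factor.

    ``cells`` is (subjects, levels, 2) with the last axis ordered as
    ``contrast_names`` (negative, positive). The Bonferroni factor is
    the number of levels. Comparisons are positive minus negative, so a
    positive t means positive > negative.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[2] != 2:
        raise ValueError("cells must be (subjects, levels, 2)")
    if cells.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    m = cells.shape[1]
    if len(level_names) != m:
        raise ValueError("level_names length must match the level axis")
    return [
        paired_ttest(cells[:, j, 1], cells[:, j, 0],
                     name=f"{level_names[j]}: {contrast_names[1]} vs {contrast_names[0]}",
                     m_comparisons=m, d_variant=d_variant)
        for j in range(m)
    ]


def subject_condition_means(table: FeatureTable, columns) -> pd.DataFrame:
    """Per-subject, per-valence means of the requested feature columns."""
    df = table.frame
    grouped = df.groupby(["subject", "label"], sort=True)[list(columns)].mean()
    return grouped.reset_index()


def _cells_from_means(means: pd.DataFrame, columns) -> np.ndarray:
    subjects = sorted(means["subject"].unique())
    out = np.full((len(subjects), len(columns), len(EMOTIONS)), np.nan)
    for si, subj in enumerate(subjects):
        for ei, emo in enumerate(EMOTIONS):
            row = means[(means["subject"] == subj) & (means["label"] == emo)]
            if len(row) == 1:
                out[si, :, ei] = row[list(columns)].to_numpy()[0]
    if np.isnan(out).any():
        raise ValueError("incomplete design: a subject is missing a condition")
    return out


def region_emotion_cells(table: FeatureTable) -> np.ndarray:
    """(subjects, 5 regions, 2 emotions) band-power cell means (F P O LT RT order)."""
    return _cells_from_means(subject_condition_means(table, REGIONS), REGIONS)


def hemisphere_emotion_cells(table: FeatureTable) -> np.ndarray:
    """(subjects, [LF, RF], 2 emotions) prefrontal band-power cell means."""
    return _cells_from_means(subject_condition_means(table, ("LF", "RF")), ("LF", "RF"))
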