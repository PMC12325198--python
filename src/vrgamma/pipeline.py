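"""End-to-end orchestration: one master seed, one run directory.

``run_full`` executes synth -> preprocess -> spectral -> connectivity ->
graphnet -> stats -> classify and writes every stage's output plus a
manifest (package version, configuration, config hash, per-stage
timings) and a human-readable summary. Per-stage and per-subject seeds
are derived deterministically from the master seed through
``numpy.random.SeedSequence(master_seed, spawn_key=(stage_index, subject))``,
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import gini_importance, repeat_protocol, subset_accuracy_curve
from .connectivity import plv_matrix
from .epochs import FeatureTable, save_epochs
from .graphnet import efficiency_table, network_metrics
from .montage import default_montage
from .preprocess import PreprocessConfig, preprocess
from .spectral import WelchConfig, band_power_table
from .stats import (
    hemisphere_emotion_cells,
    paired_ttest,
    region_emotion_cells,
    rm_anova_2way,
    simple_effects,
)
from .synth import SynthConfig, generate_session

__all__ = ["RunConfig", "run_full", "stage_seed"]

log = logging.getLogger("vrgamma.pipeline")

STAGES = ("synth", "preprocess", "spectral", "connectivity", "graphnet",
          "stats", "classify")


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage, per-subject seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGES.index(stage), index))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    out_dir: str
    master_seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    pre: PreprocessConfig = field(default_factory=PreprocessConfig)
    band: tuple[float, float] = (53.0, 80.0)
    density: float = 0.14
    n_classify_reps: int = 10
    n_importance_reps: int = 5
    subset_step: int = 5
    save_epoch_files: bool = False
    run_importance: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["plv_targets"] = {
            cond: {f"{a}-{b}": v for (a, b), v in pairs.items()}
            for cond, pairs in self.synth.plv_targets.items()
        }
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # scientific configuration only
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _anova_dict(results: dict) -> dict:
    return {name: dataclasses.asdict(r) for name, r in results.items()}


def _comparisons_dict(comparisons) -> list[dict]:
    return [dataclasses.asdict(c) for c in comparisons]


def run_full(config: RunConfig) -> Path:
    """Run the whole pipeline; returns the populated run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = default_montage()
    synth_cfg = dataclasses.replace(config.synth,
                                    seed=stage_seed(config.master_seed, "synth"))
    wcfg = WelchConfig.for_fs(synth_cfg.fs)
    timings: dict[str, float] = {}
    summary_lines: list[str] = []

    def timed(stage: str):
        class _T:
            def __enter__(self):
                log.info("stage %s: start", stage)
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[stage] = round(time.perf_counter() - self.t0, 3)
                log.info("stage %s: done in %.2fs", stage, timings[stage])

        return _T()

    power_frames, nodal_frames, local_frames = [], [], []
    with timed("synth-to-graphnet"):
        for i in range(synth_cfg.n_subjects):
            raw = generate_session(synth_cfg, i, montage)
            if config.save_epoch_files:
                save_epochs(raw, out / f"raw_{raw.subject_id}.h5")
            clean = preprocess(raw, config.pre)
            power_frames.append(band_power_table(clean, montage, wcfg, config.band).frame)
            stack = plv_matrix(clean, config.band)
            metrics = network_metrics(stack, config.density)
            nodal_frames.append(efficiency_table(metrics, montage, "nodal").frame)
            local_frames.append(efficiency_table(metrics, montage, "local").frame)

    power_table = FeatureTable(pd.concat(power_frames, ignore_index=True))
    nodal_table = FeatureTable(pd.concat(nodal_frames, ignore_index=True))
    local_table = FeatureTable(pd.concat(local_frames, ignore_index=True))
    power_table.to_csv(out / "bandpower.csv")
    nodal_table.to_csv(out / "nodal_efficiency.csv")
    local_table.to_csv(out / "local_efficiency.csv")

    with timed("stats"):
        region_cells = region_emotion_cells(power_table)
        hemi_cells = hemisphere_emotion_cells(power_table)
        region_anova = rm_anova_2way(region_cells, ("Region", "Emotion"))
        hemi_anova = rm_anova_2way(hemi_cells, ("Hemisphere", "Emotion"))
        region_simple = simple_effects(region_cells, ("F", "P", "O", "LT", "RT"))
        hemi_simple = simple_effects(hemi_cells, ("LF", "RF"))

        def subj_means(tab: FeatureTable, cols) -> np.ndarray:
            g = tab.frame.groupby(["subject", "label"])[cols].mean().mean(axis=1)
            wide = g.unstack("label")
            return wide[["positive", "negative"]].to_numpy()

        ge = subj_means(nodal_table, nodal_table.feature_names)
        le = subj_means(local_table, local_table.feature_names)
        global_t = paired_ttest(ge[:, 0], ge[:, 1], "global efficiency: pos vs neg")
        local_t = paired_ttest(le[:, 0], le[:, 1], "mean local efficiency: pos vs neg")
        stats_report = {
            "region_anova": _anova_dict(region_anova),
            "region_simple_effects": _comparisons_dict(region_simple),
            "hemisphere_anova": _anova_dict(hemi_anova),
            "hemisphere_simple_effects": _comparisons_dict(hemi_simple),
            "global_efficiency_ttest": dataclasses.asdict(global_t),
            "local_efficiency_ttest": dataclasses.asdict(local_t),
        }
        (out / "stats_report.json").write_text(json.dumps(stats_report, indent=2))

    with timed("classify"):
        seed = stage_seed(config.master_seed, "classify")
        families = {
            "power": power_table.select_features(
                [f"pow_{c}" for c in montage.channel_names]),
            "nodal": nodal_table,
            "local": local_table,
        }
        reports = {name: repeat_protocol(t, config.n_classify_reps, seed)
                   for name, t in families.items()}
        classify_report = {name: r.as_dict() for name, r in reports.items()}
        if config.run_importance:
            imp = gini_importance(families["power"], config.n_importance_reps, seed)
            sizes = [n for n in range(config.subset_step, 60, config.subset_step)
                     if n <= len(imp.ranking)]
            curve = subset_accuracy_curve(families["power"], imp.ranking, sizes,
                                          config.n_classify_reps, seed)
            classify_report["power_importance"] = {
                "ranking": imp.ranking,
                "importances": dict(zip(imp.feature_names, imp.importances.tolist())),
                "subset_accuracy_pct": {str(k): 100.0 * v for k, v in curve.items()},
            }
        (out / "classifier_report.json").write_text(json.dumps(classify_report, indent=2))

    # summary
    alpha = 0.05
    summary_lines.append(f"# vrgamma run summary (seed {config.master_seed})\n")
    summary_lines.append("## Region x Emotion band power")
    for name, r in region_anova.items():
        summary_lines.append(
            f"- {name}: F({r.df1},{r.df2}) = {r.F:.3f}, eps = {r.epsilon:.3f}, "
            f"p_GG = {r.p_gg:.4f}, partial eta^2 = {r.partial_eta_sq:.3f}"
        )
    for c in region_simple:
        flag = "*" if c.p_bonferroni < alpha else " "
        summary_lines.append(
            f"- {flag} {c.name}: t({c.df}) = {c.t:.3f}, p_bonf = {c.p_bonferroni:.4f}, "
            f"d = {c.cohens_d:.3f}"
        )
    summary_lines.append("\n## Network efficiency contrasts")
    for c in (global_t, local_t):
        flag = "*" if c.p < alpha else " "
        summary_lines.append(
            f"- {flag} {c.name}: t({c.df}) = {c.t:.3f}, p = {c.p:.4f}, d = {c.cohens_d:.3f}"
        )
    summary_lines.append("\n## Classification (positive vs negative)")
    for name, r in reports.items():
        summary_lines.append(
            f"- {name}: {100 * r.accuracy_mean:.2f}% +/- {100 * r.accuracy_sd:.2f}% "
            f"(AUC {r.auc_mean:.3f} +/- {r.auc_sd:.3f})"
        )
    (out / "summary.md").write_text("\n".join(summary_lines) + "\n")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
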