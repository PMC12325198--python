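import numpy as np
import pandas as pd
import pytest

from oracles import brute_rm_anova_2way
from vrgamma.epochs import FeatureTable
from vrgamma.stats import (
    cohens_d_paired,
    hemisphere_emotion_cells,
    paired_ttest,
    region_emotion_cells,
    rm_anova_2way,
    simple_effects,
)


class TestRMAnova:
    def test_constant_cells_give_zero_f(self):
        cells = np.tile(np.arange(5.0)[:, None, None], (1, 5, 2))  # subject offsets only
        res = rm_anova_2way(cells)
        assert all(r.F == 0.0 for r in res.values())

    def test_two_level_factor_has_unit_epsilon(self):
        rng = np.random.default_rng(0)
        res = rm_anova_2way(rng.normal(size=(8, 5, 2)), ("A", "B"))
        assert res["B"].epsilon == 1.0

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(1)
        cells = rng.normal(size=(3, 2, 2))
        mine = rm_anova_2way(cells)
        brute = brute_rm_anova_2way(cells)
        for eff in ("A", "B", "AxB"):
            F, eta = brute[eff]
            assert mine[eff].F == pytest.approx(F, abs=1e-10)
            assert mine[eff].partial_eta_sq == pytest.approx(eta, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        cells = rng.normal(size=(7, 5, 2))
        rows = [dict(subj=i, A=f"a{j}", B=f"b{k}", y=cells[i, j, k])
                for i in range(7) for j in range(5) for k in range(2)]
        ref = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within=["A", "B"],
                          subject="subj", detailed=True, effsize="np2")
        mine = rm_anova_2way(cells, ("A", "B"))
        for src, eff in (("A", "A"), ("B", "B"), ("A * B", "AxB")):
            row = ref[ref["Source"] == src].iloc[0]
            assert mine[eff].F == pytest.approx(row["F"], abs=1e-8)
            assert mine[eff].epsilon == pytest.approx(row["eps"], abs=1e-8)
            assert mine[eff].p_gg == pytest.approx(row["p_GG_corr"], abs=1e-8)
            assert mine[eff].partial_eta_sq == pytest.approx(row["np2"], abs=1e-8)

    def test_two_level_main_effect_equals_squared_paired_t(self):
        rng = np.random.default_rng(3)
        cells = rng.normal(size=(10, 3, 2))
        res = rm_anova_2way(cells)["B"]
        b_means = cells.mean(axis=1)  # subject x 2
        t = paired_ttest(b_means[:, 1], b_means[:, 0])
        assert res.F == pytest.approx(t.t**2, abs=1e-8)
        assert res.p_uncorrected == pytest.approx(t.p, abs=1e-10)

    def test_missing_cells_fatal(self):
        cells = np.ones((4, 2, 2))
        cells[1, 0, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2way(cells)


class TestPairedComparisons:
    def test_identical_conditions(self):
        x = np.arange(6.0)
        c = paired_ttest(x, x)
        assert c.t == 0.0 and c.p == 1.0 and c.cohens_d == 0.0

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = x + rng.normal(0.8, 0.5, size=12)
        c = paired_ttest(y, x, m_comparisons=2)
        assert c.p_bonferroni == pytest.approx(min(1.0, 2 * c.p))

    def test_bonferroni_capped_at_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        y = x + rng.normal(0, 1e-3, size=6)
        c = paired_ttest(y, x, m_comparisons=100)
        assert c.p_bonferroni <= 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        c = paired_ttest(x + 1.0, x)
        assert c.degenerate

    def test_simple_effects_sign_convention(self):
        rng = np.random.default_rng(6)
        cells = rng.normal(size=(10, 3, 2))
        cells[:, 0, 1] += 3.0  # positive > negative in level 0
        effects = simple_effects(cells, ("L0", "L1", "L2"))
        assert effects[0].t > 0
        assert effects[0].p_bonferroni == pytest.approx(min(1.0, 3 * effects[0].p))


class TestCohensD:
    def test_equal_vectors(self):
        x = np.arange(5.0)
        assert cohens_d_paired(x, x) == 0.0

    def test_unit_effect_hand_computed(self):
        # differences (0, 1, 2): mean 1, sample SD 1 -> d = 1
        y = np.zeros(3)
        x = np.array([0.0, 1.0, 2.0])
        assert cohens_d_paired(x, y) == pytest.approx(1.0)

    def test_zero_spread_flagged_infinite(self):
        x = np.array([1.0, 2.0, 3.0])
        assert np.isinf(cohens_d_paired(x + 1.0, x))

    def test_average_variance_variant(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 30))
        dz = cohens_d_paired(x, y, "dz")
        dav = cohens_d_paired(x, y, "av")
        assert np.sign(dz) == np.sign(dav)
        assert dz != dav


class TestCellExtraction:
    def _table(self, n_subj=3):
        rows = []
        rng = np.random.default_rng(8)
        for s in range(n_subj):
            for lab in ("positive", "negative"):
                for _ in range(4):
                    rows.append({
                        "F": rng.random(), "P": rng.random(), "O": rng.random(),
                        "LT": rng.random(), "RT": rng.random(),
                        "LF": rng.random(), "RF": rng.random(),
                        "subject": f"S{s:02d}", "label": lab,
                    })
        return FeatureTable(pd.DataFrame(rows))

    def test_region_cells_shape_and_means(self):
        t = self._table()
        cells = region_emotion_cells(t)
        assert cells.shape == (3, 5, 2)
        df = t.frame
        manual = df[(df["subject"] == "S00") & (df["label"] == "negative")]["F"].mean()
        assert cells[0, 0, 0] == pytest.approx(manual)

    def test_hemisphere_cells_shape(self):
        assert hemisphere_emotion_cells(self._table()).shape == (3, 2, 2)

    def test_incomplete_design_fatal(self):
        t = self._table()
        frame = t.frame[~((t.frame["subject"] == "S01")
                          & (t.frame["label"] == "positive"))].reset_index(drop=True)
        with pytest.raises(ValueError, match="incomplete"):
            region_emotion_cells(FeatureTable(frame))
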