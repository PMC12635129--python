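"""Mixed ANOVA, simple main effects, Tukey HSD and learning criterion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mobilearn import group_stats as gs
from mobilearn.errors import (
    DegenerateVarianceError,
    IncompleteDesignError,
    InsufficientDataError,
)

PHASES = ["B", "P1", "P2", "P3", "P4", "P5"]


def make_long(rng, ns=(8, 8), phase_effect=0.0, group_effect=0.0,
              interaction=0.0, sd=1.0, subj_sd=1.0):
    rows = []
    for g, n in enumerate(ns):
        for j in range(n):
            sid = f"g{g}s{j}"
            base = rng.normal(0, subj_sd) + group_effect * g
            for t, ph in enumerate(PHASES):
                val = base + phase_effect * t + interaction * t * g
                rows.append((sid, ph, f"G{g}", val + rng.normal(0, sd)))
    return pd.DataFrame(rows, columns=["subject_id", "phase", "group", "value"])


def naive_mixed_ss(df):
    """Independent sums-of-squares oracle: direct loops over the
    split-plot decomposition with weighted means."""
    wide = df.pivot_table(index=["subject_id", "group"], columns="phase",
                          values="value")
    Y = wide.to_numpy()
    grp = np.array(wide.index.get_level_values("group"))
    grand = Y.mean()
    p = Y.shape[1]
    ss_between = 0.0
    ss_inter = 0.0
    for lv in np.unique(grp):
        sub = Y[grp == lv]
        ss_between += p * len(sub) * (sub.mean() - grand) ** 2
        for t in range(p):
            ss_inter += len(sub) * (
                sub[:, t].mean() - sub.mean() - Y[:, t].mean() + grand
            ) ** 2
    ss_subj = sum(p * (row.mean() - grand) ** 2 for row in Y)
    ss_within = sum(len(Y) * (Y[:, t].mean() - grand) ** 2 for t in range(p))
    ss_total = ((Y - grand) ** 2).sum()
    return {
        "between": ss_between,
        "within": ss_within,
        "interaction": ss_inter,
        "err_between": ss_subj - ss_between,
        "err_within": ss_total - ss_subj - ss_within - ss_inter,
        "total": ss_total,
    }


class TestMixedAnova:
    def test_matches_naive_oracle_on_tiny_table(self, rng):
        df = make_long(rng, ns=(4, 4), phase_effect=0.4, interaction=0.2)
        table = gs.mixed_anova(df)
        oracle = naive_mixed_ss(df)
        got = dict(zip(table["source"], table["SS"]))
        for eff in ("between", "within", "interaction"):
            assert got[eff] == pytest.approx(oracle[eff], rel=1e-9)
        assert table.attrs["SS_error_between"] == pytest.approx(
            oracle["err_between"], rel=1e-9
        )
        assert table.attrs["SS_error_within"] == pytest.approx(
            oracle["err_within"], rel=1e-9
        )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for ns in [(8, 8), (7, 9), (5, 6, 7, 8)]:
            df = make_long(rng, ns=ns, phase_effect=0.3, interaction=0.1)
            mine = gs.mixed_anova(df)
            theirs = pg.mixed_anova(
                df, dv="value", within="phase", between="group",
                subject="subject_id",
            )
            np.testing.assert_allclose(
                mine["F"].to_numpy(), theirs["F"].to_numpy(), rtol=1e-8
            )
            np.testing.assert_allclose(
                mine["partial_eta_sq"].to_numpy(),
                theirs["np2"].to_numpy(),
                rtol=1e-8,
            )
            assert list(mine["df1"]) == list(theirs["DF1"])
            assert list(mine["df2"]) == list(theirs["DF2"])

    def test_identical_groups_no_between_effect(self, rng):
        df = make_long(rng, ns=(10, 10), phase_effect=0.5, sd=0.3, subj_sd=1.0)
        # duplicate group A's subject pattern exactly into group B
        a = df[df.group == "G0"].copy()
        b = a.copy()
        b["group"] = "G1"
        b["subject_id"] = b["subject_id"] + "_b"
        table = gs.mixed_anova(pd.concat([a, b], ignore_index=True))
        between = table[table.source == "between"].iloc[0]
        assert between["F"] == pytest.approx(0.0, abs=1e-9)
        assert between["p"] == pytest.approx(1.0, abs=1e-9)

    def test_decomposition_identity(self, rng):
        for _ in range(5):
            df = make_long(rng, ns=(5, 7), phase_effect=rng.uniform(0, 1))
            table = gs.mixed_anova(df)
            a = table.attrs
            total = (
                table["SS"].sum() + a["SS_error_between"] + a["SS_error_within"]
            )
            assert total == pytest.approx(a["SS_total"], rel=1e-9)

    def test_affine_invariance_of_partial_eta(self, rng):
        df = make_long(rng, ns=(6, 6), phase_effect=0.5, interaction=0.3)
        t1 = gs.mixed_anova(df)
        df2 = df.copy()
        df2["value"] = 3.7 * df2["value"] - 11.0
        t2 = gs.mixed_anova(df2)
        np.testing.assert_allclose(
            t1["partial_eta_sq"], t2["partial_eta_sq"], rtol=1e-9
        )

    def test_missing_cells_rejected(self, rng):
        df = make_long(rng, ns=(4, 4)).iloc[:-1]
        with pytest.raises(IncompleteDesignError):
            gs.mixed_anova(df)

    def test_paper_style_eta_ci(self):
        """Published-scale check: F(5, 915) = 42.90 corresponds to
        partial eta^2 = 0.190 with 95% CI ~ [0.144, 0.231]."""
        np2 = 42.90 * 5 / (42.90 * 5 + 915)
        assert np2 == pytest.approx(0.190, abs=0.001)
        lo, hi = gs.partial_eta_sq_ci(42.90, 5, 915)
        assert lo == pytest.approx(0.144, abs=0.005)
        assert hi == pytest.approx(0.231, abs=0.005)


class TestSimpleMainEffects:
    def test_identical_slices_equal_F(self, rng):
        df = make_long(rng, ns=(6, 6), phase_effect=0.5, sd=0.3)
        a = df[df.group == "G0"].copy()
        b = a.copy()
        b["group"] = "G1"
        b["subject_id"] = b["subject_id"] + "_b"
        out = gs.simple_main_effects(pd.concat([a, b], ignore_index=True))
        assert out["F"].nunique() == 1

    def test_bonferroni_threshold(self, rng):
        df = make_long(rng, ns=(5, 5), phase_effect=0.3)
        out = gs.simple_main_effects(df, alpha=0.01)
        assert out["threshold"].iloc[0] == pytest.approx(0.01 / 2)
        out6 = gs.simple_main_effects(df, direction="between-at-within", alpha=0.01)
        assert len(out6) == 6
        assert out6["threshold"].iloc[0] == pytest.approx(0.01 / 6)

    def test_effect_only_in_one_group_detected(self, rng):
        # strong phase ramp in G1 only; moderate noise, n=20/group
        rows = []
        for g in range(2):
            for j in range(20):
                sid = f"g{g}s{j}"
                base = rng.normal(0, 0.5)
                for t, ph in enumerate(PHASES):
                    val = base + (2.0 * t if g == 1 else 0.0)
                    rows.append((sid, ph, f"G{g}", val + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["subject_id", "phase", "group", "value"])
        out = gs.simple_main_effects(df).set_index("slice")
        assert bool(out.loc["G1", "significant"])
        assert not bool(out.loc["G0", "significant"])


class TestTukeyHSD:
    def test_two_groups_equal_pooled_t(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.4, 1, 15)
            vals = np.concatenate([a, b])
            grp = np.array(["A"] * 12 + ["B"] * 15)
            tk = gs.tukey_hsd(vals, grp)
            t = sps.ttest_ind(a, b)  # pooled-variance two-sample t
            assert tk["p_adj"].iloc[0] == pytest.approx(t.pvalue, rel=1e-6)
            assert tk["q"].iloc[0] == pytest.approx(
                np.sqrt(2) * abs(t.statistic), rel=1e-9
            )

    def test_identical_means_p_near_one(self, rng):
        vals = np.tile(rng.normal(0, 1, 10), 3)
        grp = np.repeat(["A", "B", "C"], 10)
        tk = gs.tukey_hsd(vals, grp)
        assert np.all(tk["p_adj"] > 0.999)

    def test_six_levels_fifteen_pairs(self, rng):
        vals = rng.normal(0, 1, 60)
        grp = np.repeat(PHASES, 10)
        tk = gs.tukey_hsd(vals, grp)
        assert len(tk) == 15

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        vals = rng.normal(0, 1, 45)
        vals[15:30] += 1.0
        grp = np.repeat(["A", "B", "C"], 15)
        tk = gs.tukey_hsd(vals, grp, alpha=0.05)
        sm = pairwise_tukeyhsd(vals, grp, alpha=0.05)
        np.testing.assert_allclose(tk["p_adj"].to_numpy(), sm.pvalues, atol=1e-6)

    def test_single_observation_level_rejected(self):
        with pytest.raises(InsufficientDataError):
            gs.tukey_hsd(np.array([1.0, 2.0, 3.0]), np.array(["A", "A", "B"]))


class TestOriginRegression:
    def test_exact_proportionality(self):
        x = np.array([1.0, 2.0, 3.0])
        assert gs.origin_regression(x, 2 * x) == pytest.approx(2.0)

    def test_x_zero_point_contributes_nothing(self):
        assert gs.origin_regression([1.0, 0.0], [0.0, 5.0]) == pytest.approx(0.0)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(0, 2, 50)
        y = rng.normal(0, 2, 50)
        naive = sum(a * b for a, b in zip(x, y)) / sum(a * a for a in x)
        assert gs.origin_regression(x, y) == pytest.approx(naive, rel=1e-12)

    def test_all_zero_x_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            gs.origin_regression([0.0, 0.0], [1.0, 2.0])


class TestLearnerFlag:
    def test_flat_ratio_not_learner(self):
        blocks = {b: 1.0 for b in PHASES}
        assert gs.learner_flag(blocks) is False

    def test_boundary_inclusive(self):
        blocks = {b: 1.0 for b in PHASES}
        blocks["P3"] = 1.5
        assert gs.learner_flag(blocks) is True

    def test_baseline_block_ignored(self):
        blocks = {b: 1.0 for b in PHASES}
        blocks["B"] = 2.0  # baseline itself cannot certify learning
        assert gs.learner_flag(blocks) is False

    def test_cluster4_synthetic_subject_is_learner(self, cluster4_session):
        from mobilearn import pipeline

        session, _, _ = cluster4_session
        ps = pipeline.process_session(session)
        con = ps.blocks[ps.blocks["limb_role"] == "ConA"].set_index("block")[
            "mean_ratio"
        ]
        assert gs.learner_flag(con) is True
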