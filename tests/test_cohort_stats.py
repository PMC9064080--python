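"""Cohort statistics: aggregation, assumptions, mixed ANOVA, post hocs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import posture_entropy as pe
from posture_entropy.cohort_stats import (
    EFFECT_SIZE_BANDS,
    bonferroni,
    classify_effect_size,
)
from posture_entropy.errors import DegenerateDataError, MissingCellError


def make_trials(values):
    """Long trial table from {(subject, group, task, repeat, direction): sampen}."""
    return pd.DataFrame(
        [
            {"subject": s, "group": g, "task": t, "repeat": r, "direction": d, "sampen": v}
            for (s, g, t, r, d), v in values.items()
        ]
    )


class TestAverageRepeats:
    def test_arithmetic_mean_of_repeats(self):
        trials = make_trials(
            {("s1", "control", "QS", r, "AP"): v for r, v in zip((1, 2, 3), (0.9, 1.0, 1.1))}
        )
        means = pe.average_repeats(trials)
        assert len(means) == 1
        assert means["sampen"].iloc[0] == pytest.approx(1.0)

    def test_infinite_repeat_excluded_with_warning(self):
        trials = make_trials(
            {
                ("s1", "control", "QS", 1, "AP"): 0.8,
                ("s1", "control", "QS", 2, "AP"): np.inf,
                ("s1", "control", "QS", 3, "AP"): 1.2,
            }
        )
        with pytest.warns(RuntimeWarning, match="excluded"):
            means = pe.average_repeats(trials)
        assert means["sampen"].iloc[0] == pytest.approx(1.0)

    def test_empty_cell_is_an_error(self):
        trials = make_trials(
            {
                ("s1", "control", "QS", 1, "AP"): np.nan,
                ("s1", "control", "QS", 2, "AP"): np.inf,
            }
        )
        with pytest.warns(RuntimeWarning):
            with pytest.raises(MissingCellError, match="s1"):
                pe.average_repeats(trials)

    def test_full_cohort_cardinality(self, default_design):
        table = pe.simulate_sampen_table(default_design)
        means = pe.average_repeats(table)
        # 38 subjects x 3 tasks x 2 directions
        assert len(means) == 38 * 3 * 2


class TestAssumptionChecks:
    def test_gaussian_cells_mostly_pass(self, default_design):
        flagged = 0
        checks = 0
        for seed in range(20):
            d = pe.CohortDesign(seed=seed)
            means = pe.average_repeats(pe.simulate_sampen_table(d.zero_effect()))
            block = pe.check_assumptions(means, "AP")
            ps = [p for p in block["shapiro"].values() if p is not None]
            ps += [p for p in block["levene"].values() if p is not None]
            ps += [block["mauchly"]["p"]]
            checks += len(ps)
            flagged += sum(p < 0.05 for p in ps)
        # under H0 each check flags at rate alpha
        assert flagged / checks == pytest.approx(0.05, abs=0.04)

    def test_degenerate_cell_skipped_with_warning(self):
        rng = np.random.default_rng(21)
        rows = {}
        for g, n in (("control", 4), ("beginner", 4), ("biathlete", 4)):
            for i in range(n):
                for t in ("QS", "SP", "AT"):
                    v = 1.0 if (g == "control" and t == "QS") else rng.uniform(0.5, 1.5)
                    rows[(f"{g}{i}", g, t, 1, "AP")] = v
        means = pe.average_repeats(make_trials(rows))
        with pytest.warns(RuntimeWarning, match="identical"):
            block = pe.check_assumptions(means, "AP")
        assert block["shapiro"]["control:QS"] is None

    def test_two_task_design_sphericity_trivial(self):
        rng = np.random.default_rng(3)
        rows = {}
        for g in ("control", "beginner"):
            for i in range(6):
                for t in ("QS", "SP"):
                    rows[(f"{g}{i}", g, t, 1, "AP")] = rng.uniform(0.5, 1.5)
        means = pe.average_repeats(make_trials(rows))
        block = pe.check_assumptions(means, "AP")
        assert block["mauchly"] == {"W": 1.0, "p": 1.0, "trivial": True}


class TestMixedAnova:
    def test_df_pattern_for_reference_design(self, default_design):
        means = pe.average_repeats(pe.simulate_sampen_table(default_design))
        rep = pe.mixed_anova(means, "AP")
        by_name = {e.name: e for e in rep.effects}
        assert (by_name["group"].df_num, by_name["task"].df_num,
                by_name["group:task"].df_num) == (2, 2, 4)
        assert by_name["group"].df_den == 35
        assert by_name["task"].df_den == by_name["group:task"].df_den == 70

    def test_balanced_two_by_two_matches_hand_computed_sums_of_squares(self):
        # 2 groups x 2 subjects x 2 tasks; SS computed from first principles
        y = {  # (subject, group): {task: value}
            ("s1", "control"): {"QS": 1.0, "SP": 2.0},
            ("s2", "control"): {"QS": 1.4, "SP": 2.2},
            ("s3", "beginner"): {"QS": 2.0, "SP": 2.4},
            ("s4", "beginner"): {"QS": 2.6, "SP": 3.4},
        }
        rows = {
            (s, g, t, 1, "AP"): v
            for (s, g), tasks in y.items()
            for t, v in tasks.items()
        }
        means = pe.average_repeats(make_trials(rows))
        rep = pe.mixed_anova(means, "AP")

        flat = np.array([[v for v in tasks.values()] for tasks in y.values()])
        grand = flat.mean()
        subj = flat.mean(axis=1)
        group = np.array([subj[:2].mean(), subj[2:].mean()])
        task = flat.mean(axis=0)
        cells = np.array([flat[:2].mean(axis=0), flat[2:].mean(axis=0)])
        k, n_per_group = 2, 2
        ss_group = k * n_per_group * ((group - grand) ** 2).sum()
        ss_subj = k * ((subj - grand) ** 2).sum()
        ss_eb = ss_subj - ss_group
        ss_task = 4 * ((task - grand) ** 2).sum()
        ss_cells = n_per_group * ((cells - grand) ** 2).sum()
        ss_inter = ss_cells - ss_group - ss_task
        ss_ew = ((flat - grand) ** 2).sum() - ss_cells - ss_eb
        f_group = (ss_group / 1) / (ss_eb / 2)
        f_task = (ss_task / 1) / (ss_ew / 2)
        f_inter = (ss_inter / 1) / (ss_ew / 2)

        by_name = {e.name: e for e in rep.effects}
        assert by_name["group"].F == pytest.approx(f_group, abs=1e-8)
        assert by_name["task"].F == pytest.approx(f_task, abs=1e-8)
        assert by_name["group:task"].F == pytest.approx(f_inter, abs=1e-8)
        noise = ss_eb + ss_ew
        assert by_name["group"].eta_g_sq == pytest.approx(ss_group / (ss_group + noise), abs=1e-10)

    def test_agrees_with_pingouin_on_unbalanced_cohort(self, default_design):
        import pingouin as pg

        means = pe.average_repeats(pe.simulate_sampen_table(default_design))
        for direction in ("AP", "ML"):
            rep = pe.mixed_anova(means, direction)
            sub = means[means["direction"] == direction]
            aov = pg.mixed_anova(
                sub, dv="sampen", within="task", subject="subject",
                between="group", effsize="ng2",
            )
            mine = {e.name: e for e in rep.effects}
            for src, name in (("group", "group"), ("task", "task"),
                              ("Interaction", "group:task")):
                row = aov[aov["Source"] == src].iloc[0]
                e = mine[name]
                assert e.F == pytest.approx(row["F"], rel=1e-10)
                assert e.p == pytest.approx(row["p_unc"], rel=1e-8)
                assert e.eta_g_sq == pytest.approx(row["ng2"], rel=1e-10)

    def test_zero_between_cell_variance_gives_zero_eta(self):
        # identical subject profiles replicated across groups: the group and
        # interaction SS are exactly zero, so eta_G^2 must be zero
        rng = np.random.default_rng(8)
        profiles = [
            {t: rng.normal(1.5, 0.3) for t in ("QS", "SP", "AT")} for _ in range(5)
        ]
        rows = {}
        for g in ("control", "beginner", "biathlete"):
            for i, profile in enumerate(profiles):
                for t, v in profile.items():
                    rows[(f"{g}{i}", g, t, 1, "AP")] = v
        means = pe.average_repeats(make_trials(rows))
        rep = pe.mixed_anova(means, "AP")
        by_name = {e.name: e for e in rep.effects}
        assert by_name["group"].eta_g_sq < 1e-12  # zero up to float residue
        assert by_name["group:task"].eta_g_sq < 1e-12

    def test_incomplete_table_rejected(self):
        rows = {
            ("s1", "control", "QS", 1, "AP"): 1.0,
            ("s1", "control", "SP", 1, "AP"): 1.1,
            ("s2", "control", "QS", 1, "AP"): 1.2,  # s2 missing SP
            ("s3", "beginner", "QS", 1, "AP"): 1.0,
            ("s3", "beginner", "SP", 1, "AP"): 1.3,
        }
        with pytest.raises(MissingCellError):
            pe.mixed_anova(pe.average_repeats(make_trials(rows)), "AP")

    def test_degenerate_zero_residuals_rejected(self):
        rows = {}
        for g, vals in (("control", (1.0, 2.0, 3.0)), ("beginner", (2.0, 3.0, 4.0))):
            for i in range(3):
                for t, v in zip(("QS", "SP", "AT"), vals):
                    rows[(f"{g}{i}", g, t, 1, "AP")] = v
        with pytest.raises(DegenerateDataError):
            pe.mixed_anova(pe.average_repeats(make_trials(rows)), "AP")


class TestPosthoc:
    @staticmethod
    def _pattern_cohort(seed=0):
        """Biathlete SP/AT means shifted far down; all groups equal in QS."""
        rng = np.random.default_rng(seed)
        rows = {}
        for g, n in (("control", 15), ("beginner", 15), ("biathlete", 8)):
            for i in range(n):
                intercept = rng.normal(0, 0.1)
                for t in ("QS", "SP", "AT"):
                    mu = 1.5
                    if g == "biathlete" and t in ("SP", "AT"):
                        mu -= 0.6  # -3 within-group SD
                    for rep in (1, 2, 3):
                        rows[(f"{g}{i}", g, t, rep, "AP")] = (
                            mu + intercept + rng.normal(0, 0.2)
                        )
        return make_trials(rows)

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.5, 9) == 1.0

    @settings(max_examples=40, deadline=None)
    @given(p=st.floats(min_value=0, max_value=1), k1=st.integers(1, 20), k2=st.integers(1, 20))
    def test_bonferroni_monotone_in_family_size(self, p, k1, k2):
        lo, hi = sorted((k1, k2))
        assert bonferroni(p, lo) <= bonferroni(p, hi)
        assert bonferroni(p, lo) >= p

    def test_recovers_planted_group_pattern(self):
        means = pe.average_repeats(self._pattern_cohort())
        rep = pe.mixed_anova(means, "AP")
        ph = pe.pairwise_posthoc(means, rep).to_frame()
        between = ph[ph["scope"] == "between-groups-within-task"]
        assert len(between) == 9  # 3 group pairs x 3 tasks
        for _, row in between.iterrows():
            involves_biathlete = "biathlete" in {row["a"], row["b"]}
            if row["stratum"] == "QS":
                assert row["p_adj"] >= 0.05
            elif involves_biathlete:
                assert row["p_adj"] < 0.05
            else:  # control vs beginner in SP/AT: no planted difference
                assert row["p_adj"] >= 0.05

    def test_gating_skips_scopes_without_omnibus_effect(self):
        rng = np.random.default_rng(12)
        rows = {}
        for g, n in (("control", 8), ("beginner", 8), ("biathlete", 8)):
            for i in range(n):
                for t in ("QS", "SP", "AT"):
                    rows[(f"{g}{i}", g, t, 1, "AP")] = rng.normal(1.5, 0.2)
        means = pe.average_repeats(make_trials(rows))
        rep = pe.mixed_anova(means, "AP")
        if all(e.p >= 0.05 for e in rep.effects):
            assert pe.pairwise_posthoc(means, rep).comparisons == []
        always = pe.pairwise_posthoc(means, rep, always=True)
        assert len(always.comparisons) == 18

    def test_adjusted_p_never_below_raw(self):
        means = pe.average_repeats(self._pattern_cohort(seed=5))
        rep = pe.mixed_anova(means, "AP")
        ph = pe.pairwise_posthoc(means, rep, always=True).to_frame()
        assert (ph["p_adj"] >= ph["p_raw"] - 1e-15).all()


class TestEffectSizeBands:
    @pytest.mark.parametrize(
        "eta,label",
        [
            (0.272, "large"),
            (0.174, "large"),
            (0.14, "large"),
            (0.079, "medium"),
            (0.107, "medium"),
            (0.06, "medium"),
            (0.0599, "small"),
            (0.01, "small"),
            (0.005, "below_small"),
            (0.0, "below_small"),
            (1.0, "large"),
        ],
    )
    def test_banding(self, eta, label):
        assert classify_effect_size(eta) == label

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 1.01, float("nan")):
            with pytest.raises(ValueError):
                classify_effect_size(bad)

    def test_bands_are_the_cohen_guidelines(self):
        assert EFFECT_SIZE_BANDS == {"small": 0.01, "medium": 0.06, "large": 0.14}
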