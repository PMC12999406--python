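"""Aggregation, descriptives, normality routing, test battery, dyadic r."""

import numpy as np
import pandas as pd
import pytest

from cprstress import (
    ValidationError,
    aggregate_by_phase,
    descriptives,
    dyadic_correlation,
    friedman_test,
    mixed_anova,
    normality_screen,
    paired_tests,
)

PHASES = ("pre", "Sim", "post")


def long_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "phase", "metric", "value"])


def cohort_frame(values, metric="m", roles=None, dyads=None):
    """values: dict participant -> {phase: value}."""
    rows = []
    for pid, phases in values.items():
        for ph, v in phases.items():
            rows.append({
                "participant_id": pid,
                "role": (roles or {}).get(pid, "TL"),
                "dyad_id": (dyads or {}).get(pid, pid),
                "phase": ph, "metric": metric, "value": v,
            })
    return pd.DataFrame(rows)


class TestAggregate:
    def test_constant_metric_three_rows(self):
        f = long_frame([("P1", ph, "hr", 70.0) for ph in PHASES])
        table, flagged = aggregate_by_phase(f)
        assert len(table) == 3
        assert (table.value == 70.0).all()
        assert flagged == []

    def test_window_values_averaged(self):
        f = long_frame([("P1", "pre", "sd1", 1.0), ("P1", "pre", "sd1", 3.0)])
        table, flagged = aggregate_by_phase(f, expected_phases=("pre",))
        assert table.value.tolist() == [2.0]

    def test_duplicate_metric_across_sources_errors(self):
        f1 = long_frame([("P1", "pre", "hr", 70.0)])
        f2 = long_frame([("P1", "pre", "hr", 71.0)])
        with pytest.raises(ValidationError):
            aggregate_by_phase([f1, f2])

    def test_missing_phase_flagged_not_imputed(self):
        f = long_frame([("P1", "pre", "hr", 70.0), ("P1", "Sim", "hr", 90.0)])
        table, flagged = aggregate_by_phase(f)
        assert ("P1", "post", "hr") in flagged
        assert len(table) == 2


class TestDescriptives:
    def test_constant_data_degenerate_intervals(self):
        t = cohort_frame({f"P{i}": {"pre": 5.0} for i in range(6)})
        row = descriptives(t, bootstrap_reps=200, seed=1).iloc[0]
        assert row.ci95_mean_lo == row.ci95_mean_hi == 5.0
        assert row.ci95_median_lo == row.ci95_median_hi == 5.0

    def test_small_sample_median_interval(self):
        t = cohort_frame({f"P{i}": {"pre": float(i + 1)} for i in range(5)})
        row = descriptives(t, bootstrap_reps=10_000, seed=1).iloc[0]
        assert row["median"] == 3.0
        assert row.ci95_median_lo <= 3.0 <= row.ci95_median_hi
        assert row.ci95_mean_lo <= row["mean"] <= row.ci95_mean_hi

    def test_seeded_reproducibility(self):
        t = cohort_frame(
            {f"P{i}": {"pre": v} for i, v in enumerate(np.random.default_rng(0).normal(size=12))}
        )
        a = descriptives(t, bootstrap_reps=500, seed=7)
        b = descriptives(t, bootstrap_reps=500, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_cell_flagged(self):
        t = cohort_frame({"P1": {"pre": 1.0}})
        row = descriptives(t, bootstrap_reps=100, seed=0).iloc[0]
        assert row.flag == "insufficient-data"


class TestNormalityScreen:
    def test_calibration_on_normal_draws(self):
        rng = np.random.default_rng(42)
        kept = sum(
            normality_screen(rng.standard_normal(500)).route == "parametric"
            for _ in range(100)
        )
        assert kept >= 94

    def test_lognormal_rejected(self):
        rng = np.random.default_rng(42)
        rejected = sum(
            normality_screen(np.exp(1.2 * rng.standard_normal(500))).route
            == "nonparametric"
            for _ in range(50)
        )
        assert rejected == 50

    def test_constant_routes_nonparametric_with_warning(self):
        d = normality_screen([3.0] * 10)
        assert d.route == "nonparametric"
        assert d.warning


class TestPairedTests:
    def test_identical_samples_degenerate(self):
        r = paired_tests([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], route="nonparametric")
        assert r.degenerate
        assert r.pvalue == 1.0

    def test_exact_one_sided_wilcoxon_shift(self):
        a = np.arange(2, 12, dtype=float)  # all differences +1
        b = np.arange(1, 11, dtype=float)
        r = paired_tests(a, b, route="nonparametric", sides="one")
        assert r.pvalue == pytest.approx(1 / 2**10)

    def test_null_calibration_paired_t(self):
        rng = np.random.default_rng(42)
        reps = 1000
        rej = 0
        for _ in range(reps):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            rej += paired_tests(a, b, route="parametric").pvalue <= 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) <= 3 * se

    def test_null_calibration_wilcoxon(self):
        rng = np.random.default_rng(42)
        reps = 1000
        rej = 0
        for _ in range(reps):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            rej += paired_tests(a, b, route="nonparametric").pvalue <= 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) <= 3 * se + 0.01  # discrete test: conservative


class TestFriedman:
    def test_identical_blocks_chi2_zero(self):
        t = cohort_frame({f"P{i}": {ph: 5.0 + i for ph in PHASES} for i in range(4)})
        r = friedman_test(t, "m")
        assert r.chi2 == 0.0
        assert r.degenerate

    def test_consistent_ranking_worked_example(self):
        # 3 participants each ranking pre < Sim < post: chi2 = 6, df = 2
        t = cohort_frame({
            "P1": {"pre": 1.0, "Sim": 2.0, "post": 3.0},
            "P2": {"pre": 4.0, "Sim": 5.0, "post": 6.0},
            "P3": {"pre": 0.1, "Sim": 0.2, "post": 0.3},
        })
        r = friedman_test(t, "m")
        assert r.chi2 == pytest.approx(6.0)
        assert r.df == 2
        assert len(r.posthoc) == 3

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        t = cohort_frame({
            f"P{i}": {ph: float(v) for ph, v in zip(PHASES, rng.normal(size=3))}
            for i in range(10)
        })
        t2 = t.copy()
        t2.value = np.exp(t2.value)
        assert friedman_test(t, "m").chi2 == pytest.approx(
            friedman_test(t2, "m").chi2
        )

    def test_incomplete_blocks_error_names_participants(self):
        t = cohort_frame({
            "P1": {"pre": 1.0, "Sim": 2.0, "post": 3.0},
            "P2": {"pre": 1.0, "Sim": 2.0},
            "P3": {"pre": 1.0, "Sim": 2.0, "post": 3.0},
        })
        with pytest.raises(ValidationError, match="P2"):
            friedman_test(t, "m")

    def test_wilcoxon_holm_posthoc_available(self):
        rng = np.random.default_rng(4)
        t = cohort_frame({
            f"P{i}": {ph: float(v) for ph, v in zip(PHASES, rng.normal(size=3))}
            for i in range(10)
        })
        r = friedman_test(t, "m", posthoc="wilcoxon-holm")
        assert len(r.posthoc) == 3
        assert (r.posthoc.pvalue <= 1.0).all()


def brute_force_mixed_anova(df):
    """Independent split-plot sums-of-squares oracle (balanced designs)."""
    k = df.phase.nunique()
    groups = df.groupby("role")
    gm = df.value.mean()
    subj_mean = df.groupby("participant_id").value.mean()
    subj_group = df.groupby("participant_id").role.first()
    n_total = df.participant_id.nunique()
    n_groups = df.role.nunique()

    group_mean = df.groupby("role").value.mean()
    ss_role = sum(
        k * (subj_group == g).sum() * (group_mean[g] - gm) ** 2
        for g in group_mean.index
    )
    ss_subj = k * sum(
        (subj_mean[s] - group_mean[subj_group[s]]) ** 2 for s in subj_mean.index
    )
    phase_mean = df.groupby("phase").value.mean()
    ss_phase = n_total * sum((phase_mean[p] - gm) ** 2 for p in phase_mean.index)
    cell_mean = df.groupby(["role", "phase"]).value.mean()
    ss_inter = sum(
        (subj_group == g).sum()
        * (cell_mean[(g, p)] - group_mean[g] - phase_mean[p] + gm) ** 2
        for g in group_mean.index
        for p in phase_mean.index
    )
    ss_err = sum(
        (r.value - subj_mean[r.participant_id]
         - cell_mean[(r.role, r.phase)] + group_mean[r.role]) ** 2
        for r in df.itertuples()
    )
    df_role, df_subj = n_groups - 1, n_total - n_groups
    df_phase = k - 1
    df_inter = df_role * df_phase
    df_err = df_subj * df_phase
    return {
        "role": (ss_role / df_role) / (ss_subj / df_subj),
        "phase": (ss_phase / df_phase) / (ss_err / df_err),
        "interaction": (ss_inter / df_inter) / (ss_err / df_err),
    }


class TestMixedAnova:
    def worked_table(self):
        rng = np.random.default_rng(8)
        rows = []
        for g, role in enumerate(["TL", "TM"]):
            for s in range(3):
                pid = f"P{g}{s}"
                for ph, v in zip(PHASES, rng.integers(1, 20, 3)):
                    rows.append({
                        "participant_id": pid, "role": role, "dyad_id": f"D{s}",
                        "phase": ph, "metric": "m", "value": float(v),
                    })
        return pd.DataFrame(rows)

    def test_matches_brute_force_sums_of_squares(self):
        t = self.worked_table()
        res = mixed_anova(t, "m")
        oracle = brute_force_mixed_anova(t)
        got = {
            str(r.source).lower(): r.F for _, r in res.effects.iterrows()
        }
        assert got["role"] == pytest.approx(oracle["role"], abs=1e-10)
        assert got["phase"] == pytest.approx(oracle["phase"], abs=1e-10)
        assert got["interaction"] == pytest.approx(oracle["interaction"], abs=1e-10)

    def test_all_equal_degenerate(self):
        t = cohort_frame(
            {f"P{i}": {ph: 4.0 for ph in PHASES} for i in range(4)},
            roles={f"P{i}": ("TL" if i % 2 else "TM") for i in range(4)},
        )
        res = mixed_anova(t, "m")
        assert res.degenerate

    def test_unbalanced_roles_warns(self):
        rng = np.random.default_rng(0)
        roles = {f"P{i}": ("TL" if i < 2 else "TM") for i in range(6)}
        t = cohort_frame(
            {f"P{i}": {ph: float(rng.normal()) for ph in PHASES} for i in range(6)},
            roles=roles,
        )
        res = mixed_anova(t, "m")
        assert "unbalanced" in res.warning

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(42)
        reps, rej = 300, 0
        for _ in range(reps):
            rows = []
            for g, role in enumerate(["TL", "TM"]):
                for s in range(5):
                    pid = f"P{g}{s}"
                    for ph in PHASES:
                        rows.append({
                            "participant_id": pid, "role": role, "dyad_id": pid,
                            "phase": ph, "metric": "m",
                            "value": float(rng.standard_normal()),
                        })
            res = mixed_anova(pd.DataFrame(rows), "m")
            p = res.effects.set_index("source").loc["phase", "pvalue"]
            rej += p <= 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) <= 3 * se


class TestDyadicCorrelation:
    def build(self, xs, ys):
        rows = []
        for i, (x, y) in enumerate(zip(xs, ys)):
            d = f"D{i}"
            rows.append({"participant_id": f"L{i}", "role": "TL", "dyad_id": d,
                         "phase": "pre", "metric": "tonic_eda", "value": x})
            rows.append({"participant_id": f"M{i}", "role": "TM", "dyad_id": d,
                         "phase": "post", "metric": "scr_rate", "value": y})
        return pd.DataFrame(rows)

    def test_perfect_positive(self):
        t = self.build([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        r = dyadic_correlation(t, ("TL", "pre", "tonic_eda"), ("TM", "post", "scr_rate"))
        assert r.r == pytest.approx(1.0)
        assert r.n == 4

    def test_perfect_negative(self):
        t = self.build([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0])
        r = dyadic_correlation(t, ("TL", "pre", "tonic_eda"), ("TM", "post", "scr_rate"))
        assert r.r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        t = self.build([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        r = dyadic_correlation(t, ("TL", "pre", "tonic_eda"), ("TM", "post", "scr_rate"))
        assert r.flag == "zero-variance margin"
        assert np.isnan(r.r)

    def test_too_few_dyads_error(self):
        t = self.build([1.0, 2.0], [2.0, 1.0])
        with pytest.raises(ValidationError):
            dyadic_correlation(t, ("TL", "pre", "tonic_eda"), ("TM", "post", "scr_rate"))
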