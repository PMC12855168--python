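"""Kinetic-area phenotyping: AUC, normalization, MAR, ANOVA, Scott-Knott."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from halogwas.phenotyping import (
    KineticCurve, anova_screen, areas_from_readings, compute_auc,
    metabolic_activity_reduction, normalize_activity, scott_knott,
    scott_knott_from_normalized, tolerance_profile,
)


def make_curve(times, signals, strain="s", cond="0", rep=1):
    return KineticCurve(strain, cond, rep, np.asarray(times, float),
                        np.asarray(signals, float))


class TestComputeAuc:
    @pytest.mark.parametrize("times,signals,expected", [
        ([0, 96], [10, 10], 960.0),          # rectangle
        ([0, 48, 96], [0, 0, 0], 0.0),       # flat zero
        ([0, 96], [0, 96], 4608.0),          # linear ramp, triangle
    ])
    def test_closed_forms(self, times, signals, expected):
        assert compute_auc(make_curve(times, signals)) == \
            pytest.approx(expected)

    def test_ramp_matches_riemann_sum_oracle(self):
        """Trapezoid on the hourly grid equals a dense midpoint Riemann sum
        for a linear ramp, and agrees within 0.5% for a smooth curve."""
        times = np.arange(0.0, 97.0)
        curve = make_curve(times, times)
        dense = np.linspace(0, 96, 96_001)
        riemann = np.sum((dense[1:] - dense[:-1]) *
                         (dense[1:] + dense[:-1]) / 2)
        assert compute_auc(curve) == pytest.approx(riemann, rel=1e-9)
        smooth = 50 / (1 + np.exp(-(times - 40) / 6.0))
        dense_vals = 50 / (1 + np.exp(-(dense - 40) / 6.0))
        dense_area = np.trapezoid(dense_vals, dense)
        assert compute_auc(make_curve(times, smooth)) == \
            pytest.approx(dense_area, rel=5e-3)

    def test_collinear_midpoint_invariance(self):
        base = make_curve([0, 10], [2, 8])
        split = make_curve([0, 5, 10], [2, 5, 8])
        assert compute_auc(base) == pytest.approx(compute_auc(split))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            make_curve([1], [5])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            make_curve([0, 2, 2], [1, 1, 1])


class TestNormalizeActivity:
    def areas(self, rows):
        return pd.DataFrame(rows, columns=["strain", "condition",
                                           "replicate", "aou"])

    def test_simple_ratio(self):
        df = self.areas([("a", 0, 1, 1000.0), ("a", 400, 1, 500.0)])
        out = normalize_activity(df)
        row = out[(out["strain"] == "a") & (out["condition"] == 400)]
        assert row["mean_ratio"].iloc[0] == pytest.approx(0.5)

    def test_ratio_uses_control_mean(self):
        df = self.areas([("a", 0, 1, 900.0), ("a", 0, 2, 1100.0),
                         ("a", 400, 1, 1000.0)])
        out = normalize_activity(df)
        row = out[out["condition"] == 400]
        assert row["mean_ratio"].iloc[0] == pytest.approx(1.0)

    def test_control_mean_ratio_is_one_panel_wide(self, rng):
        rows = []
        for s in range(6):
            for rep in range(1, 4):
                rows.append((f"s{s}", 0, rep, rng.uniform(800, 1200)))
                rows.append((f"s{s}", 600, rep, rng.uniform(100, 900)))
        out = normalize_activity(self.areas(rows))
        ctrl = out[out["condition"] == 0]
        assert ctrl["mean_ratio"].to_numpy() == pytest.approx(
            np.ones(6), abs=1e-12)

    def test_noisy_recovery_monte_carlo(self):
        """True ratio 0.7 with 5% CV noise, 3 replicates: the estimated
        mean ratio falls in [0.6, 0.8] in >= 99% of seeded runs."""
        hits = 0
        n_runs = 400
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            ctrl = 1000 * (1 + r.normal(0, 0.05, size=3))
            test = 700 * (1 + r.normal(0, 0.05, size=3))
            rows = [("a", 0, i + 1, ctrl[i]) for i in range(3)] + \
                   [("a", 400, i + 1, test[i]) for i in range(3)]
            out = normalize_activity(self.areas(rows))
            mr = out.loc[out["condition"] == 400, "mean_ratio"].iloc[0]
            hits += (0.6 <= mr <= 0.8)
        assert hits / n_runs >= 0.99

    def test_nonpositive_control_excluded_with_warning(self):
        df = self.areas([("bad", 0, 1, 0.0), ("bad", 400, 1, 10.0),
                         ("ok", 0, 1, 100.0), ("ok", 400, 1, 50.0)])
        with pytest.warns(UserWarning, match="bad"):
            out = normalize_activity(df)
        assert set(out["strain"]) == {"ok"}


class TestMar:
    @pytest.mark.parametrize("ratio,expected", [
        (0.828, 17.2), (1.0, 0.0), (0.25, 75.0),
    ])
    def test_values(self, ratio, expected):
        assert metabolic_activity_reduction(ratio) == pytest.approx(expected)

    def test_monotone_decreasing_in_ratio(self):
        ratios = np.linspace(-0.2, 1.3, 40)
        mars = [metabolic_activity_reduction(r) for r in ratios]
        assert all(a >= b for a, b in zip(mars, mars[1:]))

    def test_stimulation_goes_negative_and_is_flagged(self):
        assert metabolic_activity_reduction(1.1) == pytest.approx(-10.0)
        norm = pd.DataFrame({"strain": ["a"], "condition": [200],
                             "mean_ratio": [1.1]})
        prof = tolerance_profile(norm)
        assert bool(prof["stimulated"].iloc[0])


class TestAnovaScreen:
    def norm_table(self, ratio_lists, cond=400):
        return pd.DataFrame({
            "strain": [f"s{i}" for i in range(len(ratio_lists))],
            "condition": cond,
            "replicate_ratios": ratio_lists,
        })

    def test_identical_strains_give_p_near_one(self):
        out = anova_screen(self.norm_table([[0.5, 0.6, 0.7],
                                            [0.5, 0.6, 0.7]]))
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_strains_highly_significant(self):
        a = [0.19, 0.20, 0.21]
        b = [0.79, 0.80, 0.81]
        out = anova_screen(self.norm_table([a, b]))
        assert out["p"].iloc[0] < 1e-6
        f_ref, p_ref = stats.f_oneway(np.array(a), np.array(b))
        assert out["F"].iloc[0] == pytest.approx(f_ref)
        assert out["p"].iloc[0] == pytest.approx(p_ref)

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError):
            anova_screen(self.norm_table([[0.5, 0.6]]))

    def test_zero_within_variance_warns(self):
        with pytest.warns(UserWarning):
            out = anova_screen(self.norm_table([[0.2, 0.2], [0.8, 0.8]]))
        assert out["p"].iloc[0] == 0.0


def brute_force_first_cut(means_desc):
    """Exhaustive max-B0 search over all contiguous cuts (the oracle)."""
    g = len(means_desc)
    total = sum(means_desc)
    best, best_b0 = None, -np.inf
    for i in range(1, g):
        if means_desc[i - 1] == means_desc[i]:
            continue
        t1 = sum(means_desc[:i])
        b0 = t1 ** 2 / i + (total - t1) ** 2 / (g - i) - total ** 2 / g
        if b0 > best_b0:
            best, best_b0 = i, b0
    return best


class TestScottKnott:
    def test_all_equal_means_single_group(self):
        res = scott_knott({c: 0.5 for c in "abcd"}, mse=0.01, df_error=8,
                          n_reps=3)
        assert res.n_groups == 1

    def test_two_clear_clusters(self):
        means = {"a": 0.9, "b": 0.89, "c": 0.88,
                 "d": 0.3, "e": 0.29, "f": 0.28}
        res = scott_knott(means, mse=1e-4, df_error=12, n_reps=3)
        assert res.ordered_groups == [("A", ["a", "b", "c"]),
                                      ("B", ["d", "e", "f"])]

    def test_tiny_separation_large_error_single_group(self):
        eps = 1e-4
        res = scott_knott({"a": 0.5 + eps, "b": 0.5}, mse=1.0, df_error=4,
                          n_reps=3)
        assert res.n_groups == 1

    def test_groups_contiguous_in_sorted_order(self, rng):
        for _ in range(20):
            means = {f"s{i}": float(rng.uniform(0, 1)) for i in range(10)}
            res = scott_knott(means, mse=float(rng.uniform(1e-5, 1e-2)),
                              df_error=20, n_reps=3)
            ordered = sorted(means, key=lambda s: (-means[s], s))
            flat = [s for _, grp in res.ordered_groups for s in grp]
            assert flat == ordered

    def test_first_cut_matches_exhaustive_search(self, rng):
        from halogwas.phenotyping import _max_b0_cut
        for _ in range(50):
            g = int(rng.integers(2, 9))
            means = np.sort(rng.uniform(0, 1, size=g))[::-1]
            cut, _ = _max_b0_cut(means)
            assert cut == brute_force_first_cut(list(means))

    def test_from_normalized_table_pools_error_per_condition(self, rng):
        rows = []
        for i, center in enumerate([0.9, 0.895, 0.3]):
            reps = center + rng.normal(0, 0.02, size=3)
            rows.append({"strain": f"s{i}", "condition": 600,
                         "mean_ratio": float(reps.mean()),
                         "replicate_ratios": list(reps)})
        res = scott_knott_from_normalized(pd.DataFrame(rows), 600)
        assert res.n_groups == 2
        assert res.letter_of("s2") == "B"


def test_areas_from_readings_roundtrip():
    times = np.arange(0.0, 97.0, 8.0)
    rows = []
    for rep in (1, 2):
        for t in times:
            rows.append({"strain": "a", "condition": 0, "replicate": rep,
                         "time_h": t, "signal": 10.0})
    out = areas_from_readings(pd.DataFrame(rows))
    assert len(out) == 2
    assert out["aou"].to_numpy() == pytest.approx([960.0, 960.0])
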