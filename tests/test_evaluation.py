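"""Evaluation statistics: agreement, acceleration, concordance, probe-wise r."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiclockbench import (
    EpiclockError,
    acceleration_difference,
    acceleration_residual,
    compare_estimates,
    compare_methods,
    kendall_tau,
    probewise_platform_correlation,
    replicate_concordance,
)
from epiclockbench.evaluation import AgeEstimateSet


class TestCompareEstimates:
    def test_identical_vectors(self):
        out = compare_estimates([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["r"] == pytest.approx(1.0)
        assert out["median_abs_diff"] == 0.0

    def test_constant_offset_blind_r_sensitive_error(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        out = compare_estimates(x, x + 3)
        assert out["r"] == pytest.approx(1.0)
        assert out["median_abs_diff"] == pytest.approx(3.0)

    def test_perfect_anticorrelation(self):
        out = compare_estimates([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert out["r"] == pytest.approx(-1.0)

    def test_zero_variance_reported_undefined(self):
        out = compare_estimates([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not out["defined"] and np.isnan(out["r"])

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a, b = compare_estimates(x, y), compare_estimates(y, x)
        assert a["r"] == pytest.approx(b["r"])
        assert a["median_abs_diff"] == pytest.approx(b["median_abs_diff"])


class TestAcceleration:
    def test_difference_examples(self):
        np.testing.assert_allclose(
            acceleration_difference([22.0, 30.0, 38.0], [20.0, 30.0, 40.0]), [2, 0, -2]
        )
        np.testing.assert_allclose(acceleration_difference([5.0, 5.0], [5.0, 5.0]), 0)

    def test_difference_shifts_exactly_with_constant(self):
        rng = np.random.default_rng(1)
        chrono = rng.uniform(20, 50, 30)
        dnam = chrono + rng.normal(0, 3, 30)
        d0 = acceleration_difference(dnam, chrono)
        d5 = acceleration_difference(dnam + 5, chrono)
        np.testing.assert_allclose(d5 - d0, 5.0, rtol=0, atol=1e-12)

    def test_residual_perfect_fit_and_zero_sum(self):
        res = acceleration_residual([22.0, 30.0, 38.0], [20.0, 30.0, 40.0])
        np.testing.assert_allclose(res, 0, atol=1e-12)
        rng = np.random.default_rng(2)
        chrono = rng.uniform(20, 50, 25)
        dnam = 0.8 * chrono + rng.normal(0, 2, 25)
        assert abs(acceleration_residual(dnam, chrono).sum()) < 1e-8

    def test_residual_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        chrono = rng.uniform(20, 50, 40)
        dnam = chrono + rng.normal(0, 3, 40)
        r0 = acceleration_residual(dnam, chrono)
        r5 = acceleration_residual(dnam + 5, chrono)
        assert np.max(np.abs(r5 - r0)) < 1e-8

    def test_constant_chronological_age_rejected(self):
        with pytest.raises(EpiclockError, match="constant"):
            acceleration_residual([20.0, 21.0, 22.0], [30.0, 30.0, 30.0])


def kendall_tau_brute(x, y):
    """All-pairs concordant/discordant count oracle (no ties assumed)."""
    n = len(x)
    conc = disc = 0
    for i, j in itertools.combinations(range(n), 2):
        s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        if s > 0:
            conc += 1
        elif s < 0:
            disc += 1
    return (conc - disc) / (n * (n - 1) / 2)


class TestKendallTau:
    def test_single_swap_example(self):
        # 6 pairs: 5 concordant, 1 discordant -> (5-1)/6 = 2/3
        tau, _ = kendall_tau([1, 2, 3, 4], [1, 2, 4, 3])
        assert tau == pytest.approx(2 / 3)

    @settings(max_examples=80, derandomize=True)
    @given(
        perm=st.permutations(list(range(5))),
        n=st.integers(min_value=3, max_value=5),
    )
    def test_matches_brute_force_oracle(self, perm, n):
        x = list(range(n))
        y = [perm[i] for i in range(n)]
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(kendall_tau_brute(x, y))


def build_estimates(conditions: dict, chrono, platform="B", clock="clk"):
    rows = []
    for method, dnam in conditions.items():
        for i, (d, c) in enumerate(zip(dnam, chrono)):
            rows.append(
                {"sample_id": f"s{i}", "platform": platform, "preprocessing": method,
                 "clock": clock, "dnam_age": float(d), "chronological_age": float(c)}
            )
    return AgeEstimateSet(pd.DataFrame(rows))


class TestCompareMethods:
    def test_identical_conditions(self):
        rng = np.random.default_rng(5)
        chrono = rng.uniform(20, 50, 20)
        dnam = chrono + rng.normal(0, 2, 20)
        est = build_estimates({"m1": dnam, "m2": dnam.copy()}, chrono)
        out = compare_methods(est, metric="dnam_age")
        assert out.loc[0, "median_abs_diff"] == 0.0
        assert out.loc[0, "kendall_tau"] == pytest.approx(1.0)

    def test_constant_offset_contrast_between_metrics(self):
        """A mean shift moves the difference metric but not the residual one."""
        rng = np.random.default_rng(6)
        chrono = rng.uniform(20, 50, 30)
        dnam = chrono + rng.normal(0, 2, 30)
        est = build_estimates({"m1": dnam, "m2": dnam + 4.0}, chrono)
        diff = compare_methods(est, metric="difference")
        resid = compare_methods(est, metric="residual")
        assert diff.loc[0, "median_abs_diff"] == pytest.approx(4.0)
        assert resid.loc[0, "median_abs_diff"] < 1e-8
        assert diff.loc[0, "kendall_tau"] == pytest.approx(1.0)
        # offset is detected by the paired test on differences, not residuals
        assert diff.loc[0, "p_adj"] < 0.001
        assert resid.loc[0, "p_adj"] > 0.99

    def test_wilcoxon_alternative(self):
        rng = np.random.default_rng(8)
        chrono = rng.uniform(20, 50, 30)
        dnam = chrono + rng.normal(0, 2, 30)
        est = build_estimates({"m1": dnam, "m2": dnam + 4.0}, chrono)
        out = compare_methods(est, metric="difference", test="wilcoxon")
        assert out.loc[0, "p_adj"] < 0.001

    def test_unmatched_samples_rejected(self):
        rng = np.random.default_rng(7)
        chrono = rng.uniform(20, 50, 10)
        est = build_estimates({"m1": chrono, "m2": chrono}, chrono)
        table = est.table.drop(index=[0]).reset_index(drop=True)
        with pytest.raises(EpiclockError, match="missing"):
            compare_methods(AgeEstimateSet(table), metric="dnam_age")


class TestProbewiseCorrelation:
    def test_identical_matrices_all_one(self):
        rng = np.random.default_rng(9)
        beta = pd.DataFrame(rng.uniform(0.05, 0.95, (10, 8)),
                            index=[f"cg{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(8)])
        table, summary = probewise_platform_correlation(beta, beta)
        assert (table["r"].dropna() > 0.999999).all()
        assert summary["n_defined"] == 10

    def test_constant_probe_flagged_undefined(self):
        beta = pd.DataFrame(
            {"s0": [0.5, 0.1], "s1": [0.5, 0.5], "s2": [0.5, 0.9]},
            index=["cg_const", "cg_var"],
        )
        table, summary = probewise_platform_correlation(beta, beta)
        assert not table.set_index("probe_id").loc["cg_const", "defined"]
        assert summary["n_undefined"] == 1

    def test_invariant_probes_show_lower_correlation(self):
        """Low-range probes correlate worse across platforms than variable ones
        under independent measurement noise — the range-vs-r association."""
        rng = np.random.default_rng(10)
        n_samples = 60
        var_true = rng.uniform(0.2, 0.8, (30, 1)) + rng.uniform(-0.25, 0.25, (30, n_samples))
        inv_true = np.repeat(rng.uniform(0.3, 0.7, (30, 1)), n_samples, axis=1)
        true = np.clip(np.vstack([var_true, inv_true]), 0.01, 0.99)
        noise = lambda: rng.normal(0, 0.02, true.shape)
        probes = [f"var{i}" for i in range(30)] + [f"inv{i}" for i in range(30)]
        samples = [f"s{i}" for i in range(n_samples)]
        a = pd.DataFrame(np.clip(true + noise(), 0, 1), index=probes, columns=samples)
        b = pd.DataFrame(np.clip(true + noise(), 0, 1), index=probes, columns=samples)
        table, summary = probewise_platform_correlation(a, b)
        table = table.set_index("probe_id")
        med_var = table.loc[[p for p in probes if p.startswith("var")], "r"].median()
        med_inv = table.loc[[p for p in probes if p.startswith("inv")], "r"].median()
        assert med_inv < med_var
        assert summary["range_vs_r_correlation"] > 0


class TestReplicateConcordance:
    def test_identical_replicates_all_zero(self):
        chrono = [30.0, 40.0]
        rows = []
        for s, d in zip(["a", "a_rep", "b", "b_rep"], [33.0, 33.0, 41.0, 41.0]):
            rows.append({"sample_id": s, "platform": "B", "preprocessing": "raw",
                         "clock": "clk", "dnam_age": d, "chronological_age": 30.0})
        est = AgeEstimateSet(pd.DataFrame(rows))
        out = replicate_concordance(est, {"g1": ["a", "a_rep"], "g2": ["b", "b_rep"]})
        assert (out["abs_diff"] == 0).all()

    def test_median_of_pair_differences(self):
        pairs = {"g1": ["a", "a2"], "g2": ["b", "b2"], "g3": ["c", "c2"]}
        ages = {"a": 30.0, "a2": 32.0, "b": 40.0, "b2": 41.0, "c": 50.0, "c2": 55.0}
        rows = [
            {"sample_id": s, "platform": "B", "preprocessing": "raw", "clock": "clk",
             "dnam_age": d, "chronological_age": 35.0}
            for s, d in ages.items()
        ]
        est = AgeEstimateSet(pd.DataFrame(rows))
        out = replicate_concordance(est, pairs)
        med = out[out["pair"] == "<median>"]["abs_diff"].iloc[0]
        assert med == pytest.approx(2.0)
        assert sorted(out[out["pair"] != "<median>"]["abs_diff"]) == [1.0, 2.0, 5.0]

    def test_singleton_group_warned_and_skipped(self):
        rows = [
            {"sample_id": s, "platform": "B", "preprocessing": "raw", "clock": "clk",
             "dnam_age": 30.0, "chronological_age": 30.0}
            for s in ["a", "b", "b2"]
        ]
        est = AgeEstimateSet(pd.DataFrame(rows))
        with pytest.warns(UserWarning, match="skipped"):
            out = replicate_concordance(est, {"g1": ["a"], "g2": ["b", "b2"]})
        assert (out[out["pair"] != "<median>"]["group"] == "g2").all()


def test_statistics_invariant_under_sample_permutation():
    rng = np.random.default_rng(11)
    x = rng.uniform(20, 60, 25)
    y = x + rng.normal(0, 2, 25)
    perm = rng.permutation(25)
    a = compare_estimates(x, y)
    b = compare_estimates(x[perm], y[perm])
    assert a["r"] == pytest.approx(b["r"])
    assert a["median_abs_diff"] == pytest.approx(b["median_abs_diff"])
    t1, _ = kendall_tau(x, y)
    t2, _ = kendall_tau(x[perm], y[perm])
    assert t1 == pytest.approx(t2)
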