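"""Preprocessing routes: noob, quantile, GenomeStudio-style, raw."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from epiclockbench import EpiclockError, compute_beta
from epiclockbench.clock import normexp_signal
from epiclockbench.preprocessing import (
    gs_correct,
    noob_correct,
    preprocess,
    preprocess_raw,
    quantile_normalize,
)
from epiclockbench.simulate import SimulationConfig, simulate_cohort, simulate_intensities


def normexp_posterior_mean_quad(x, mu_b, sigma_b, alpha):
    """Numerical-integration oracle for E[S | X=x], S~Exp(alpha), B~N(mu_b, sigma_b)."""

    def joint(s):
        return (1.0 / alpha) * np.exp(-s / alpha) * stats.norm.pdf(x - mu_b - s, 0, sigma_b)

    # finite interval with a breakpoint at the Gaussian peak so quad cannot
    # step over the (possibly very narrow) mass
    peak = max(x - mu_b, 0.0)
    hi = peak + 12 * sigma_b + 5 * alpha
    num, _ = integrate.quad(lambda s: s * joint(s), 0, hi, points=[peak], limit=400)
    den, _ = integrate.quad(joint, 0, hi, points=[peak], limit=400)
    return num / den


class TestNormexpPosteriorMean:
    @pytest.mark.parametrize(
        "x,mu_b,sigma_b,alpha",
        [
            (500.0, 500.0, 100.0, 3000.0),   # pure background
            (2000.0, 500.0, 100.0, 3000.0),  # clear signal
            (600.0, 500.0, 100.0, 500.0),    # weak signal, small alpha
            (300.0, 500.0, 100.0, 3000.0),   # below background mean
        ],
    )
    def test_matches_numerical_integration(self, x, mu_b, sigma_b, alpha):
        expected = normexp_posterior_mean_quad(x, mu_b, sigma_b, alpha)
        got = float(normexp_signal(x, mu_b, sigma_b, alpha))
        assert got == pytest.approx(expected, rel=1e-4)

    def test_pure_background_small_positive_below_sigma(self):
        for alpha in (10.0, 1000.0, 1e6):
            val = float(normexp_signal(500.0, 500.0, 100.0, alpha))
            assert 0 < val < 100.0

    def test_degenerate_noise_limit_is_plain_subtraction(self):
        assert float(normexp_signal(1500.0, 500.0, 0.0, 3000.0)) == pytest.approx(1000.0)

    def test_deep_background_tail_is_stable(self):
        # far below background: posterior mean tiny but positive, no overflow
        val = float(normexp_signal(0.0, 5000.0, 100.0, 3000.0))
        assert 0 < val < 10.0


@pytest.fixture(scope="module")
def noob_setup():
    cfg = SimulationConfig(
        n_subjects=30, n_invariant_cpgs=100, replicate_pairs=0, seed=21,
        signal_scale=3000.0, bg_mean=500.0, bg_sd=100.0,
    )
    _, truth = simulate_cohort(cfg)
    inten = simulate_intensities(truth, cfg, "A")
    return cfg, truth, inten


class TestNoob:
    def test_recovers_beta_better_than_raw(self, noob_setup):
        """Background correction must beat raw betas on the generative model."""
        cfg, truth, inten = noob_setup
        raw_beta = preprocess_raw(inten)
        corrected, params = noob_correct(inten)
        noob_beta = compute_beta(corrected)
        true = truth.true_beta.loc[raw_beta.index].to_numpy()
        rmse_raw = np.sqrt(np.nanmean((raw_beta.to_numpy() - true) ** 2))
        rmse_noob = np.sqrt(np.nanmean((noob_beta.to_numpy() - true) ** 2))
        assert rmse_noob < rmse_raw

    def test_fitted_background_parameters_sane(self, noob_setup):
        cfg, _, inten = noob_setup
        _, params = noob_correct(inten)
        assert params.table["mu_b"].between(cfg.bg_mean - 50, cfg.bg_mean + 50).all()
        assert params.table["sigma_b"].between(cfg.bg_sd * 0.5, cfg.bg_sd * 1.5).all()
        assert (params.table["alpha"] > 0).all()

    def test_corrected_intensities_positive(self, noob_setup):
        _, _, inten = noob_setup
        corrected, _ = noob_correct(inten)
        assert corrected.methylated.to_numpy().min() > 0
        assert corrected.unmethylated.to_numpy().min() > 0

    def test_per_sample_locality(self, noob_setup):
        """Adding an unrelated sample never changes another sample's output."""
        _, _, inten = noob_setup
        full, _ = noob_correct(inten)
        first = list(inten.sample_ids)[:5]
        sub = _subset_samples(inten, first)
        part, _ = noob_correct(sub)
        pd.testing.assert_frame_equal(part.methylated, full.methylated[first])

    def test_too_few_oob_draws_rejected(self, noob_setup):
        _, _, inten = noob_setup
        starved = inten.copy()
        starved.oob = {ch: df.iloc[:10] for ch, df in inten.oob.items()}
        with pytest.raises(EpiclockError, match="OOB draws"):
            noob_correct(starved)


def _subset_samples(inten, samples):
    out = inten.copy()
    out.methylated = out.methylated[samples]
    out.unmethylated = out.unmethylated[samples]
    out.oob = {ch: df[samples] for ch, df in out.oob.items()}
    if out.controls is not None:
        out.controls = out.controls[samples]
    return out


class TestQuantileNormalize:
    def test_three_point_definition(self):
        df = pd.DataFrame({"s1": [0.1, 0.2, 0.3], "s2": [0.2, 0.4, 0.6]},
                          index=["a", "b", "c"])
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["s1"], [0.15, 0.3, 0.45])
        np.testing.assert_allclose(out["s2"], [0.15, 0.3, 0.45])

    def test_identical_samples_fixed_point(self):
        rng = np.random.default_rng(3)
        col = rng.uniform(0, 1, 50)
        df = pd.DataFrame({"s1": col, "s2": col.copy(), "s3": col.copy()})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy(), atol=1e-12)

    def test_sorted_values_identical_across_samples(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(rng.uniform(0, 1, (1000, 10)),
                          columns=[f"s{i}" for i in range(10)])
        out = quantile_normalize(df)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        spread = sorted_cols.max(axis=1) - sorted_cols.min(axis=1)
        assert spread.max() < 1e-12

    def test_strata_normalized_separately(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.uniform(0, 1, (100, 4)))
        strata = pd.Series(["I"] * 50 + ["II"] * 50, index=df.index)
        out = quantile_normalize(df, strata=strata)
        for label in ("I", "II"):
            block = out.loc[strata == label].to_numpy()
            sorted_cols = np.sort(block, axis=0)
            assert (sorted_cols.max(axis=1) - sorted_cols.min(axis=1)).max() < 1e-12

    def test_missing_left_missing(self):
        df = pd.DataFrame({"s1": [0.1, np.nan, 0.3, 0.5], "s2": [0.2, 0.4, 0.6, 0.8]})
        out = quantile_normalize(df)
        assert np.isnan(out.loc[1, "s1"])
        assert out.notna().sum().sum() == 7

    def test_single_sample_identity_with_warning(self):
        df = pd.DataFrame({"s1": [0.1, 0.2]})
        with pytest.warns(UserWarning, match="single sample"):
            out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)


@pytest.fixture(scope="module")
def gs_setup():
    cfg = SimulationConfig(n_subjects=20, n_invariant_cpgs=80, replicate_pairs=0, seed=22)
    _, truth = simulate_cohort(cfg)
    return cfg, truth, simulate_intensities(truth, cfg, "A")


class TestGsCorrect:
    def test_shift_floor_and_scale_on_crafted_input(self):
        """Subtraction, flooring and the norm-control channel ratio, exactly."""
        from epiclockbench.core import IntensityData, Manifest

        probes = pd.Index(["cgG", "cgR"], name="probe_id")
        manifest = Manifest(
            pd.DataFrame(
                {"design_type": ["I", "I"], "color_channel": ["Grn", "Red"],
                 "probe_class": ["cg", "cg"]},
                index=probes,
            )
        )
        controls = pd.DataFrame(
            {"s0": [200.0, 200.0, 2000.0, 1000.0]},
            index=pd.MultiIndex.from_tuples(
                [("negative_control", "Grn", "n0"), ("negative_control", "Red", "n1"),
                 ("norm_control", "Grn", "m0"), ("norm_control", "Red", "m1")],
                names=["probe_class", "channel", "probe_id"],
            ),
        )
        inten = IntensityData(
            methylated=pd.DataFrame({"s0": [500.0, 500.0]}, index=probes),
            unmethylated=pd.DataFrame({"s0": [100.0, 100.0]}, index=probes),
            controls=controls,
            manifest=manifest,
        )
        out = gs_correct(inten)
        # Grn: (500-200)=300 then scaled by Red/Grn norm-control ratio:
        # corrected norm means are (2000-200)=1800 vs (1000-200)=800 -> 800/1800
        assert out.methylated.loc["cgG", "s0"] == pytest.approx(300 * 800 / 1800)
        # Red is the reference channel: plain subtraction
        assert out.methylated.loc["cgR", "s0"] == pytest.approx(300.0)
        # below-background observation floors at the positive constant
        assert out.unmethylated.loc["cgR", "s0"] == pytest.approx(1.0)

    def test_corrected_intensities_positive(self, gs_setup):
        _, _, inten = gs_setup
        out = gs_correct(inten)
        assert out.methylated.to_numpy().min() > 0
        assert out.unmethylated.to_numpy().min() > 0

    def test_beta_closer_to_truth_than_raw(self, gs_setup):
        cfg, truth, inten = gs_setup
        raw_beta = compute_beta(inten)
        gs_beta = compute_beta(gs_correct(inten))
        true = truth.true_beta.loc[raw_beta.index].to_numpy()
        rmse_raw = np.sqrt(np.nanmean((raw_beta.to_numpy() - true) ** 2))
        rmse_gs = np.sqrt(np.nanmean((gs_beta.to_numpy() - true) ** 2))
        assert rmse_gs < rmse_raw

    def test_per_sample_locality(self, gs_setup):
        _, _, inten = gs_setup
        full = gs_correct(inten)
        first = list(inten.sample_ids)[:4]
        part = gs_correct(_subset_samples(inten, first))
        pd.testing.assert_frame_equal(part.methylated, full.methylated[first])

    def test_missing_negative_controls_rejected(self, gs_setup):
        _, _, inten = gs_setup
        bare = inten.copy()
        bare.controls = None
        with pytest.raises(EpiclockError, match="control"):
            gs_correct(bare)


def test_all_methods_preserve_axes_and_ranges(small_intensities):
    for method in ("raw", "gs", "quantile", "noob"):
        beta = preprocess(small_intensities, method)
        assert beta.index.equals(small_intensities.probe_ids)
        assert beta.columns.equals(small_intensities.sample_ids)
        vals = beta.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1


def test_unknown_method_rejected(small_intensities):
    with pytest.raises(EpiclockError, match="unknown preprocessing"):
        preprocess(small_intensities, "swan")
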