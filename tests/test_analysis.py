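"""Triad analysis: OLS/closed-form identity, residuals, bootstrap, verdict."""

import numpy as np
import pandas as pd
import pytest

from resconfound import (
    AdjustedEffect,
    AdjustedEffects,
    DiffScoreResult,
    LatentSpec,
    adjudicate,
    adjusted_effects_all,
    correlation_triad,
    difference_score_regression,
    generate_latent_triad,
    partial_beta,
    population_partial_oracle,
    residual_scatter,
)
from resconfound.analysis import EFFECT_ORDER


def _triad_frame(n, rho, rng):
    z = rng.standard_normal((n, 3)) @ np.linalg.cholesky(rho).T
    return pd.DataFrame({"seb": z[:, 0], "ca": z[:, 1], "edu": z[:, 2]})


@pytest.fixture
def sample_frame(rng):
    rho = np.array([[1, 0.4, 0.3], [0.4, 1, 0.5], [0.3, 0.5, 1]])
    return _triad_frame(2000, rho, rng)


class TestCorrelationTriad:
    def test_listwise_equals_pairwise_on_complete_data(self, sample_frame):
        a = correlation_triad(sample_frame, policy="listwise")
        b = correlation_triad(sample_frame, policy="pairwise")
        assert (a.r_sc, a.r_sd, a.r_cd) == (b.r_sc, b.r_sd, b.r_cd)
        assert a.n == b.n == len(sample_frame)

    def test_policies_differ_with_missingness(self, sample_frame):
        df = sample_frame.copy()
        df.loc[:200, "edu"] = np.nan
        a = correlation_triad(df, policy="listwise")
        b = correlation_triad(df, policy="pairwise")
        assert a.r_sc != b.r_sc  # seb-ca pair keeps the rows listwise drops
        assert a.n < len(df)

    def test_collinear_pair_still_psd(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"seb": x, "ca": 2 * x + 1, "edu": rng.standard_normal(100)})
        t = correlation_triad(df)
        assert t.r_sc == pytest.approx(1.0)

    def test_constant_column_rejected(self, rng):
        df = pd.DataFrame({"seb": np.ones(50), "ca": rng.standard_normal(50),
                           "edu": rng.standard_normal(50)})
        with pytest.raises(ValueError):
            correlation_triad(df)

    def test_calibrated_generator_recovers_printed_correlations(self, calibrated_spec):
        d = generate_latent_triad(calibrated_spec(n=100_000, seed=1)).derived()
        t = correlation_triad(d)
        assert t.r_sc == pytest.approx(0.395, abs=0.01)
        assert t.r_sd == pytest.approx(0.353, abs=0.01)
        assert t.r_cd == pytest.approx(0.508, abs=0.01)


class TestAdjustedEffects:
    def test_null_world_gives_null_betas(self, rng):
        df = _triad_frame(50_000, np.eye(3), rng)
        eff = adjusted_effects_all(df, B=0)
        assert all(abs(e.beta) < 0.02 for e in eff.effects)

    def test_betas_equal_closed_form_partials(self, sample_frame):
        """OLS on standardized variables is algebraically the correlation-matrix
        closed form — exact on the same complete-case sample."""
        eff = adjusted_effects_all(sample_frame, B=0)
        t = correlation_triad(sample_frame)
        lookup = {"seb": {"ca": t.r_sc, "edu": t.r_sd}, "ca": {"seb": t.r_sc, "edu": t.r_cd},
                  "edu": {"seb": t.r_sd, "ca": t.r_cd}}
        for e in eff.effects:
            expected = partial_beta(
                lookup[e.predictor][e.outcome],
                lookup[e.predictor][e.adjuster],
                lookup[e.outcome][e.adjuster],
            )
            assert e.beta == pytest.approx(expected, abs=1e-10)

    def test_betas_equal_explicit_ols(self, sample_frame):
        eff = adjusted_effects_all(sample_frame, B=0)
        arr = sample_frame.to_numpy()
        z = (arr - arr.mean(0)) / arr.std(0)
        cols = dict(zip(("seb", "ca", "edu"), z.T))
        for e in eff.effects:
            X = np.column_stack([cols[e.predictor], cols[e.adjuster]])
            coef = np.linalg.lstsq(X, cols[e.outcome], rcond=None)[0]
            assert e.beta == pytest.approx(coef[0], abs=1e-10)

    def test_bootstrap_ci_brackets_beta_and_is_seeded(self, sample_frame):
        a = adjusted_effects_all(sample_frame, B=200, seed=5)
        b = adjusted_effects_all(sample_frame, B=200, seed=5)
        c = adjusted_effects_all(sample_frame, B=200, seed=6)
        assert [e.ci_low for e in a.effects] == [e.ci_low for e in b.effects]
        assert [e.ci_low for e in a.effects] != [e.ci_low for e in c.effects]
        for e in a.effects:
            assert e.ci_low <= e.beta <= e.ci_high

    def test_collinearity_rejected(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"seb": x, "ca": x, "edu": rng.standard_normal(100)})
        with pytest.raises(ValueError):
            adjusted_effects_all(df, B=0)

    def test_bootstrap_coverage_of_population_partial(self, calibrated_spec):
        """Percentile-bootstrap 95% CI for the SEB->Edu|CA effect covers the
        population value in roughly 95% of replications."""
        spec0 = calibrated_spec()
        target = population_partial_oracle(spec0, "edu_obs", "seb_obs", "ca_obs")
        covered = 0
        reps = 500
        for i in range(reps):
            spec = LatentSpec(**{**spec0.to_dict(), "n": 1000, "seed": 10_000 + i})
            d = generate_latent_triad(spec).derived()
            e = adjusted_effects_all(d, B=600, seed=i).get(outcome="edu", predictor="seb")
            covered += e.ci_low <= target <= e.ci_high
        assert 0.93 <= covered / reps <= 0.97


class TestResidualScatter:
    def test_residual_correlation_is_partial_correlation(self, sample_frame):
        out = residual_scatter(sample_frame, ("ca", "edu"), "seb")
        r_res = np.corrcoef(out["residual_ca"], out["residual_edu"])[0, 1]
        t = correlation_triad(sample_frame)
        expected = (t.r_cd - t.r_sc * t.r_sd) / np.sqrt((1 - t.r_sc**2) * (1 - t.r_sd**2))
        assert r_res == pytest.approx(expected, abs=1e-12)

    def test_residuals_orthogonal_to_adjuster(self, sample_frame):
        out = residual_scatter(sample_frame, ("seb", "edu"), "ca")
        arr = sample_frame.to_numpy()
        z = (arr[:, 1] - arr[:, 1].mean()) / arr[:, 1].std()
        assert abs(out["residual_seb"] @ z) < 1e-10 * len(z)
        assert abs(out["residual_edu"] @ z) < 1e-10 * len(z)

    def test_uncorrelated_adjuster_leaves_raw_correlation(self, rng):
        n = 200_000
        rho = np.array([[1, 0.5, 0], [0.5, 1, 0], [0, 0, 1]])
        df = _triad_frame(n, rho, rng)
        out = residual_scatter(df, ("seb", "ca"), "edu")
        raw = np.corrcoef(df["seb"], df["ca"])[0, 1]
        res = np.corrcoef(out["residual_seb"], out["residual_ca"])[0, 1]
        assert res == pytest.approx(raw, abs=0.005)

    def test_bad_trait_names_rejected(self, sample_frame):
        with pytest.raises(ValueError):
            residual_scatter(sample_frame, ("seb", "ca"), "seb")


class TestDifferenceScoreRegression:
    def test_identical_components_give_zero(self, rng):
        x = rng.standard_normal(1000)
        df = pd.DataFrame({"seb": rng.standard_normal(1000), "ca": x, "edu": x})
        res = difference_score_regression(df, B=0)
        assert res.beta == pytest.approx(0.0, abs=1e-12)

    def test_beta_is_correlation_difference(self, sample_frame):
        t = correlation_triad(sample_frame)
        res = difference_score_regression(sample_frame, B=200, seed=3)
        assert res.beta == pytest.approx(t.r_sd - t.r_sc, abs=1e-12)

    def test_calibrated_world_matches_printed_interval(self, calibrated_spec):
        """Population beta from the printed correlations is -0.042, inside the
        study's printed CI (-0.081, -0.021)."""
        d = generate_latent_triad(calibrated_spec(n=200_000, seed=8)).derived()
        res = difference_score_regression(d, B=0)
        assert res.beta == pytest.approx(0.353 - 0.395, abs=0.01)
        assert -0.081 < res.beta < -0.021

    def test_discrimination_world_gives_positive_beta(self):
        spec = LatentSpec(
            n=100_000,
            rho_true=((1, 0.2, 0.0), (0.2, 1, 0.5), (0.0, 0.5, 1)),
            rel=(1, 1, 1),
            scenario="discrimination",
            direct_effect=0.5,
            seed=17,
        )
        d = generate_latent_triad(spec).derived()
        res = difference_score_regression(d, B=0)
        assert res.ci_low > 0


def _make_effects(betas, half=0.03):
    effects = tuple(
        AdjustedEffect(outcome=y, predictor=x, adjuster=z,
                       beta=b, ci_low=b - half, ci_high=b + half)
        for (y, x, z), b in zip(EFFECT_ORDER, betas)
    )
    return AdjustedEffects(effects=effects, n_analysis=1000)


class TestAdjudication:
    def test_all_positive_with_negative_diff_is_residual_confounding(self):
        eff = _make_effects([0.25, 0.18, 0.29, 0.44, 0.21, 0.42])
        diff = DiffScoreResult(beta=-0.051, ci_low=-0.081, ci_high=-0.021, n=4654)
        out = adjudicate(eff, diff)
        assert out.verdict == "residual_confounding_consistent"
        assert len(out.evidence) == 7

    def test_negative_reversal_with_positive_diff_is_discrimination(self):
        betas = [-0.2 if (y, x) == ("ca", "seb") else 0.2 for (y, x, z) in EFFECT_ORDER]
        eff = _make_effects(betas)
        diff = DiffScoreResult(beta=0.2, ci_low=0.1, ci_high=0.3, n=1000)
        assert adjudicate(eff, diff).verdict == "discrimination_consistent"

    def test_straddling_ci_on_decisive_contrast_is_inconclusive(self):
        eff = _make_effects([0.25, 0.01, 0.29, 0.44, 0.21, 0.42])  # edu|seb CI straddles 0
        diff = DiffScoreResult(beta=-0.05, ci_low=-0.08, ci_high=-0.02, n=1000)
        assert adjudicate(eff, diff).verdict == "inconclusive"

    def test_positive_diff_blocks_residual_confounding_verdict(self):
        eff = _make_effects([0.25, 0.18, 0.29, 0.44, 0.21, 0.42])
        diff = DiffScoreResult(beta=0.2, ci_low=0.1, ci_high=0.3, n=1000)
        assert adjudicate(eff, diff).verdict == "inconclusive"

    def test_verdict_is_pure_function_of_evidence(self):
        eff = _make_effects([0.25, 0.18, 0.29, 0.44, 0.21, 0.42])
        diff = DiffScoreResult(beta=-0.05, ci_low=-0.08, ci_high=-0.02, n=1000)
        assert adjudicate(eff, diff).verdict == adjudicate(eff, diff).verdict
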