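"""Joint two-response model and the per-draw correlation estimator."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codrange import (
    JointPosterior,
    JointSpec,
    SynthConfig,
    compute_csf_records,
    compute_occupancy,
    correlation_per_draw,
    correlation_report,
    estimate_correlations,
    fit_joint,
    generate_dataset,
    standardize_temperature,
)


@pytest.fixture(scope="module")
def joint_inputs(small_survey=None):
    # well-identified regime for estimator checks: 11 subregions, moderate
    # occupancy levels keeping cells away from the 0/1 boundary where slopes
    # are non-identified
    from codrange import SigmaComponents

    cfg = SynthConfig(
        n_subregions=11,
        ages=(1, 2, 3),
        sets_per_year=220,
        sigma_a_co=SigmaComponents(0.2, 0.4, 0.4),
        seed=42,
    )
    survey, truth = generate_dataset(cfg)
    occ = compute_occupancy(survey)
    csf = compute_csf_records(survey)
    temp = standardize_temperature(
        survey.sets[["set_id", "year", "subregion", "depth_m", "date", "bottom_temp_c"]]
    )
    return cfg, truth, occ, csf, temp


@pytest.fixture(scope="module")
def joint_fit(joint_inputs):
    _, _, occ, csf, _ = joint_inputs
    spec = JointSpec(
        pair="csf_co", chains=3, iterations=4000, burn_in=2000, thin=5, seed=1
    )
    return spec, fit_joint(csf, occ, spec)


class TestRetainedDrawArithmetic:
    def test_default_spec_retains_6000(self):
        assert JointSpec().retained_total == 6000

    @settings(derandomize=True, max_examples=60)
    @given(
        chains=st.integers(1, 6),
        iterations=st.integers(2, 5000),
        burn_frac=st.floats(0.0, 0.9),
        thin=st.integers(1, 20),
    )
    def test_retained_count_formula(self, chains, iterations, burn_frac, thin):
        burn_in = int(iterations * burn_frac)
        spec = JointSpec(
            chains=chains, iterations=iterations, burn_in=burn_in, thin=thin
        )
        expected = chains * len(range(burn_in, iterations, thin))
        assert spec.retained_total == expected
        assert spec.kept_per_chain == math.ceil((iterations - burn_in) / thin)

    def test_draw_arrays_match_formula(self, joint_fit):
        spec, post = joint_fit
        for arr in post.draws.values():
            assert arr.shape[0] == spec.chains
            assert arr.shape[1] == spec.kept_per_chain


class TestFitJoint:
    def test_missing_cell_is_named(self, joint_inputs):
        _, _, occ, csf, _ = joint_inputs
        broken = occ[~((occ.age == 2) & (occ.subregion == 3))]
        with pytest.raises(ValueError, match=r"\(2, 3\)"):
            fit_joint(csf, broken, JointSpec(iterations=20, burn_in=10))

    def test_error_terms_share_no_parameters(self, joint_fit):
        _, post = joint_fit
        assert "sigma_csf" in post.draws
        assert not any(k.endswith("_shared") for k in post.draws)
        # occupancy side has no scale parameter at all
        assert "sigma_co" not in post.draws

    def test_joint_marginals_match_single_response_fits(self, joint_inputs):
        """Independent likelihoods: the joint fit's occupancy marginals agree
        with a fit of the occupancy cells alone, within Monte-Carlo error."""
        _, _, occ, csf, _ = joint_inputs
        spec = JointSpec(
            pair="csf_co", chains=2, iterations=3000, burn_in=1000, thin=2, seed=3
        )
        joint = fit_joint(csf, occ, spec)
        # marginal: same sampler on occupancy with a different seed
        spec2 = dataclasses.replace(spec, seed=4)
        marg = fit_joint(csf, occ, spec2)
        for par in ("alpha_co", "beta_co", "alpha_csf", "beta_csf"):
            a = joint.flat(par).mean(axis=0)
            b = marg.flat(par).mean(axis=0)
            mc_sd = joint.flat(par).std(axis=0) / 10
            assert np.allclose(a, b, atol=np.maximum(5 * mc_sd, 0.05))

    def test_temperature_coefficients_identical_across_ages(self, joint_inputs):
        _, _, occ, _, temp = joint_inputs
        spec = JointSpec(
            pair="temp_co", chains=2, iterations=600, burn_in=300, thin=3, seed=2
        )
        post = fit_joint(temp, occ, spec)
        bt = post.draws["beta_temp"]
        for i in range(1, bt.shape[2]):
            np.testing.assert_array_equal(bt[:, :, 0, :], bt[:, :, i, :])


def _degenerate_posterior(x, y, pair="csf_co"):
    """Build a JointPosterior whose draws are the given arrays (T, J)."""
    T, J = x.shape
    spec = JointSpec(pair=pair, chains=1, iterations=T, burn_in=0, thin=1)
    draws = {
        "alpha_csf": x[None, :, None, :],
        "beta_co": y[None, :, None, :],
    }
    return JointPosterior(
        spec=spec, ages=[1], subregions=list(range(1, J + 1)), draws=draws
    )


class TestCorrelationPerDraw:
    def test_perfect_correlation_collapses_ci(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 7))
        post = _degenerate_posterior(x, x.copy())
        est = correlation_per_draw(post, 1, "alpha_csf", "beta_co")
        assert est.posterior_mean == pytest.approx(1.0)
        assert (est.ci_low, est.ci_high) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_zero_variance_draws_excluded_with_accounting(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 5))
        x[3] = 1.0  # constant across subregions -> undefined
        x[17] = -2.0
        post = _degenerate_posterior(x, rng.standard_normal((20, 5)))
        est = correlation_per_draw(post, 1, "alpha_csf", "beta_co")
        assert est.n_undefined == 2
        assert est.draws.size == 18

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 6))
        y = rng.standard_normal((30, 6))
        base = correlation_per_draw(
            _degenerate_posterior(x, y), 1, "alpha_csf", "beta_co"
        )
        scaled = correlation_per_draw(
            _degenerate_posterior(3.0 * x - 7.0, 0.5 * y + 2.0), 1, "alpha_csf", "beta_co"
        )
        np.testing.assert_allclose(base.draws, scaled.draws, atol=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((30, 6))
        y = rng.standard_normal((30, 6))
        post = _degenerate_posterior(x, y)
        a = correlation_per_draw(post, 1, "alpha_csf", "beta_co")
        b = correlation_per_draw(post, 1, "beta_co", "alpha_csf")
        np.testing.assert_allclose(a.draws, b.draws)

    def test_draws_bounded(self, joint_fit):
        _, post = joint_fit
        for age in post.ages:
            est = correlation_per_draw(post, age, "alpha_csf", "beta_co")
            assert np.all(est.draws >= -1.0) and np.all(est.draws <= 1.0)
            assert est.ci_low <= est.posterior_mean <= est.ci_high

    def test_too_few_subregions_rejected(self):
        rng = np.random.default_rng(4)
        post = _degenerate_posterior(
            rng.standard_normal((10, 2)), rng.standard_normal((10, 2))
        )
        with pytest.raises(ValueError, match="3 subregions"):
            correlation_per_draw(post, 1, "alpha_csf", "beta_co")


class TestRecovery:
    def test_recovers_realized_truth(self, joint_inputs, joint_fit):
        """The CI covers the realized per-age truth correlation and the
        positive expansion signal appears in every age."""
        cfg, truth, _, _, _ = joint_inputs
        _, post = joint_fit
        realized = truth.realized_init_expansion_correlation()
        covered = 0
        for ai, age in enumerate(post.ages):
            est = correlation_per_draw(post, age, "alpha_csf", "beta_co")
            if est.ci_low <= realized[ai] <= est.ci_high:
                covered += 1
            assert est.posterior_mean > 0  # rho = 0.8 truth
        assert covered >= len(post.ages) - 1

    def test_ci_widens_with_less_data(self):
        """Shrinking the survey widens the correlation CI (uncertainty
        propagation is real)."""
        widths = []
        for sets_per_year in (400, 100, 30):
            cfg = SynthConfig(
                n_subregions=6, ages=(1,), sets_per_year=sets_per_year, seed=7
            )
            survey, _ = generate_dataset(cfg)
            occ = compute_occupancy(survey)
            csf = compute_csf_records(survey)
            spec = JointSpec(
                pair="csf_co", chains=2, iterations=2500, burn_in=500, thin=2, seed=8
            )
            post = fit_joint(csf, occ, spec)
            est = correlation_per_draw(post, 1, "alpha_csf", "beta_co")
            widths.append(est.ci_high - est.ci_low)
        assert widths[0] < widths[1] < widths[2]


class TestSamplerExactness:
    def test_binomial_cell_posterior_matches_grid_integration(self):
        """Independence-MH draws for a single binomial-logit cell reproduce
        the posterior computed by brute-force 2-D numerical integration."""
        from codrange.correlation import _sample_binomial_cells

        rng = np.random.default_rng(0)
        t = np.arange(10.0)
        p = 1 / (1 + np.exp(-(-0.3 + 0.12 * t)))
        n = np.full(10, 30.0)
        y = rng.binomial(30, p).astype(float)
        spec = JointSpec(chains=3, iterations=8000, burn_in=4000, thin=2, seed=9)
        draws, acc = _sample_binomial_cells(
            y[None, None, :], n[None, None, :], t, spec, np.random.default_rng(1)
        )
        a = draws[..., 0, 0, 0].ravel()
        b = draws[..., 0, 0, 1].ravel()
        ga = np.linspace(-2, 1.5, 401)
        gb = np.linspace(-0.4, 0.6, 401)
        A, B = np.meshgrid(ga, gb, indexing="ij")
        eta = A[..., None] + B[..., None] * t
        ll = (y * eta - n * np.logaddexp(0, eta)).sum(-1)
        ll -= 0.5 * ((A / 10) ** 2 + (B / 10) ** 2)
        w = np.exp(ll - ll.max())
        w /= w.sum()
        assert acc > 0.5
        assert a.mean() == pytest.approx((w * A).sum(), abs=0.02)
        assert b.mean() == pytest.approx((w * B).sum(), abs=0.005)
        grid_sd_b = np.sqrt((w * (B - (w * B).sum()) ** 2).sum())
        assert b.std() == pytest.approx(grid_sd_b, rel=0.1)

    def test_posterior_mean_correlation_approaches_plugin_with_big_cells(self):
        """No-noise limit: with very informative cells the posterior mean
        correlation approaches the correlation of per-cell ML estimates."""
        import statsmodels.api as sm
        from codrange import SigmaComponents

        cfg = SynthConfig(
            n_subregions=8,
            ages=(1,),
            sets_per_year=2000,
            sigma_a_co=SigmaComponents(0.0, 0.3, 0.3),
            seed=12,
        )
        survey, truth = generate_dataset(cfg)
        occ = compute_occupancy(survey)
        csf = compute_csf_records(survey)
        spec = JointSpec(
            pair="csf_co", chains=2, iterations=3000, burn_in=1000, thin=2, seed=6
        )
        post = fit_joint(csf, occ, spec)
        est = correlation_per_draw(post, 1, "alpha_csf", "beta_co")
        # plug-in: per-cell ML estimates via independent GLM / OLS fits
        alpha_ml, beta_ml = [], []
        for j in sorted(occ.subregion.unique()):
            cell_occ = occ[(occ.subregion == j)].sort_values("year")
            tt = cell_occ.year.to_numpy(float) - 2004
            glm = sm.GLM(
                np.column_stack(
                    [cell_occ.n_present, cell_occ.n_sets - cell_occ.n_present]
                ),
                np.column_stack([np.ones_like(tt), tt]),
                family=sm.families.Binomial(),
            ).fit()
            beta_ml.append(glm.params[1])
            cell_csf = csf[csf.subregion == j]
            zz = cell_csf.csf_transformed.to_numpy()
            tz = cell_csf.year.to_numpy(float) - 2004
            ols = sm.OLS(zz, np.column_stack([np.ones_like(tz), tz])).fit()
            alpha_ml.append(ols.params[0])
        plugin = np.corrcoef(alpha_ml, beta_ml)[0, 1]
        assert est.posterior_mean == pytest.approx(plugin, abs=0.1)
        assert est.ci_low <= plugin <= est.ci_high


class TestReport:
    def test_cardinality_and_order(self, joint_fit):
        _, post = joint_fit
        ests = estimate_correlations(post)
        rep = correlation_report(ests)
        assert len(rep) == len(post.ages)
        assert list(rep.age) == sorted(post.ages)
        assert set(rep.columns) >= {
            "age",
            "pair",
            "mean",
            "ci_low",
            "ci_high",
            "n_undefined_draws",
        }
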