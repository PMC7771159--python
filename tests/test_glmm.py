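"""Hierarchical trend models: design assembly, recovery, and representations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codrange import (
    GlmmSpec,
    RandomStructure,
    SigmaComponents,
    SynthConfig,
    build_design,
    compare_models,
    compute_csf_records,
    compute_occupancy,
    fit_glmm,
    generate_dataset,
)


class TestSpec:
    def test_burn_in_must_be_smaller_than_iterations(self):
        with pytest.raises(ValueError, match="burn_in"):
            GlmmSpec(iterations=100, burn_in=100)

    def test_link_forced_by_response(self):
        assert GlmmSpec(response="occupancy").link == "logit"
        assert GlmmSpec(response="csf").link == "identity"

    def test_intercept_only_structure_is_representable(self):
        # slopes can be switched off, but slopes-without-intercepts cannot be
        # expressed: random_slopes=False yields intercept-only effects.
        spec = GlmmSpec(random_slopes=False)
        assert not spec.random_slopes


class TestBuildDesign:
    def test_year_2004_maps_to_zero(self, small_occupancy):
        spec = GlmmSpec(response="occupancy")
        design = build_design(small_occupancy, spec)
        assert design.t.min() == 0.0
        assert (
            design.t[small_occupancy.reset_index().year == 2004] == 0.0
        ).all()

    def test_interaction_cells_product_count(self, small_occupancy):
        design = build_design(small_occupancy, GlmmSpec(response="occupancy"))
        assert design.factors[0].n_levels == 3 * 5  # ages x subregions

    def test_none_structure_has_no_factors(self, small_occupancy):
        design = build_design(
            small_occupancy,
            GlmmSpec(response="occupancy", random_structure="none"),
        )
        assert design.factors == []

    def test_additive_structure_has_two_factors(self, small_occupancy):
        design = build_design(
            small_occupancy,
            GlmmSpec(response="occupancy", random_structure="age_plus_subregion"),
        )
        assert [f.n_levels for f in design.factors] == [3, 5]

    def test_missing_label_rejected(self, small_occupancy):
        broken = small_occupancy.copy()
        broken.loc[0, "subregion"] = np.nan
        with pytest.raises(ValueError, match="subregion"):
            build_design(broken, GlmmSpec(response="occupancy"))

    def test_nonpositive_trials_rejected(self, small_occupancy):
        broken = small_occupancy.copy()
        broken.loc[0, "n_sets"] = 0
        with pytest.raises(ValueError, match="trial"):
            build_design(broken, GlmmSpec(response="occupancy"))

    def test_autoscale_rule(self, small_csf):
        spec = GlmmSpec(response="csf", autoscale=True)
        design = build_design(small_csf, spec)
        z = small_csf.csf_transformed.to_numpy()
        t = small_csf.year.to_numpy(float) - 2004
        assert design.prior_sds[0] == pytest.approx(10 * z.std())
        assert design.prior_sds[1] == pytest.approx(2.5 * z.std() / t.std())


class TestGaussianFit:
    def test_noiseless_linear_data_matches_ols(self):
        """Identity-link fit without random effects lands on the OLS slope."""
        import statsmodels.api as sm

        years = np.repeat(np.arange(2004, 2014), 30)
        z = -1.0 + 0.07 * (years - 2004)
        df = pd.DataFrame(
            {
                "year": years,
                "subregion": 1,
                "age": 1,
                "csf_transformed": z + np.random.default_rng(0).normal(0, 0.05, z.size),
            }
        )
        spec = GlmmSpec(
            response="csf",
            random_structure="none",
            chains=2,
            iterations=600,
            burn_in=300,
            seed=1,
        )
        post, _ = fit_glmm(df, spec)
        x = sm.add_constant(df.year - 2004)
        ols = sm.OLS(df.csf_transformed, x).fit()
        beta = post.draws["beta"]
        assert beta.mean() == pytest.approx(ols.params.iloc[1], abs=3 * beta.std())

    def test_zero_slope_variance_truth_detected(self):
        """Data generated with no slope variation concentrate sigma_b near 0."""
        cfg = SynthConfig(
            n_subregions=6,
            ages=(1, 2, 3),
            sets_per_year=200,
            sigma_a_csf=SigmaComponents(0.0, 0.0, 0.5),
            sigma_b_csf=SigmaComponents(0.0, 0.0, 0.0),
            prob_empty_stomach=0.0,
            seed=8,
        )
        survey, _ = generate_dataset(cfg)
        csf = compute_csf_records(survey)
        spec = GlmmSpec(
            response="csf", chains=2, iterations=800, burn_in=400, seed=2
        )
        post, _ = fit_glmm(csf, spec)
        sigma_b = np.median(post.draws["sigma_b_age_by_subregion"])
        assert sigma_b < 0.5 / 10  # generator sigma_a / 10


class TestBinomialFit:
    def test_parameter_recovery_coverage(self, interaction_only_config):
        """95% credible intervals for alpha and beta cover the generator truth
        in nearly all replicates (interaction-structured truth)."""
        import dataclasses

        hits_alpha = hits_beta = 0
        n_rep = 8
        for rep in range(n_rep):
            cfg = dataclasses.replace(interaction_only_config, seed=500 + rep)
            survey, truth = generate_dataset(cfg)
            occ = compute_occupancy(survey)
            spec = GlmmSpec(
                response="occupancy",
                chains=2,
                iterations=700,
                burn_in=350,
                seed=900 + rep,
            )
            post, _ = fit_glmm(occ, spec)
            a = post.draws["alpha"].ravel()
            b = post.draws["beta"].ravel()
            if np.quantile(a, 0.025) <= cfg.alpha_co <= np.quantile(a, 0.975):
                hits_alpha += 1
            if np.quantile(b, 0.025) <= cfg.beta_co <= np.quantile(b, 0.975):
                hits_beta += 1
        assert hits_alpha >= n_rep - 2
        assert hits_beta >= n_rep - 2

    def test_bernoulli_and_aggregated_representations_agree(self):
        """Set-level Bernoulli rows and aggregated binomial cells differ only
        by a constant in the likelihood: posteriors agree in distribution."""
        cfg = SynthConfig(
            n_subregions=3, ages=(1, 2), sets_per_year=60, seed=31
        )
        survey, _ = generate_dataset(cfg)
        occ = compute_occupancy(survey)
        # set-level representation: one Bernoulli row per (set, age)
        rows = []
        for age in (1, 2):
            sub = survey.sets[["year", "subregion", f"present_age{age}"]]
            rows.append(
                sub.rename(columns={f"present_age{age}": "n_present"}).assign(
                    age=age, n_sets=1
                )
            )
        bern = pd.concat(rows, ignore_index=True)
        spec = dict(
            response="occupancy", chains=2, iterations=1200, burn_in=200, seed=5
        )
        post_cell, _ = fit_glmm(occ, GlmmSpec(**spec))
        post_set, _ = fit_glmm(bern, GlmmSpec(**{**spec, "seed": 6}))
        for par in ("alpha", "beta"):
            d = stats.ks_2samp(
                post_cell.draws[par].ravel(), post_set.draws[par].ravel()
            ).statistic
            assert d < 0.1

    def test_failed_block_is_reported(self):
        # a single-cell, single-year dataset starves the sampler blocks
        df = pd.DataFrame(
            {
                "year": [2004],
                "subregion": [1],
                "age": [1],
                "n_sets": [5],
                "n_present": [3],
            }
        )
        spec = GlmmSpec(
            response="occupancy", chains=2, iterations=50, burn_in=10, seed=0
        )
        post, diag = fit_glmm(df, spec)  # must either work or raise loudly
        assert np.isfinite(post.draws["alpha"]).all()


class TestModelLadder:
    def test_interaction_variation_ranked_above_pooled(self):
        cfg = SynthConfig(
            n_subregions=5,
            ages=(1, 2, 3),
            sets_per_year=150,
            sigma_a_co=SigmaComponents(0.0, 0.0, 0.8),
            sigma_b_co=SigmaComponents(0.0, 0.0, 0.25),
            seed=3,
        )
        survey, _ = generate_dataset(cfg)
        occ = compute_occupancy(survey)
        common = dict(response="occupancy", chains=2, iterations=800, burn_in=400)
        full, _ = fit_glmm(occ, GlmmSpec(random_structure="age_by_subregion", seed=1, **common))
        none, _ = fit_glmm(occ, GlmmSpec(random_structure="none", seed=2, **common))
        table = compare_models({"age_by_subregion": full, "none": none})
        assert table.iloc[0].model == "age_by_subregion"
        # the preference is decisive, not within noise
        row = table[table.model == "none"].iloc[0]
        assert row.d_elpd_loo < -2 * row.d_se

    def test_no_spurious_preference_without_group_variation(self):
        cfg = SynthConfig(
            n_subregions=5,
            ages=(1, 2, 3),
            sets_per_year=150,
            sigma_a_co=SigmaComponents(),
            sigma_b_co=SigmaComponents(),
            seed=4,
        )
        survey, _ = generate_dataset(cfg)
        occ = compute_occupancy(survey)
        common = dict(response="occupancy", chains=2, iterations=800, burn_in=400)
        full, _ = fit_glmm(occ, GlmmSpec(random_structure="age_by_subregion", seed=1, **common))
        none, _ = fit_glmm(occ, GlmmSpec(random_structure="none", seed=2, **common))
        table = compare_models({"age_by_subregion": full, "none": none})
        worse = table.iloc[1]
        assert abs(worse.d_elpd_loo) <= 2 * max(worse.d_se, 1.0)

    def test_healthy_fit_diagnostics(self, small_occupancy):
        spec = GlmmSpec(
            response="occupancy", chains=4, iterations=600, burn_in=300, seed=11
        )
        _, diag = fit_glmm(small_occupancy, spec)
        assert diag.max_rhat < 1.02
        assert diag.min_ess > 100
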