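"""Joint-model checks: gradient exactness, fast-kernel agreement, design
construction, determinism, and the held-out family likelihood oracle."""

import numpy as np
import pytest

from dyadconflict.irt import ItemParameters, pattern_loglik
from dyadconflict.model import (
    JointModel,
    ModelOptions,
    ModelSpec,
    SamplerConfig,
    build_predictor_matrix,
    conditional_mean_impute,
    fit_joint,
    loglik_family,
)

VARIANTS = [
    ("M3_interpersonal", ModelOptions()),
    ("M4_interpersonal_gender", ModelOptions()),
    ("M2_depression_gender", ModelOptions(likelihood="normal", theta_anchor=True)),
    ("M1_depression", ModelOptions(likelihood="t", fix_nu=4.0, fix_sigma=0.7, fix_tau=0.3)),
]


def _model_for(variant, matrix, y):
    model_id, opts = variant
    return JointModel(ModelSpec(model_id), matrix, y, options=opts)


@pytest.mark.parametrize("variant", VARIANTS, ids=[v[0] + "/" + v[1].likelihood for v in VARIANTS])
def test_reference_gradient_matches_finite_differences(variant, small_matrix, small_items):
    model = _model_for(variant, small_matrix, small_items)
    rng = np.random.default_rng(0)
    v = model.initial_point(rng) + rng.normal(0, 0.3, model.dim)
    _, g = model.logp_grad_reference(v)
    eps = 1e-6
    idx = rng.choice(model.dim, size=min(40, model.dim), replace=False)
    for i in idx:
        vp, vm = v.copy(), v.copy()
        vp[i] += eps
        vm[i] -= eps
        num = (model.logp_grad_reference(vp)[0] - model.logp_grad_reference(vm)[0]) / (2 * eps)
        assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-5)


@pytest.mark.parametrize("variant", VARIANTS, ids=[v[0] + "/" + v[1].likelihood for v in VARIANTS])
def test_fast_kernel_agrees_with_reference(variant, small_matrix, small_items):
    model = _model_for(variant, small_matrix, small_items)
    rng = np.random.default_rng(1)
    for _ in range(3):
        v = model.initial_point(rng) + rng.normal(0, 0.5, model.dim)
        lp_ref, g_ref = model.logp_grad_reference(v)
        lp_fast, g_fast = model.logp_grad(v)
        assert lp_fast == pytest.approx(lp_ref, abs=1e-8)
        np.testing.assert_allclose(g_fast, g_ref, atol=1e-7)


class TestPredictorMatrix:
    def test_age_centering_and_dummy(self, small_study, small_scores):
        ds, _ = small_study
        mat = build_predictor_matrix(ds, small_scores)
        adol = ds.adolescent_by_family()
        parents = ds.parent_by_id()
        for i, (fam, pid) in enumerate(zip(mat.family_ids, mat.parent_ids)):
            assert mat.age_centered[i] == adol[fam].age_years - 15
            assert mat.mother[i] == (1.0 if parents[pid].gender == "mother" else 0.0)

    def test_continuous_predictors_standardized(self, small_matrix):
        x = small_matrix.x
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0, ddof=1)
        np.testing.assert_allclose(mu, 0.0, atol=1e-10)
        np.testing.assert_allclose(sd, 1.0, atol=1e-10)

    def test_whole_scale_missing_flagged_not_filled(self, small_study, small_scores):
        ds, _ = small_study
        mat = build_predictor_matrix(ds, small_scores)
        for i, pid in enumerate(mat.parent_ids):
            row = small_scores.loc[pid]
            if row["iipc_missing"]:
                assert np.isnan(mat.x[i, :3]).all()
            if row["scl_missing"]:
                assert np.isnan(mat.x[i, 3])


def test_fit_joint_deterministic_under_seed(small_matrix, small_items):
    cfg = SamplerConfig(chains=2, warmup_iterations=60, sampling_iterations=40, seed=4)
    kwargs = dict(y_items=small_items, sampler=cfg, check_convergence=False)
    a = fit_joint(ModelSpec("M3_interpersonal"), small_matrix, **kwargs)
    b = fit_joint(ModelSpec("M3_interpersonal"), small_matrix, **kwargs)
    np.testing.assert_array_equal(a.draws["b"], b.draws["b"])
    np.testing.assert_array_equal(a.draws["theta"], b.draws["theta"])


def test_model_spec_coefficients():
    assert ModelSpec("M1_depression").coef_names == ["depression", "age"]
    assert ModelSpec("M2_depression_gender").coef_names == [
        "intercept", "depression", "mother", "depression_x_mother", "age"]
    assert not ModelSpec("M3_interpersonal").includes_intercept
    assert ModelSpec("M4_interpersonal_gender").includes_intercept
    with pytest.raises(ValueError):
        ModelSpec("M5")


def test_conditional_mean_impute_matches_regression():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(4, 4))
    Sigma = A @ A.T + np.eye(4)
    mu = rng.normal(size=4)
    row = np.array([1.0, np.nan, 0.5, np.nan])
    out = conditional_mean_impute(row, mu, Sigma)
    obs = [0, 2]
    mis = [1, 3]
    expected = mu[mis] + Sigma[np.ix_(mis, obs)] @ np.linalg.solve(
        Sigma[np.ix_(obs, obs)], row[obs] - mu[obs]
    )
    np.testing.assert_allclose(out[mis], expected)
    np.testing.assert_array_equal(out[obs], row[obs])


@pytest.fixture(scope="module")
def tiny_posterior(small_matrix, small_items):
    cfg = SamplerConfig(chains=2, warmup_iterations=80, sampling_iterations=60, seed=6)
    return fit_joint(
        ModelSpec("M3_interpersonal"), small_matrix, y_items=small_items,
        sampler=cfg, check_convergence=False,
    )


class TestLoglikFamily:

    def test_single_item_at_difficulty_is_log_half(self):
        # hand-built posterior: zero coefficients put the expected theta at 0,
        # where the item difficulty also sits, so P(y=1) = 0.5 in every draw
        from dyadconflict.model import PosteriorSamples

        draws = {
            "b": np.zeros((2, 5, 4)),
            "alpha": np.full((2, 5, 16), 2.0),
            "beta": np.zeros((2, 5, 16)),
            "sigma": np.full((2, 5), 0.5),
        }
        post = PosteriorSamples(
            draws=draws,
            coef_names=["agency", "communion", "elevation", "age"],
            spec=ModelSpec("M3_interpersonal"),
            options=ModelOptions(),
            diagnostics={},
        )
        y = np.full((1, 16), np.nan)
        y[0, 0] = 1.0
        ll = loglik_family(post, post.spec, np.zeros((1, 4)), np.zeros(1), np.zeros(1), y)
        np.testing.assert_allclose(ll, np.log(0.5), atol=1e-12)

    def test_two_dyad_family_is_sum_of_parts(self, tiny_posterior):
        post = tiny_posterior
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 4))
        mother = np.array([0.0, 1.0])
        age = np.array([1.0, 1.0])
        y = rng.integers(0, 2, (2, 16)).astype(float)
        both = loglik_family(post, post.spec, x, mother, age, y)
        one = loglik_family(post, post.spec, x[:1], mother[:1], age[:1], y[:1])
        two = loglik_family(post, post.spec, x[1:], mother[1:], age[1:], y[1:])
        np.testing.assert_allclose(both, one + two, atol=1e-10)

    def test_matches_brute_force_recomputation(self, tiny_posterior):
        """Independent oracle: rebuild the per-draw likelihood item by item."""
        post = tiny_posterior
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 4))
        mother = np.array([1.0, 0.0])
        age = np.array([-2.0, -2.0])
        y = rng.integers(0, 2, (2, 16)).astype(float)
        y[0, 5] = np.nan
        ll = loglik_family(post, post.spec, x, mother, age, y)
        b = post.pooled("b")
        alpha, beta = post.pooled("alpha"), post.pooled("beta")
        coef = dict(zip(post.coef_names, b.T))
        for s in rng.choice(len(ll), 25, replace=False):
            total = 0.0
            for d in range(2):
                theta = (
                    coef["agency"][s] * x[d, 0]
                    + coef["communion"][s] * x[d, 1]
                    + coef["elevation"][s] * x[d, 2]
                    + coef["age"][s] * age[d]
                )
                items = ItemParameters(alpha[s], beta[s])
                total += pattern_loglik(y[d], theta, items)
            assert ll[s] == pytest.approx(total, abs=1e-12)

    def test_intercept_integration_collapses_at_zero_tau(self, tiny_posterior):
        import dataclasses

        post = tiny_posterior
        zero_tau = dataclasses.replace(
            post, draws={**post.draws, "tau": np.zeros_like(post.draws["tau"])}
        )
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 4))
        y = rng.integers(0, 2, (1, 16)).astype(float)
        base = loglik_family(zero_tau, post.spec, x, np.zeros(1), np.zeros(1), y)
        integ = loglik_family(
            zero_tau, post.spec, x, np.zeros(1), np.zeros(1), y,
            integrate_intercept_draws=10,
        )
        np.testing.assert_allclose(integ, base, atol=1e-12)

    def test_plugin_posterior_mean_variant(self, tiny_posterior):
        post = tiny_posterior
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 4))
        y = rng.integers(0, 2, (1, 16)).astype(float)
        ll = loglik_family(
            post, post.spec, x, np.zeros(1), np.zeros(1), y, plugin_posterior_mean=True
        )
        assert ll.shape == (1,)
        b_mean = post.pooled("b").mean(axis=0)
        theta = float(
            np.dot(b_mean, [x[0, 0], x[0, 1], x[0, 2], 0.0])
        )
        items = ItemParameters(
            post.pooled("alpha").mean(axis=0), post.pooled("beta").mean(axis=0)
        )
        assert ll[0] == pytest.approx(pattern_loglik(y[0], theta, items), abs=1e-10)

    def test_predictor_correlations_well_formed(self, tiny_posterior):
        from dyadconflict.model import predictor_correlations

        table = predictor_correlations(tiny_posterior)
        assert len(table) == 6  # all unordered pairs of the 4 predictors
        assert ((table["ci_low"] >= -1) & (table["ci_high"] <= 1)).all()
        assert ((table["ci_low"] <= table["mean"]) & (table["mean"] <= table["ci_high"])).all()

    def test_family_without_observations_rejected(self, tiny_posterior):
        with pytest.raises(ValueError, match="no observed"):
            loglik_family(
                tiny_posterior, tiny_posterior.spec,
                np.zeros((1, 4)), np.zeros(1), np.zeros(1), np.full((1, 16), np.nan),
            )
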