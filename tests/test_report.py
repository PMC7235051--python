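"""Posterior summary conventions: 93% intervals, tail/interval probabilities,
derived coefficients, diagnostics, and the reported parameter table."""

import numpy as np
import pytest

from dyadconflict.model import ModelOptions, ModelSpec, PosteriorSamples
from dyadconflict.report import (
    classic_rhat,
    combine_coefficients,
    interval_probability,
    report,
    summarize,
    tail_probability,
)


def _fake_posterior(model_id, coef_names, seed=0, chains=2, n=400, extras=()):
    rng = np.random.default_rng(seed)
    draws = {"b": rng.normal(0, 1, (chains, n, len(coef_names)))}
    for name in extras:
        draws[name] = np.abs(rng.normal(1, 0.2, (chains, n))) + (20.0 if name == "nu" else 0.0)
    return PosteriorSamples(
        draws=draws, coef_names=list(coef_names), spec=ModelSpec(model_id),
        options=ModelOptions(), diagnostics={},
    )


class TestSummarize:
    def test_pooled_mean_of_sequence(self):
        draws = np.arange(1.0, 1001.0).reshape(2, 500)
        assert summarize(draws).mean == pytest.approx(500.5)

    def test_constant_draws(self):
        s = summarize(np.full((2, 100), 3.3))
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert (s.ci93_low, s.ci93_high) == (3.3, 3.3)

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(42)
        draws = rng.standard_normal((4, 2500))
        s = summarize(draws)
        assert s.ci93_low == pytest.approx(-1.812, abs=0.08)
        assert s.ci93_high == pytest.approx(1.812, abs=0.08)

    def test_quantile_sandwich(self):
        rng = np.random.default_rng(3)
        draws = rng.gamma(2, 1, (2, 500))
        s = summarize(draws)
        med = np.median(draws)
        assert s.ci93_low <= med <= s.ci93_high

    def test_iid_chains_pass_rhat(self):
        rng = np.random.default_rng(11)
        s = summarize(rng.standard_normal((4, 1000)))
        assert s.rhat < 1.01
        assert s.ess > 1000

    def test_classic_rhat_near_one_for_iid(self):
        rng = np.random.default_rng(5)
        assert classic_rhat(rng.standard_normal((4, 1000))) == pytest.approx(1.0, abs=0.01)

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            summarize(np.ones(10))
        with pytest.raises(ValueError):
            summarize(np.ones((1, 50)))


class TestProbabilities:
    def test_tail_examples(self):
        draws = np.array([-0.2, 0.0, 0.2, 0.4])
        assert tail_probability(draws, 0.1, "below") == 0.5
        assert tail_probability(draws, -1.0, "above") == 1.0
        assert tail_probability(draws, 1.0, "below") == 1.0

    def test_tail_partition_is_exact(self):
        rng = np.random.default_rng(1)
        draws = np.round(rng.normal(0, 1, 1000), 1)
        t = 0.0
        below = tail_probability(draws, t, "below")
        above = tail_probability(draws, t, "above")
        at = np.mean(draws == t)
        assert below + above + at == pytest.approx(1.0, abs=1e-15)

    def test_interval_examples(self):
        draws = np.array([-0.15, -0.05, 0.05, 0.15])
        assert interval_probability(draws, -0.1, 0.1) == 0.5
        assert interval_probability(draws, -1, 1) == 1.0
        assert interval_probability(draws, 0.3, 0.4) == 0.0
        with pytest.raises(ValueError):
            interval_probability(draws, 0.5, 0.5)

    def test_direction_validated(self):
        with pytest.raises(ValueError):
            tail_probability(np.ones(3), 0.0, "sideways")


class TestCombine:
    def test_combine_with_zero_is_identity(self):
        post = _fake_posterior("M2_depression_gender",
                               ["intercept", "depression", "mother", "depression_x_mother", "age"])
        post.draws["b"][:, :, 3] = 0.0
        combined = combine_coefficients(post, ["depression", "depression_x_mother"])
        np.testing.assert_array_equal(combined, post.draws["b"][:, :, 1])

    def test_combine_with_negative_cancels(self):
        post = _fake_posterior("M2_depression_gender",
                               ["intercept", "depression", "mother", "depression_x_mother", "age"])
        post.draws["b"][:, :, 3] = -post.draws["b"][:, :, 1]
        combined = combine_coefficients(post, ["depression", "depression_x_mother"])
        np.testing.assert_allclose(combined, 0.0)

    def test_linearity_of_means(self):
        post = _fake_posterior("M2_depression_gender",
                               ["intercept", "depression", "mother", "depression_x_mother", "age"])
        combined = combine_coefficients(post, ["depression", "depression_x_mother"])
        assert combined.mean() == pytest.approx(
            post.draws["b"][:, :, 1].mean() + post.draws["b"][:, :, 3].mean()
        )

    def test_unknown_name_rejected(self):
        post = _fake_posterior("M1_depression", ["depression", "age"])
        with pytest.raises(KeyError):
            combine_coefficients(post, ["agency"])


class TestReportTable:
    def test_interpersonal_model_rows(self):
        post = _fake_posterior(
            "M3_interpersonal", ["agency", "communion", "elevation", "age"],
            extras=("sigma", "tau", "nu"),
        )
        table = report(post)
        assert list(table.index) == [
            "Agency", "Communion", "Elevation", "Adolescent age",
            "Variance of errors", "Variance of random effects",
            "Degrees of freedom in t-likelihood",
        ]
        assert table["rhat"].notna().all()
        assert (table["ci93_low"] <= table["ci93_high"]).all()

    def test_dummy_coded_model_gets_interaction_and_total_rows(self):
        post = _fake_posterior(
            "M2_depression_gender",
            ["intercept", "depression", "mother", "depression_x_mother", "age"],
            extras=("sigma", "tau", "nu"),
        )
        table = report(post)
        assert "Intercept" in table.index
        assert "Depressive symptoms x mother" in table.index
        assert "Depressive symptoms total for mothers" in table.index

    def test_variance_rows_are_squared_scales(self):
        post = _fake_posterior("M1_depression", ["depression", "age"], extras=("sigma",))
        table = report(post)
        assert table.loc["Variance of errors", "mean"] == pytest.approx(
            (post.draws["sigma"] ** 2).mean()
        )
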