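import numpy as np
import pandas as pd
import pytest

from telodyn import (
    ModelSpec,
    aicc,
    build_cross_sectional_set,
    build_longitudinal_set,
    fit_lmm,
    rank_models,
    within_between_contrast,
    within_subject_centre,
)
from telodyn.lmm import ModelFit


class TestAicc:
    def test_large_n_limit_approaches_aic(self):
        assert aicc(0.0, 1, 1_000_001) == pytest.approx(2.000004, abs=1e-6)

    def test_direct_arithmetic(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_k_zero_is_minus_two_loglik(self):
        assert aicc(-3.5, 0, 10) == 7.0

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(0.0, 9, 10)

    def test_monotone_to_aic_in_n(self):
        vals = [aicc(0.0, 3, n) for n in (10, 30, 100, 1000)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(6.0, abs=0.05)


def _fake_fit(name, aicc_val, k=3, n=100, criterion="ML", converged=True):
    return ModelFit(
        spec=ModelSpec("y", (), (), name=name),
        estimates={},
        variance_components={},
        resid_var=1.0,
        loglik=0.0,
        n_obs=n,
        k_params=k,
        aicc=aicc_val,
        converged=converged,
        fit_criterion=criterion,
    )


class TestRanking:
    def test_equal_aicc_split_weights(self):
        rk = rank_models([_fake_fit("a", 10.0), _fake_fit("b", 10.0)])
        weights = [w for *_, w in rk.entries]
        assert weights == pytest.approx([0.5, 0.5])

    def test_delta_two_weights(self):
        rk = rank_models([_fake_fit("a", 10.0), _fake_fit("b", 12.0)])
        weights = [w for *_, w in rk.entries]
        assert weights[0] == pytest.approx(0.7311, abs=1e-4)
        assert weights[1] == pytest.approx(0.2689, abs=1e-4)

    def test_single_fit_weight_one(self):
        rk = rank_models([_fake_fit("only", 5.0)])
        assert rk.entries[0][3] == pytest.approx(1.0)

    def test_ties_broken_by_fewer_parameters(self):
        rk = rank_models([_fake_fit("big", 10.0, k=5), _fake_fit("small", 10.0, k=2)])
        assert rk.best.name == "small"

    def test_mixed_criteria_rejected(self):
        with pytest.raises(ValueError):
            rank_models([_fake_fit("a", 1.0, criterion="ML"), _fake_fit("b", 2.0, criterion="REML")])

    def test_differing_n_rejected(self):
        with pytest.raises(ValueError):
            rank_models([_fake_fit("a", 1.0, n=100), _fake_fit("b", 2.0, n=90)])

    def test_flagged_fits_refused_unless_overridden(self):
        fits = [_fake_fit("a", 1.0), _fake_fit("b", 2.0, converged=False)]
        with pytest.raises(ValueError):
            rank_models(fits)
        rk = rank_models(fits, allow_flagged=True)
        assert len(rk.entries) == 2


class TestModelSets:
    def test_cross_sectional_set_contents(self, small_samples):
        specs = build_cross_sectional_set(small_samples)
        assert len(specs) == 11  # 10 ranked + interaction follow-up
        for s in specs:
            assert set(s.random_terms) == {"bird_id", "catch_year", "plate_id"}
        null = [s for s in specs if s.name == "Null model"]
        assert null and null[0].fixed_terms == ()
        assert any("age_log_x_cohort" in s.fixed_terms for s in specs)

    def test_longitudinal_set_contents(self, small_samples):
        centred = within_subject_centre(small_samples)
        specs = build_longitudinal_set(centred)
        assert len(specs) == 8
        for s in specs:
            assert "plate_id" not in s.random_terms
            assert "mean_age" in s.fixed_terms

    def test_quadratic_requires_linear(self):
        with pytest.raises(ValueError):
            ModelSpec("y", ("age_quadratic",), ())


class TestCentring:
    def test_linear_example(self):
        df = pd.DataFrame(
            {
                "bird_id": ["a"] * 3,
                "sample_id": [1, 2, 3],
                "age_years": [1.0, 2.0, 3.0],
                "sqrt_rtl": [1.0, 1.0, 1.0],
            }
        )
        out = within_subject_centre(df)
        assert list(out["delta_age"]) == [-1.0, 0.0, 1.0]
        assert (out["mean_age"] == 2.0).all()

    def test_single_sample_birds_dropped(self):
        df = pd.DataFrame(
            {
                "bird_id": ["a", "a", "b"],
                "sample_id": [1, 2, 3],
                "age_years": [1.0, 2.0, 5.0],
                "sqrt_rtl": [1.0, 1.0, 1.0],
            }
        )
        out = within_subject_centre(df)
        assert set(out["bird_id"]) == {"a"}

    def test_deltas_sum_to_zero_and_log_centring_matches(self, small_samples):
        out = within_subject_centre(small_samples)
        sums = out.groupby("bird_id")["delta_log_age"].sum()
        assert np.allclose(sums, 0.0, atol=1e-12)
        manual = np.log(out["age_years"]) - out.groupby("bird_id")["age_years"].transform(
            lambda a: np.mean(np.log(a))
        )
        assert np.allclose(out["delta_log_age"], manual, atol=1e-12)


class TestFitLmm:
    def test_intercept_only_no_randoms_is_sample_mean(self, small_samples):
        fit = fit_lmm(ModelSpec("sqrt_rtl", (), ()), small_samples, criterion="ML")
        assert fit.coef("Intercept") == pytest.approx(small_samples["sqrt_rtl"].mean(), abs=1e-10)

    def test_balanced_oneway_matches_anova_components(self):
        rng = np.random.default_rng(11)
        k, n_i = 40, 4
        g = np.repeat(np.arange(k), n_i)
        y = rng.normal(0, 1.0, k)[g] + rng.normal(0, 0.5, k * n_i)
        df = pd.DataFrame({"sqrt_rtl": y, "bird_id": g})
        fit = fit_lmm(ModelSpec("sqrt_rtl", (), ("bird_id",)), df, criterion="REML")
        means = df.groupby("bird_id")["sqrt_rtl"].mean()
        msb = n_i * ((means - df["sqrt_rtl"].mean()) ** 2).sum() / (k - 1)
        msw = ((df["sqrt_rtl"] - means.loc[df["bird_id"]].to_numpy()) ** 2).sum() / (
            k * (n_i - 1)
        )
        assert fit.resid_var == pytest.approx(msw, rel=1e-3)
        assert fit.variance_components["bird_id"] == pytest.approx((msb - msw) / n_i, rel=1e-3)

    def test_missing_columns_reported(self, small_samples):
        spec = ModelSpec("sqrt_rtl", ("insect",), ())
        with pytest.raises(ValueError, match="insect_abundance"):
            fit_lmm(spec, small_samples.drop(columns=["insect_abundance"]))

    def test_aicc_consistent_with_loglik(self, small_samples):
        fit = fit_lmm(
            ModelSpec("sqrt_rtl", ("age_log",), ("bird_id",)), small_samples, criterion="ML"
        )
        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.k_params, fit.n_obs))


class TestWithinBetweenContrast:
    @staticmethod
    def _simulate(rng, between_excess, n_birds=400):
        rows = []
        beta_w = -0.07
        for b in range(n_birds):
            first = rng.choice([0.5, 1.0, 2.0])
            ages = [first, first + 1, first + 3]
            mla = np.mean(np.log(ages))
            u = rng.normal(0, 0.05)
            for a in ages:
                la = np.log(a)
                y = (
                    1.0
                    + beta_w * (la - mla)
                    + (beta_w + between_excess) * mla
                    + u
                    + rng.normal(0, 0.08)
                )
                rows.append(
                    dict(
                        bird_id=b,
                        sample_id=f"{b}-{a}",
                        age_years=a,
                        sqrt_rtl=y,
                        catch_year=2000 + int(a),
                    )
                )
        return pd.DataFrame(rows)

    def test_null_contrast_covers_zero(self):
        rng = np.random.default_rng(12)
        cover = 0
        for _ in range(10):
            df = self._simulate(rng, 0.0, n_birds=150)
            est, (lo, hi), _ = within_between_contrast(df, randoms=("bird_id",))
            cover += lo <= 0.0 <= hi
        assert cover >= 8

    def test_recovers_between_minus_within_difference(self):
        rng = np.random.default_rng(13)
        df = self._simulate(rng, 0.05, n_birds=2000)
        est, (lo, hi), _ = within_between_contrast(df, randoms=("bird_id",))
        assert est == pytest.approx(0.05, abs=0.01)
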