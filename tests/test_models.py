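"""Model fitting, AICc arithmetic and model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import insuladiv as iv
from insuladiv.models import FitError, ModelFit, aicc, akaike_weights


def _pts(x, y, taxa=None):
    return pd.DataFrame({"x": x, "y": y, "taxon_group": taxa if taxa is not None else [""] * len(x)})


def grid_search_breakpoint(points, n_grid=1000, taxon=False):
    """Independent RSS-minimizing breakpoint search on a dense psi grid."""
    x = points["x"].to_numpy(float)
    y = points["y"].to_numpy(float)
    lo, hi = x.min(), x.max()
    best = (np.inf, None)
    for psi in np.linspace(lo + 1e-9, hi - 1e-9, n_grid):
        u = np.clip(x - psi, 0.0, None)
        X = np.column_stack([np.ones_like(x), x, u])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        if rss < best[0]:
            best = (rss, psi)
    return best  # (rss, psi)


class TestConstrainedLinear:
    def test_exact_fit_on_line(self):
        fit = iv.fit_constrained_linear(_pts([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), taxon=False)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert fit.coefficients["slope"] == pytest.approx(1.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_null_constraints_forced_residuals(self):
        fit = iv.fit_constrained_linear(
            _pts([1.0, 2.0], [2.0, 3.0]), slope=1.0, intercept=0.0, taxon=False
        )
        assert fit.model_name == "null"
        assert fit.k == 1  # only the variance parameter is estimated
        assert fit.rss == pytest.approx(2.0)
        assert fit.sigma2_hat == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, points_factory):
        """Free fit equals the closed-form normal-equations solution."""
        pts = points_factory(n=12)
        fit = iv.fit_constrained_linear(pts, taxon=False)
        X = np.column_stack([np.ones(len(pts)), pts["x"]])
        beta = np.linalg.solve(X.T @ X, X.T @ pts["y"].to_numpy())
        assert fit.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.coefficients["slope"] == pytest.approx(beta[1], abs=1e-10)

    def test_matches_statsmodels_with_taxon_effects(self, points_factory):
        """Sum-to-zero taxon fit agrees with statsmodels OLS on the same design."""
        sm = pytest.importorskip("statsmodels.api")
        pts = points_factory(n=30, taxon=True)
        fit = iv.fit_constrained_linear(pts, taxon=True)
        levels = sorted(pts["taxon_group"].unique())
        arr = pts["taxon_group"].to_numpy()
        T = np.column_stack(
            [np.where(arr == lv, 1.0, np.where(arr == levels[-1], -1.0, 0.0)) for lv in levels[:-1]]
        )
        X = np.column_stack([np.ones(len(pts)), pts["x"].to_numpy(), T])
        res = sm.OLS(pts["y"].to_numpy(), X).fit()
        assert fit.coefficients["intercept"] == pytest.approx(res.params[0], abs=1e-8)
        assert fit.coefficients["slope"] == pytest.approx(res.params[1], abs=1e-8)
        assert fit.rss == pytest.approx(res.ssr, rel=1e-10)

    def test_rank_deficient_design_fatal(self):
        pts = _pts([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(FitError, match="rank-deficient"):
            iv.fit_constrained_linear(pts, taxon=False)

    def test_too_few_points_fatal(self):
        with pytest.raises(FitError, match="cannot identify"):
            iv.fit_constrained_linear(_pts([1.0, 2.0], [1.0, 2.0]), taxon=False)


class TestTransformed:
    def test_exact_log_recovery(self):
        x = np.linspace(1.0, 5.0, 10)
        fit = iv.fit_transformed(_pts(x, 2.0 * np.log(x)), "log", taxon=False)
        assert fit.coefficients["coef"] == pytest.approx(2.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_log_fit_reduces_to_linear_on_transformed_x(self, points_factory):
        pts = points_factory(n=15)
        log_fit = iv.fit_transformed(pts, "log", taxon=False)
        lin_on_logx = iv.fit_constrained_linear(
            _pts(np.log(pts["x"].to_numpy()), pts["y"].to_numpy()), taxon=False
        )
        assert log_fit.coefficients["coef"] == pytest.approx(lin_on_logx.coefficients["slope"], abs=1e-10)
        assert log_fit.rss == pytest.approx(lin_on_logx.rss, rel=1e-10)

    def test_constant_x_rank_deficient(self):
        with pytest.raises(FitError, match="rank-deficient"):
            iv.fit_transformed(_pts([2.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0]), "log", taxon=False)

    def test_log_requires_positive_x(self):
        with pytest.raises(FitError, match="x > 0"):
            iv.fit_transformed(_pts([-1.0, 1.0, 2.0], [0.0, 1.0, 2.0]), "log", taxon=False)


class TestBrokenStick:
    def test_recovers_known_breakpoint(self, rng):
        x = np.sort(rng.uniform(0.0, 1.0, 80))
        psi_true = 0.5
        y = np.where(x <= psi_true, x, psi_true)  # slope 1 then 0
        fit = iv.fit_broken_stick(_pts(x, y), taxon=False, tol=1e-10)
        assert not fit.boundary_flag
        assert fit.psi == pytest.approx(psi_true, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_matches_grid_search_oracle(self, rng):
        """Iterative estimate agrees with a dense grid-search RSS minimizer."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            x = np.sort(r.uniform(1.0, 5.0, 60))
            y = np.where(x <= 2.5, 1.0 + x, 1.0 + 2.5 + 0.3 * (x - 2.5)) + r.normal(0, 0.05, 60)
            fit = iv.fit_broken_stick(_pts(x, y), taxon=False, tol=1e-10)
            rss_grid, psi_grid = grid_search_breakpoint(_pts(x, y), n_grid=1000)
            assert fit.psi == pytest.approx(psi_grid, abs=(x.max() - x.min()) / 500)
            assert fit.rss <= rss_grid + 1e-8

    def test_pure_linear_data_flags_boundary(self, rng):
        x = np.linspace(1.0, 5.0, 40)
        y = 0.5 + 0.8 * x
        fit = iv.fit_broken_stick(_pts(x, y), taxon=False)
        assert fit.boundary_flag

    def test_noisy_linear_data_flags_boundary(self, rng):
        x = np.linspace(1.0, 5.0, 60)
        y = 0.5 + 0.8 * x + rng.normal(0, 0.2, 60)
        fit = iv.fit_broken_stick(_pts(x, y), taxon=False)
        lin = iv.fit_constrained_linear(_pts(x, y), taxon=False)
        assert fit.rss <= lin.rss + 1e-12  # nesting regardless of boundary outcome

    def test_init_psi_outside_range_fatal(self):
        x = np.linspace(1.0, 5.0, 10)
        with pytest.raises(FitError, match="init_psi"):
            iv.fit_broken_stick(_pts(x, x), taxon=False, init_psi=9.0)


class TestNesting:
    @pytest.mark.parametrize("taxon", [False, True])
    def test_rss_ordering_over_random_datasets(self, taxon):
        """RSS(null) >= RSS(semi_null) >= RSS(linear) >= RSS(broken_stick)."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = 30
            x = r.uniform(1.0, 5.0, n)
            y = r.uniform(0.5, 2.0) * x + r.normal(0, 0.7, n)
            y = y - y.min() + 1.0
            taxa = r.choice(["birds", "fish", "plants"], n) if taxon else [""] * n
            pts = _pts(x, y, taxa)
            common = dict(taxon=taxon)
            rss = [
                iv.fit_constrained_linear(pts, slope=1.0, intercept=0.0, **common).rss,
                iv.fit_constrained_linear(pts, intercept=0.0, **common).rss,
                iv.fit_constrained_linear(pts, **common).rss,
                iv.fit_broken_stick(pts, **common).rss,
            ]
            assert all(rss[i] >= rss[i + 1] - 1e-9 for i in range(3)), (seed, rss)


class TestAicc:
    def test_closed_form(self):
        fit = ModelFit(model_name="m", side="within", n=10, k=3, coefficients={}, loglik=-5.0)
        assert aicc(fit) == pytest.approx(20.0)  # AIC 16 + 24/6

    @given(
        n=st.integers(10, 10_000),
        k=st.integers(1, 6),
        loglik=st.floats(-1e4, 1e4),
    )
    def test_correction_positive_and_vanishing(self, n, k, loglik):
        fit = ModelFit(model_name="m", side="within", n=n, k=k, coefficients={}, loglik=loglik)
        aic = 2 * k - 2 * loglik
        assert aicc(fit) >= aic
        big = ModelFit(model_name="m", side="within", n=10**8, k=1, coefficients={}, loglik=loglik)
        assert aicc(big) == pytest.approx(2 * 1 - 2 * loglik, abs=1e-4)

    def test_undefined_when_n_too_small(self):
        fit = ModelFit(model_name="m", side="within", n=4, k=3, coefficients={}, loglik=0.0)
        with pytest.raises(FitError, match="AICc undefined"):
            aicc(fit)


def _fits_with_aicc(values, side="within"):
    """Fabricate fits whose AICc equal the given values (k=1, n=100)."""
    fits = []
    for i, a in enumerate(values):
        # AICc = 2k - 2 loglik + corr -> loglik = (2k + corr - a)/2
        k, n = 1, 100
        corr = 2 * k * (k + 1) / (n - k - 1)
        fits.append(
            ModelFit(
                model_name=f"m{i}",
                side=side,
                n=n,
                k=k,
                coefficients={},
                loglik=(2 * k + corr - a) / 2.0,
                data_hash="shared",
            )
        )
    return fits


class TestComparison:
    def test_weights_from_published_deltas(self):
        """Deltas 0/5.6/8.9/23.8 give weights 0.932/0.057/0.011/<0.001."""
        cmp = iv.compare_models(_fits_with_aicc([100.0, 105.6, 108.9, 123.8]))
        assert np.round(cmp.weights[:3], 3).tolist() == [0.932, 0.057, 0.011]
        assert cmp.weights[3] < 0.0005
        assert cmp.delta_aicc.min() == 0.0

    def test_equal_aicc_splits_evenly(self):
        cmp = iv.compare_models(_fits_with_aicc([50.0, 50.0]))
        assert np.allclose(cmp.weights, [0.5, 0.5])

    def test_evidence_ratio_closed_form(self):
        cmp = iv.compare_models(_fits_with_aicc([0.0, 25.4]))
        assert cmp.evidence_ratio("m0", "m1") == pytest.approx(np.exp(12.7))
        assert cmp.evidence_ratio("m0", "m1") > 10_000

    def test_weights_sum_to_one_and_decrease_with_delta(self, points_factory):
        pts = points_factory(n=25)
        cmp = iv.compare_models(iv.fit_model_suite(pts, side="within", taxon=False))
        assert cmp.weights.sum() == pytest.approx(1.0, abs=1e-12)
        order = np.argsort(cmp.delta_aicc)
        assert (np.diff(cmp.weights[order]) <= 1e-15).all()

    def test_permutation_invariance(self):
        fits = _fits_with_aicc([10.0, 12.0, 17.0])
        a = iv.compare_models(fits)
        b = iv.compare_models(fits[::-1])
        for name in ("m0", "m1", "m2"):
            assert a.weight_of(name) == pytest.approx(b.weight_of(name))

    @given(shift=st.floats(-100, 100))
    def test_weights_invariant_to_aicc_shift(self, shift):
        base = akaike_weights([3.0, 5.0, 9.0])
        moved = akaike_weights([3.0 + shift, 5.0 + shift, 9.0 + shift])
        assert np.allclose(base, moved, atol=1e-12)

    def test_different_point_sets_not_comparable(self, points_factory):
        f1 = iv.fit_constrained_linear(points_factory(n=12), taxon=False)
        f2 = iv.fit_constrained_linear(points_factory(n=12), taxon=False)
        with pytest.raises(ValueError, match="different point sets"):
            iv.compare_models([f1, f2])


def test_null_loglik_depends_only_on_residuals():
    """With both constraints fixed the model estimates no mean parameters."""
    pts = _pts([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 2.5, 4.5])
    fit = iv.fit_constrained_linear(pts, slope=1.0, intercept=0.0, taxon=False)
    resid = pts["y"] - pts["x"]
    sigma2 = float((resid**2).mean())
    expect = -len(pts) / 2 * (np.log(2 * np.pi * sigma2) + 1)
    assert fit.loglik == pytest.approx(expect)
    assert fit.coefficients == {}
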