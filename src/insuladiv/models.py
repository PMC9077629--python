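"""Candidate regression models and AICc-based model comparison.

The paired points are fitted to a small suite of Gaussian models of the
insular aggregate y as a function of the non-insular aggregate x:

* ``null`` — y = x (slope fixed at 1, intercept fixed at 0): insularity
  has no effect, points scatter about the one-to-one line;
* ``semi_null`` — y = b·x (intercept fixed at 0): a proportional effect;
* ``linear`` — y = a + b·x, both free;
* ``log_transformed`` — y = a + c·log(x), a concave approximation to a
  piecewise (threshold) relationship;
* ``exp_transformed`` — y = a + c·exp(x), the convex counterpart;
* ``broken_stick`` — a continuous two-segment linear model with an
  estimated breakpoint psi, fitted by iterative linearization.

Within-side models additionally carry taxon-group fixed effects coded as
sum-to-zero deviations, so that "intercept fixed at 0" always refers to
the taxon-averaged line. All fits use a Gaussian likelihood with the
maximum-likelihood residual variance RSS/n, which keeps log-likelihoods
comparable across models with different fixed coefficients; models are
ranked by AICc with Akaike weights and evidence ratios.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelFit",
    "ModelComparison",
    "fit_constrained_linear",
    "fit_transformed",
    "fit_broken_stick",
    "fit_model_suite",
    "aicc",
    "akaike_weights",
    "compare_models",
    "WITHIN_SUITE",
    "AMONG_SUITE",
]

WITHIN_SUITE = ("null", "semi_null", "linear", "log_transformed", "exp_transformed", "broken_stick")
AMONG_SUITE = ("null", "semi_null", "linear", "exp_transformed", "broken_stick")

#: floor applied to sigma2 inside the log-likelihood so that zero-residual
#: (degenerate, noiseless) fits tie on likelihood and rank purely by k
_SIGMA2_FLOOR = 1e-12


class FitError(ValueError):
    """The requested fit is not estimable on the given points."""


def _data_hash(x: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.round(x, 12).tobytes())
    h.update(np.round(y, 12).tobytes())
    return h.hexdigest()


def _taxon_design(taxa: pd.Series, coding: str = "sum_to_zero") -> tuple[np.ndarray, list[str], list[str]]:
    """Design columns for taxon fixed effects over the levels present."""
    levels = sorted(taxa.unique())
    if len(levels) < 2:
        return np.empty((len(taxa), 0)), [], levels
    cols = []
    names = []
    arr = taxa.to_numpy()
    if coding == "sum_to_zero":
        ref = levels[-1]
        for lv in levels[:-1]:
            col = np.where(arr == lv, 1.0, np.where(arr == ref, -1.0, 0.0))
            cols.append(col)
            names.append(f"taxon[{lv}]")
    elif coding == "reference_level":
        for lv in levels[1:]:
            cols.append((arr == lv).astype(float))
            names.append(f"taxon[{lv}]")
    else:
        raise ValueError(f"unknown taxon coding {coding!r}")
    return np.column_stack(cols), names, levels


@dataclass
class ModelFit:
    """One fitted candidate model on a paired-point dataset."""

    model_name: str
    side: str
    n: int
    k: int
    coefficients: dict[str, float]
    constraints: dict[str, float] = field(default_factory=dict)
    taxon_levels: list[str] = field(default_factory=list)
    taxon_coding: str = "sum_to_zero"
    rss: float = np.nan
    sigma2_hat: float = np.nan
    loglik: float = np.nan
    converged: bool = True
    boundary_flag: bool = False
    psi: float | None = None
    transform: str | None = None
    data_hash: str = ""

    @property
    def slope(self) -> float | None:
        if "slope" in self.coefficients:
            return self.coefficients["slope"]
        return self.constraints.get("slope")

    @property
    def intercept(self) -> float | None:
        if "intercept" in self.coefficients:
            return self.coefficients["intercept"]
        return self.constraints.get("intercept")

    def predict_mean(self, x: np.ndarray) -> np.ndarray:
        """Taxon-averaged fitted curve (taxon deviations average to zero
        under sum-to-zero coding)."""
        x = np.asarray(x, float)
        a = self.intercept if self.intercept is not None else 0.0
        c = self.coefficients
        if self.model_name in ("null", "semi_null", "linear"):
            return a + (self.slope or 0.0) * x
        if self.model_name == "log_transformed":
            return a + c["coef"] * np.log(x)
        if self.model_name == "exp_transformed":
            return a + c["coef"] * np.exp(x)
        if self.model_name == "broken_stick":
            u = np.clip(x - self.psi, 0.0, None)
            return a + c["slope"] * x + c["slope_change"] * u
        raise ValueError(f"unknown model {self.model_name!r}")


def _finish_fit(fit: ModelFit, resid: np.ndarray) -> ModelFit:
    n = fit.n
    rss = float(resid @ resid)
    sigma2 = rss / n
    fit.rss = rss
    fit.sigma2_hat = sigma2
    fit.loglik = -n / 2.0 * (np.log(2.0 * np.pi * max(sigma2, _SIGMA2_FLOOR)) + 1.0)
    return fit


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]) -> np.ndarray:
    if X.shape[1] == 0:
        return np.empty(0)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(f"design matrix rank-deficient; collinear columns among {names}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _extract(points: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    x = points["x"].to_numpy(float)
    y = points["y"].to_numpy(float)
    taxa = points["taxon_group"] if "taxon_group" in points else pd.Series([""] * len(points))
    return x, y, taxa


def fit_constrained_linear(
    points: pd.DataFrame,
    side: str = "within",
    slope: float | None = None,
    intercept: float | None = None,
    taxon: bool = True,
    taxon_coding: str = "sum_to_zero",
    model_name: str | None = None,
) -> ModelFit:
    """Least-squares linear fit with optionally fixed slope and/or intercept.

    A fixed slope is handled by offsetting y by slope*x; a fixed intercept
    by suppressing the global constant. k counts the free mean parameters
    plus the residual-variance parameter.
    """
    x, y, taxa = _extract(points)
    n = len(x)
    constraints: dict[str, float] = {}
    cols, names = [], []
    if intercept is None:
        cols.append(np.ones(n))
        names.append("intercept")
    else:
        constraints["intercept"] = float(intercept)
    work_y = y - (0.0 if intercept is None else intercept)
    if slope is None:
        cols.append(x)
        names.append("slope")
    else:
        constraints["slope"] = float(slope)
        work_y = work_y - slope * x
    tx_names: list[str] = []
    levels: list[str] = []
    if taxon:
        T, tx_names, levels = _taxon_design(taxa, taxon_coding)
        if T.shape[1]:
            cols.append(T)
            names.extend(tx_names)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    k = X.shape[1] + 1
    if n <= X.shape[1]:
        raise FitError(f"n={n} points cannot identify {X.shape[1]} mean parameters")
    beta = _ols(X, work_y, names)
    coefs = dict(zip(names, beta))
    resid = work_y - (X @ beta if X.shape[1] else 0.0)
    if model_name is None:
        if slope is not None and intercept is not None:
            model_name = "null"
        elif intercept is not None:
            model_name = "semi_null"
        else:
            model_name = "linear"
    fit = ModelFit(
        model_name=model_name,
        side=side,
        n=n,
        k=k,
        coefficients=coefs,
        constraints=constraints,
        taxon_levels=levels,
        taxon_coding=taxon_coding,
        data_hash=_data_hash(x, y),
    )
    return _finish_fit(fit, resid)


def fit_transformed(
    points: pd.DataFrame,
    transform: str,
    side: str = "within",
    taxon: bool = True,
    taxon_coding: str = "sum_to_zero",
) -> ModelFit:
    """OLS of y on log(x) or exp(x) (natural log/exponential) plus intercept."""
    x, y, taxa = _extract(points)
    n = len(x)
    if transform == "log":
        if np.any(x <= 0):
            raise FitError("log transform requires x > 0; shift the data to unit minimum first")
        t = np.log(x)
        name = "log_transformed"
    elif transform == "exp":
        t = np.exp(x)
        if not np.all(np.isfinite(t)):
            bad = x[~np.isfinite(np.exp(x))][0]
            raise FitError(f"exp overflow at x={bad}; standardize the data first")
        name = "exp_transformed"
    else:
        raise ValueError(f"unknown transform {transform!r}")
    cols = [np.ones(n), t]
    names = ["intercept", "coef"]
    levels: list[str] = []
    if taxon:
        T, tx_names, levels = _taxon_design(taxa, taxon_coding)
        if T.shape[1]:
            cols.append(T)
            names.extend(tx_names)
    X = np.column_stack(cols)
    k = X.shape[1] + 1
    if n <= X.shape[1]:
        raise FitError(f"n={n} points cannot identify {X.shape[1]} mean parameters")
    beta = _ols(X, y, names)
    resid = y - X @ beta
    fit = ModelFit(
        model_name=name,
        side=side,
        n=n,
        k=k,
        coefficients=dict(zip(names, beta)),
        taxon_levels=levels,
        taxon_coding=taxon_coding,
        transform=transform,
        data_hash=_data_hash(x, y),
    )
    return _finish_fit(fit, resid)


def _segmented_refit(
    x: np.ndarray, y: np.ndarray, T: np.ndarray, psi: float
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Continuous two-segment fit at a fixed breakpoint psi."""
    u = np.clip(x - psi, 0.0, None)
    cols = [np.ones(len(x)), x, u]
    names = ["intercept", "slope", "slope_change"]
    if T.shape[1]:
        cols.append(T)
        names.extend(f"taxon[{i}]" for i in range(T.shape[1]))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta, names


def fit_broken_stick(
    points: pd.DataFrame,
    side: str = "within",
    taxon: bool = True,
    taxon_coding: str = "sum_to_zero",
    init_psi: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    guard_frac: float = 0.02,
) -> ModelFit:
    """Two-segment continuous linear model with estimated breakpoint psi.

    Uses the iterative-linearization scheme of segmented regression: at
    each step y is regressed on {1, x, U=(x-psi)_+, V=-1[x>psi]} (plus
    taxon effects) and psi is updated by coef(V)/coef(U); a
    non-converged path (oscillation, drift to an edge) is represented by
    its best-RSS iterate. If the U coefficient vanishes at every start,
    or the estimated psi lies within ``guard_frac`` of the x-range of
    either data edge, the fit is flagged as a boundary outcome —
    segmenting did not improve on a straight line. The reported model is always the continuous
    segmented fit at the final psi, which nests the plain linear model,
    so RSS(broken_stick) <= RSS(linear) by construction.
    """
    x, y, taxa = _extract(points)
    n = len(x)
    if n < 6:
        raise FitError("broken-stick fit needs at least 6 points")
    x_min, x_max = float(x.min()), float(x.max())
    span = x_max - x_min
    if span <= 0:
        raise FitError("x has zero range")
    guard = guard_frac * span
    T = np.empty((n, 0))
    levels: list[str] = []
    if taxon:
        T, _, levels = _taxon_design(taxa, taxon_coding)

    starts = []
    if init_psi is not None:
        if not (x_min < init_psi < x_max):
            raise FitError(f"init_psi={init_psi} outside the open data range ({x_min}, {x_max})")
        starts.append(float(init_psi))
    starts.extend(float(np.quantile(x, q)) for q in (0.5, 0.25, 0.75))

    best: tuple[float, float, bool] | None = None  # (rss, psi, converged)
    for psi0 in starts:
        psi = psi0
        converged = False
        ok = True
        track: tuple[float, float] | None = None  # best (rss, psi) along this path
        for _ in range(max_iter):
            _, resid_t, _ = _segmented_refit(x, y, T, psi)
            rss_t = float(resid_t @ resid_t)
            if track is None or rss_t < track[0]:
                track = (rss_t, psi)
            u = np.clip(x - psi, 0.0, None)
            v = -(x > psi).astype(float)
            cols = [np.ones(n), x, u, v]
            if T.shape[1]:
                cols.append(T)
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            coef_u, coef_v = beta[2], beta[3]
            if abs(coef_u) < 1e-12:
                ok = False
                break
            new_psi = min(max(psi + coef_v / coef_u, x_min + 1e-12), x_max - 1e-12)
            if abs(new_psi - psi) < tol:
                psi = new_psi
                converged = True
                break
            psi = new_psi
        if not ok or track is None:
            continue
        # a non-converged path (oscillation near the optimum, or drift to the
        # edge) is represented by its best-RSS iterate
        if converged:
            _, resid_f, _ = _segmented_refit(x, y, T, psi)
            rss_f = float(resid_f @ resid_f)
            if rss_f < track[0]:
                track = (rss_f, psi)
        rss, psi_best = track
        if best is None or rss < best[0] - 1e-15:
            best = (rss, psi_best, converged)

    if best is None:
        # every start lost the U column (e.g. exactly linear data): report
        # the segmented fit at the median, flagged as a boundary outcome
        psi, converged = float(np.quantile(x, 0.5)), False
        boundary = True
    else:
        _, psi, converged = best
        boundary = (psi - x_min <= guard) or (x_max - psi <= guard)

    beta, resid, _ = _segmented_refit(x, y, T, psi)
    # the segmented model nests the straight line (slope_change = 0); when a
    # near-boundary psi makes the design ill-conditioned the nested solution
    # can beat the solver's, so take whichever residual is smaller
    lin_cols = [np.ones(n), x] + ([T] if T.shape[1] else [])
    Xl = np.column_stack(lin_cols)
    beta_l, *_ = np.linalg.lstsq(Xl, y, rcond=None)
    resid_l = y - Xl @ beta_l
    if float(resid_l @ resid_l) < float(resid @ resid):
        beta = np.concatenate([beta_l[:2], [0.0], beta_l[2:]])
        resid = resid_l
        boundary = True
    coefs = {"intercept": beta[0], "slope": beta[1], "slope_change": beta[2]}
    # k: intercept, two segment slopes, psi, taxon deviations, variance
    k = 3 + 1 + T.shape[1] + 1
    if n <= k - 1:
        raise FitError(f"n={n} points cannot identify {k - 1} mean-structure parameters")
    fit = ModelFit(
        model_name="broken_stick",
        side=side,
        n=n,
        k=k,
        coefficients=coefs,
        taxon_levels=levels,
        taxon_coding=taxon_coding,
        converged=converged,
        boundary_flag=bool(boundary),
        psi=float(psi),
        data_hash=_data_hash(x, y),
    )
    return _finish_fit(fit, resid)


def fit_model_suite(
    points: pd.DataFrame,
    side: str = "within",
    taxon: bool | None = None,
    taxon_coding: str = "sum_to_zero",
    broken_stick_kwargs: dict | None = None,
) -> dict[str, ModelFit]:
    """Fit the side's full candidate suite.

    The within side fits six models (null, semi-null, linear, log- and
    exp-transformed, broken stick) with taxon fixed effects; the among
    side fits five (no log-transformed model, no taxon term).
    """
    if taxon is None:
        taxon = side == "within"
    suite = WITHIN_SUITE if side == "within" else AMONG_SUITE
    bkw = broken_stick_kwargs or {}
    fits: dict[str, ModelFit] = {}
    common = dict(side=side, taxon=taxon, taxon_coding=taxon_coding)
    for name in suite:
        if name == "null":
            fits[name] = fit_constrained_linear(points, slope=1.0, intercept=0.0, **common)
        elif name == "semi_null":
            fits[name] = fit_constrained_linear(points, intercept=0.0, **common)
        elif name == "linear":
            fits[name] = fit_constrained_linear(points, **common)
        elif name == "log_transformed":
            fits[name] = fit_transformed(points, "log", **common)
        elif name == "exp_transformed":
            fits[name] = fit_transformed(points, "exp", **common)
        elif name == "broken_stick":
            fits[name] = fit_broken_stick(points, **common, **bkw)
    return fits


def aicc(fit: ModelFit) -> float:
    """Small-sample corrected Akaike information criterion.

    AIC = 2k - 2*loglik; AICc = AIC + 2k(k+1)/(n-k-1).
    """
    n, k = fit.n, fit.k
    if n <= k + 1:
        raise FitError(f"AICc undefined for n={n}, k={k} (needs n > k+1)")
    aic = 2.0 * k - 2.0 * fit.loglik
    return aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights exp(-delta/2), normalized; invariant to adding a
    constant to every AICc value."""
    a = np.asarray(aicc_values, float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelComparison:
    """Models ranked by AICc with Akaike weights."""

    fits: list[ModelFit]
    aicc: np.ndarray
    delta_aicc: np.ndarray
    weights: np.ndarray

    @property
    def names(self) -> list[str]:
        return [f.model_name for f in self.fits]

    def __getitem__(self, name: str) -> ModelFit:
        return self.fits[self.names.index(name)]

    def delta_of(self, name: str) -> float:
        return float(self.delta_aicc[self.names.index(name)])

    def weight_of(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])

    @property
    def best_name(self) -> str:
        order = np.lexsort(([f.k for f in self.fits], self.aicc))
        return self.fits[order[0]].model_name

    def evidence_ratio(self, name_i: str, name_j: str) -> float:
        """weight_i / weight_j = exp((delta_j - delta_i)/2)."""
        di = self.delta_of(name_i)
        dj = self.delta_of(name_j)
        return float(np.exp((dj - di) / 2.0))

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "model": self.names,
                "k": [f.k for f in self.fits],
                "aicc": self.aicc,
                "delta_aicc": self.delta_aicc,
                "weight": self.weights,
            }
        )
        return df.sort_values(["delta_aicc", "k"], kind="mergesort").reset_index(drop=True)


def compare_models(fits: list[ModelFit] | dict[str, ModelFit]) -> ModelComparison:
    """Rank fitted models by AICc; all fits must be on identical points."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) != 1:
        raise ValueError("fits were computed on different point sets; not comparable")
    a = np.array([aicc(f) for f in fits])
    delta = a - a.min()
    return ModelComparison(fits=list(fits), aicc=a, delta_aicc=delta, weights=akaike_weights(a))
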