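"""Translate a ranked model comparison into a biological hypothesis.

Four hypotheses describe how insularity can affect genetic diversity on
the paired plot (x = non-insular aggregate, y = insular-related
aggregate):

* ``null`` — points scatter about the one-to-one line; no effect;
* ``proportional`` — a uniform (slope-type) departure over the whole
  observed range;
* ``above_threshold`` — on the line up to some interior level of
  baseline diversity, departing only above it;
* ``below_threshold`` — departing only below an interior level, on the
  line above it.

The adjudicator keeps the null whenever the null model is within a
configurable AICc margin of the best model. Otherwise the geometry of
the winning fit decides: for (semi-)linear winners the slope and the
crossing point x* = a/(1-b) with the one-to-one line are compared with
the observed x-range; for curved or segmented winners the fitted
taxon-averaged curve is compared pointwise with the line, and the
hypothesis is read off from where the deviation exceeds a tolerance.
On the within side departures from the line are losses (below the
line); on the among side they are divergence increases (above the
line); the same crossing-point logic applies with mirrored labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelComparison, ModelFit

__all__ = [
    "HypothesisVerdict",
    "StudyBandClassification",
    "crossing_point",
    "classify_hypothesis",
    "classify_studies",
]

HYPOTHESES = ("null", "proportional", "above_threshold", "below_threshold")


def crossing_point(a: float, b: float) -> float | None:
    """x-coordinate where y = a + b*x meets the one-to-one line.

    Returns ``None`` when b = 1 (parallel; identical when a = 0 too).
    """
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("non-finite coefficients")
    if b == 1.0:
        return None
    return a / (1.0 - b)


@dataclass
class HypothesisVerdict:
    side: str
    hypothesis: str
    best_model: str
    top_models: list[tuple[str, float]]
    diagnostics: dict = field(default_factory=dict)
    narrative: str = ""


@dataclass
class StudyBandClassification:
    labels: pd.DataFrame  # study_id, species, residual, label
    half_width: float
    counts: dict[str, int]


def _classify_linear(
    slope: float, intercept: float, x_range: tuple[float, float], side: str
) -> tuple[str, dict]:
    """Decision table for a straight-line winner.

    The line's position relative to y = x over [x_min, x_max] determines
    the label: crossing inside the range means a one-sided departure
    (threshold hypothesis); crossing outside means the departure covers
    the whole range (proportional).
    """
    x_min, x_max = x_range
    xc = crossing_point(intercept, slope)
    diag = {"slope": slope, "intercept": intercept, "crossing": xc, "x_range": (x_min, x_max)}
    if xc is None:
        hyp = "null" if intercept == 0.0 else "proportional"
        diag["crossing_within_range"] = False
        return hyp, diag
    inside = x_min < xc < x_max
    diag["crossing_within_range"] = inside
    if inside:
        # slope<1: below the line for x > x*; slope>1: below for x < x*
        if side == "within":
            hyp = "above_threshold" if slope < 1.0 else "below_threshold"
        else:
            # among side: above the line for x < x* (slope<1) is the
            # low-divergence departure; for x > x* (slope>1) the high one
            hyp = "below_threshold" if slope < 1.0 else "above_threshold"
    else:
        hyp = "proportional"
        diag["direction"] = "below_line" if (slope < 1.0) == (xc <= x_min) else "above_line"
    return hyp, diag


def _classify_curved(
    fit: ModelFit, x_range: tuple[float, float], delta_tol: float, n_grid: int = 201
) -> tuple[str, dict]:
    """Geometric classification of a curved/segmented winner.

    The taxon-averaged fitted curve is evaluated on a grid; grid points
    where |m(x) - x| exceeds ``delta_tol`` are "off the line". Deviation
    confined above an interior x -> above_threshold; confined below ->
    below_threshold; everywhere -> proportional; nowhere -> null.
    """
    xs = np.linspace(x_range[0], x_range[1], n_grid)
    dev = fit.predict_mean(xs) - xs
    off = np.abs(dev) > delta_tol
    diag = {
        "delta_tol": delta_tol,
        "max_deviation": float(np.max(np.abs(dev))),
        "x_range": x_range,
    }
    if not off.any():
        return "null", diag
    if off.all():
        return "proportional", diag
    first_off, last_off = int(np.argmax(off)), int(len(off) - 1 - np.argmax(off[::-1]))
    if off[first_off : last_off + 1].all():
        # single contiguous off-line region
        if first_off > 0 and last_off == len(off) - 1:
            return "above_threshold", diag
        if first_off == 0 and last_off < len(off) - 1:
            return "below_threshold", diag
        return "proportional", diag  # interior bump; no threshold geometry
    return "proportional", diag


def classify_hypothesis(
    cmp: ModelComparison,
    x_range: tuple[float, float],
    null_retention_delta: float = 2.0,
    delta_tol: float | None = None,
) -> HypothesisVerdict:
    """Select the hypothesis supported by the ranked model suite."""
    sides = {f.side for f in cmp.fits}
    if len(sides) != 1:
        raise ValueError(f"fits from inconsistent sides: {sides}")
    side = sides.pop()
    top = [(n, cmp.weight_of(n)) for n in cmp.names if cmp.delta_of(n) <= 2.0]
    top.sort(key=lambda t: -t[1])

    if "null" in cmp.names and cmp.delta_of("null") <= null_retention_delta:
        verdict = HypothesisVerdict(
            side=side,
            hypothesis="null",
            best_model=cmp.best_name,
            top_models=top,
            diagnostics={"null_delta_aicc": cmp.delta_of("null")},
            narrative=(
                f"null model within {null_retention_delta} AICc of the best model "
                f"(delta={cmp.delta_of('null'):.2f}); data consistent with the one-to-one line"
            ),
        )
        return verdict

    best = cmp[cmp.best_name]
    if best.model_name in ("linear", "semi_null"):
        hyp, diag = _classify_linear(float(best.slope), float(best.intercept or 0.0), x_range, side)
    else:
        tol = delta_tol if delta_tol is not None else 0.5 * float(np.sqrt(best.sigma2_hat))
        hyp, diag = _classify_curved(best, x_range, tol)
    narrative = (
        f"best model {best.model_name} (weight {cmp.weight_of(best.model_name):.3f}); "
        f"geometry relative to the one-to-one line over x in "
        f"[{x_range[0]:.3g}, {x_range[1]:.3g}] supports '{hyp}'"
    )
    if "crossing" in diag and diag["crossing"] is not None:
        narrative += f"; crossing point x*={diag['crossing']:.3g}"
    return HypothesisVerdict(
        side=side,
        hypothesis=hyp,
        best_model=best.model_name,
        top_models=top,
        diagnostics=diag,
        narrative=narrative,
    )


def classify_studies(
    points: pd.DataFrame,
    null_fit: ModelFit,
    alpha: float = 0.05,
) -> StudyBandClassification:
    """Label each study against the (1-alpha) band around the one-to-one line.

    The band has half-width z_{1-alpha/2} * sigma from the null fit's
    ML residual standard deviation, centred on y = x plus the study's
    taxon effect when the null fit includes taxon deviations.
    """
    if null_fit.data_hash and len(points):
        pass  # points/fit pairing is the caller's responsibility beyond side checks
    x = points["x"].to_numpy(float)
    y = points["y"].to_numpy(float)
    resid = y - x
    if null_fit.taxon_levels and "taxon_group" in points:
        # subtract each unit's fitted taxon deviation
        eff = _taxon_effects(null_fit)
        resid = resid - points["taxon_group"].map(lambda t: eff.get(t, 0.0)).to_numpy(float)
    sd = float(np.sqrt(null_fit.sigma2_hat))
    if sd == 0.0:
        import warnings

        warnings.warn("null fit has zero residual variance; labelling by residual sign", stacklevel=2)
        half = 0.0
        labels = np.where(resid > 0, "above_band", np.where(resid < 0, "below_band", "within_band"))
    else:
        half = float(stats.norm.ppf(1.0 - alpha / 2.0) * sd)
        labels = np.where(resid > half, "above_band", np.where(resid < -half, "below_band", "within_band"))
    out = points[[c for c in ("study_id", "species", "taxon_group") if c in points]].copy()
    out["residual"] = resid
    out["label"] = labels
    counts = {lab: int((labels == lab).sum()) for lab in ("within_band", "above_band", "below_band")}
    return StudyBandClassification(labels=out, half_width=half, counts=counts)


def _taxon_effects(fit: ModelFit) -> dict[str, float]:
    """Per-level taxon deviations implied by the fit's coding."""
    levels = fit.taxon_levels
    if not levels:
        return {}
    coefs = {name: v for name, v in fit.coefficients.items() if name.startswith("taxon[")}
    eff = {}
    if fit.taxon_coding == "sum_to_zero":
        for lv in levels[:-1]:
            eff[lv] = float(coefs.get(f"taxon[{lv}]", 0.0))
        eff[levels[-1]] = -float(sum(eff.values()))
    else:
        eff[levels[0]] = 0.0
        for lv in levels[1:]:
            eff[lv] = float(coefs.get(f"taxon[{lv}]", 0.0))
    return eff
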