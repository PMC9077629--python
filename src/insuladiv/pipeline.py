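"""End-to-end orchestration: validate -> standardize -> pair -> shift ->
fit -> compare -> adjudicate -> classify, with table rendering and
reproducible on-disk reports."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjudicate import (
    HypothesisVerdict,
    StudyBandClassification,
    classify_hypothesis,
    classify_studies,
)
from .models import ModelComparison, compare_models, fit_constrained_linear, fit_model_suite
from .preprocess import pair_among, pair_within, shift_to_unit_min, standardize
from .records import RecordSet, read_records, validate_inclusion
from .synth import SynthConfig, generate_metadataset

__all__ = ["RunConfig", "SideResult", "RunReport", "analyse_side", "run_pipeline", "render_comparison_table"]

#: model -> hypothesis families a model can express (for the report tables)
MODEL_HYPOTHESIS_MAP = {
    "null": "null",
    "semi_null": "proportional",
    "linear": "proportional / above_threshold / below_threshold (by parameters)",
    "log_transformed": "threshold (by geometry)",
    "exp_transformed": "threshold (by geometry)",
    "broken_stick": "above_threshold / below_threshold (by breakpoint)",
}


@dataclass
class RunConfig:
    gd_path: str | None = None
    divergence_path: str | None = None
    schema_config: dict | None = None
    synth: SynthConfig | None = None
    sides: tuple[str, ...] = ("within", "among")
    taxon_in_models: bool = True
    taxon_coding: str = "sum_to_zero"
    averaging: str = "population_first"
    band_alpha: float = 0.05
    null_retention_delta: float = 2.0
    broken_stick_kwargs: dict = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0


@dataclass
class SideResult:
    side: str
    points: pd.DataFrame
    shift_constant: float
    fits: dict
    comparison: ModelComparison
    verdict: HypothesisVerdict
    bands: StudyBandClassification | None
    bands_unadjusted: StudyBandClassification | None = None


@dataclass
class RunReport:
    config: RunConfig
    record_set: RecordSet
    exclusion_log: pd.DataFrame
    standardization_constants: pd.DataFrame
    sides: dict[str, SideResult]
    manifest: dict


def analyse_side(
    rs: RecordSet,
    side: str,
    taxon_in_models: bool = True,
    taxon_coding: str = "sum_to_zero",
    averaging: str = "population_first",
    band_alpha: float = 0.05,
    null_retention_delta: float = 2.0,
    broken_stick_kwargs: dict | None = None,
) -> SideResult:
    """Run one analysis side (within or among) on a validated RecordSet."""
    std = standardize(rs)
    if side == "within":
        paired = pair_within(std, averaging=averaging)
        taxon = taxon_in_models
    elif side == "among":
        paired = pair_among(std)
        taxon = False  # among-side models carry no taxon term
    else:
        raise ValueError(f"unknown side {side!r}")
    if len(paired) < 8:
        raise ValueError(f"{side} side has only {len(paired)} paired points; too few to fit the suite")
    paired, shift_c = shift_to_unit_min(paired)
    fits = fit_model_suite(
        paired,
        side=side,
        taxon=taxon,
        taxon_coding=taxon_coding,
        broken_stick_kwargs=broken_stick_kwargs,
    )
    cmp = compare_models(fits)
    x_range = (float(paired["x"].min()), float(paired["x"].max()))
    verdict = classify_hypothesis(cmp, x_range, null_retention_delta=null_retention_delta)
    bands = classify_studies(paired, fits["null"], alpha=band_alpha)
    bands_raw = None
    if taxon:
        raw_null = fit_constrained_linear(paired, side=side, slope=1.0, intercept=0.0, taxon=False)
        bands_raw = classify_studies(paired, raw_null, alpha=band_alpha)
    return SideResult(
        side=side,
        points=paired,
        shift_constant=shift_c,
        fits=fits,
        comparison=cmp,
        verdict=verdict,
        bands=bands,
        bands_unadjusted=bands_raw,
    )


def render_comparison_table(cmp: ModelComparison, mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Publication-style comparison table: rows sorted by ascending
    ΔAICc, the best model's ΔAICc shown as an em dash, weights to three
    decimals with values below 0.0005 rendered '<0.001'."""
    mapping = mapping or MODEL_HYPOTHESIS_MAP
    tab = cmp.table()
    rows = []
    for _, r in tab.iterrows():
        delta = "—" if r["delta_aicc"] == 0.0 else f"{r['delta_aicc']:.1f}"
        weight = "<0.001" if r["weight"] < 0.0005 else f"{r['weight']:.3f}"
        fit = cmp[r["model"]]
        flags = " (boundary)" if getattr(fit, "boundary_flag", False) else ""
        rows.append(
            {
                "model": r["model"] + flags,
                "hypothesis": mapping.get(r["model"], ""),
                "delta_aicc": delta,
                "weight": weight,
            }
        )
    return pd.DataFrame(rows)


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    d = dataclasses.asdict(cfg)
    d.pop("outdir", None)  # hash covers the analysis, not where it is written
    blob = json.dumps(d, default=default, sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _verdict_json(v: HypothesisVerdict) -> dict:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(x) for k, x in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(x) for x in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return clean(
        {
            "side": v.side,
            "hypothesis": v.hypothesis,
            "best_model": v.best_model,
            "top_models": v.top_models,
            "diagnostics": v.diagnostics,
            "narrative": v.narrative,
        }
    )


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full paired insularity analysis and (optionally) write
    its report files under ``cfg.outdir``."""
    if cfg.synth is not None:
        rs, _truth = generate_metadataset(cfg.synth)
    elif cfg.gd_path is not None:
        rs, _report = read_records(cfg.gd_path, cfg.divergence_path, cfg.schema_config)
    else:
        raise ValueError("RunConfig needs either input paths or a synth config")
    rs, log = validate_inclusion(rs)
    std = standardize(rs)

    sides: dict[str, SideResult] = {}
    for side in cfg.sides:
        try:
            sides[side] = analyse_side(
                rs,
                side,
                taxon_in_models=cfg.taxon_in_models,
                taxon_coding=cfg.taxon_coding,
                averaging=cfg.averaging,
                band_alpha=cfg.band_alpha,
                null_retention_delta=cfg.null_retention_delta,
                broken_stick_kwargs=cfg.broken_stick_kwargs,
            )
        except ValueError as exc:
            raise ValueError(f"[{side}] {exc}") from exc

    manifest = {
        "insuladiv_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "sides": list(sides),
        "n_within_units": len(rs.within_units or []),
        "n_among_units": len(rs.among_units or []),
    }
    report = RunReport(
        config=cfg,
        record_set=rs,
        exclusion_log=log,
        standardization_constants=std.constants,
        sides=sides,
        manifest=manifest,
    )
    if cfg.outdir is not None:
        _write_report(report, Path(cfg.outdir))
    return report


def _write_report(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.exclusion_log.to_csv(outdir / "exclusion_log.tsv", sep="\t", index=False)
    report.standardization_constants.to_csv(outdir / "standardization_constants.tsv", sep="\t", index=False)
    for side, res in report.sides.items():
        render_comparison_table(res.comparison).to_csv(
            outdir / f"{side}_model_comparison.tsv", sep="\t", index=False
        )
        pts = res.points.copy()
        xs = pts["x"].to_numpy(float)
        for name, fit in res.fits.items():
            pts[f"fitted_{name}"] = fit.predict_mean(xs)
        pts.to_csv(outdir / f"{side}_paired_points.tsv", sep="\t", index=False)
        with open(outdir / f"{side}_verdict.json", "w") as fh:
            json.dump(_verdict_json(res.verdict), fh, indent=2, sort_keys=True)
        if res.bands is not None:
            bands = res.bands.labels.copy()
            bands["band_half_width"] = res.bands.half_width
            bands.to_csv(outdir / f"{side}_study_bands.tsv", sep="\t", index=False)
        if res.bands_unadjusted is not None:
            bands = res.bands_unadjusted.labels.copy()
            bands["band_half_width"] = res.bands_unadjusted.half_width
            bands.to_csv(outdir / f"{side}_study_bands_unadjusted.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
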