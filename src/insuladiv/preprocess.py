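"""Standardization and paired aggregation of genetic-diversity records.

Published studies report diversity on incommensurable scales (allele
counts, heterozygosities, percent polymorphism, ...), so every metric
type is z-scored across all population-level values of that type before
any cross-study comparison. Each study-species unit is then collapsed to
a single paired point: x is the aggregate over non-insular populations
and y the aggregate over insular populations (within side), or x the
mean divergence over non-insular/non-insular pairs and y over
insular/non-insular pairs (among side). Finally both axes are shifted by
a common constant so the minimum value in the paired dataset is exactly
1, which keeps the log-transformed candidate model well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import RecordSet

__all__ = [
    "StandardizedDataset",
    "standardize",
    "pair_within",
    "pair_among",
    "shift_to_unit_min",
    "PAIRED_COLUMNS",
]

PAIRED_COLUMNS = ["study_id", "species", "taxon_group", "side", "x", "y"]


class StandardizationError(ValueError):
    """A metric type cannot be standardized (too few values or zero variance)."""


@dataclass
class StandardizedDataset:
    """RecordSet with a z-scored ``z_value`` column and the constants used."""

    records: RecordSet
    gd: pd.DataFrame          # gd records + z_value
    divergence: pd.DataFrame  # divergence records + z_value
    constants: pd.DataFrame   # metric_type, table, mean, sd, n


def _zscore_table(df: pd.DataFrame, table: str) -> tuple[pd.DataFrame, list[dict]]:
    df = df.copy()
    df["z_value"] = np.nan
    consts = []
    for metric, sub in df.groupby("metric_type", sort=True):
        vals = sub["value"].to_numpy(float)
        if len(vals) < 2 or np.unique(vals).size < 2:
            raise StandardizationError(
                f"metric {metric!r} has fewer than two distinct values; cannot standardize"
            )
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if sd == 0.0:
            raise StandardizationError(f"metric {metric!r} has zero variance")
        df.loc[sub.index, "z_value"] = (vals - mean) / sd
        consts.append({"metric_type": metric, "table": table, "mean": mean, "sd": sd, "n": len(vals)})
    return df, consts


def standardize(records: RecordSet) -> StandardizedDataset:
    """z-score each metric type over all population-level values of that type.

    Within-population GD metrics and among-population divergence metrics
    are standardized independently; the per-metric (mean, sd, n)
    constants are retained so the transform can be inverted for
    reporting.
    """
    consts: list[dict] = []
    if len(records.gd):
        gd, c = _zscore_table(records.gd, "gd")
        consts.extend(c)
    else:
        gd = records.gd.assign(z_value=pd.Series(dtype=float))
    if len(records.divergence):
        div, c = _zscore_table(records.divergence, "divergence")
        consts.extend(c)
    else:
        div = records.divergence.assign(z_value=pd.Series(dtype=float))
    constants = pd.DataFrame(consts, columns=["metric_type", "table", "mean", "sd", "n"])
    return StandardizedDataset(records=records, gd=gd, divergence=div, constants=constants)


def pair_within(std: StandardizedDataset, averaging: str = "population_first") -> pd.DataFrame:
    """Collapse each within-side unit to one (x, y) paired point.

    With ``averaging='population_first'`` (default) each population's
    z-values are first averaged across the metric types it reports, then
    those population means are averaged across non-insular populations
    (x) and insular populations (y); this stops a single population
    reporting many metrics from dominating its study. ``'flat'`` averages
    all (population, metric) cells directly.
    """
    if averaging not in ("population_first", "flat"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    units = std.records.within_units
    if units is None:
        units = std.records.units()
    rows = []
    gd = std.gd
    for study, species in units:
        sub = gd[(gd["study_id"] == study) & (gd["species"] == species)]
        if not len(sub):
            continue
        if averaging == "population_first":
            pop_means = sub.groupby(["population_id", "insular"])["z_value"].mean().reset_index()
            x_vals = pop_means.loc[~pop_means["insular"], "z_value"]
            y_vals = pop_means.loc[pop_means["insular"], "z_value"]
        else:
            x_vals = sub.loc[~sub["insular"], "z_value"]
            y_vals = sub.loc[sub["insular"], "z_value"]
        if not len(x_vals) or not len(y_vals):
            continue  # no usable values on one side; unit skipped
        pops = sub[["population_id", "insular"]].drop_duplicates()
        rows.append(
            {
                "study_id": study,
                "species": species,
                "taxon_group": sub["taxon_group"].iloc[0],
                "side": "within",
                "x": float(x_vals.mean()),
                "y": float(y_vals.mean()),
                "n_metrics_averaged": int(sub["metric_type"].nunique()),
                "n_populations_x": int((~pops["insular"]).sum()),
                "n_populations_y": int(pops["insular"].sum()),
            }
        )
    return pd.DataFrame(rows)


def pair_among(std: StandardizedDataset) -> pd.DataFrame:
    """Collapse each among-side study to one (x, y) paired divergence point.

    x averages standardized divergence over non-insular/non-insular
    pairs, y over insular/non-insular pairs; insular/insular pairs are
    excluded (and counted) because they were too rare in the literature
    to analyse.
    """
    studies = std.records.among_units
    if studies is None:
        studies = sorted(set(std.divergence["study_id"])) if len(std.divergence) else []
    rows = []
    for study in studies:
        sub = std.divergence[std.divergence["study_id"] == study]
        flags = std.records.population_flags(study)
        kinds = sub.apply(
            lambda r: (
                "ins_ins"
                if flags.get(r["population_id_a"]) and flags.get(r["population_id_b"])
                else "non_non"
                if not flags.get(r["population_id_a"]) and not flags.get(r["population_id_b"])
                else "ins_non"
            ),
            axis=1,
        )
        x_vals = sub.loc[kinds == "non_non", "z_value"]
        y_vals = sub.loc[kinds == "ins_non", "z_value"]
        if not len(x_vals) or not len(y_vals):
            continue
        gd_sub = std.records.gd[std.records.gd["study_id"] == study]
        taxon = gd_sub["taxon_group"].iloc[0] if len(gd_sub) else ""
        rows.append(
            {
                "study_id": study,
                "species": gd_sub["species"].iloc[0] if len(gd_sub) else "",
                "taxon_group": taxon,
                "side": "among",
                "x": float(x_vals.mean()),
                "y": float(y_vals.mean()),
                "n_metrics_averaged": int(sub["metric_type"].nunique()),
                "n_pairs_x": int(len(x_vals)),
                "n_pairs_y": int(len(y_vals)),
                "n_ins_ins_excluded": int((kinds == "ins_ins").sum()),
            }
        )
    return pd.DataFrame(rows)


def shift_to_unit_min(paired: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Shift both axes by one constant so the dataset minimum is exactly 1.

    The constant is c = 1 - min over all x and y values; applying it to
    both axes preserves every slope, intercept offset and crossing with
    the one-to-one line while guaranteeing log(x) is defined.
    """
    if not len(paired):
        raise ValueError("empty paired dataset")
    xy = np.concatenate([paired["x"].to_numpy(float), paired["y"].to_numpy(float)])
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite paired values")
    c = 1.0 - float(xy.min())
    out = paired.copy()
    out["x"] = out["x"] + c
    out["y"] = out["y"] + c
    # guard against floating drift: the minimum must be exactly 1
    m = min(out["x"].min(), out["y"].min())
    if m != 1.0:
        out[["x", "y"]] = out[["x", "y"]] + (1.0 - m)
    return out, c
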