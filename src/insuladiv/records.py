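"""Reading, validating and filtering literature-style genetic-diversity records.

The analysis consumes two long-format tables harvested from published
studies:

* within-population genetic-diversity (GD) measurements — one row per
  (study, species, population, metric type);
* among-population divergence measurements — one row per (study,
  population pair, metric type).

This module parses those tables, normalizes categorical labels, enforces
the record invariants, and applies the inclusion criteria: a study-species
unit enters the within-population analysis only if it reports at least
three populations, at least one flagged a priori as insular and at least
two as non-insular, with at least one GD metric; the among-population side
additionally needs at least one non-insular/non-insular pair and one
insular/non-insular pair of divergence values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TAXON_GROUPS",
    "GD_METRICS",
    "DIVERGENCE_METRICS",
    "HABITATS",
    "MARKER_TYPES",
    "DEFAULT_TAXON_ALIASES",
    "RecordSet",
    "ParseReport",
    "RecordValidationError",
    "DuplicateKeyError",
    "read_records",
    "write_records",
    "validate_inclusion",
]

TAXON_GROUPS = ("mammals", "birds", "herps", "fish", "invertebrates", "plants")
GD_METRICS = (
    "mean_alleles",
    "allelic_richness",
    "heterozygosity",
    "haplotype_diversity",
    "nucleotide_diversity",
    "percent_polymorphism",
)
DIVERGENCE_METRICS = ("FST", "GST", "nei_distance", "jost_d", "rogers_distance", "migrants")
HABITATS = ("marine", "terrestrial", "freshwater")
MARKER_TYPES = ("microsatellite", "allozyme", "RFLP", "SNP", "mtDNA")

#: Common literature labels mapped onto the six crude taxon groups.
DEFAULT_TAXON_ALIASES = {
    "reptiles": "herps",
    "amphibians": "herps",
    "herptiles": "herps",
    "mammal": "mammals",
    "bird": "birds",
    "fishes": "fish",
    "invertebrate": "invertebrates",
    "insects": "invertebrates",
    "plant": "plants",
}

GD_COLUMNS = [
    "study_id",
    "species",
    "taxon_group",
    "habitat",
    "population_id",
    "insular",
    "metric_type",
    "value",
    "marker_type",
]
DIV_COLUMNS = ["study_id", "population_id_a", "population_id_b", "metric_type", "value"]

_UNIT_INTERVAL_GD = {"heterozygosity", "haplotype_diversity"}
_UNIT_INTERVAL_DIV = {"FST", "GST", "jost_d"}

_TRUE_LABELS = {"1", "true", "t", "yes", "y", "insular"}
_FALSE_LABELS = {"0", "false", "f", "no", "n", "non-insular", "noninsular", "non_insular"}


class RecordValidationError(ValueError):
    """Fatal structural problem in an input record table."""


class DuplicateKeyError(RecordValidationError):
    """A (study, population, metric) key occurs more than once."""


@dataclass
class ParseReport:
    """Row-level parse problems and non-fatal validation warnings."""

    skipped_rows: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped_rows)


@dataclass
class RecordSet:
    """Container for the two harvested tables plus inclusion bookkeeping.

    ``gd`` and ``divergence`` are DataFrames with the canonical column
    sets; ``within_units`` / ``among_units`` are filled by
    :func:`validate_inclusion`.
    """

    gd: pd.DataFrame
    divergence: pd.DataFrame
    within_units: list[tuple[str, str]] | None = None
    among_units: list[str] | None = None

    def study_index(self) -> pd.DataFrame:
        """Per-study roster: one row per population with insular flag and taxon."""
        cols = ["study_id", "species", "taxon_group", "population_id", "insular"]
        return self.gd[cols].drop_duplicates().reset_index(drop=True)

    def population_flags(self, study_id: str) -> dict[str, bool]:
        sub = self.gd[self.gd["study_id"] == study_id]
        return dict(zip(sub["population_id"], sub["insular"]))

    def units(self) -> list[tuple[str, str]]:
        """All (study_id, species) analysis units present in the GD table."""
        return sorted(set(zip(self.gd["study_id"], self.gd["species"])))


def _empty_gd() -> pd.DataFrame:
    return pd.DataFrame(columns=GD_COLUMNS)


def _empty_div() -> pd.DataFrame:
    return pd.DataFrame(columns=DIV_COLUMNS)


def _parse_bool(raw: str) -> bool:
    token = str(raw).strip().lower()
    if token in _TRUE_LABELS:
        return True
    if token in _FALSE_LABELS:
        return False
    raise ValueError(f"cannot interpret insular flag {raw!r}")


def _apply_mapping(df: pd.DataFrame, mapping: dict[str, str] | None, required: list[str], table: str) -> pd.DataFrame:
    if mapping:
        df = df.rename(columns={v: k for k, v in mapping.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordValidationError(f"{table} table is missing required column(s): {', '.join(missing)}")
    return df


def _parse_gd(df: pd.DataFrame, aliases: dict[str, str], report: ParseReport) -> pd.DataFrame:
    required = ["study_id", "taxon_group", "population_id", "insular", "metric_type", "value"]
    rows = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            value = float(row["value"])
        except (TypeError, ValueError):
            report.skipped_rows.append((line, f"unparseable value {row['value']!r}"))
            continue
        if pd.isna(value):
            report.skipped_rows.append((line, "missing value"))
            continue
        if not pd.notna(value) or value != value or abs(value) == float("inf"):
            report.skipped_rows.append((line, f"non-finite value {value!r}"))
            continue
        taxon = str(row["taxon_group"]).strip().lower()
        taxon = aliases.get(taxon, taxon)
        if taxon not in TAXON_GROUPS:
            raise RecordValidationError(
                f"unknown taxon group {row['taxon_group']!r} at line {line}; "
                f"allowed: {', '.join(TAXON_GROUPS)} (add an alias to the schema config)"
            )
        metric = str(row["metric_type"]).strip()
        metric_l = metric.lower()
        if metric_l not in GD_METRICS:
            raise RecordValidationError(f"unknown GD metric type {metric!r} at line {line}")
        try:
            insular = _parse_bool(row["insular"])
        except ValueError as exc:
            report.skipped_rows.append((line, str(exc)))
            continue
        habitat = row.get("habitat")
        habitat = str(habitat).strip().lower() if pd.notna(habitat) and str(habitat).strip() else None
        if habitat is not None and habitat not in HABITATS:
            report.warnings.append(f"line {line}: unknown habitat {habitat!r} kept as-is")
        marker = row.get("marker_type")
        marker = str(marker).strip() if pd.notna(marker) and str(marker).strip() else None
        if metric_l in _UNIT_INTERVAL_GD and not (0.0 <= value <= 1.0):
            report.warnings.append(
                f"line {line}: {metric_l} value {value} outside [0,1] (kept; literature rounding)"
            )
        rows.append(
            {
                "study_id": str(row["study_id"]).strip(),
                "species": str(row.get("species", "") or "").strip(),
                "taxon_group": taxon,
                "habitat": habitat,
                "population_id": str(row["population_id"]).strip(),
                "insular": insular,
                "metric_type": metric_l,
                "value": value,
                "marker_type": marker,
            }
        )
    out = pd.DataFrame(rows, columns=GD_COLUMNS) if rows else _empty_gd()
    key = ["study_id", "species", "population_id", "metric_type"]
    if len(out):
        dup = out.duplicated(subset=key, keep=False)
        if dup.any():
            first = out.loc[dup, key].iloc[0].tolist()
            raise DuplicateKeyError(f"duplicate (study, population, metric) key: {tuple(first)}")
    return out


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _parse_div(df: pd.DataFrame, report: ParseReport) -> pd.DataFrame:
    rows = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            value = float(row["value"])
        except (TypeError, ValueError):
            report.skipped_rows.append((line, f"unparseable divergence value {row['value']!r}"))
            continue
        if pd.isna(value):
            report.skipped_rows.append((line, "missing divergence value"))
            continue
        metric = str(row["metric_type"]).strip()
        canon = {m.lower(): m for m in DIVERGENCE_METRICS}
        if metric.lower() not in canon:
            raise RecordValidationError(f"unknown divergence metric {metric!r} at line {line}")
        metric = canon[metric.lower()]
        a = str(row["population_id_a"]).strip()
        b = str(row["population_id_b"]).strip()
        if a == b:
            report.skipped_rows.append((line, f"self-pair ({a},{b})"))
            continue
        a, b = _canonical_pair(a, b)
        if metric in _UNIT_INTERVAL_DIV and not (0.0 <= value <= 1.0):
            report.warnings.append(f"line {line}: {metric} value {value} outside [0,1] (kept)")
        if metric == "migrants" and value < 0:
            report.skipped_rows.append((line, f"negative migrant count {value}"))
            continue
        rows.append(
            {
                "study_id": str(row["study_id"]).strip(),
                "population_id_a": a,
                "population_id_b": b,
                "metric_type": metric,
                "value": value,
            }
        )
    out = pd.DataFrame(rows, columns=DIV_COLUMNS) if rows else _empty_div()
    if len(out):
        out = out.drop_duplicates().reset_index(drop=True)
    return out


def read_records(
    gd_path,
    divergence_path=None,
    schema_config: dict | None = None,
) -> tuple[RecordSet, ParseReport]:
    """Read the GD and (optionally) divergence CSV tables.

    ``schema_config`` may contain ``gd_columns`` / ``divergence_columns``
    (mapping canonical column name -> file column name) and
    ``taxon_aliases`` (extra label -> canonical taxon group entries merged
    over the defaults).
    """
    schema_config = schema_config or {}
    aliases = dict(DEFAULT_TAXON_ALIASES)
    aliases.update(schema_config.get("taxon_aliases", {}))
    report = ParseReport()

    raw = pd.read_csv(gd_path, dtype=str, keep_default_na=True)
    raw = _apply_mapping(
        raw,
        schema_config.get("gd_columns"),
        ["study_id", "taxon_group", "population_id", "insular", "metric_type", "value"],
        "GD",
    )
    gd = _parse_gd(raw, aliases, report)

    if divergence_path is not None:
        raw_div = pd.read_csv(divergence_path, dtype=str, keep_default_na=True)
        raw_div = _apply_mapping(
            raw_div,
            schema_config.get("divergence_columns"),
            DIV_COLUMNS,
            "divergence",
        )
        div = _parse_div(raw_div, report)
    else:
        div = _empty_div()
    return RecordSet(gd=gd, divergence=div), report


def write_records(records: RecordSet, gd_path, divergence_path=None) -> None:
    """Write the canonical CSV tables; round-trips through :func:`read_records`."""
    records.gd.to_csv(gd_path, index=False)
    if divergence_path is not None:
        if len(records.divergence):
            records.divergence.to_csv(divergence_path, index=False)
        else:
            warnings.warn("divergence table empty; divergence file not written", stacklevel=2)


def _pair_kinds(div: pd.DataFrame, flags: dict[str, bool]) -> pd.Series:
    def kind(row):
        fa = flags.get(row["population_id_a"])
        fb = flags.get(row["population_id_b"])
        if fa is None or fb is None:
            return "unknown"
        if fa and fb:
            return "ins_ins"
        if not fa and not fb:
            return "non_non"
        return "ins_non"

    if not len(div):
        return pd.Series(dtype=object)
    return div.apply(kind, axis=1)


def validate_inclusion(records: RecordSet) -> tuple[RecordSet, pd.DataFrame]:
    """Apply the study-level inclusion criteria per analysis side.

    Returns a filtered RecordSet (with ``within_units`` and ``among_units``
    populated) and an exclusion log DataFrame with columns
    (study_id, species, side, reason). A unit may pass one side and fail
    the other independently.
    """
    if not len(records.gd) and not len(records.divergence):
        raise RecordValidationError("empty record set")

    log_rows = []
    within_units: list[tuple[str, str]] = []
    for (study, species), sub in records.gd.groupby(["study_id", "species"], sort=True):
        pops = sub[["population_id", "insular"]].drop_duplicates()
        n_pops = len(pops)
        n_ins = int(pops["insular"].sum())
        n_non = n_pops - n_ins
        if sub["taxon_group"].nunique() > 1:
            log_rows.append((study, species, "within", "inconsistent taxon group within unit"))
            continue
        if n_pops < 3:
            log_rows.append((study, species, "within", "fewer than three populations"))
            continue
        if n_ins < 1:
            log_rows.append((study, species, "within", "no insular population"))
            continue
        if n_non < 2:
            log_rows.append((study, species, "within", "fewer than two non-insular populations"))
            continue
        within_units.append((study, species))

    among_units: list[str] = []
    div_studies = sorted(set(records.divergence["study_id"])) if len(records.divergence) else []
    for study in div_studies:
        flags = records.population_flags(study)
        sub = records.divergence[records.divergence["study_id"] == study]
        kinds = _pair_kinds(sub, flags)
        if (kinds == "unknown").any():
            log_rows.append((study, "", "among", "divergence pair references population missing from roster"))
            continue
        pops = set(sub["population_id_a"]) | set(sub["population_id_b"]) | set(flags)
        n_ins = sum(bool(flags.get(p)) for p in pops if p in flags)
        n_non = sum(not flags[p] for p in pops if p in flags)
        if n_ins + n_non < 3:
            log_rows.append((study, "", "among", "fewer than three populations"))
            continue
        if n_ins < 1:
            log_rows.append((study, "", "among", "no insular population"))
            continue
        if n_non < 2:
            log_rows.append((study, "", "among", "fewer than two non-insular populations"))
            continue
        if not (kinds == "non_non").any():
            log_rows.append((study, "", "among", "no non-insular/non-insular divergence pair"))
            continue
        if not (kinds == "ins_non").any():
            log_rows.append((study, "", "among", "no insular/non-insular divergence pair"))
            continue
        among_units.append(study)
    # GD-only studies that never report divergence are logged on the among side
    for study, species in records.units():
        if study not in div_studies:
            log_rows.append((study, species, "among", "no divergence records"))

    log = pd.DataFrame(log_rows, columns=["study_id", "species", "side", "reason"])
    if not within_units and not among_units:
        raise RecordValidationError(
            "all studies excluded by the inclusion criteria; first reasons:\n"
            + log.head(10).to_string(index=False)
        )

    keep_gd = records.gd.apply(
        lambda r: (r["study_id"], r["species"]) in set(within_units) or r["study_id"] in set(among_units),
        axis=1,
    )
    gd = records.gd[keep_gd].reset_index(drop=True) if len(records.gd) else records.gd
    div = (
        records.divergence[records.divergence["study_id"].isin(among_units)].reset_index(drop=True)
        if len(records.divergence)
        else records.divergence
    )
    filtered = RecordSet(gd=gd, divergence=div, within_units=within_units, among_units=among_units)
    return filtered, log
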