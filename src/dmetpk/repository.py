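"""Readers, writers and the meta-analysis inclusion filter.

The repository file format mirrors a curated literature spreadsheet: one row
per published observation, with the column dictionary documented in
:data:`COLUMNS`.  ``filter_for_meta`` applies the pre-defined inclusion
criteria used to select studies for pooling:

i.   only individual (non-pooled) donor samples;
ii.  absolute quantification by LC-MS/MS or Western blotting (excluding
     global proteomics, mRNA and activity data);
iii. abundance expressed per mg microsomal protein (canonical unit or a
     power-of-ten rescaling; arbitrary/relative units are excluded, never
     converted heuristically);
iv.  at least two reports from different laboratories (distinct citation
     keys) per protein/tissue group.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import (
    CANONICAL_UNIT,
    MATRICES,
    METHODS,
    ProteinAbundanceRecord,
    StudyObservation,
    StudySet,
    TISSUES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "COLUMNS",
    "RepositoryFormatError",
    "ExclusionReport",
    "read_repository",
    "write_repository",
    "filter_for_meta",
]

#: documented header of the repository CSV/TSV/XLSX interchange format.
COLUMNS = [
    "protein_name",
    "gene_name",
    "uniprot_id",
    "tissue",
    "matrix",
    "stat_kind",
    "value",
    "value_sd",
    "range_min",
    "range_max",
    "value_cv_pct",
    "unit",
    "n_donors",
    "pooled",
    "method",
    "quant_mode",
    "age",
    "sex",
    "ethnicity",
    "genotype",
    "disease",
    "source",
    "year",
]

_DEMOGRAPHIC_COLS = ("age", "sex", "ethnicity", "genotype", "disease")

#: methods admissible under inclusion criterion ii
ELIGIBLE_METHODS = ("LC-MS/MS", "Western blot")


class RepositoryFormatError(ValueError):
    """Raised for malformed repository files; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


def _missing(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    if isinstance(cell, str) and cell.strip() == "":
        return True
    return False


def _as_float(cell, row: int, col: str) -> float | None:
    if _missing(cell):
        return None
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise RepositoryFormatError(f"malformed numeric cell {col}={cell!r}", row)


def _as_bool(cell, row: int, col: str) -> bool:
    if isinstance(cell, bool):
        return cell
    if isinstance(cell, (int, float)) and cell in (0, 1):
        return bool(cell)
    if isinstance(cell, str):
        s = cell.strip().lower()
        if s in ("true", "yes", "1"):
            return True
        if s in ("false", "no", "0"):
            return False
    raise RepositoryFormatError(f"malformed boolean cell {col}={cell!r}", row)


def _coerce_enum(value: str, allowed: tuple[str, ...], col: str, row: int) -> str:
    if value in allowed:
        return value
    logger.warning("row %d: unknown %s %r loaded as 'other'", row, col, value)
    return "other"


def read_repository(path: str | Path, format: str | None = None) -> list[ProteinAbundanceRecord]:
    """Load a repository table into records.

    ``format`` is one of ``csv``, ``tsv``, ``xlsx``; when omitted it is
    inferred from the file suffix.  Missing cells become missing values, never
    zeros.  Row numbers (1-based data rows) are used in error messages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "xlsx":
        df = pd.read_excel(path, sheet_name=0, dtype=object)
    else:
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype=object, comment="#")

    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise RepositoryFormatError(
            f"header is missing required columns: {missing_cols}"
        )

    records: list[ProteinAbundanceRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        value = _as_float(row["value"], i, "value")
        if value is None:
            raise RepositoryFormatError("value cell is empty", i)
        n_donors = _as_float(row["n_donors"], i, "n_donors")
        if n_donors is None or n_donors != int(n_donors):
            raise RepositoryFormatError(
                f"n_donors must be a positive integer, got {row['n_donors']!r}", i
            )
        rmin = _as_float(row["range_min"], i, "range_min")
        rmax = _as_float(row["range_max"], i, "range_max")
        vrange = (rmin, rmax) if rmin is not None and rmax is not None else None
        year = _as_float(row["year"], i, "year")
        demographics = {
            c: str(row[c]).strip()
            for c in _DEMOGRAPHIC_COLS
            if not _missing(row[c])
        }
        try:
            rec = ProteinAbundanceRecord(
                protein_name=str(row["protein_name"]).strip(),
                gene_name="" if _missing(row["gene_name"]) else str(row["gene_name"]).strip(),
                uniprot_id=None if _missing(row["uniprot_id"]) else str(row["uniprot_id"]).strip(),
                tissue=_coerce_enum(str(row["tissue"]).strip(), TISSUES, "tissue", i),
                matrix=_coerce_enum(str(row["matrix"]).strip(), MATRICES, "matrix", i),
                stat_kind=str(row["stat_kind"]).strip(),
                value=value,
                value_sd=_as_float(row["value_sd"], i, "value_sd"),
                value_range=vrange,
                value_cv_pct=_as_float(row["value_cv_pct"], i, "value_cv_pct"),
                unit=str(row["unit"]).strip(),
                n_donors=int(n_donors),
                pooled=_as_bool(row["pooled"], i, "pooled"),
                method=_coerce_enum(str(row["method"]).strip(), METHODS, "method", i),
                quant_mode=str(row["quant_mode"]).strip(),
                demographics=demographics,
                source=str(row["source"]).strip(),
                year=None if year is None else int(year),
            )
        except ValueError as exc:
            raise RepositoryFormatError(str(exc), i) from exc
        records.append(rec)
    return records


def write_repository(records: list[ProteinAbundanceRecord], path: str | Path,
                     format: str | None = None) -> None:
    """Write records back out in the documented schema (round-trip safe)."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower(), "csv")
    rows = []
    for r in records:
        rows.append({
            "protein_name": r.protein_name,
            "gene_name": r.gene_name,
            "uniprot_id": r.uniprot_id,
            "tissue": r.tissue,
            "matrix": r.matrix,
            "stat_kind": r.stat_kind,
            "value": r.value,
            "value_sd": r.value_sd,
            "range_min": r.value_range[0] if r.value_range else None,
            "range_max": r.value_range[1] if r.value_range else None,
            "value_cv_pct": r.value_cv_pct,
            "unit": r.unit,
            "n_donors": r.n_donors,
            "pooled": r.pooled,
            "method": r.method,
            "quant_mode": r.quant_mode,
            "age": r.demographics.get("age"),
            "sex": r.demographics.get("sex"),
            "ethnicity": r.demographics.get("ethnicity"),
            "genotype": r.demographics.get("genotype"),
            "disease": r.demographics.get("disease"),
            "source": r.source,
            "year": r.year,
        })
    df = pd.DataFrame(rows, columns=COLUMNS)
    if format == "xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, sep="\t" if format == "tsv" else ",")


@dataclass
class ExclusionReport:
    """Per-criterion accounting of how every input record was dispatched.

    ``retained + sum(excluded.values())`` always equals the number of input
    records: each record is counted against the first criterion it fails.
    """

    total: int = 0
    retained: int = 0
    excluded: dict[str, int] = field(default_factory=lambda: {
        "pooled_sample": 0,
        "non_microsomal_matrix": 0,
        "ineligible_method": 0,
        "relative_quantification": 0,
        "non_standard_unit": 0,
        "single_source_group": 0,
    })
    range_only_studies: int = 0  # retained, but unusable for variance-based pooling

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_records": self.total,
                "retained": self.retained,
                "excluded": self.excluded,
                "range_only_studies": self.range_only_studies,
            },
            indent=2,
        )


def _record_passes(rec: ProteinAbundanceRecord) -> str | None:
    """Return the exclusion reason for a record, or None if eligible."""
    if rec.pooled:
        return "pooled_sample"
    if rec.matrix != "microsomes":
        return "non_microsomal_matrix"
    if rec.method not in ELIGIBLE_METHODS:
        return "ineligible_method"
    if rec.quant_mode != "absolute":
        return "relative_quantification"
    if not rec.canonical_unit:
        return "non_standard_unit"
    return None


def filter_for_meta(
    records: list[ProteinAbundanceRecord],
) -> tuple[list[StudySet], ExclusionReport]:
    """Apply the inclusion criteria and group eligible records by protein/tissue.

    Records failing criteria i–iii are counted against the first criterion
    they fail; eligible records whose (protein, tissue) group has fewer than
    two distinct citation keys are excluded under criterion iv.  Studies
    reporting only a range (no SD, no CV) are retained — they still inform
    the sample-size-weighted mean — and counted in ``range_only_studies``.
    """
    report = ExclusionReport(total=len(records))
    groups: dict[tuple[str, str], list[ProteinAbundanceRecord]] = {}
    for rec in records:
        reason = _record_passes(rec)
        if reason is not None:
            report.excluded[reason] += 1
            continue
        groups.setdefault((rec.protein_name, rec.tissue), []).append(rec)

    study_sets: list[StudySet] = []
    for (protein, tissue), recs in sorted(groups.items()):
        sources = {r.source for r in recs}
        if len(sources) < 2:
            report.excluded["single_source_group"] += len(recs)
            logger.info(
                "%s (%s): excluded, only one reporting laboratory (%s)",
                protein, tissue, ", ".join(sorted(sources)),
            )
            continue
        observations = []
        for r in recs:
            sd = r.sd_in_canonical_unit()
            cv = r.value_cv_pct / 100.0 if r.value_cv_pct is not None else None
            if sd is None and cv is None:
                report.range_only_studies += 1
                logger.info(
                    "%s (%s): study %s reports no SD/CV; kept for weighted "
                    "mean only", protein, tissue, r.label,
                )
            observations.append(
                StudyObservation(
                    label=r.label,
                    mean=r.value_in_canonical_unit(),
                    sd=sd,
                    n=r.n_donors,
                    cv=cv,
                    source=r.source,
                    from_median=(r.stat_kind == "median"),
                )
            )
        report.retained += len(recs)
        study_sets.append(StudySet(protein=protein, tissue=tissue,
                                   observations=observations))
    return study_sets, report
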