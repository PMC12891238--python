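"""Reading, writing and validation of the tabular formats the pipeline consumes.

Rearrangement tables follow the AIRR Community Rearrangement schema column
names and are carried in memory as :class:`pandas.DataFrame` objects with one
row per annotated heavy-chain sequence.  Region boundaries are stored in the
TSV as 1-based inclusive coordinates (AIRR convention) and converted to
0-based half-open intervals for in-memory use.

Immune-subset proportion matrices (patients x subsets, percentages of CD45+
cells per tissue) are carried as a small :class:`ProportionMatrix` wrapper
around a DataFrame.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("PBMC", "adjacent", "tumor")
ISOTYPES = ("IGHM", "IGHG", "IGHA", "IGHD", "IGHE")
SUBISOTYPES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4")

#: region names in alignment order; CDR3 is delimited only by its start.
REGIONS = ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3")

#: AIRR-style 1-based inclusive boundary columns stored in the TSV.
REGION_COLUMNS = [f"{r}_{e}" for r in REGIONS for e in ("start", "end")] + ["cdr3_start"]

REQUIRED_COLUMNS = [
    "sequence_id",
    "patient_id",
    "tissue",
    "isotype",
    "subisotype",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "productive",
    "junction",
    "junction_aa",
    "sequence_alignment",
    "germline_alignment",
    "duplicate_count",
    "clone_id",
] + REGION_COLUMNS


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


def to_half_open(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_1based


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


def collapse_allele(call: str) -> str:
    """Collapse an IMGT-style allele call to the gene level.

    ``"IGHV3-7*01"`` -> ``"IGHV3-7"``.  Idempotent: calls without an allele
    suffix pass through unchanged.
    """
    return call.split("*", 1)[0] if isinstance(call, str) else call


def collapse_gene_to_family(gene: str) -> str:
    """Collapse a gene name to the family level: ``"IGHV3-7"`` -> ``"IGHV3"``."""
    return collapse_allele(gene).split("-", 1)[0] if isinstance(gene, str) else gene


def region_bounds(row: pd.Series) -> dict[str, tuple[int, int]]:
    """Return the five delimited regions of a record as 0-based half-open
    intervals plus the CDR3 start under the key ``"cdr3"`` (open-ended)."""
    bounds = {}
    for r in REGIONS:
        bounds[r] = to_half_open(int(row[f"{r}_start"]), int(row[f"{r}_end"]))
    bounds["cdr3"] = (int(row["cdr3_start"]) - 1, None)
    return bounds


def _row_errors(row: pd.Series) -> list[str]:
    errs = []
    obs, germ = row["sequence_alignment"], row["germline_alignment"]
    if not isinstance(obs, str) or not isinstance(germ, str):
        errs.append("missing alignment string")
        return errs
    if len(obs) != len(germ):
        errs.append(
            f"alignment length mismatch ({len(obs)} vs {len(germ)})"
        )
    try:
        dup = int(row["duplicate_count"])
        if dup < 1:
            errs.append(f"duplicate_count {dup} < 1")
    except (TypeError, ValueError):
        errs.append("non-integer duplicate_count")
    if row["tissue"] not in TISSUES:
        errs.append(f"unknown tissue {row['tissue']!r}")
    # region intervals: ordered, non-overlapping, inside the alignment
    prev_end = 0
    for r in REGIONS:
        try:
            s, e = to_half_open(int(row[f"{r}_start"]), int(row[f"{r}_end"]))
        except (TypeError, ValueError):
            errs.append(f"non-integer bounds for {r}")
            continue
        if s < prev_end or e < s:
            errs.append(f"region {r} out of order")
        if isinstance(obs, str) and e > len(obs):
            errs.append(f"region {r} exceeds alignment")
        prev_end = max(prev_end, e)
    if (
        row.get("productive", False)
        and isinstance(row["junction"], str)
        and isinstance(row["junction_aa"], str)
        and len(row["junction"]) % 3 == 0
        and len(row["junction_aa"]) * 3 != len(row["junction"])
    ):
        errs.append("junction_aa length inconsistent with junction")
    return errs


def validate_rearrangements(table: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate a rearrangement table against the data-model invariants.

    In strict mode (default) the first violation raises
    :class:`ValidationError`; in lenient mode offending rows are dropped with
    one logged warning each and the surviving rows are returned.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    keep = np.ones(len(table), dtype=bool)
    for i, (_, row) in enumerate(table.iterrows()):
        errs = _row_errors(row)
        if errs:
            msg = f"record {row['sequence_id']!r}: {'; '.join(errs)}"
            if strict:
                raise ValidationError(msg)
            logger.warning("dropping invalid %s", msg)
            keep[i] = False
    return table.loc[keep].reset_index(drop=True)


def read_rearrangements(path, strict: bool = True) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV into a validated table."""
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"sequence_id": str, "patient_id": str, "clone_id": str,
               "subisotype": str, "d_call": str, "c_call": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    table["productive"] = table["productive"].map(
        {"T": True, "F": False, "TRUE": True, "FALSE": False, True: True, False: False}
    )
    table["duplicate_count"] = pd.to_numeric(table["duplicate_count"]).astype(int)
    for col in REGION_COLUMNS:
        table[col] = pd.to_numeric(table[col]).astype(int)
    return validate_rearrangements(table, strict=strict)


def write_rearrangements(table: pd.DataFrame, path) -> None:
    """Write a rearrangement table as an AIRR TSV.

    Column order follows the schema; rows are sorted by ``sequence_id`` so two
    writes of the same table are byte-identical.
    """
    out = table.copy()
    extra = [c for c in out.columns if c not in REQUIRED_COLUMNS]
    out = out[REQUIRED_COLUMNS + sorted(extra)]
    out = out.sort_values("sequence_id", kind="mergesort").reset_index(drop=True)
    out["productive"] = out["productive"].map({True: "T", False: "F"})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class ProportionMatrix:
    """Patients x immune-subset percentage matrix for one tissue.

    ``values`` has patient ids as the index and subset names as columns;
    entries are percentages of CD45+ cells.  ``flagged`` lists patients whose
    row sum deviates from 100 beyond the configured tolerance.
    """

    values: pd.DataFrame
    tissue: str
    flagged: list[str] = field(default_factory=list)

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    @property
    def subsets(self) -> list[str]:
        return list(self.values.columns)


def read_proportion_matrix(path, tissue: str = "tumor",
                           tolerance: float = 1.0) -> ProportionMatrix:
    """Read a patients x subsets CSV of percentages and validate it.

    Negative entries raise :class:`ValidationError`; non-numeric cells raise
    :class:`SchemaError`.  Rows whose sum deviates from 100 by more than
    ``tolerance`` percentage points are recorded in ``flagged`` (never
    silently repaired).
    """
    raw = pd.read_csv(path, index_col=0)
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric cell in proportion matrix: {exc}") from exc
    if (values.values < 0).any():
        bad = values.index[(values.values < 0).any(axis=1)][0]
        raise ValidationError(f"negative proportion for patient {bad!r}")
    values.index = values.index.astype(str)
    sums = values.sum(axis=1)
    flagged = list(values.index[(sums - 100.0).abs() > tolerance])
    return ProportionMatrix(values=values, tissue=tissue, flagged=flagged)


def write_proportion_matrix(matrix: ProportionMatrix, path) -> None:
    matrix.values.to_csv(path, lineterminator="\n")
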