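"""Somatic hypermutation accounting against reconstructed germlines.

Mutations are counted between the IMGT-gapped observed and germline
alignments of each record.  A position counts as mutated when both bases are
unambiguous nucleotides (A/C/G/T) and differ; gap characters ('.', '-') and
Ns are excluded from both numerator and denominator.  Each mutated position
is classified replacement (R) or silent (S) by substituting only that
position into the germline codon and comparing translations; positions whose
germline codon is broken by a gap or N are counted in ``total`` but tracked
as unclassifiable.  Region accounting splits mutations into CDR (CDR1+CDR2)
and FWR (FWR1-FWR3); CDR3/junction positions are excluded from the region
partition by default since the junction is not germline-encoded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .airr_io import region_bounds

__all__ = ["MutationCounts", "count_mutations", "shm_summary"]

_NT = frozenset("ACGT")

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


@dataclass
class MutationCounts:
    """Per-sequence mutation tallies.

    ``total`` counts every mutated unambiguous position and equals
    ``r + s + unclassifiable``; region counts cover positions inside the
    delimited FWR/CDR intervals only.
    """

    total: int = 0
    r: int = 0
    s: int = 0
    unclassifiable: int = 0
    fwr_r: int = 0
    fwr_s: int = 0
    cdr_r: int = 0
    cdr_s: int = 0
    informative_positions: int = 0

    @property
    def shm_frequency(self) -> float:
        return self.total / self.informative_positions if self.informative_positions else float("nan")


def _classify(germline: str, position: int, observed_base: int | str) -> str | None:
    """R/S for a single substitution at ``position`` of the gapped germline.

    Returns "R", "S", or None when the germline codon frame at that position
    is broken by a gap or ambiguous base.  The codon frame is anchored at
    alignment position 0.
    """
    codon_start = (position // 3) * 3
    codon = germline[codon_start:codon_start + 3]
    if len(codon) < 3 or any(b not in _NT for b in codon):
        return None
    mutated = list(codon)
    mutated[position - codon_start] = observed_base
    return "S" if CODON_TABLE["".join(codon)] == CODON_TABLE["".join(mutated)] else "R"


def count_mutations(observed: str, germline: str,
                    bounds: dict[str, tuple[int, int]] | None = None,
                    include_cdr3: bool = False) -> MutationCounts:
    """Count and classify the substitutions between two gapped alignments."""
    if len(observed) != len(germline):
        raise ValueError(
            f"alignment length mismatch ({len(observed)} vs {len(germline)})")
    cdr, fwr = [], []
    limit = len(observed)
    if bounds:
        cdr = [bounds[r] for r in ("cdr1", "cdr2") if r in bounds]
        fwr = [bounds[r] for r in ("fwr1", "fwr2", "fwr3") if r in bounds]
        if include_cdr3 and "cdr3" in bounds:
            s, e = bounds["cdr3"]
            cdr.append((s, e if e is not None else limit))
        for s, e in cdr + fwr:
            if s < 0 or (e is not None and e > limit):
                raise ValueError("region bounds outside alignment")

    counts = MutationCounts()
    for i, (o, g) in enumerate(zip(observed, germline)):
        if o not in _NT or g not in _NT:
            continue
        counts.informative_positions += 1
        if o == g:
            continue
        counts.total += 1
        cls = _classify(germline, i, o)
        if cls is None:
            counts.unclassifiable += 1
            continue
        if cls == "R":
            counts.r += 1
        else:
            counts.s += 1
        in_cdr = any(s <= i < e for s, e in cdr)
        in_fwr = any(s <= i < e for s, e in fwr)
        if in_cdr:
            counts.cdr_r += cls == "R"
            counts.cdr_s += cls == "S"
        elif in_fwr:
            counts.fwr_r += cls == "R"
            counts.fwr_s += cls == "S"
    return counts


def mutation_table(table: pd.DataFrame, include_cdr3: bool = False) -> pd.DataFrame:
    """Per-sequence mutation counts for every record of a rearrangement table."""
    rows = []
    for _, row in table.iterrows():
        c = count_mutations(row["sequence_alignment"], row["germline_alignment"],
                            region_bounds(row), include_cdr3=include_cdr3)
        rows.append({
            "sequence_id": row["sequence_id"], "patient_id": row["patient_id"],
            "tissue": row["tissue"], "isotype": row["isotype"],
            "subisotype": row["subisotype"],
            "total": c.total, "r": c.r, "s": c.s,
            "unclassifiable": c.unclassifiable,
            "fwr_r": c.fwr_r, "fwr_s": c.fwr_s, "cdr_r": c.cdr_r, "cdr_s": c.cdr_s,
            "informative_positions": c.informative_positions,
            "shm_frequency": c.shm_frequency,
            "r_frequency": c.r / c.informative_positions if c.informative_positions else float("nan"),
            "r_percentage": 100.0 * c.r / c.total if c.total else float("nan"),
        })
    return pd.DataFrame(rows)


def shm_summary(table: pd.DataFrame,
                by: tuple[str, ...] = ("tissue", "isotype"),
                pooled: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sequence SHM table plus group summaries over ``by``.

    Group summaries are means of per-sequence frequencies by default
    (``pooled=True`` instead divides summed counts by summed informative
    positions).  Sequences with zero informative positions are flagged and
    excluded from means.  Returns ``(per_sequence, per_group)``.
    """
    per_seq = mutation_table(table)
    per_seq["flagged"] = per_seq["informative_positions"] == 0
    usable = per_seq.loc[~per_seq["flagged"]]
    groups = usable.groupby(list(by), dropna=False)
    if pooled:
        agg = groups[["total", "r", "informative_positions"]].sum()
        summary = pd.DataFrame({
            "mean_shm_frequency": agg["total"] / agg["informative_positions"],
            "r_percentage": 100.0 * agg["r"] / agg["total"].where(agg["total"] > 0),
            "r_frequency": agg["r"] / agg["informative_positions"],
            "n_sequences": groups.size(),
        }).reset_index()
    else:
        summary = groups.agg(
            mean_shm_frequency=("shm_frequency", "mean"),
            r_percentage=("r_percentage", "mean"),
            r_frequency=("r_frequency", "mean"),
            n_sequences=("sequence_id", "size"),
        ).reset_index()
    return per_seq, summary
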