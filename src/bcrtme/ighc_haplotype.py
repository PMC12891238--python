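"""Constant-region (IGHC) genotyping and haplotype-resolved class switching.

Near-full-length IgG reads are treated as co-linear with a per-gene
constant-region reference (substitution-only model): position i of a read's
constant segment corresponds to reference position i.  The stages are

1. length filtering of constant segments (default 900-1100 bp, inclusive);
2. heterozygous-SNV calling from per-position base counts;
3. read phasing into two haplotypes by minimum error correction (MEC) —
   exact consensus-pair enumeration for small site counts, deterministic
   multi-start refinement otherwise;
4. allele calling from exact-identity read clusters at a >= 5% read-fraction
   threshold, matched to a reference allele set;
5. haplotype x subisotype class-switch tables with fold ratios, and
   per-clone, per-allele mutation contrasts.

Haplotype 1 is always the partition side carrying more reads (ties broken by
the lexicographically smaller consensus), anchoring the otherwise arbitrary
labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .airr_io import collapse_allele

__all__ = [
    "SnvSite", "HaplotypePartition", "AlleleCall", "ClassSwitchTable",
    "filter_constant_reads", "call_het_sites", "phase_reads", "mec_score",
    "call_alleles", "class_switch_table", "clone_allele_mutation_contrast",
    "subisotype_stats",
]

_NT = "ACGT"


def constant_region(read_row: pd.Series) -> str:
    return read_row["sequence"][int(read_row["c_start"]):]


def filter_constant_reads(reads: pd.DataFrame, min_len: int = 900,
                          max_len: int = 1100) -> pd.DataFrame:
    """Keep reads whose constant segment length is within [min_len, max_len]."""
    if reads.empty:
        return reads
    lengths = reads["sequence"].str.len() - reads["c_start"]
    return reads.loc[(lengths >= min_len) & (lengths <= max_len)].reset_index(drop=True)


@dataclass(frozen=True)
class SnvSite:
    position: int       # 0-based on the gene reference
    ref: str
    alt: str
    depth: int
    alt_fraction: float


def call_het_sites(reads: pd.DataFrame, reference: str, min_depth: int = 10,
                   af_range: tuple[float, float] = (0.2, 0.8)) -> list[SnvSite]:
    """Call heterozygous sites from per-position base counts.

    A site is reported when the second-most-common base reaches a fraction
    inside ``af_range`` at depth >= ``min_depth``.  The alt base is the most
    common base differing from the reference.
    """
    if reads.empty:
        return []
    lo, hi = af_range
    n_pos = len(reference)
    counts = np.zeros((n_pos, 4), dtype=int)
    code = {b: i for i, b in enumerate(_NT)}
    for _, row in reads.iterrows():
        seg = constant_region(row)[:n_pos]
        arr = np.frombuffer(seg.encode(), dtype=np.uint8)
        for k, b in enumerate(_NT):
            counts[: len(arr), k] += arr == ord(b)
    sites = []
    for pos in range(n_pos):
        depth = counts[pos].sum()
        if depth < min_depth:
            continue
        order = np.argsort(counts[pos], kind="stable")[::-1]
        second = counts[pos, order[1]]
        frac = second / depth
        if not lo <= frac <= hi:
            continue
        ref_base = reference[pos]
        alts = [i for i in order if _NT[i] != ref_base and counts[pos, i] > 0]
        if not alts:
            continue
        alt_base = _NT[alts[0]]
        sites.append(SnvSite(position=pos, ref=ref_base, alt=alt_base,
                             depth=int(depth),
                             alt_fraction=float(counts[pos, code[alt_base]] / depth)))
    return sites


@dataclass
class HaplotypePartition:
    """Two-part read partition with its MEC score.

    ``assignment`` maps read_id -> {1, 2}; ``consensus`` maps haplotype ->
    allele string over the het sites ('0' = ref, '1' = alt); ``mec`` is the
    total number of mismatches between reads and their side's consensus at
    the het sites.
    """

    assignment: pd.Series
    consensus: dict[int, str]
    mec: int
    sites: list[SnvSite] = field(default_factory=list)


def _allele_matrix(reads: pd.DataFrame, sites: list[SnvSite]) -> np.ndarray:
    """n_reads x n_sites matrix in {0 ref, 1 alt, -1 missing/other}."""
    A = np.full((len(reads), len(sites)), -1, dtype=np.int8)
    for r, (_, row) in enumerate(reads.iterrows()):
        seg = constant_region(row)
        for s, site in enumerate(sites):
            if site.position < len(seg):
                b = seg[site.position]
                if b == site.ref:
                    A[r, s] = 0
                elif b == site.alt:
                    A[r, s] = 1
    return A


def _cost_to_consensus(A: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Per-read mismatch count against consensus vector h (missing ignored)."""
    covered = A >= 0
    return ((A != h[None, :]) & covered).sum(axis=1)


def _mec_of_sides(A: np.ndarray, side: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """MEC of a 0/1 side assignment with majority consensus per side."""
    cons = []
    for lab in (0, 1):
        sub = A[side == lab]
        h = np.zeros(A.shape[1], dtype=np.int8)
        for s in range(A.shape[1]):
            col = sub[:, s]
            ones = (col == 1).sum()
            zeros = (col == 0).sum()
            h[s] = 1 if ones > zeros else 0
        cons.append(h)
    cost = 0
    for lab, h in enumerate(cons):
        sub = A[side == lab]
        if len(sub):
            cost += int(_cost_to_consensus(sub, h).sum())
    return cost, cons[0], cons[1]


def _phase_exact(A: np.ndarray) -> np.ndarray:
    """Optimal side assignment by consensus-pair enumeration.

    With every candidate consensus pair scored by nearest-assignment, the
    minimum over pairs equals the MEC optimum (any partition's majority
    consensus is one of the enumerated pairs, and nearest assignment can
    only reduce its cost).
    """
    n, s = A.shape
    all_h = np.array(list(itertools.product((0, 1), repeat=s)), dtype=np.int8)
    costs = np.stack([_cost_to_consensus(A, h) for h in all_h])  # 2^s x n
    best, best_pair = None, (0, 0)
    for i in range(len(all_h)):
        both = np.minimum(costs[i], costs[i:])  # pairs (i, j>=i)
        totals = both.sum(axis=1)
        j = int(np.argmin(totals))
        if best is None or totals[j] < best:
            best, best_pair = int(totals[j]), (i, i + j)
    c1, c2 = costs[best_pair[0]], costs[best_pair[1]]
    return (c2 < c1).astype(np.int8)


def _phase_refine(A: np.ndarray, n_starts: int = 10) -> np.ndarray:
    """Deterministic multi-start iterative refinement (greedy seeding)."""
    n = len(A)
    best_cost, best_side = None, None
    for start in range(min(n, n_starts)):
        h1 = np.where(A[start] >= 0, np.maximum(A[start], 0), 0).astype(np.int8)
        h2 = (1 - h1).astype(np.int8)
        side = np.zeros(n, dtype=np.int8)
        for _ in range(100):
            c1 = _cost_to_consensus(A, h1)
            c2 = _cost_to_consensus(A, h2)
            new_side = (c2 < c1).astype(np.int8)
            cost, h1, h2 = _mec_of_sides(A, new_side)
            if np.array_equal(new_side, side):
                break
            side = new_side
        cost, _, _ = _mec_of_sides(A, side)
        if best_cost is None or cost < best_cost:
            best_cost, best_side = cost, side.copy()
    return best_side


def mec_score(reads: pd.DataFrame, sites: list[SnvSite],
              assignment: pd.Series) -> int:
    """MEC of an arbitrary assignment (majority consensus per side)."""
    A = _allele_matrix(reads, sites)
    side = (assignment.reindex(reads["read_id"]).to_numpy() == 2).astype(np.int8)
    cost, _, _ = _mec_of_sides(A, side)
    return cost


def phase_reads(reads: pd.DataFrame, sites: list[SnvSite],
                max_exact_sites: int = 6) -> HaplotypePartition:
    """Partition reads into two haplotypes minimizing MEC.

    Exact for <= ``max_exact_sites`` het sites (consensus enumeration);
    deterministic multi-start refinement above that.  Haplotype 1 is the
    side with more reads, ties broken by lexicographically smaller
    consensus allele string.
    """
    if not sites:
        raise ValueError("need >= 1 het site")
    A = _allele_matrix(reads, sites)
    covered = (A >= 0).any(axis=1)
    if not covered.any():
        raise ValueError("no read covers any het site")
    Ause = A[covered]
    if len(sites) <= max_exact_sites:
        side = _phase_exact(Ause)
    else:
        side = _phase_refine(Ause)
    cost, h0, h1 = _mec_of_sides(Ause, side)

    n0, n1 = int((side == 0).sum()), int((side == 1).sum())
    s0, s1 = "".join(map(str, h0)), "".join(map(str, h1))
    if n1 > n0 or (n1 == n0 and s1 < s0):
        side, s0, s1 = 1 - side, s1, s0
    read_ids = reads.loc[covered, "read_id"]
    assignment = pd.Series(np.where(side == 0, 1, 2), index=read_ids.values,
                           name="haplotype")
    return HaplotypePartition(assignment=assignment,
                              consensus={1: s0, 2: s1}, mec=cost, sites=sites)


@dataclass
class AlleleCall:
    representative: str
    n_reads: int
    fraction: float
    allele: str | None
    distance: int | None
    novel: bool


def call_alleles(reads: pd.DataFrame, references: dict[str, str],
                 min_cluster_fraction: float = 0.05) -> list[AlleleCall]:
    """Cluster identical constant segments and assign reference alleles.

    Clusters are exact string-identity groups; those holding at least
    ``min_cluster_fraction`` of the reads (boundary inclusive) are matched
    to the reference allele with the fewest mismatches (edit distance).
    A tie between references is flagged novel.
    """
    if reads.empty:
        return []
    segs = [constant_region(row) for _, row in reads.iterrows()]
    clusters = pd.Series(segs).value_counts()
    total = len(segs)
    calls = []
    for seq, n in clusters.items():
        frac = n / total
        if frac < min_cluster_fraction:
            continue
        dists = {name: edlib.align(seq, ref, task="distance")["editDistance"]
                 for name, ref in references.items()}
        dmin = min(dists.values())
        best = sorted(name for name, d in dists.items() if d == dmin)
        novel = len(best) > 1
        calls.append(AlleleCall(representative=seq, n_reads=int(n), fraction=float(frac),
                                allele=None if novel else best[0],
                                distance=int(dmin), novel=novel))
    return calls


@dataclass
class ClassSwitchTable:
    """Haplotype x subisotype read counts with clone resolution."""

    counts: pd.DataFrame           # index haplotype, columns subisotype
    by_clone: pd.DataFrame         # clone_id x haplotype x subisotype counts

    def fold_ratio(self, haplotype: int, iso_a: str, iso_b: str) -> float | None:
        """count(hap, iso_a) / count(hap, iso_b); None when undefined."""
        a = self.counts.at[haplotype, iso_a] if iso_a in self.counts.columns else 0
        b = self.counts.at[haplotype, iso_b] if iso_b in self.counts.columns else 0
        if b == 0:
            return None
        return float(a / b)


def class_switch_table(reads: pd.DataFrame,
                       partition: HaplotypePartition) -> ClassSwitchTable:
    """Tabulate phased reads by haplotype and subisotype (overall and per clone)."""
    phased = reads[reads["read_id"].isin(partition.assignment.index)].copy()
    phased["haplotype"] = partition.assignment.reindex(phased["read_id"]).values
    counts = (phased.groupby(["haplotype", "subisotype"]).size()
              .unstack(fill_value=0))
    for hap in (1, 2):
        if hap not in counts.index:
            counts.loc[hap] = 0
    counts = counts.sort_index()
    by_clone = (phased.groupby(["clone_id", "haplotype", "subisotype"]).size()
                .rename("n_reads").reset_index())
    assert int(counts.to_numpy().sum()) == len(phased), "marginals must equal totals"
    return ClassSwitchTable(counts=counts, by_clone=by_clone)


def clone_allele_mutation_contrast(table: pd.DataFrame, allele_of: pd.Series,
                                   clone_ids: list[str]) -> pd.DataFrame:
    """Per clone x allele R-mutation comparison.

    ``table`` is a rearrangement table with alignments and clone ids;
    ``allele_of`` maps sequence_id -> allele label (e.g. the phased IGHC
    allele its read carries).  For each listed clone and allele the mean R
    frequency, mean R percentage, and CDR vs FWR R counts are reported;
    empty clone x allele cells are omitted.
    """
    from .mutation_profile import mutation_table

    sub = table[table["clone_id"].isin(clone_ids)]
    if sub.empty:
        return pd.DataFrame(columns=["clone_id", "allele", "n_sequences",
                                     "r_frequency", "r_percentage", "cdr_r", "fwr_r"])
    muts = mutation_table(sub).set_index("sequence_id")
    muts["allele"] = allele_of.reindex(muts.index)
    muts["clone_id"] = sub.set_index("sequence_id")["clone_id"]
    muts = muts.dropna(subset=["allele"])
    rows = []
    for (clone, allele), grp in muts.groupby(["clone_id", "allele"]):
        rows.append({
            "clone_id": clone, "allele": allele, "n_sequences": len(grp),
            "r_frequency": float(grp["r_frequency"].mean()),
            "r_percentage": float(grp["r_percentage"].mean()),
            "cdr_r": int(grp["cdr_r"].sum()), "fwr_r": int(grp["fwr_r"].sum()),
        })
    return pd.DataFrame(rows)


def subisotype_stats(records: pd.DataFrame,
                     by: tuple[str, ...] = ("patient_id",)) -> pd.DataFrame:
    """Per-sample IgG subisotype frequencies and the (G1+G4)/(G2+G3) ratio.

    ``records`` needs ``subisotype`` plus the grouping columns; rows without
    a subisotype are ignored.  A zero G2+G3 denominator yields a NaN ratio
    with ``ratio_undefined`` set.
    """
    sub = records.dropna(subset=["subisotype"])
    if sub.empty:
        raise ValueError("no subisotyped records")
    freq = (sub.groupby(list(by))["subisotype"].value_counts(normalize=True)
            .unstack(fill_value=0.0))
    for g in ("IGHG1", "IGHG2", "IGHG3", "IGHG4"):
        if g not in freq.columns:
            freq[g] = 0.0
    num = freq["IGHG1"] + freq["IGHG4"]
    den = freq["IGHG2"] + freq["IGHG3"]
    out = freq.copy()
    out["g1g4_over_g2g3"] = np.where(den > 0, num / den.replace(0, np.nan), np.nan)
    out["ratio_undefined"] = den == 0
    return out.reset_index()
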