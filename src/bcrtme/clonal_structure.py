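"""Clonal clustering and clonality statistics.

Clones are inferred by single-linkage clustering of junction nucleotide
sequences within each patient x V gene x J gene x junction-length group, at a
configurable normalized Hamming distance threshold (default 0.15).  Clones
are scoped within patient across tissues and isotypes so a clone can be
tracked between compartments; per-sample statistics restrict members with a
filter.

Statistics:

* polarization — the minimum number of clones covering 80% of a sample's
  sequences, divided by the total clone count (lower = more clonally
  expanded);
* diversity — Hill number of order q over clone frequencies (q=2 is the
  inverse Simpson index) with a percentile bootstrap CI over resampled
  sequences;
* top_clone_set — the largest ceil(fraction x n_clones) clones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .airr_io import collapse_allele

__all__ = ["ClonePartition", "DiversityEstimate", "assign_clones",
           "polarization", "diversity", "top_clone_set", "sample_filter"]


@dataclass
class ClonePartition:
    """Record -> clone mapping plus the annotated source table.

    ``table`` is the input rearrangement table with ``clone_id`` filled in;
    ``threshold`` is the normalized Hamming distance used.
    """

    table: pd.DataFrame
    threshold: float

    def clone_sizes(self, mask: pd.Series | None = None) -> pd.Series:
        """Clone-size table (sequences per clone), optionally restricted."""
        sub = self.table if mask is None else self.table.loc[mask]
        return sub.groupby("clone_id").size().sort_values(ascending=False)


@dataclass
class DiversityEstimate:
    point: float
    ci_low: float
    ci_high: float
    q: float
    n_boot: int


def sample_filter(table: pd.DataFrame, patient: str | None = None,
                  tissue: str | None = None, isotype: str | None = None,
                  subisotype: str | None = None) -> pd.Series:
    """Boolean mask selecting one sample's records."""
    mask = pd.Series(True, index=table.index)
    for col, val in (("patient_id", patient), ("tissue", tissue),
                     ("isotype", isotype), ("subisotype", subisotype)):
        if val is not None:
            mask &= table[col] == val
    return mask


def _hamming_condensed(junctions: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(junctions).encode(), dtype="S1")
    arr = arr.reshape(len(junctions), -1)
    return pdist(arr.view(np.uint8), metric="hamming")


def assign_clones(table: pd.DataFrame, threshold: float = 0.15) -> ClonePartition:
    """Cluster records into clones and return the filled-in partition.

    Single linkage at normalized junction Hamming distance <= ``threshold``
    within each (patient, V gene, J gene, junction length) group.  Clone ids
    are deterministic: groups are visited in sorted key order and clusters
    numbered by their smallest member ``sequence_id``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if (table["junction"].astype(str).str.len() == 0).any():
        raise ValueError("empty junction(s) present")
    out = table.copy()
    v_gene = out["v_call"].map(collapse_allele)
    j_gene = out["j_call"].map(collapse_allele)
    jlen = out["junction"].str.len()
    clone_ids = pd.Series(index=out.index, dtype=object)
    for (patient, v, j, ln), idx in out.groupby(
            [out["patient_id"], v_gene, j_gene, jlen], sort=True).groups.items():
        sub = out.loc[idx].sort_values("sequence_id")
        juncs = sub["junction"].tolist()
        if len(juncs) == 1:
            labels = np.array([1])
        else:
            d = _hamming_condensed(juncs)
            labels = fcluster(linkage(d, method="single"), t=threshold,
                              criterion="distance")
        # number clusters by smallest member sequence_id for stability
        order = {}
        for lab, sid in sorted(zip(labels, sub["sequence_id"]), key=lambda x: x[1]):
            order.setdefault(lab, len(order))
        clone_ids.loc[sub.index] = [
            f"{patient}_{v}_{j}_{ln}_c{order[lab]}" for lab in labels
        ]
    out["clone_id"] = clone_ids
    return ClonePartition(table=out, threshold=threshold)


def polarization(partition: ClonePartition, mask: pd.Series | None = None,
                 coverage: float = 0.8, weighted: bool = False) -> float:
    """n80 / total clones for the selected sample.

    n80 is the smallest number of clones (largest first) whose sequences
    cover at least ``coverage`` of the sample.  With ``weighted=True``
    sequences count with their ``duplicate_count``.
    """
    sub = partition.table if mask is None else partition.table.loc[mask]
    if sub.empty:
        raise ValueError("empty sample")
    w = sub["duplicate_count"] if weighted else pd.Series(1, index=sub.index)
    sizes = w.groupby(sub["clone_id"]).sum().sort_values(ascending=False)
    cum = sizes.cumsum() / sizes.sum()
    n80 = int(np.searchsorted(cum.values, coverage) + 1)
    return n80 / len(sizes)


def _hill(freqs: np.ndarray, q: float) -> float:
    freqs = freqs[freqs > 0]
    if q == 1.0:
        return float(math.exp(-(freqs * np.log(freqs)).sum()))
    return float((freqs**q).sum() ** (1.0 / (1.0 - q)))


def diversity(partition: ClonePartition, mask: pd.Series | None = None,
              q: float = 2.0, n_boot: int = 200,
              seed: int | np.random.SeedSequence = 0) -> DiversityEstimate:
    """Hill-number diversity of order ``q`` with a bootstrap 95% CI.

    q=2 gives the inverse Simpson index.  The CI is the point estimate plus
    or minus 1.96 bootstrap standard deviations over ``n_boot`` resamples of
    sequences (default 200 replicates).  Centering on the estimate avoids
    the downward richness bias of percentile intervals when many clones are
    singletons, and guarantees the CI contains the point estimate.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    sub = partition.table if mask is None else partition.table.loc[mask]
    if len(sub) < 2:
        raise ValueError("need >= 2 sequences")
    clones = sub["clone_id"].to_numpy()
    counts = pd.Series(clones).value_counts().to_numpy(dtype=float)
    point = _hill(counts / counts.sum(), q)
    rng = np.random.default_rng(seed)
    codes = pd.factorize(clones)[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        resampled = rng.integers(0, len(codes), size=len(codes))
        c = np.bincount(codes[resampled]).astype(float)
        boots[b] = _hill(c / c.sum(), q)
    half = 1.959963984540054 * float(boots.std(ddof=1))
    return DiversityEstimate(point=point, ci_low=max(1.0, point - half),
                             ci_high=point + half, q=q, n_boot=n_boot)


def top_clone_set(partition: ClonePartition, mask: pd.Series | None = None,
                  fraction: float = 0.10) -> list[str]:
    """Ids of the top ceil(fraction x n_clones) clones by size.

    Ties are broken lexicographically by clone id so the set is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    sizes = partition.clone_sizes(mask)
    if sizes.empty:
        raise ValueError("no clones in scope")
    k = math.ceil(fraction * len(sizes))
    ranked = sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [cid for cid, _ in ranked[:k]]
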