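"""Gene-usage frequencies, tumor-enrichment deltas, and CDR3 features.

The central contrast subtracts each gene's frequency in a patient's PBMC IgM
repertoire (the circulating naive baseline) from its frequency in the
matched tumor IgM or tumor IgG repertoire.  Cohort-level enrichment is a
one-sample t-test of those per-patient deltas against zero with Bonferroni
correction over the genes tested; per-patient recurrence counts how often a
gene ranks in the top k deltas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .airr_io import collapse_allele, collapse_gene_to_family
from .clonal_structure import ClonePartition, sample_filter, top_clone_set
from .mutation_profile import mutation_table

logger = logging.getLogger(__name__)

__all__ = [
    "usage_frequencies", "delta_vs_baseline", "cohort_enrichment_test",
    "recurrent_top_genes", "cdr3_features", "Cdr3Features",
    "enriched_depleted_contrast", "enriched_fraction",
]

_SEGMENT_COLUMN = {"v": "v_call", "d": "d_call", "j": "j_call", "c": "c_call"}

BASIC_AA = frozenset("RKH")
ACIDIC_AA = frozenset("DE")
VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def usage_frequencies(table: pd.DataFrame, segment: str = "v",
                      level: str = "gene", productive_only: bool = True,
                      by: tuple[str, ...] = ("patient_id", "tissue", "isotype"),
                      weight_by_clone: bool = False) -> pd.DataFrame:
    """Samples x genes frequency matrix for one segment class.

    Rows are indexed by the ``by`` key; each row sums to 1.  Allele calls are
    collapsed to ``level`` ("allele", "gene" or "family").  With
    ``weight_by_clone`` each clone counts once instead of each sequence.
    """
    seg = segment.lower()
    if seg.startswith("igh"):
        seg = seg[3:]
    col = _SEGMENT_COLUMN[seg]
    sub = table[table["productive"]] if productive_only else table
    calls = sub[col]
    if level == "gene":
        calls = calls.map(collapse_allele)
    elif level == "family":
        calls = calls.map(collapse_gene_to_family)
    elif level != "allele":
        raise ValueError(f"unknown call level {level!r}")
    frame = sub.assign(_gene=calls)
    if weight_by_clone:
        frame = frame.drop_duplicates(subset=list(by) + ["clone_id"])
    counts = frame.groupby(list(by) + ["_gene"]).size().unstack(fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("empty sample(s) after filtering: %s", list(counts.index[empty]))
    freqs = counts.div(totals.where(totals > 0), axis=0)
    freqs.columns.name = "gene"
    return freqs


def delta_vs_baseline(target: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Per-patient gene-frequency deltas: target minus baseline.

    Both inputs are usage matrices whose index carries ``patient_id`` at
    level 0 (extra index levels, e.g. tissue/isotype, are dropped).  The gene
    universe is the union of both columns, absent genes counting as 0; each
    row therefore sums to 0.  Patients missing either sample are skipped with
    a warning.
    """
    def per_patient(m: pd.DataFrame) -> pd.DataFrame:
        idx = m.index.get_level_values(0) if isinstance(m.index, pd.MultiIndex) else m.index
        out = m.copy()
        out.index = idx
        return out

    t, b = per_patient(target), per_patient(baseline)
    shared = t.index.intersection(b.index)
    missing = set(t.index).symmetric_difference(b.index)
    if missing:
        logger.warning("skipping unpaired patient(s): %s", sorted(missing))
    genes = sorted(set(t.columns) | set(b.columns))
    t = t.reindex(index=shared, columns=genes, fill_value=0.0)
    b = b.reindex(index=shared, columns=genes, fill_value=0.0)
    delta = t - b
    assert np.allclose(delta.sum(axis=1), 0.0, atol=1e-9), "delta rows must sum to 0"
    return delta


@dataclass
class EnrichmentResult:
    gene: str
    mean_delta: float
    t: float
    p: float
    q: float
    direction: str
    n_patients: int
    degenerate: bool = False


def cohort_enrichment_test(deltas: pd.DataFrame,
                           target: pd.DataFrame | None = None,
                           baseline: pd.DataFrame | None = None,
                           min_patients: int = 5,
                           alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t-test of per-gene deltas against 0, Bonferroni-corrected.

    A gene is tested when it is used (nonzero frequency in the target or
    baseline sample) in at least ``min_patients`` patients; the Bonferroni
    divisor is the number of genes actually tested.  A zero-variance nonzero
    delta vector cannot produce a finite t statistic and is reported with a
    ``degenerate`` flag, q = 0 sentinel and the direction of its mean.
    """
    if len(deltas) < 2:
        raise ValueError("need >= 2 patients")
    used = (deltas != 0)
    if target is not None:
        used |= target.reindex(index=deltas.index, columns=deltas.columns, fill_value=0.0) != 0
    if baseline is not None:
        used |= baseline.reindex(index=deltas.index, columns=deltas.columns, fill_value=0.0) != 0
    tested = [g for g in deltas.columns if used[g].sum() >= min_patients]
    m = len(tested)
    rows = []
    for gene in tested:
        x = deltas[gene].to_numpy(dtype=float)
        mean = float(x.mean())
        degenerate = np.allclose(x, x[0]) and not np.allclose(x, 0.0)
        if np.allclose(x, 0.0):
            t_stat, p = 0.0, 1.0
        elif degenerate:
            t_stat, p = math.inf if mean > 0 else -math.inf, 0.0
        else:
            t_stat, p = stats.ttest_1samp(x, 0.0)
        q = 0.0 if degenerate else min(1.0, p * m)
        direction = "enriched" if mean > 0 else ("depleted" if mean < 0 else "none")
        rows.append(EnrichmentResult(gene=gene, mean_delta=mean, t=float(t_stat),
                                     p=float(p), q=float(q), direction=direction,
                                     n_patients=len(x), degenerate=degenerate))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if not out.empty:
        out["significant"] = out["q"] < alpha
    return out


def recurrent_top_genes(deltas: pd.DataFrame, target: pd.DataFrame | None = None,
                        k: int = 5, min_recurrence: int = 5) -> pd.DataFrame:
    """Genes ranking in a patient's top-k deltas in >= ``min_recurrence`` patients.

    Per patient, genes are ranked by delta descending; ties break on larger
    target (tumor) frequency when provided, then gene name.  Returns a table
    (gene, n_patients_top_k) for genes meeting the recurrence threshold,
    sorted by count descending then name.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    tgt = None
    if target is not None:
        idx = (target.index.get_level_values(0)
               if isinstance(target.index, pd.MultiIndex) else target.index)
        tgt = target.copy()
        tgt.index = idx
    for patient, row in deltas.iterrows():
        tumor_freq = (tgt.loc[patient] if tgt is not None and patient in tgt.index
                      else pd.Series(0.0, index=deltas.columns))
        ranked = sorted(deltas.columns,
                        key=lambda g: (-row[g], -tumor_freq.get(g, 0.0), g))
        for g in ranked[:k]:
            counts[g] = counts.get(g, 0) + 1
    out = pd.DataFrame(
        [(g, n) for g, n in counts.items() if n >= min_recurrence],
        columns=["gene", "n_patients_top_k"],
    )
    return out.sort_values(["n_patients_top_k", "gene"],
                           ascending=[False, True]).reset_index(drop=True)


@dataclass
class Cdr3Features:
    """Physicochemical summary of a CDR3 amino-acid sequence.

    Net charge is the formal charge at neutral pH: (+1 per R/K) - (1 per
    D/E); histidine counts toward the basic fraction but contributes no net
    charge.
    """

    length: int
    net_charge: int
    basic_fraction: float
    acidic_fraction: float


def cdr3_features(junction_aa: str) -> Cdr3Features:
    if not junction_aa:
        raise ValueError("empty CDR3 amino-acid sequence")
    bad = set(junction_aa) - VALID_AA
    if bad:
        raise ValueError(f"invalid amino-acid letter(s): {sorted(bad)}")
    n = len(junction_aa)
    rk = sum(aa in "RK" for aa in junction_aa)
    de = sum(aa in ACIDIC_AA for aa in junction_aa)
    basic = sum(aa in BASIC_AA for aa in junction_aa)
    return Cdr3Features(length=n, net_charge=rk - de,
                        basic_fraction=basic / n, acidic_fraction=de / n)


_CONTRAST_FEATURES = ("normalized_clone_size", "shm_frequency", "r_frequency",
                      "cdr3_length", "net_charge", "basic_fraction", "acidic_fraction")


def _per_set_features(sub: pd.DataFrame, muts: pd.DataFrame,
                      total_productive: int) -> dict[str, float]:
    sizes = sub.groupby("clone_id").size() / total_productive
    size_per_seq = sub["clone_id"].map(sizes)
    feats = [cdr3_features(aa) for aa in sub["junction_aa"]]
    m = muts.loc[sub.index]
    return {
        "normalized_clone_size": float(size_per_seq.mean()),
        "shm_frequency": float(m["shm_frequency"].mean()),
        "r_frequency": float(m["r_frequency"].mean()),
        "cdr3_length": float(np.mean([f.length for f in feats])),
        "net_charge": float(np.mean([f.net_charge for f in feats])),
        "basic_fraction": float(np.mean([f.basic_fraction for f in feats])),
        "acidic_fraction": float(np.mean([f.acidic_fraction for f in feats])),
    }


def enriched_depleted_contrast(table: pd.DataFrame, partition: ClonePartition,
                               enriched: set[str], depleted: set[str],
                               tissue: str = "tumor", isotype: str = "IGHM",
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient BCR-feature means for enriched- vs depleted-gene sequences.

    For each patient the mean over sequences of each feature (clone size
    normalized to productive sequences in the sample, SHM frequency, R
    frequency, CDR3 length/charge/basic/acidic fractions) is computed
    separately for sequences using enriched and depleted V genes; a paired
    t-test per feature summarizes the cohort.  Returns
    ``(per_patient, cohort_tests)``.
    """
    if not enriched or not depleted:
        raise ValueError("both gene sets must be non-empty")
    t = partition.table
    muts = mutation_table(t).set_index(t.index)
    rows = []
    for patient in sorted(t["patient_id"].unique()):
        mask = sample_filter(t, patient=patient, tissue=tissue, isotype=isotype)
        sample = t.loc[mask & t["productive"]]
        if sample.empty:
            continue
        genes = sample["v_call"].map(collapse_allele)
        e_sub = sample.loc[genes.isin(enriched)]
        d_sub = sample.loc[genes.isin(depleted)]
        if e_sub.empty or d_sub.empty:
            logger.warning("patient %s lacks sequences in one gene set; excluded", patient)
            continue
        total = len(sample)
        e_feats = _per_set_features(e_sub, muts, total)
        d_feats = _per_set_features(d_sub, muts, total)
        for feat in _CONTRAST_FEATURES:
            rows.append({"patient_id": patient, "feature": feat,
                         "enriched": e_feats[feat], "depleted": d_feats[feat],
                         "difference": e_feats[feat] - d_feats[feat]})
    per_patient = pd.DataFrame(rows)
    tests = []
    for feat in _CONTRAST_FEATURES:
        sub = per_patient[per_patient["feature"] == feat]
        if len(sub) < 2:
            continue
        t_stat, p = stats.ttest_rel(sub["enriched"], sub["depleted"])
        tests.append({"feature": feat, "mean_difference": sub["difference"].mean(),
                      "t": float(t_stat), "p": float(p), "n_patients": len(sub)})
    return per_patient, pd.DataFrame(tests)


def enriched_fraction(table: pd.DataFrame, enriched: set[str],
                      mask: pd.Series | None = None) -> float:
    """Fraction of in-scope sequences whose V gene is in the enriched set."""
    sub = table if mask is None else table.loc[mask]
    if sub.empty:
        raise ValueError("empty scope")
    genes = sub["v_call"].map(collapse_allele)
    return float(genes.isin(enriched).mean())


def enriched_fraction_top_clones(table: pd.DataFrame, partition: ClonePartition,
                                 enriched: set[str], mask: pd.Series | None = None,
                                 fraction: float = 0.10) -> float:
    """Enriched-gene fraction among sequences of the top-decile clones."""
    top = set(top_clone_set(partition, mask, fraction))
    t = partition.table
    scope = t["clone_id"].isin(top)
    if mask is not None:
        scope &= mask
    return enriched_fraction(t, enriched, scope)
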