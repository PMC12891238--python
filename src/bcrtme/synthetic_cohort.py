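"""Synthetic matched-tissue cohort generator with known ground truth.

Emulates the data layout of a matched PBMC / adjacent-lung / tumor study:

* per-patient bulk heavy-chain repertoires (IgM and IgG sequenced separately)
  with tissue-dependent clone-size skew and somatic hypermutation,
* tumor repertoires whose V-gene usage is spiked on a configurable gene set,
* group-structured immune-subset proportion matrices (percent of CD45+ cells),
* near-full-length IgG reads carrying a diploid constant-region locus with
  heterozygous SNVs and haplotype-biased class switching.

Every stochastic stage derives its own child seed from the single config seed
via :class:`numpy.random.SeedSequence`, so stages are individually
reproducible.  All default rates and sizes are stated in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _germline as gl
from .airr_io import REQUIRED_COLUMNS

__all__ = [
    "CloneSizeDistribution",
    "CohortConfig",
    "IghcHaplotypeModel",
    "GroundTruth",
    "simulate_repertoire",
    "simulate_cohort",
    "simulate_ighc_reads",
    "default_usage",
]


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


# --------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class CloneSizeDistribution:
    """Clone-size law for one sample.

    ``geometric``: clone i gets weight ratio**i (0 < ratio < 1; ratio -> 1 is
    uniform, small ratio is heavily skewed).  ``power``: weight (i+1)**-ratio.
    ``uniform``: equal weights.
    """

    n_clones: int
    kind: str = "geometric"
    ratio: float = 0.98

    def weights(self) -> np.ndarray:
        if self.n_clones < 1:
            raise ConfigError("clone distribution must yield >= 1 clone")
        i = np.arange(self.n_clones, dtype=float)
        if self.kind == "geometric":
            if not 0.0 < self.ratio < 1.0:
                raise ConfigError("geometric ratio must be in (0, 1)")
            w = self.ratio**i
        elif self.kind == "power":
            w = (i + 1.0) ** (-self.ratio)
        elif self.kind == "uniform":
            w = np.ones_like(i)
        else:
            raise ConfigError(f"unknown clone-size law {self.kind!r}")
        return w / w.sum()


def default_usage(genes: tuple[str, ...], seed: int = 7) -> dict[str, float]:
    """Fixed baseline usage vector: exponentially tilted, deterministic."""
    rng = np.random.default_rng(seed)
    w = np.sort(rng.dirichlet(np.full(len(genes), 2.0)))[::-1]
    return dict(zip(genes, w))


def _validated_probs(p: dict[str, float], what: str) -> dict[str, float]:
    vals = np.array(list(p.values()), dtype=float)
    if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{what} probabilities must be a distribution summing to 1")
    return p


# 66 immune-subset names: 15 B, 15 CD4, 15 CD8, 6 NK, 5 TCRgd, 10 myeloid.
B_SUBSETS = tuple(
    f"B_{s}" for s in (
        "resident_activated_memory", "IgD_activated_memory", "antigen_presenting",
        "activated", "activated_memory", "atypical_resident", "resident_memory",
        "plasma", "IgD_plasma", "terminally_diff_plasma", "naive", "activated_naive",
        "IgD_memory", "inflammatory", "Breg",
    )
)
CD4_SUBSETS = tuple(f"CD4_{i:02d}" for i in range(1, 14)) + (
    "CD4_CD69_central_memory", "CD4_Th1_effector")
CD8_SUBSETS = tuple(f"CD8_{i:02d}" for i in range(1, 13)) + (
    "CD8_resident_memory", "CD8_senescent", "CD8_TEMRA")
NK_SUBSETS = ("NK_cytotoxic", "NK_mature", "NK_01", "NK_02", "NK_03", "NK_04")
TCRGD_SUBSETS = tuple(f"TCRgd_{i}" for i in range(1, 5)) + ("TCRgd_effector_memory",)
MYELOID_SUBSETS = ("My_classical_monocyte", "My_early_MDSC", "My_cDC", "My_pDC",
                   "My_granulocyte_prec") + tuple(f"My_{i:02d}" for i in range(1, 6))
ALL_SUBSETS = B_SUBSETS + CD4_SUBSETS + CD8_SUBSETS + NK_SUBSETS + TCRGD_SUBSETS + MYELOID_SUBSETS
assert len(ALL_SUBSETS) == 66


@dataclass
class CohortConfig:
    """Study-shaped generator configuration.

    Defaults mirror the emulated study design: 48 patients in four groups of
    21/10/3/14 profiled by cytometry; a 29-patient subset with matched
    PBMC/adjacent/tumor IgM+IgG repertoires; peripheral IgM nearly unmutated
    (SHM 0.004/site) with higher mutation loads in tissue and in IgG; tumor
    clone-size distributions more skewed than blood; tumor V usage spiked on a
    small gene set.
    """

    n_patients: int = 48
    n_airr_patients: int = 29
    group_labels: tuple[str, ...] = ("G1", "G2", "G3", "G4")
    group_proportions: tuple[float, ...] = (21 / 48, 10 / 48, 3 / 48, 14 / 48)
    tissues: tuple[str, ...] = ("PBMC", "adjacent", "tumor")
    isotypes: tuple[str, ...] = ("IGHM", "IGHG")
    sequences_per_sample: int = 500
    clone_distributions: dict[str, CloneSizeDistribution] = field(
        default_factory=lambda: {
            "PBMC": CloneSizeDistribution(n_clones=300, ratio=0.995),
            "adjacent": CloneSizeDistribution(n_clones=200, ratio=0.97),
            "tumor": CloneSizeDistribution(n_clones=150, ratio=0.93),
        }
    )
    v_usage: dict[str, float] = field(default_factory=lambda: default_usage(gl.V_GENES))
    d_usage: dict[str, float] = field(default_factory=lambda: default_usage(gl.D_GENES, seed=8))
    j_usage: dict[str, float] = field(default_factory=lambda: default_usage(gl.J_GENES, seed=9))
    tumor_spike: dict[str, float] = field(
        default_factory=lambda: {"IGHV3-7": 0.08, "IGHV3-74": 0.05, "IGHV1-24": 0.05}
    )
    shm_rate: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("PBMC", "IGHM"): 0.004, ("adjacent", "IGHM"): 0.020, ("tumor", "IGHM"): 0.025,
            ("PBMC", "IGHG"): 0.050, ("adjacent", "IGHG"): 0.060, ("tumor", "IGHG"): 0.055,
        }
    )
    # IgG subisotype composition per group (IGHG1..IGHG4)
    subisotype_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "G1": {"IGHG1": 0.45, "IGHG2": 0.15, "IGHG3": 0.10, "IGHG4": 0.30},
            "G2": {"IGHG1": 0.30, "IGHG2": 0.35, "IGHG3": 0.25, "IGHG4": 0.10},
            "G3": {"IGHG1": 0.40, "IGHG2": 0.25, "IGHG3": 0.20, "IGHG4": 0.15},
            "G4": {"IGHG1": 0.30, "IGHG2": 0.35, "IGHG3": 0.25, "IGHG4": 0.10},
        }
    )
    proportion_concentration: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        for name, p in (("v_usage", self.v_usage), ("d_usage", self.d_usage),
                        ("j_usage", self.j_usage)):
            _validated_probs(p, name)
        gp = np.array(self.group_proportions)
        if abs(gp.sum() - 1.0) > 1e-9 or (gp < 0).any():
            raise ConfigError("group proportions must sum to 1")
        for g, p in self.subisotype_probs.items():
            _validated_probs(p, f"subisotype[{g}]")
        for key, r in self.shm_rate.items():
            if not 0.0 <= r <= 0.2:
                raise ConfigError(f"shm_rate{key} outside [0, 0.2]")
        spiked = dict(self.v_usage)
        total_delta = sum(self.tumor_spike.values())
        for gene, delta in self.tumor_spike.items():
            spiked[gene] = spiked.get(gene, 0.0) + delta
        # remaining mass is scaled down; every entry must stay a probability
        if total_delta >= 1.0 or any(v < 0 or v > 1 for v in spiked.values()):
            raise ConfigError("tumor_spike does not leave a valid usage distribution")


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream inference must recover."""

    patient_groups: dict[str, str] = field(default_factory=dict)
    spiked_genes: dict[str, float] = field(default_factory=dict)
    clone_membership: pd.Series | None = None  # sequence_id -> true clone id
    read_haplotypes: pd.DataFrame | None = None  # read_id, haplotype, subisotype, clone_id
    switch_ratios: dict[int, float] = field(default_factory=dict)
    subset_group_means: dict[str, pd.DataFrame] = field(default_factory=dict)


# --------------------------------------------------------------------------
# repertoire simulation


def _spiked_usage(usage: dict[str, float], spike: dict[str, float]) -> dict[str, float]:
    """Add the spike deltas and rescale the unspiked genes to keep sum 1."""
    total_delta = sum(spike.values())
    base_other = sum(f for g, f in usage.items() if g not in spike)
    scale = (base_other - total_delta) / base_other if base_other > 0 else 0.0
    out = {}
    for g, f in usage.items():
        out[g] = f + spike[g] if g in spike else f * scale
    for g, d in spike.items():
        out.setdefault(g, d)
    return out


def _sample_genes(rng, usage: dict[str, float], n: int) -> np.ndarray:
    genes = np.array(sorted(usage))
    p = np.array([usage[g] for g in genes], dtype=float)
    return genes[rng.choice(len(genes), size=n, p=p / p.sum())]


def _random_junction(rng) -> str:
    """In-frame junction: conserved C...W anchors around random stop-free codons."""
    n_inner = rng.integers(10, 19)  # total length 36..63 nt
    inner = "".join(gl._SAFE_CODONS[i]
                    for i in rng.integers(0, len(gl._SAFE_CODONS), size=n_inner))
    return "TGT" + inner + "TGG"


_CODON_AA: dict[str, str] = {}


def _translate(nt: str) -> str:
    global _CODON_AA
    if not _CODON_AA:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_AA = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_AA[stop] = "*"
    return "".join(_CODON_AA[nt[i:i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3))


def _mutate(rng, seq: str, rate: float, lo: int, hi: int) -> str:
    """Independent uniform substitutions at `rate` per site over [lo, hi)."""
    if rate <= 0.0:
        return seq
    n_sites = hi - lo
    k = rng.binomial(n_sites, rate)
    if k == 0:
        return seq
    positions = lo + rng.choice(n_sites, size=k, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def simulate_repertoire(
    n_sequences: int,
    clone_distribution: CloneSizeDistribution,
    usage_vectors: tuple[dict[str, float], dict[str, float], dict[str, float]] | None = None,
    shm_rate: float = 0.02,
    seed: int | np.random.SeedSequence = 0,
    *,
    patient_id: str = "P1",
    tissue: str = "tumor",
    isotype: str = "IGHM",
    subisotype_probs: dict[str, float] | None = None,
    junction_mutation_rate: float = 0.0,
    id_prefix: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate one sample's annotated repertoire.

    Returns the rearrangement table and a Series mapping sequence_id to the
    true clone id (the ground-truth partition).  Somatic mutations are placed
    independently and uniformly over the V region (FWR1-FWR3); the junction
    and the retained J nucleotides are mutated only at
    ``junction_mutation_rate`` (default 0, so clone members share junctions).
    """
    if n_sequences < 1:
        raise ConfigError("n_sequences must be >= 1")
    rng = np.random.default_rng(seed)
    v_usage, d_usage, j_usage = usage_vectors or (
        default_usage(gl.V_GENES), default_usage(gl.D_GENES, 8), default_usage(gl.J_GENES, 9))

    weights = clone_distribution.weights()
    sizes = rng.multinomial(n_sequences, weights)
    layout = gl.region_layout()
    prefix = id_prefix or f"{patient_id}_{tissue}_{isotype}"

    # clone-level draws
    n_clones = len(weights)
    clone_v = _sample_genes(rng, v_usage, n_clones)
    clone_d = _sample_genes(rng, d_usage, n_clones)
    clone_j = _sample_genes(rng, j_usage, n_clones)
    clone_junc = [_random_junction(rng) for _ in range(n_clones)]

    rows, truth_ids, truth_clones = [], [], []
    seq_no = 0
    for ci in range(n_clones):
        if sizes[ci] == 0:
            continue
        v, d, j = clone_v[ci], clone_d[ci], clone_j[ci]
        junction = clone_junc[ci]
        # germline junction is N-masked (not germline-encoded), so informative
        # positions coincide exactly with the V region where SHM is placed
        germ = gl.v_allele(v) + "N" * len(junction)
        cdr3_start0 = gl.V_LENGTH
        for _ in range(sizes[ci]):
            obs = _mutate(rng, gl.v_allele(v) + junction, shm_rate, 0, gl.V_LENGTH)
            if junction_mutation_rate > 0:
                obs = _mutate(rng, obs, junction_mutation_rate,
                              gl.V_LENGTH, gl.V_LENGTH + len(junction))
            obs_junction = obs[cdr3_start0:cdr3_start0 + len(junction)]
            sub = None
            if subisotype_probs:
                subs = sorted(subisotype_probs)
                sub = subs[rng.choice(len(subs),
                                      p=np.array([subisotype_probs[s] for s in subs]))]
            sid = f"{prefix}_{seq_no:06d}"
            seq_no += 1
            row = {
                "sequence_id": sid,
                "patient_id": patient_id,
                "tissue": tissue,
                "isotype": isotype,
                "subisotype": sub,
                "v_call": f"{v}*01",
                "d_call": f"{d}*01",
                "j_call": f"{j}*01",
                "c_call": f"{sub or isotype}*01",
                "productive": True,
                "junction": obs_junction,
                "junction_aa": _translate(obs_junction),
                "sequence_alignment": obs,
                "germline_alignment": germ,
                "duplicate_count": int(rng.geometric(0.6)),
                "clone_id": None,
            }
            for r, (s0, e0) in layout.items():
                row[f"{r}_start"], row[f"{r}_end"] = s0 + 1, e0
            row["cdr3_start"] = cdr3_start0 + 1
            rows.append(row)
            truth_ids.append(sid)
            truth_clones.append(f"{patient_id}:{tissue}:{isotype}:{ci}")
    table = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    truth = pd.Series(truth_clones, index=pd.Index(truth_ids, name="sequence_id"),
                      name="true_clone")
    return table, truth


# --------------------------------------------------------------------------
# proportion matrices

_GROUP_EFFECTS = {
    # (subset, added percentage points in that group's tumor mean)
    "G1": [("B_resident_activated_memory", 6.66), ("B_naive", 1.1),
           ("B_antigen_presenting", 1.0), ("B_activated_memory", 2.0),
           ("B_plasma", 2.0), ("CD4_CD69_central_memory", 2.0)],
    "G2": [("CD8_resident_memory", 13.0)],
    "G3": [("CD4_Th1_effector", 25.6)],
    "G4": [("My_classical_monocyte", 8.8), ("My_early_MDSC", 1.4),
           ("NK_mature", 2.9), ("CD8_senescent", 1.6)],
}


def _tissue_baseline(tissue: str) -> np.ndarray:
    rng = np.random.default_rng({"PBMC": 101, "adjacent": 102, "tumor": 103}[tissue])
    w = rng.dirichlet(np.full(len(ALL_SUBSETS), 3.0))
    return 100.0 * w


def _group_mean(tissue: str, group: str) -> np.ndarray:
    mean = _tissue_baseline(tissue).copy()
    if tissue == "tumor":
        idx = {s: i for i, s in enumerate(ALL_SUBSETS)}
        for subset, delta in _GROUP_EFFECTS.get(group, []):
            mean[idx[subset]] += delta
        mean *= 100.0 / mean.sum()
    return mean


def simulate_proportions(patients: list[str], groups: dict[str, str], tissue: str,
                         concentration: float, rng) -> pd.DataFrame:
    """Dirichlet-resampled percentages around each group's tissue mean."""
    rows = []
    for p in patients:
        mean = _group_mean(tissue, groups[p]) / 100.0
        rows.append(100.0 * rng.dirichlet(concentration * mean))
    return pd.DataFrame(rows, index=pd.Index(patients, name="patient_id"),
                        columns=list(ALL_SUBSETS))


# --------------------------------------------------------------------------
# full cohort


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], GroundTruth]:
    """Generate the full synthetic study.

    Returns ``(rearrangements, proportion_matrices, truth)`` where
    ``rearrangements`` concatenates all patient x tissue x isotype samples,
    ``proportion_matrices`` maps tissue -> patients x 66-subset percentage
    DataFrame, and ``truth`` carries the generating parameters.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_groups, ss_props, ss_rep = root.spawn(3)

    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    rng_g = np.random.default_rng(ss_groups)
    group_idx = rng_g.choice(len(config.group_labels), size=config.n_patients,
                             p=np.array(config.group_proportions))
    groups = {p: config.group_labels[i] for p, i in zip(patients, group_idx)}

    rng_p = np.random.default_rng(ss_props)
    proportions = {
        t: simulate_proportions(patients, groups, t, config.proportion_concentration, rng_p)
        for t in config.tissues
    }

    truth = GroundTruth(
        patient_groups=groups,
        spiked_genes=dict(config.tumor_spike),
        subset_group_means={
            t: pd.DataFrame(
                {g: _group_mean(t, g) for g in config.group_labels},
                index=list(ALL_SUBSETS)).T
            for t in config.tissues
        },
    )

    airr_patients = patients[: config.n_airr_patients]
    tables, truths = [], []
    child_seeds = iter(ss_rep.spawn(len(airr_patients) * len(config.tissues) * len(config.isotypes)))
    spiked_v = _spiked_usage(config.v_usage, config.tumor_spike)
    for p in airr_patients:
        for t in config.tissues:
            v_usage = spiked_v if t == "tumor" else config.v_usage
            for iso in config.isotypes:
                sub_probs = config.subisotype_probs[groups[p]] if iso == "IGHG" else None
                tbl, tr = simulate_repertoire(
                    config.sequences_per_sample,
                    config.clone_distributions[t],
                    (v_usage, config.d_usage, config.j_usage),
                    shm_rate=config.shm_rate[(t, iso)],
                    seed=next(child_seeds),
                    patient_id=p, tissue=t, isotype=iso,
                    subisotype_probs=sub_probs,
                )
                tables.append(tbl)
                truths.append(tr)
    rearrangements = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=REQUIRED_COLUMNS)
    truth.clone_membership = pd.concat(truths) if truths else pd.Series(dtype=object)
    return rearrangements, proportions, truth


# --------------------------------------------------------------------------
# near-full-length IgG reads over a diploid constant-region locus


@dataclass
class IghcHaplotypeModel:
    """Diploid constant-region locus with haplotype-biased class switching.

    ``het_sites`` maps each IGHG gene to the 0-based positions (on the gene
    reference) where the two chromosomal alleles differ; an empty tuple means
    the gene is homozygous.  ``switch_bias`` gives, per haplotype, the
    probability that a read from that chromosome uses each subisotype;
    ``haplotype_weights`` is the chromosome mixture over reads.
    """

    het_sites: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"IGHG1": (120, 480, 777), "IGHG4": (88, 402, 650),
                                 "IGHG2": (), "IGHG3": ()}
    )
    switch_bias: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            # haplotype 1 dominated by IGHG4 (IGHG4:IGHG1 = 4.6), haplotype 2
            # minor and evenly split between IGHG1 and IGHG4
            1: {"IGHG1": 0.98 / 5.6, "IGHG2": 0.01, "IGHG3": 0.01, "IGHG4": 4.508 / 5.6},
            2: {"IGHG1": 0.45, "IGHG2": 0.05, "IGHG3": 0.05, "IGHG4": 0.45},
        }
    )
    haplotype_weights: tuple[float, float] = (0.8, 0.2)
    error_rate: float = 0.0

    def validate(self) -> None:
        if not self.het_sites:
            raise ConfigError("model needs at least one constant-region gene")
        for h, bias in self.switch_bias.items():
            _validated_probs(bias, f"switch_bias[{h}]")
        if abs(sum(self.haplotype_weights) - 1.0) > 1e-9:
            raise ConfigError("haplotype weights must sum to 1")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ConfigError("error_rate outside [0, 0.2]")
        for g, sites in self.het_sites.items():
            if any(p >= 900 for p in sites):
                raise ConfigError(f"het sites for {g} must be < 900 so all reads cover them")

    def allele(self, gene: str, haplotype: int) -> str:
        """Constant-region sequence carried by ``haplotype`` (1 or 2) for ``gene``."""
        if haplotype == 1 or not self.het_sites.get(gene):
            return gl.c_allele(gene, "01")
        return gl.c_allele(gene, "02", tuple(self.het_sites[gene]))

    def expected_hap1_ratio(self, iso_a: str = "IGHG4", iso_b: str = "IGHG1") -> float:
        return self.switch_bias[1][iso_a] / self.switch_bias[1][iso_b]


def simulate_ighc_reads(
    model: IghcHaplotypeModel,
    clone_table: pd.DataFrame,
    n_reads: int,
    seed: int | np.random.SeedSequence = 0,
    length_window: tuple[int, int] = (900, 1100),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate near-full-length IgG reads: sampled VDJ + haplotyped constant region.

    Returns ``(reads, truth)``.  ``reads`` has columns read_id, sequence,
    c_start (0-based offset of the constant region), c_gene, subisotype and
    clone_id; ``truth`` additionally records the generating haplotype per read.
    """
    model.validate()
    if n_reads < 1:
        raise ConfigError("n_reads must be >= 1")
    if clone_table.empty:
        raise ConfigError("clone_table is empty")
    rng = np.random.default_rng(seed)
    lo, hi = length_window

    subs = sorted(model.switch_bias[1])
    hap_w = np.array(model.haplotype_weights)
    rows, truth_rows = [], []
    src = clone_table.reset_index(drop=True)
    for i in range(n_reads):
        rec = src.iloc[int(rng.integers(0, len(src)))]
        hap = int(rng.choice([1, 2], p=hap_w))
        bias = model.switch_bias[hap]
        sub = subs[rng.choice(len(subs), p=np.array([bias[s] for s in subs]))]
        c_full = model.allele(sub, hap)
        c_len = int(rng.integers(lo, min(hi, len(c_full)) + 1))
        vdj = rec["sequence_alignment"].replace(".", "").replace("-", "")
        read = vdj + c_full[:c_len]
        read = _mutate(rng, read, model.error_rate, 0, len(read))
        rid = f"read_{i:06d}"
        rows.append({
            "read_id": rid, "sequence": read, "c_start": len(vdj),
            "c_gene": sub, "subisotype": sub,
            "clone_id": rec.get("clone_id") or rec["sequence_id"],
            "v_call": rec["v_call"], "sequence_id": rec["sequence_id"],
        })
        truth_rows.append({"read_id": rid, "haplotype": hap, "subisotype": sub,
                           "clone_id": rows[-1]["clone_id"]})
    reads = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return reads, truth
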