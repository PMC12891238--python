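"""Synthetic germline reference for the cohort generator.

A small, packaged set of heavy-chain V/D/J and constant-region (IGHC) allele
sequences with IMGT-style names.  The sequences are synthetic: they are
generated deterministically from the gene name (CRC32-seeded), carry the real
genes' approximate lengths and region layout, and contain no stop codons in
the V reading frame, but they are not copies of any database entry.

Layout of a V allele (294 nt, in-frame):
FWR1 75 | CDR1 24 | FWR2 51 | CDR2 30 | FWR3 114; CDR3 begins at position 294.
"""

from __future__ import annotations

import zlib
from functools import lru_cache

import numpy as np

NT = np.array(list("ACGT"))

#: (region, length) layout of the V segment in alignment coordinates.
V_LAYOUT = (("fwr1", 75), ("cdr1", 24), ("fwr2", 51), ("cdr2", 30), ("fwr3", 114))
V_LENGTH = sum(n for _, n in V_LAYOUT)
J_TAIL_LENGTH = 30  # J-segment nucleotides retained downstream of the junction

V_GENES = (
    "IGHV1-2", "IGHV1-24", "IGHV1-69", "IGHV2-5", "IGHV3-7", "IGHV3-23",
    "IGHV3-30", "IGHV3-74", "IGHV4-34", "IGHV4-59", "IGHV5-51", "IGHV6-1",
)
D_GENES = ("IGHD1-1", "IGHD2-2", "IGHD3-10", "IGHD4-17", "IGHD5-12", "IGHD6-19")
J_GENES = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")
C_GENES = ("IGHM", "IGHG1", "IGHG2", "IGHG3", "IGHG4")
C_LENGTH = 1000

STOP_CODONS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def _rng_for(name: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(name.encode()))


def _random_orf(rng: np.random.Generator, n_nt: int) -> str:
    """Random sequence of ``n_nt`` nucleotides (multiple of 3) with no stop codon."""
    assert n_nt % 3 == 0
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_nt // 3)
    return "".join(_SAFE_CODONS[i] for i in idx)


@lru_cache(maxsize=None)
def v_allele(gene: str, allele: str = "01") -> str:
    """294-nt in-frame V-segment sequence for ``gene`` (e.g. ``"IGHV3-7"``)."""
    return _random_orf(_rng_for(f"{gene}*{allele}"), V_LENGTH)


@lru_cache(maxsize=None)
def j_tail(gene: str, allele: str = "01") -> str:
    """J-segment nucleotides appended after the junction (frame-preserving)."""
    return _random_orf(_rng_for(f"{gene}*{allele}"), J_TAIL_LENGTH)


@lru_cache(maxsize=None)
def c_allele(gene: str, allele: str = "01",
             het_positions: tuple[int, ...] = ()) -> str:
    """Constant-region allele sequence of ``C_LENGTH`` nt.

    ``allele="01"`` is the reference; other alleles differ from it at
    ``het_positions`` (each flipped to the next base in ACGT order), modelling
    heterozygous SNVs between the two chromosomes.
    """
    base = "".join(NT[_rng_for(f"{gene}*01").integers(0, 4, size=C_LENGTH)])
    if allele == "01":
        return base
    seq = list(base)
    for pos in het_positions:
        seq[pos] = NT[(list(NT).index(seq[pos]) + 1) % 4]
    return "".join(seq)


def region_layout() -> dict[str, tuple[int, int]]:
    """0-based half-open intervals of the five delimited V regions."""
    bounds, pos = {}, 0
    for name, n in V_LAYOUT:
        bounds[name] = (pos, pos + n)
        pos += n
    return bounds
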