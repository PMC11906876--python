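"""Genetic-code helpers shared across the package.

The standard nuclear genetic code is taken from Biopython's codon tables.
Codons are indexed as ``16*i0 + 4*i1 + i2`` with bases ordered A,C,G,T,
which lets consequence annotation run vectorised over whole coding
sequences.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Column order of every L x 20 substitution grid in this package.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

STOP = "*"

CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]

_forward = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _forward[_stop] = STOP

#: Amino acid (one-letter, ``*`` for stop) for each codon index 0..63.
AA64 = np.array([_forward[c] for c in CODONS])

CONSEQUENCES = ("synonymous", "missense", "nonsense", "stop_loss", "other")

_base_lut = np.full(256, -1, dtype=np.int64)
for _b, _i in BASE_INDEX.items():
    _base_lut[ord(_b)] = _i
    _base_lut[ord(_b.lower())] = _i


def cds_to_indices(cds: str) -> np.ndarray:
    """Map a nucleotide string to integer base indices (A=0,C=1,G=2,T=3)."""
    raw = np.frombuffer(cds.encode("ascii"), dtype=np.uint8)
    idx = _base_lut[raw]
    if (idx < 0).any():
        bad = cds[int(np.argmax(idx < 0))]
        raise ValueError(f"non-ACGT base {bad!r} in coding sequence")
    return idx


def codon_indices(cds_idx: np.ndarray) -> np.ndarray:
    """Codon index (0..63) for each codon of an in-frame index array."""
    if cds_idx.size % 3:
        raise ValueError("coding sequence length not divisible by 3")
    return 16 * cds_idx[0::3] + 4 * cds_idx[1::3] + cds_idx[2::3]


def translate_cds(cds: str, strip_terminal_stop: bool = True) -> str:
    """Translate an in-frame CDS; the terminal stop is dropped by default."""
    aa = AA64[codon_indices(cds_to_indices(cds))]
    protein = "".join(aa)
    if strip_terminal_stop and protein.endswith(STOP):
        protein = protein[:-1]
    return protein


def consequence_of(ref_aa: str, alt_aa: str) -> str:
    """Consequence class of a single amino-acid change.

    Single-nucleotide substitutions only ever produce the first four
    classes; ``other`` is reserved for records read from external tables.
    """
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == STOP:
        return "nonsense"
    if ref_aa == STOP:
        return "stop_loss"
    return "missense"


def consequences_of(ref_aa: np.ndarray, alt_aa: np.ndarray) -> np.ndarray:
    """Vectorised :func:`consequence_of` over aligned arrays."""
    ref_aa = np.asarray(ref_aa)
    alt_aa = np.asarray(alt_aa)
    return np.select(
        [ref_aa == alt_aa, alt_aa == STOP, ref_aa == STOP],
        ["synonymous", "nonsense", "stop_loss"],
        default="missense",
    )


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))
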