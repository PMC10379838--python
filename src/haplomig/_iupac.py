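"""IUPAC nucleotide code arithmetic on 4-bit masks (A=1, C=2, G=4, T=8).

Direct Sanger sequencing of a heterozygous template superimposes two alleles
in one chromatogram; basecallers emit IUPAC ambiguity codes at the mixed
positions. All genotype logic in this package therefore runs on bitmasks so
"compatible" (shared bit) and "exact" comparisons stay cheap and explicit.
"""

from __future__ import annotations

import numpy as np

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

# full IUPAC alphabet as bit-unions
CODE_TO_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}
MASK_TO_CODE: dict[int, str] = {v: k for k, v in CODE_TO_MASK.items()}

#: 256-entry lookup: ASCII byte -> mask (0 for non-IUPAC characters)
MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in CODE_TO_MASK.items():
    MASK_LUT[ord(_c)] = _m
    MASK_LUT[ord(_c.lower())] = _m

#: number of bases a mask represents (popcount of the low 4 bits)
POPCOUNT_LUT = np.array([bin(i).count("1") for i in range(16)], dtype=np.uint8)


def mask_of(base: str) -> int:
    """Mask for a single IUPAC character (0 if unrecognized)."""
    return CODE_TO_MASK.get(base.upper(), 0)


def merge_bases(a: str, b: str) -> str:
    """IUPAC code for the superposition of two base calls.

    Models what direct sequencing of a heterozygote reports at a position
    where the two alleles read ``a`` and ``b``.
    """
    m = mask_of(a) | mask_of(b)
    if m == 0:
        raise ValueError(f"cannot merge non-IUPAC bases {a!r}, {b!r}")
    return MASK_TO_CODE[m]


def merge_strings(a: str, b: str) -> str:
    """Position-wise IUPAC merge of two allele strings.

    The merged read stops at the shorter allele, as a chromatogram read off
    a mixed template of unequal lengths effectively does once the frames
    diverge. Used to emulate direct-read artifacts of heterozygous indels.
    """
    return "".join(merge_bases(x, y) for x, y in zip(a, b))


def to_mask_array(seq: str) -> np.ndarray:
    """uint8 mask array for a sequence string (0 for unknown characters)."""
    return MASK_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def is_unambiguous(mask: np.ndarray | int):
    return POPCOUNT_LUT[mask] == 1
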