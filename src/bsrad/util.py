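"""Small sequence and RNG helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# reduced alphabets for three-letter bisulfite comparison
CT_REDUCE = str.maketrans("C", "T")
GA_REDUCE = str.maketrans("G", "A")

# internal 2-bit-ish base codes used by the simulator and aligner; N is kept
# distinct so it can never silently match a real base
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code vector (A=0,C=1,G=2,T=3,N=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_seqs(seqs, length: int | None = None) -> np.ndarray:
    """Encode equal-length DNA strings as a (n, L) uint8 code matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, length or 0), dtype=np.uint8)
    L = length if length is not None else len(seqs[0])
    out = np.empty((len(seqs), L), dtype=np.uint8)
    for i, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError("sequences must all have the same length")
        out[i] = _ENCODE_LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    return out


def decode_seq(codes: np.ndarray) -> str:
    return CODE_TO_BASE[codes].tobytes().decode("ascii")


def decode_seqs(mat: np.ndarray) -> list[str]:
    return [CODE_TO_BASE[row].tobytes().decode("ascii") for row in mat]


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent generator for a pipeline stage, derived from the run seed.

    Keeps every source of randomness behind the single run seed while letting
    stages draw in any order without perturbing each other.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))
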