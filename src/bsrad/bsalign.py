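"""Three-letter alignment of bisulfite reads to per-individual references.

RAD reads start at the cut site, so every read is anchored at a locus start
and alignment reduces to an ungapped Hamming comparison under a reduced
alphabet.  Two strand hypotheses are scored against every locus of a
reference copy:

* complementary-to-original-bottom (CTOB): the read reports '−'-strand
  cytosines at top-strand G positions, so read-A over reference-G is a
  bisulfite-explainable difference — both sequences are compared after G→A
  reduction and such differences cost nothing by construction;
* original-top (OT): a converted top-strand read, compared after C→T
  reduction (read-T over reference-C is free).

The best placement (locus × hypothesis) wins if its mismatch count is within
``max_mm`` and it is unique; any tie is reported as ambiguous/unmapped.  Each
reference copy of an individual is aligned independently — a read from a
homozygous locus legitimately maps to both copies, giving the two report
columns per individual used downstream.  N bases never match anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .refbuild import PseudoReference
from .util import CT_REDUCE, GA_REDUCE, encode_seqs

STRAND_CLASSES = ("OT", "OB", "CTOT", "CTOB")
_FRAME_CLASS = {"GA": "CTOB", "CT": "OT"}


def reduce_alphabet(seq: str, mode: str) -> str:
    """Collapse a bisulfite-convertible base: mode 'C->T' or 'G->A'."""
    if mode in ("C->T", "CT"):
        return seq.translate(CT_REDUCE)
    if mode in ("G->A", "GA"):
        return seq.translate(GA_REDUCE)
    raise ValueError(f"unknown reduction mode {mode!r}")


@dataclass(frozen=True)
class BsAlignment:
    read_id: str
    locus_id: int | None
    copy: str | None
    strand_class: str | None
    mismatches: int | None
    mapped: bool
    read_index: int = -1  # position of the read in the aligned batch


class _CopyIndex:
    """Reduced-alphabet matrices and exact-match lookups for one copy."""

    def __init__(self, ref: PseudoReference):
        self.copy = ref.copy
        self.locus_ids = list(ref.locus_ids)
        self.L = ref.locus_len
        seqs = [ref.locus_seqs[lid] for lid in ref.locus_ids]
        mat = encode_seqs(seqs, self.L)
        self.ga_mat = mat.copy()
        self.ga_mat[self.ga_mat == 2] = 0  # G -> A
        self.ct_mat = mat.copy()
        self.ct_mat[self.ct_mat == 1] = 3  # C -> T
        self.ga_lookup: dict[str, list[int]] = {}
        self.ct_lookup: dict[str, list[int]] = {}
        for lid, s in zip(self.locus_ids, seqs):
            self.ga_lookup.setdefault(s.translate(GA_REDUCE), []).append(lid)
            self.ct_lookup.setdefault(s.translate(CT_REDUCE), []).append(lid)


def _align_batch_to_copy(seqs, ids, index: _CopyIndex, max_mm, min_anchor):
    """Align equal-length reads to one reference copy."""
    out: list[BsAlignment | None] = [None] * len(seqs)
    slow: list[int] = []
    L = index.L

    for i, s in enumerate(seqs):
        if len(s) < min_anchor:
            out[i] = BsAlignment(ids[i], None, index.copy, None, None, False, i)
            continue
        if len(s) == L:
            ga_hits = index.ga_lookup.get(s.translate(GA_REDUCE), [])
            ct_hits = index.ct_lookup.get(s.translate(CT_REDUCE), [])
            if len(ga_hits) == 1 and not ct_hits:
                out[i] = BsAlignment(ids[i], ga_hits[0], index.copy, "CTOB", 0, True, i)
                continue
            if len(ct_hits) == 1 and not ga_hits:
                out[i] = BsAlignment(ids[i], ct_hits[0], index.copy, "OT", 0, True, i)
                continue
            if ga_hits or ct_hits:  # exact in both frames, or non-unique
                out[i] = BsAlignment(ids[i], None, index.copy, None, 0, False, i)
                continue
        slow.append(i)

    # exhaustive reduced-alphabet Hamming scan for the remainder
    by_len: dict[int, list[int]] = {}
    for i in slow:
        by_len.setdefault(min(len(seqs[i]), L), []).append(i)

    for Lc, idxs in by_len.items():
        reads = encode_seqs([seqs[i][:Lc] for i in idxs], Lc)
        r_ga = reads.copy()
        r_ga[r_ga == 2] = 0
        r_ct = reads.copy()
        r_ct[r_ct == 1] = 3
        n_ref = index.ga_mat.shape[0]
        chunk = max(1, int(2e7 // (n_ref * Lc + 1)))
        for lo in range(0, len(idxs), chunk):
            hi = min(len(idxs), lo + chunk)
            mm_ga = (r_ga[lo:hi, None, :] != index.ga_mat[None, :, :Lc]).sum(2)
            mm_ct = (r_ct[lo:hi, None, :] != index.ct_mat[None, :, :Lc]).sum(2)
            mm = np.stack([mm_ga, mm_ct])  # (frame, read, ref)
            best = mm.min(axis=(0, 2))
            for rj in range(hi - lo):
                i = idxs[lo + rj]
                b = int(best[rj])
                if b > max_mm:
                    out[i] = BsAlignment(ids[i], None, index.copy, None, None, False, i)
                    continue
                frames, refs = np.nonzero(mm[:, rj, :] == b)
                if len(refs) != 1:
                    out[i] = BsAlignment(ids[i], None, index.copy, None, b, False, i)
                    continue
                cls = _FRAME_CLASS["GA" if frames[0] == 0 else "CT"]
                out[i] = BsAlignment(
                    ids[i], index.locus_ids[int(refs[0])], index.copy, cls, b, True, i
                )
    return out


def align_reads(
    reads,
    refs: tuple[PseudoReference, PseudoReference],
    max_mm: int = 1,
    min_anchor: int = 20,
) -> list[BsAlignment]:
    """Align barcode-trimmed reads to both reference copies of an individual.

    Returns one :class:`BsAlignment` per read per copy (mapped or not), in
    read order with copy A before copy B.
    """
    seqs = [r.seq for r in reads]
    ids = [r.id for r in reads]
    out: list[BsAlignment] = []
    for ref in refs:
        out.extend(_align_batch_to_copy(seqs, ids, _CopyIndex(ref), max_mm, min_anchor))
    return out


def align_read(read, refs, max_mm: int = 1, min_anchor: int = 20):
    """Single-read convenience wrapper: alignments against copy A and B."""
    return align_reads([read], refs, max_mm=max_mm, min_anchor=min_anchor)


def strand_filter(alignments, keep=("CTOT", "CTOB")) -> list[BsAlignment]:
    """Retain only mapped alignments of the requested strand classes.

    By default only complementary-to-original strands survive, matching the
    observation that original-strand molecules are rare and low-coverage.
    """
    keep = set(keep)
    bad = keep - set(STRAND_CLASSES)
    if bad:
        raise ValueError(f"unknown strand classes: {sorted(bad)}")
    return [a for a in alignments if a.mapped and a.strand_class in keep]


def scan_windows(read_seq: str, reference: str, max_mm: int):
    """Toy-scale external-reference mode: score every window of an arbitrary
    FASTA sequence with the same two-frame reduced-alphabet comparison.

    Quadratic in the reference length; intended for small supplied references
    only.  Returns (start, strand_class, mismatches) for the best unique
    window, or None.
    """
    L = len(read_seq)
    r_ga = reduce_alphabet(read_seq, "GA")
    r_ct = reduce_alphabet(read_seq, "CT")
    hits = []
    for start in range(len(reference) - L + 1):
        window = reference[start : start + L]
        mm_ga = sum(a != b for a, b in zip(r_ga, reduce_alphabet(window, "GA")))
        mm_ct = sum(a != b for a, b in zip(r_ct, reduce_alphabet(window, "CT")))
        if mm_ga <= max_mm:
            hits.append((mm_ga, start, "CTOB"))
        if mm_ct <= max_mm:
            hits.append((mm_ct, start, "OT"))
    if not hits:
        return None
    hits.sort()
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return None
    mm, start, cls = hits[0]
    return (start, cls, mm)
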