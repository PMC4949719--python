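"""Per-cytosine methylation reports (CX-report style) per sample x copy.

For complementary-to-original-bottom (CTOB) alignments, cytosines live on the
'−' strand, i.e. at top-strand G positions of the stored reference: a read G
there supports methylation, a read A supports conversion (no methylation),
and any other base (sequencing error) supports neither and is excluded from
both counts.  The first ``trim_head`` bases of every read correspond to the
P1 adapter overhang and are never scored.  Context is always derived from
the reference copy's own sequence — never from reads — which is what makes
SNP/SMP disambiguation possible downstream.  A record is emitted for every
reference cytosine, including uncovered ones, so that "no cytosine in this
individual's genotype" and "no coverage" remain distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .refbuild import PseudoReference
from .util import encode_seqs

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class CytosineRecord:
    locus_id: int
    offset: int
    strand: str
    context: str
    coverage: int
    meth_count: int

    def __post_init__(self):
        if not 0 <= self.meth_count <= self.coverage:
            raise ValueError("meth_count must lie in [0, coverage]")

    @property
    def level(self) -> float:
        return self.meth_count / self.coverage if self.coverage else float("nan")


def classify_context(locus_seq: str, offset: int, strand: str) -> str:
    """CpG / CHG / CHH context of the cytosine at ``offset`` on ``strand``.

    Looks at the two bases 3' of the cytosine on its own strand, staying
    within the locus; insufficient bases or N give 'unknown'.  Raises if the
    base at ``offset`` is not a cytosine on the requested strand.
    """
    if strand == "+":
        if locus_seq[offset] != "C":
            raise ValueError(f"base at offset {offset} is not C on '+' strand")
        b1 = locus_seq[offset + 1] if offset + 1 < len(locus_seq) else None
        b2 = locus_seq[offset + 2] if offset + 2 < len(locus_seq) else None
    elif strand == "-":
        if locus_seq[offset] != "G":
            raise ValueError(f"base at offset {offset} is not C on '-' strand")
        b1 = _COMP[locus_seq[offset - 1]] if offset - 1 >= 0 else None
        b2 = _COMP[locus_seq[offset - 2]] if offset - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    if b1 is None or b1 == "N":
        return "unknown"
    if b1 == "G":
        return "CpG"
    if b2 is None or b2 == "N":
        return "unknown"
    if b2 == "G":
        return "CHG"
    return "CHH"


def call_methylation(
    reads,
    alignments,
    ref: PseudoReference,
    trim_head: int = 4,
) -> list[CytosineRecord]:
    """Summarize strand-filtered alignments into per-cytosine records.

    ``alignments`` must carry ``read_index`` into ``reads`` (as produced by
    the aligner); only CTOB alignments belonging to ``ref``'s copy are
    scored.  Records cover every '−'-strand cytosine of every non-padded
    locus in the reference, coverage 0 included.
    """
    by_locus: dict[int, list[int]] = {}
    for a in alignments:
        if a.mapped and a.copy == ref.copy and a.strand_class == "CTOB":
            by_locus.setdefault(a.locus_id, []).append(a.read_index)

    records: list[CytosineRecord] = []
    for lid in ref.locus_ids:
        allele = ref.locus_seqs[lid]
        if allele.startswith("N"):  # padding for a locus absent in this sample
            continue
        gpos = [i for i, b in enumerate(allele) if b == "G"]
        if not gpos:
            continue
        idxs = by_locus.get(lid, [])
        if idxs:
            L = len(allele)
            mat = encode_seqs([reads[i].seq[:L].ljust(L, "N") for i in idxs], L)
            sub = mat[:, gpos]
            cov_g = (sub == 2).sum(axis=0)
            cov_a = (sub == 0).sum(axis=0)
        else:
            cov_g = np.zeros(len(gpos), dtype=int)
            cov_a = np.zeros(len(gpos), dtype=int)
        for k, off in enumerate(gpos):
            if off < trim_head:
                meth, cov = 0, 0
            else:
                meth = int(cov_g[k])
                cov = meth + int(cov_a[k])
            records.append(
                CytosineRecord(
                    locus_id=lid,
                    offset=off,
                    strand="-",
                    context=classify_context(allele, off, "-"),
                    coverage=cov,
                    meth_count=meth,
                )
            )
    return records


def conversion_efficiency(records) -> float | None:
    """Bisulfite conversion rate proxy from apparent CHH methylation.

    Returns ``1 - pooled CHH meth / pooled CHH coverage``.  Only meaningful
    where true CHH methylation is negligible (e.g. vertebrate-like genomes).
    Returns None when no CHH position has coverage.
    """
    cov = sum(r.coverage for r in records if r.context == "CHH")
    if cov == 0:
        return None
    meth = sum(r.meth_count for r in records if r.context == "CHH")
    return 1.0 - meth / cov


def write_cx_report(records, path) -> None:
    """CX-report-like TSV: 1-based position, strand, counts, context."""
    with open(path, "w") as fh:
        fh.write("locus_id\tpos\tstrand\tmeth_count\tunmeth_count\tcontext\n")
        for r in records:
            fh.write(
                f"{r.locus_id}\t{r.offset + 1}\t{r.strand}\t"
                f"{r.meth_count}\t{r.coverage - r.meth_count}\t{r.context}\n"
            )


def read_cx_report(path) -> list[CytosineRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["locus_id", "pos", "strand", "meth_count", "unmeth_count", "context"]:
            raise ValueError(f"unrecognized CX report header: {header!r}")
        for line in fh:
            lid, pos, strand, meth, unmeth, ctx = line.rstrip("\n").split("\t")
            records.append(
                CytosineRecord(
                    locus_id=int(lid),
                    offset=int(pos) - 1,
                    strand=strand,
                    context=ctx,
                    coverage=int(meth) + int(unmeth),
                    meth_count=int(meth),
                )
            )
    return records


def write_bedgraph(records, path) -> None:
    """bedGraph of methylation levels x100, 0-based half-open, covered sites only."""
    with open(path, "w") as fh:
        for r in records:
            if r.coverage:
                fh.write(
                    f"{r.locus_id}\t{r.offset}\t{r.offset + 1}\t"
                    f"{100.0 * r.meth_count / r.coverage:.6g}\n"
                )
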