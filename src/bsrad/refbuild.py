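"""Per-individual pseudo-references from catalog alleles.

Each individual gets *two* concatenated reference sequences (copies A and B):
at heterozygous loci the two alleles are split between the copies at random
(phasing is irrelevant because RAD loci are far apart); homozygous alleles
are duplicated.  The catalog's locus order is identical for every sample and
both copies, so a (locus, offset, strand) triple — a :class:`GlobalPosition`
— identifies homologous cytosines across the whole experiment.  Loci absent
from an individual are padded with N runs so the frame never shifts; a 2-base
NN spacer between loci prevents spurious trinucleotide contexts spanning a
junction.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import NamedTuple

from .radloci import Catalog

SPACER = "NN"


class GlobalPosition(NamedTuple):
    locus_id: int
    offset: int
    strand: str


@dataclass
class PseudoReference:
    sample: str
    copy: str  # "A" or "B"
    locus_ids: list[int]
    locus_seqs: dict[int, str]  # per-locus sequence placed in this copy
    offsets: dict[int, int]  # locus id -> start in the concatenation
    locus_len: int

    @property
    def sequence(self) -> str:
        return SPACER.join(self.locus_seqs[lid] for lid in self.locus_ids)

    def fasta_header(self) -> str:
        return f"{self.sample}|copy{self.copy}"


def build_pseudo_references(
    catalog: Catalog, sample: str, rng
) -> tuple[PseudoReference, PseudoReference]:
    """Build the two concatenated per-individual references for ``sample``.

    Heterozygous loci: the two retained alleles go to copies A/B at random
    under ``rng``; homozygous loci are duplicated; absent loci become N runs.
    """
    if not catalog.loci:
        raise ValueError("empty catalog")
    locus_len = len(catalog.loci[0].consensus)

    seqs = {"A": {}, "B": {}}
    locus_ids = []
    for loc in catalog.loci:
        alleles = loc.alleles.get(sample, ())
        for a in alleles:
            if len(a) != locus_len:
                raise ValueError(
                    f"allele length {len(a)} != locus length {locus_len} "
                    f"at locus {loc.id}"
                )
        if not alleles:
            a = b = "N" * locus_len
        elif len(set(alleles)) == 1:
            a = b = alleles[0]
        else:
            first, second = alleles[0], alleles[1]
            if rng.random() < 0.5:
                first, second = second, first
            a, b = first, second
        seqs["A"][loc.id] = a
        seqs["B"][loc.id] = b
        locus_ids.append(loc.id)

    offsets = {}
    pos = 0
    for lid in locus_ids:
        offsets[lid] = pos
        pos += locus_len + len(SPACER)

    return tuple(
        PseudoReference(
            sample=sample,
            copy=c,
            locus_ids=list(locus_ids),
            locus_seqs=seqs[c],
            offsets=dict(offsets),
            locus_len=locus_len,
        )
        for c in ("A", "B")
    )


def map_offset(ref: PseudoReference, coordinate: int, strand: str = "-") -> GlobalPosition:
    """Map a 0-based concatenated coordinate back to (locus, offset, strand).

    Raises ValueError for coordinates falling in an inter-locus spacer or
    outside the reference.
    """
    if coordinate < 0:
        raise ValueError("negative coordinate")
    starts = [ref.offsets[lid] for lid in ref.locus_ids]
    k = bisect.bisect_right(starts, coordinate) - 1
    if k < 0:
        raise ValueError("coordinate before first locus")
    lid = ref.locus_ids[k]
    off = coordinate - starts[k]
    if off >= ref.locus_len:
        raise ValueError(f"coordinate {coordinate} falls in a spacer or past the end")
    return GlobalPosition(lid, off, strand)


def global_coordinate(ref: PseudoReference, pos: GlobalPosition) -> int:
    """Inverse of :func:`map_offset`."""
    if pos.offset >= ref.locus_len:
        raise ValueError("offset beyond locus length")
    return ref.offsets[pos.locus_id] + pos.offset


def write_fasta(refs, path) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.fasta_header()}\n{ref.sequence}\n")


def write_offsets(ref: PseudoReference, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tstart\n")
        for lid in ref.locus_ids:
            fh.write(f"{lid}\t{ref.offsets[lid]}\n")
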