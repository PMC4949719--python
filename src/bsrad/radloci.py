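"""De novo RAD locus assembly: stacks -> per-sample loci -> shared catalog.

A deliberately simple, deterministic re-creation of the Stacks-style de novo
pipeline: exact-duplicate reads above a depth threshold form *stacks*; stacks
of one individual within M mismatches merge (single linkage) into a *locus*
holding up to ``max_locus_stacks`` alleles; per-sample loci within n
mismatches of each other merge across individuals into *catalog* loci with a
deterministic (lexicographic-by-consensus) order shared by every sample.
Secondary (sub-threshold) reads are never used for haplotype calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .util import encode_seqs


@dataclass(frozen=True)
class Stack:
    sequence: str
    depth: int
    sample: str


@dataclass(frozen=True)
class Locus:
    sample: str
    alleles: tuple[str, ...]
    depths: tuple[int, ...]


@dataclass
class CatalogLocus:
    id: int
    consensus: str
    alleles: dict[str, tuple[str, ...]]  # sample -> retained allele sequences

    @property
    def snp_positions(self) -> list[int]:
        """Columns where any two retained alleles (any samples) differ."""
        seqs = sorted({a for al in self.alleles.values() for a in al})
        if len(seqs) <= 1:
            return []
        first = seqs[0]
        return [
            i
            for i in range(len(first))
            if any(s[i] != first[i] for s in seqs[1:])
        ]

    @property
    def heterozygosity(self) -> float:
        """Fraction of samples carrying the locus with >= 2 distinct alleles."""
        if not self.alleles:
            return 0.0
        het = sum(1 for al in self.alleles.values() if len(set(al)) >= 2)
        return het / len(self.alleles)


@dataclass
class Catalog:
    loci: list[CatalogLocus] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loci)


def build_stacks(reads, min_stack_depth: int, sample: str = "") -> list[Stack]:
    """Pile identical reads into stacks with depth >= ``min_stack_depth``.

    Sub-threshold sequences are dropped (secondary reads are not used for
    haplotype calls).
    """
    counts = Counter(reads)
    if counts and len({len(s) for s in counts}) > 1:
        raise ValueError("reads must all have the same length")
    return [
        Stack(seq, depth, sample)
        for seq, depth in sorted(counts.items())
        if depth >= min_stack_depth
    ]


def _pairwise_components(seqs: list[str], max_mismatch: int) -> np.ndarray:
    """Single-linkage component label per sequence (Hamming <= max_mismatch)."""
    n = len(seqs)
    if n == 0:
        return np.empty(0, dtype=int)
    mat = encode_seqs(seqs)
    rows, cols = [], []
    chunk = max(1, int(4e7 // (n * mat.shape[1] + 1)))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        d = (mat[lo:hi, None, :] != mat[None, :, :]).sum(axis=2)
        r, c = np.nonzero(d <= max_mismatch)
        rows.append(r + lo)
        cols.append(c)
    adj = coo_matrix(
        (np.ones(sum(len(r) for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def merge_stacks_to_loci(
    stacks: list[Stack], max_mismatch: int = 7, max_locus_stacks: int = 2
) -> list[Locus]:
    """Single-linkage merge of one sample's stacks into loci.

    Groups holding more than ``max_locus_stacks`` stacks are dropped as
    putative repeats.
    """
    if not stacks:
        return []
    samples = {s.sample for s in stacks}
    if len(samples) > 1:
        raise ValueError("merge_stacks_to_loci expects stacks from one sample")
    labels = _pairwise_components([s.sequence for s in stacks], max_mismatch)
    loci = []
    for lab in np.unique(labels):
        members = [s for s, l in zip(stacks, labels) if l == lab]
        if len(members) > max_locus_stacks:
            continue
        members.sort(key=lambda s: s.sequence)
        loci.append(
            Locus(
                sample=members[0].sample,
                alleles=tuple(s.sequence for s in members),
                depths=tuple(s.depth for s in members),
            )
        )
    loci.sort(key=lambda l: l.alleles)
    return loci


def _consensus(seq_list: list[str]) -> str:
    """Per-column majority base; ties resolve to the alphabetically smallest."""
    mat = encode_seqs(seq_list)
    counts = np.zeros((5, mat.shape[1]), dtype=np.int64)
    for b in range(5):
        counts[b] = (mat == b).sum(axis=0)
    # order A,C,G,T,N with argmax taking the first (smallest) on ties
    best = counts.argmax(axis=0)
    return "".join("ACGTN"[b] for b in best)


def build_catalog(
    per_sample_loci: dict[str, list[Locus]], max_mismatch: int = 9
) -> Catalog:
    """Merge per-sample loci across individuals into an ordered catalog.

    Single linkage on per-sample consensus sequences (Hamming <=
    ``max_mismatch``); every sample sees the same lexicographic locus order.
    """
    entries = []  # (sample, Locus, consensus)
    for sample, loci in per_sample_loci.items():
        for loc in loci:
            entries.append((sample, loc, _consensus(list(loc.alleles))))
    if not entries:
        return Catalog(loci=[], samples=sorted(per_sample_loci))

    uniq = sorted({c for _, _, c in entries})
    uniq_idx = {c: i for i, c in enumerate(uniq)}
    labels = _pairwise_components(uniq, max_mismatch)

    groups: dict[int, list[tuple[str, Locus]]] = {}
    for sample, loc, cons in entries:
        groups.setdefault(int(labels[uniq_idx[cons]]), []).append((sample, loc))

    catalog_loci = []
    for members in groups.values():
        all_alleles = [a for _, loc in members for a in loc.alleles]
        consensus = _consensus(all_alleles)
        alleles: dict[str, tuple[str, ...]] = {}
        for sample, loc in members:
            merged = tuple(sorted(set(alleles.get(sample, ())) | set(loc.alleles)))
            alleles[sample] = merged
        catalog_loci.append((consensus, alleles))

    catalog_loci.sort(key=lambda t: t[0])
    return Catalog(
        loci=[
            CatalogLocus(id=i, consensus=cons, alleles=alleles)
            for i, (cons, alleles) in enumerate(catalog_loci)
        ],
        samples=sorted(per_sample_loci),
    )


def filter_catalog(
    catalog: Catalog, max_snps: int = 10, max_het: float = 0.75
) -> Catalog:
    """Drop loci with too many polymorphic columns or excess heterozygosity."""
    kept = [
        loc
        for loc in catalog.loci
        if len(loc.snp_positions) <= max_snps and loc.heterozygosity <= max_het
    ]
    return Catalog(loci=kept, samples=list(catalog.samples))


def select_alleles(catalog: Catalog, max_alleles: int = 2, rng=None) -> Catalog:
    """Retain at most ``max_alleles`` alleles per sample per locus (random)."""
    if rng is None:
        rng = np.random.default_rng(0)
    new_loci = []
    for loc in catalog.loci:
        alleles = {}
        for sample in sorted(loc.alleles):
            al = loc.alleles[sample]
            if len(al) > max_alleles:
                keep = rng.choice(len(al), size=max_alleles, replace=False)
                al = tuple(sorted(al[i] for i in keep))
            alleles[sample] = al
        new_loci.append(CatalogLocus(id=loc.id, consensus=loc.consensus, alleles=alleles))
    return Catalog(loci=new_loci, samples=list(catalog.samples))


def export_catalog(catalog: Catalog, path) -> None:
    """TSV export: one row per (locus, sample, allele) plus consensus rows."""
    with open(path, "w") as fh:
        fh.write("locus_id\tsample_id\tallele_idx\tsequence\n")
        for loc in catalog.loci:
            fh.write(f"{loc.id}\tconsensus\t0\t{loc.consensus}\n")
            for sample in sorted(loc.alleles):
                for ai, seq in enumerate(loc.alleles[sample]):
                    fh.write(f"{loc.id}\t{sample}\t{ai}\t{seq}\n")


def import_catalog(path) -> Catalog:
    """Read a catalog TSV (the export format, or a Stacks-style table)."""
    loci: dict[int, CatalogLocus] = {}
    samples = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["locus_id", "sample_id", "allele_idx", "sequence"]:
            raise ValueError(f"unrecognized catalog header: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"malformed catalog row at line {lineno}")
            lid_s, sample, _ai, seq = parts
            try:
                lid = int(lid_s)
            except ValueError as exc:
                raise ValueError(f"bad locus id at line {lineno}") from exc
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"bad sequence at line {lineno}")
            loc = loci.setdefault(lid, CatalogLocus(id=lid, consensus="", alleles={}))
            if sample == "consensus":
                loc.consensus = seq
            else:
                samples.add(sample)
                loc.alleles[sample] = tuple(
                    sorted(set(loc.alleles.get(sample, ())) | {seq})
                )
    ordered = [loci[k] for k in sorted(loci)]
    for loc in ordered:
        if not loc.consensus:
            loc.consensus = _consensus(
                [a for al in loc.alleles.values() for a in al]
            )
    return Catalog(loci=ordered, samples=sorted(samples))
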