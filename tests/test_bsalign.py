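"""Reduced-alphabet alignment: reductions, placements, strand classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsrad.bsalign import align_reads, reduce_alphabet, scan_windows, strand_filter
from bsrad.ioutils import FastqRead
from bsrad.radloci import Catalog, CatalogLocus
from bsrad.refbuild import build_pseudo_references
from bsrad.simdata import ctob_sequence

dna = st.text(alphabet="ACGTN", min_size=0, max_size=50)


class TestReduceAlphabet:
    def test_ct(self):
        assert reduce_alphabet("ACGT", "C->T") == "ATGT"

    def test_ga(self):
        assert reduce_alphabet("ACGT", "G->A") == "ACAT"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq=dna)
    def test_idempotent(self, seq):
        for mode in ("C->T", "G->A"):
            once = reduce_alphabet(seq, mode)
            assert reduce_alphabet(once, mode) == once

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            reduce_alphabet("ACGT", "A->G")


def _toy_refs(n_loci=6, L=40, seed=0, sample="s1"):
    rng = np.random.default_rng(seed)
    seqs = [
        "TGCAGG" + "".join("ACGT"[b] for b in rng.integers(0, 4, size=L - 6))
        for _ in range(n_loci)
    ]
    cat = Catalog(
        loci=[
            CatalogLocus(id=i, consensus=s, alleles={sample: (s,)})
            for i, s in enumerate(sorted(seqs))
        ],
        samples=[sample],
    )
    refs = build_pseudo_references(cat, sample, np.random.default_rng(1))
    return cat, refs


class TestAlignment:
    def test_simulated_ctob_read_maps_exactly(self):
        cat, refs = _toy_refs()
        allele = cat.loci[2].consensus
        read = FastqRead("r1", ctob_sequence(allele, {}), "I" * len(allele))
        alns = align_reads([read], refs, max_mm=1)
        mapped = [a for a in alns if a.mapped]
        assert len(mapped) == 2  # homozygous: both copies
        for a in mapped:
            assert (a.locus_id, a.strand_class, a.mismatches) == (2, "CTOB", 0)

    def test_snp_costs_one_mismatch(self):
        cat, refs = _toy_refs()
        allele = list(cat.loci[3].consensus)
        # a non-bisulfite-explainable substitution: T -> C in the read frame
        i = allele.index("T", 10)
        read_seq = list(ctob_sequence("".join(allele), {}))
        read_seq[i] = "C"
        read = FastqRead("r1", "".join(read_seq), "I" * len(read_seq))
        (a, *_), = [
            [x for x in align_reads([read], refs, max_mm=1) if x.copy == "A"]
        ]
        assert a.mapped and a.mismatches == 1 and a.locus_id == 3

    def test_converted_top_strand_read_classified_ot(self):
        cat, refs = _toy_refs()
        allele = cat.loci[1].consensus
        seq = allele.replace("C", "T")  # fully converted top strand
        read = FastqRead("r1", seq, "I" * len(seq))
        mapped = [a for a in align_reads([read], refs, max_mm=1) if a.mapped]
        assert mapped and all(a.strand_class == "OT" for a in mapped)

    def test_short_read_unmapped(self):
        _, refs = _toy_refs()
        read = FastqRead("r1", "TGCAGGAC", "I" * 8)
        assert not any(a.mapped for a in align_reads([read], refs))

    def test_excess_mismatches_unmapped(self):
        cat, refs = _toy_refs()
        seq = list(ctob_sequence(cat.loci[0].consensus, {}))
        for i in (10, 14, 18):  # three read-frame T -> C changes
            seq[i] = "C" if seq[i] != "C" else "T"
        read = FastqRead("r1", "".join(seq), "I" * len(seq))
        assert not any(a.mapped for a in align_reads([read], refs, max_mm=1))

    def test_agreement_with_bruteforce_oracle(self):
        cat, refs = _toy_refs(n_loci=8, seed=3)
        rng = np.random.default_rng(4)
        L = len(cat.loci[0].consensus)
        reads = []
        for i in range(400):
            kind = rng.integers(3)
            if kind == 0:  # CTOB read with random methylation and noise
                allele = cat.loci[rng.integers(len(cat.loci))].consensus
                meth = {
                    j: bool(rng.random() < 0.5)
                    for j, b in enumerate(allele)
                    if b == "G"
                }
                seq = list(ctob_sequence(allele, meth))
            elif kind == 1:  # converted top read
                allele = cat.loci[rng.integers(len(cat.loci))].consensus
                seq = [
                    ("T" if rng.random() < 0.99 else "C") if b == "C" else b
                    for b in allele
                ]
            else:  # random junk
                seq = ["ACGT"[b] for b in rng.integers(0, 4, size=L)]
            for _ in range(rng.integers(0, 3)):  # sprinkle errors
                j = int(rng.integers(L))
                seq[j] = "ACGT"[(("ACGT".index(seq[j])) + 1) % 4]
            reads.append(FastqRead(f"r{i}", "".join(seq), "I" * L))

        got = align_reads(reads, refs, max_mm=1)

        # independent oracle: exhaustive reduced-alphabet Hamming scan
        for copy_ref in refs:
            for i, read in enumerate(reads):
                hits = []
                for lid in copy_ref.locus_ids:
                    ref_seq = copy_ref.locus_seqs[lid]
                    mm_ga = sum(
                        a != b
                        for a, b in zip(
                            read.seq.translate(str.maketrans("G", "A")),
                            ref_seq.translate(str.maketrans("G", "A")),
                        )
                    )
                    mm_ct = sum(
                        a != b
                        for a, b in zip(
                            read.seq.translate(str.maketrans("C", "T")),
                            ref_seq.translate(str.maketrans("C", "T")),
                        )
                    )
                    hits.append((mm_ga, lid, "CTOB"))
                    hits.append((mm_ct, lid, "OT"))
                hits.sort(key=lambda t: t[0])
                best = hits[0][0]
                uniq = sum(1 for h in hits if h[0] == best) == 1
                expect_mapped = best <= 1 and uniq
                aln = next(
                    a
                    for a in got
                    if a.read_index == i and a.copy == copy_ref.copy
                )
                assert aln.mapped == expect_mapped, (read.id, copy_ref.copy)
                if expect_mapped:
                    assert (aln.locus_id, aln.strand_class, aln.mismatches) == (
                        hits[0][1],
                        hits[0][2],
                        best,
                    )


class TestStrandFilter:
    def test_all_ctob_unchanged(self):
        cat, refs = _toy_refs()
        allele = cat.loci[0].consensus
        reads = [
            FastqRead(f"r{i}", ctob_sequence(allele, {}), "I" * len(allele))
            for i in range(5)
        ]
        alns = [a for a in align_reads(reads, refs) if a.mapped]
        assert strand_filter(alns) == alns

    def test_pure_ot_reads_removed(self):
        cat, refs = _toy_refs()
        seq = cat.loci[0].consensus.replace("C", "T")
        reads = [FastqRead(f"r{i}", seq, "I" * len(seq)) for i in range(5)]
        alns = [a for a in align_reads(reads, refs) if a.mapped]
        assert alns and strand_filter(alns) == []

    def test_partition_conserves_counts(self):
        cat, refs = _toy_refs()
        ctob = ctob_sequence(cat.loci[0].consensus, {})
        ot = cat.loci[1].consensus.replace("C", "T")
        reads = [
            FastqRead(f"r{i}", s, "I" * len(s))
            for i, s in enumerate([ctob, ot, ctob, ot])
        ]
        mapped = [a for a in align_reads(reads, refs) if a.mapped]
        kept = strand_filter(mapped)
        dropped = [a for a in mapped if a not in kept]
        assert len(kept) + len(dropped) == len(mapped)
        assert {a.strand_class for a in kept} == {"CTOB"}
        assert {a.strand_class for a in dropped} == {"OT"}

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            strand_filter([], keep=("XX",))


class TestScanWindows:
    def test_finds_embedded_locus(self):
        rng = np.random.default_rng(9)
        core = "TGCAGG" + "".join("ACGT"[b] for b in rng.integers(0, 4, size=30))
        flank = "".join("ACGT"[b] for b in rng.integers(0, 4, size=25))
        genome = flank + core + flank[::-1]
        read = ctob_sequence(core, {})
        hit = scan_windows(read, genome, max_mm=1)
        assert hit is not None
        start, cls, mm = hit
        assert (start, cls, mm) == (len(flank), "CTOB", 0)
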