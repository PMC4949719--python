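"""Simulation of bisulfite-converted RAD experiments with full ground truth.

The generator emulates a directional bsRAD library: genomic DNA is cut with a
rare-cutting enzyme (SbfI by default, CCTGCA/GG), a barcoded P1 adapter is
ligated onto the 4-base overhang, the library is bisulfite treated and the
complement of the converted bottom ('−') strand is sequenced.  Each read is
therefore ``barcode + CTOB(locus)`` where the CTOB transform leaves every base
of the top strand untouched except G positions: the base read there reports
the methylation state of the cytosine on the '−' strand (G = methylated,
A = converted, i.e. unmethylated).  A small configurable fraction of reads is
emitted as converted *top* strand instead, mimicking the ~0.1–1% of original-
strand molecules observed in real libraries.

Ground truth (genotypes per allele copy, per-individual methylation levels,
planted group differences and planted SNPs) is recorded in a
:class:`TruthTable` so downstream calls can be scored exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ioutils import FastqRead, Sample
from .util import decode_seq, encode_seq, stage_rng

CONTEXTS = ("CpG", "CHG", "CHH")

#: population Beta priors for the per-position methylation level, one pair of
#: shape parameters per context.  Means follow the levels reported for alpine
#: Heliosperma-like plants (CpG 74%, CHG 1.8%, CHH 1.1%); the small CpG shape
#: parameters give the bimodal (mostly-on / mostly-off) profile typical of
#: plant CpG methylation.  A prior of (0, b) is read as "exactly zero", which
#: is how an animal-like CHH-free genome is simulated.
DEFAULT_METH_PRIOR: dict[str, tuple[float, float]] = {
    "CpG": (0.37, 0.13),
    "CHG": (0.036, 1.964),
    "CHH": (0.022, 1.978),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated bsRAD experiment.

    All probabilities are in [0, 1]; all randomness derives from ``seed``.
    """

    seed: int = 0
    n_loci: int = 50
    locus_len: int = 94
    ploidy: int = 2
    n_samples_per_group: int = 9
    group_names: tuple[str, str] = ("group1", "group2")
    snp_rate: float = 0.001
    meth_prior: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METH_PRIOR)
    )
    sample_concentration: float = 10.0
    n_diff_positions: int = 0
    diff_delta: float = 0.8
    diff_context: str = "CpG"
    n_ct_snps: int = 0
    n_context_snps: int = 0
    snp_carrier_fraction: float = 1 / 3
    conversion_rate: float = 0.99
    seq_error_rate: float = 0.001
    mean_coverage: float = 50.0
    rad_mean_coverage: float = 100.0
    ot_read_fraction: float = 0.005
    barcode_len: int = 6
    enzyme_motif: str = "CCTGCAGG"
    cut_offset: int = 6

    def __post_init__(self):
        for name in (
            "snp_rate",
            "conversion_rate",
            "seq_error_rate",
            "ot_read_fraction",
            "snp_carrier_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.diff_delta <= 1.0:
            raise ValueError("diff_delta must be in [0, 1]")
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.locus_len < 10 or self.locus_len < len(self.remnant):
            raise ValueError(
                "locus too short to host the restriction-site remnant"
            )
        if not 0 < self.cut_offset <= len(self.enzyme_motif):
            raise ValueError("cut_offset outside enzyme motif")
        if self.overhang_len < 0:
            raise ValueError("cut geometry implies a negative overhang")
        if self.diff_context not in CONTEXTS:
            raise ValueError(f"diff_context must be one of {CONTEXTS}")
        for ctx in CONTEXTS:
            if ctx not in self.meth_prior:
                raise ValueError(f"meth_prior missing context {ctx}")

    @property
    def remnant(self) -> str:
        """Top-strand sequence every locus starts with after the cut."""
        return self.enzyme_motif[len(self.enzyme_motif) - self.cut_offset :]

    @property
    def overhang_len(self) -> int:
        """Length of the sticky-end overhang the P1 adapter replaces.

        The bottom strand under the first ``overhang_len`` bases of a read is
        adapter-derived; its single cytosine is left unmethylated, which is
        what makes the TACAAA prefix diagnostic of complete conversion.
        """
        return 2 * self.cut_offset - len(self.enzyme_motif)

    @property
    def n_samples(self) -> int:
        return 2 * self.n_samples_per_group

    @property
    def read_len(self) -> int:
        return self.barcode_len + self.locus_len


@dataclass
class TruthTable:
    """Ground truth for one simulated experiment.

    positions
        One row per '−'-strand cytosine site (a top-strand G in at least one
        allele copy of at least one sample): locus, offset, strand, context
        (from the ancestral sequence where possible), population level
        ``theta``, per-group true means, differential flag and planted-SNP
        class (none / ct / context).
    meth
        Per-sample true methylation probability, aligned with ``positions``;
        NaN where the sample carries no cytosine at that site.
    genotypes
        One row per (locus, sample, copy) allele sequence.
    """

    positions: pd.DataFrame
    meth: pd.DataFrame
    genotypes: pd.DataFrame

    def genotype_map(self) -> dict[tuple[int, str], list[str]]:
        """(locus, sample) -> list of allele-copy sequences."""
        out: dict[tuple[int, str], list[str]] = {}
        for row in self.genotypes.itertuples():
            out.setdefault((row.locus, row.sample), []).append(row.sequence)
        return out


POSITION_COLUMNS = [
    "locus",
    "offset",
    "strand",
    "context",
    "theta",
    "group1_mean",
    "group2_mean",
    "is_diff",
    "snp_class",
]


def _minus_context(seq: str, offset: int) -> str:
    """Context of the '−'-strand cytosine paired with the G at ``offset``."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if offset < 2:
        return "unknown"
    b1 = comp.get(seq[offset - 1], "N")
    b2 = comp.get(seq[offset - 2], "N")
    if "N" in (b1, b2):
        return "unknown"
    if b1 == "G":
        return "CpG"
    if b2 == "G":
        return "CHG"
    return "CHH"


def generate_barcodes(n: int, length: int, rng, min_dist: int = 3) -> list[str]:
    """Draw ``n`` barcodes with pairwise Hamming distance >= ``min_dist``."""
    bases = "ACGT"
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 100_000:
            raise ValueError("cannot place barcodes at the requested distance")
        cand = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if all(sum(a != b for a, b in zip(cand, c)) >= min_dist for c in chosen):
            chosen.append(cand)
    return chosen


def bisulfite_convert(seq: str, meth_mask, rate: float, rng) -> str:
    """Bisulfite-convert a (top-strand view of a) sequence.

    ``meth_mask`` holds one boolean per C in ``seq`` (in order).  Methylated
    cytosines are always retained; unmethylated ones read as T with
    probability ``rate``.  Non-C bases are untouched.
    """
    meth_mask = list(meth_mask)
    n_c = seq.count("C")
    if len(meth_mask) != n_c:
        raise ValueError(
            f"meth_mask has {len(meth_mask)} entries for {n_c} cytosines"
        )
    out = []
    it = iter(meth_mask)
    for base in seq:
        if base == "C":
            if next(it):
                out.append("C")
            else:
                out.append("T" if rng.random() < rate else "C")
        else:
            out.append(base)
    return "".join(out)


def ctob_sequence(allele: str, meth_by_offset: dict[int, bool]) -> str:
    """Complement-of-converted-bottom-strand read for an allele (error-free).

    ``meth_by_offset`` maps top-strand G offsets to the (post-conversion)
    state of the paired '−'-strand cytosine: True reads as G, False as A.
    Offsets absent from the map default to unmethylated.
    """
    out = []
    for i, base in enumerate(allele):
        if base == "G":
            out.append("G" if meth_by_offset.get(i, False) else "A")
        else:
            out.append(base)
    return "".join(out)


def make_read(
    allele: str,
    p_by_offset: dict[int, float],
    config: SimConfig,
    rng,
    barcode: str = "",
    read_id: str = "simread",
) -> FastqRead:
    """Draw one CTOB read from an allele.

    Methylation is Bernoulli(p) per '−'-strand cytosine; unmethylated
    cytosines escape conversion (and read as G) with probability
    ``1 - conversion_rate``; sequencing errors are applied per base.
    Adapter-overhang cytosines (top-strand G at offset < overhang_len) are
    always unmethylated.
    """
    states = {}
    for i, base in enumerate(allele):
        if base != "G":
            continue
        p = 0.0 if i < config.overhang_len else float(p_by_offset.get(i, 0.0))
        meth = rng.random() < p
        escaped = rng.random() >= config.conversion_rate
        states[i] = bool(meth or escaped)
    seq = ctob_sequence(allele, states)
    if config.seq_error_rate > 0:
        bases = "ACGT"
        seq = "".join(
            bases[(bases.index(b) + rng.integers(1, 4)) % 4]
            if rng.random() < config.seq_error_rate
            else b
            for b in seq
        )
    full = barcode + seq
    return FastqRead(read_id, full, "I" * len(full))


def _mutate_copies(ancestral_codes, config, rng):
    """Apply random per-copy substitutions outside the enzyme remnant."""
    L = config.locus_len
    start = len(config.remnant)
    copies = []
    for _ in range(config.ploidy):
        cp = ancestral_codes.copy()
        if config.snp_rate > 0:
            mask = rng.random(L) < config.snp_rate
            mask[:start] = False
            idx = np.nonzero(mask)[0]
            if idx.size:
                cp[idx] = (cp[idx] + rng.integers(1, 4, size=idx.size)) % 4
        copies.append(cp)
    return copies


def simulate_loci(config: SimConfig):
    """Generate ancestral loci, per-sample genotypes and the methylation truth.

    Returns ``(loci, truth)`` where ``loci`` are the ancestral top-strand
    sequences (each starting with the post-cut enzyme remnant) and ``truth``
    is a fully populated :class:`TruthTable`.
    """
    rng = stage_rng(config.seed, 1)
    L = config.locus_len
    remnant = encode_seq(config.remnant)
    rem_len = len(config.remnant)

    samples = [
        f"{g}_{i + 1:02d}"
        for g in config.group_names
        for i in range(config.n_samples_per_group)
    ]
    groups = {
        s: config.group_names[0] if k < config.n_samples_per_group else config.group_names[1]
        for k, s in enumerate(samples)
    }

    loci_codes = []
    for _ in range(config.n_loci):
        codes = rng.integers(0, 4, size=L).astype(np.uint8)
        codes[:rem_len] = remnant
        loci_codes.append(codes)

    # per-sample, per-copy genotypes
    genotypes: dict[tuple[int, str], list[np.ndarray]] = {}
    for li, anc in enumerate(loci_codes):
        for s in samples:
            genotypes[(li, s)] = _mutate_copies(anc, config, rng)

    n_carriers = max(1, round(config.snp_carrier_fraction * config.n_samples))

    def _clean_site(li, i, lo):
        """All copies of all samples match the ancestral bases on [lo, i]."""
        anc = loci_codes[li]
        for s in samples:
            for cp in genotypes[(li, s)]:
                if not np.array_equal(cp[lo : i + 1], anc[lo : i + 1]):
                    return False
        return True

    planted: dict[tuple[int, int], str] = {}  # (locus, offset) -> class

    # planted C->T SNPs on the '−' strand: top-strand G -> A, homozygous in a
    # subset of individuals, one site per locus
    loci_cycle = iter(range(config.n_loci))
    for _ in range(config.n_ct_snps):
        while True:
            try:
                li = next(loci_cycle)
            except StopIteration:
                raise ValueError("not enough loci to host planted C->T SNPs")
            anc = loci_codes[li]
            cand = [
                i
                for i in range(rem_len, L)
                if anc[i] == 2 and (li, i) not in planted and _clean_site(li, i, i)
            ]
            if cand:
                break
        i = int(rng.choice(cand))
        carriers = rng.choice(samples, size=n_carriers, replace=False)
        for s in carriers:
            for cp in genotypes[(li, s)]:
                cp[i] = 0  # A
        planted[(li, i)] = "ct"

    # planted context-changing SNPs: the C one base 3' of the '−'-strand
    # cytosine (top-strand offset i-1) mutates C->A, turning CpG into CHH
    for _ in range(config.n_context_snps):
        while True:
            try:
                li = next(loci_cycle)
            except StopIteration:
                raise ValueError(
                    "not enough loci to host planted context-changing SNPs"
                )
            anc = loci_codes[li]
            cand = [
                i
                for i in range(rem_len + 1, L)
                if anc[i] == 2
                and anc[i - 1] == 1
                and (li, i) not in planted
                and (li, i - 1) not in planted
                and _clean_site(li, i, i - 2)
            ]
            if cand:
                break
        i = int(rng.choice(cand))
        carriers = rng.choice(samples, size=n_carriers, replace=False)
        for s in carriers:
            for cp in genotypes[(li, s)]:
                cp[i - 1] = 0  # C -> A
        planted[(li, i)] = "context"

    loci = [decode_seq(c) for c in loci_codes]

    # position frame: every top-strand G present in any copy of any sample
    rows = []
    for li, anc in enumerate(loci_codes):
        has_g = anc == 2
        for s in samples:
            for cp in genotypes[(li, s)]:
                has_g = has_g | (cp == 2)
        for i in np.nonzero(has_g)[0]:
            i = int(i)
            if anc[i] == 2:
                ctx = _minus_context(loci[li], i)
            else:
                ctx = "unknown"
                for s in samples:
                    for cp in genotypes[(li, s)]:
                        if cp[i] == 2:
                            ctx = _minus_context(decode_seq(cp), i)
                            break
                    if ctx != "unknown":
                        break
            rows.append((li, i, "-", ctx))

    positions = pd.DataFrame(rows, columns=["locus", "offset", "strand", "context"])

    # candidate differential positions: ancestral context matches, site and
    # its context bases are SNP-free in every copy, outside the adapter region
    eligible = []
    for k, row in enumerate(positions.itertuples()):
        if (
            row.context == config.diff_context
            and row.offset >= max(config.overhang_len, 2)
            and loci_codes[row.locus][row.offset] == 2
            and (row.locus, row.offset) not in planted
            and _clean_site(row.locus, row.offset, row.offset - 2)
        ):
            eligible.append(k)
    if config.n_diff_positions > len(eligible):
        raise ValueError(
            f"requested {config.n_diff_positions} differential positions but "
            f"only {len(eligible)} eligible {config.diff_context} sites exist"
        )
    diff_idx = (
        rng.choice(eligible, size=config.n_diff_positions, replace=False)
        if config.n_diff_positions
        else np.empty(0, dtype=int)
    )
    is_diff = np.zeros(len(positions), dtype=bool)
    is_diff[diff_idx] = True

    # population level theta and per-sample probabilities
    theta = np.empty(len(positions))
    for k, row in enumerate(positions.itertuples()):
        ctx = row.context if row.context in CONTEXTS else "CHH"
        a, b = config.meth_prior[ctx]
        theta[k] = 0.0 if a == 0 else float(rng.beta(a, b))
    # adapter-overhang cytosines are never methylated
    theta[positions["offset"].to_numpy() < config.overhang_len] = 0.0

    g1_mean = theta.copy()
    g2_mean = theta.copy()
    meth = np.empty((len(positions), len(samples)))
    kappa = config.sample_concentration
    for k in range(len(positions)):
        if is_diff[k]:
            u = float(rng.uniform(0.0, 1.0 - config.diff_delta))
            hi, lo = u + config.diff_delta, u
            if rng.random() < 0.5:
                hi, lo = lo, hi
            g1_mean[k], g2_mean[k] = hi, lo
            meth[k, : config.n_samples_per_group] = hi
            meth[k, config.n_samples_per_group :] = lo
        else:
            t = theta[k]
            if 0.0 < t < 1.0 and kappa > 0:
                meth[k] = rng.beta(t * kappa, (1.0 - t) * kappa, size=len(samples))
            else:
                meth[k] = t

    # mask samples without a cytosine at the site
    for k, row in enumerate(positions.itertuples()):
        for j, s in enumerate(samples):
            if not any(cp[row.offset] == 2 for cp in genotypes[(row.locus, s)]):
                meth[k, j] = np.nan

    positions["theta"] = theta
    positions["group1_mean"] = g1_mean
    positions["group2_mean"] = g2_mean
    positions["is_diff"] = is_diff
    positions["snp_class"] = [
        planted.get((r.locus, r.offset), "none") for r in positions.itertuples()
    ]

    meth_df = pd.DataFrame(meth, columns=samples)

    # tetraploid bookkeeping: mark the two copies the catalog is meant to keep
    gt_rows = []
    for (li, s), copies in genotypes.items():
        retained = set(range(len(copies)))
        if config.ploidy == 4:
            retained = set(rng.choice(len(copies), size=2, replace=False).tolist())
        for ci, cp in enumerate(copies):
            gt_rows.append((li, s, ci, groups[s], decode_seq(cp), ci in retained))
    genotypes_df = pd.DataFrame(
        gt_rows, columns=["locus", "sample", "copy", "group", "sequence", "retained"]
    )

    truth = TruthTable(positions=positions, meth=meth_df, genotypes=genotypes_df)
    return loci, truth


@dataclass
class Experiment:
    """A fully simulated experiment: reads plus ground truth."""

    config: SimConfig
    samples: list[Sample]
    loci: list[str]
    truth: TruthTable
    bs_reads: list[FastqRead]
    rad_reads: list[FastqRead]

    @property
    def groups(self) -> dict[str, str]:
        return {s.name: s.group for s in self.samples}


def _batch_ctob_reads(codes, n, p_by_gpos, gpos, config, rng):
    """Vectorized CTOB reads for one allele copy: (n, L) code matrix."""
    L = codes.size
    arr = np.broadcast_to(codes, (n, L)).copy()
    if gpos.size:
        meth = rng.random((n, gpos.size)) < p_by_gpos[None, :]
        escape = rng.random((n, gpos.size)) >= config.conversion_rate
        show_g = meth | escape
        arr[:, gpos] = np.where(show_g, 2, 0).astype(np.uint8)
    if config.seq_error_rate > 0:
        err = rng.random((n, L)) < config.seq_error_rate
        k = err.sum()
        if k:
            arr[err] = (arr[err] + rng.integers(1, 4, size=k)) % 4
    return arr


def _batch_top_reads(codes, n, config, rng):
    """Vectorized converted-top-strand reads (all cytosines unmethylated)."""
    L = codes.size
    arr = np.broadcast_to(codes, (n, L)).copy()
    cpos = np.nonzero(codes == 1)[0]
    if cpos.size:
        escape = rng.random((n, cpos.size)) >= config.conversion_rate
        arr[:, cpos] = np.where(escape, 1, 3).astype(np.uint8)
    if config.seq_error_rate > 0:
        err = rng.random((n, L)) < config.seq_error_rate
        k = err.sum()
        if k:
            arr[err] = (arr[err] + rng.integers(1, 4, size=k)) % 4
    return arr


def simulate_experiment(config: SimConfig, read_stage: int = 2) -> Experiment:
    """Simulate loci, truth, and both read sets (bisulfite and standard RAD).

    ``read_stage`` selects the read-noise stream: re-running with a
    different value redraws reads (a technical replicate) over the *same*
    genotypes and methylation truth.
    """
    loci, truth = simulate_loci(config)
    rng = stage_rng(config.seed, read_stage)

    sample_names = list(truth.meth.columns)
    barcodes = generate_barcodes(len(sample_names), config.barcode_len, rng)
    group_of = dict(
        truth.genotypes[["sample", "group"]].drop_duplicates().itertuples(index=False)
    )
    samples = [
        Sample(name, group_of[name], bc) for name, bc in zip(sample_names, barcodes)
    ]

    # per-locus lookup: offset -> row index in the truth frames
    pos_by_locus: dict[int, dict[int, int]] = {}
    for k, row in enumerate(truth.positions.itertuples()):
        pos_by_locus.setdefault(row.locus, {})[row.offset] = k
    meth_mat = truth.meth.to_numpy()
    sample_col = {s: j for j, s in enumerate(sample_names)}

    gt_codes: dict[tuple[int, str], list[np.ndarray]] = {}
    for row in truth.genotypes.itertuples():
        gt_codes.setdefault((row.locus, row.sample), []).append(
            encode_seq(row.sequence)
        )

    bs_reads: list[FastqRead] = []
    rad_reads: list[FastqRead] = []
    bs_counter = itertools.count()
    rad_counter = itertools.count()
    qual = "I" * config.read_len

    for sm in samples:
        j = sample_col[sm.name]
        for li in range(config.n_loci):
            copies = gt_codes[(li, sm.name)]
            offmap = pos_by_locus.get(li, {})

            # bisulfite-converted reads
            n_total = int(rng.poisson(config.mean_coverage))
            if n_total:
                copy_of = rng.integers(0, len(copies), size=n_total)
                is_top = rng.random(n_total) < config.ot_read_fraction
                for ci, codes in enumerate(copies):
                    n_ctob = int(((copy_of == ci) & ~is_top).sum())
                    n_top = int(((copy_of == ci) & is_top).sum())
                    gpos = np.nonzero(codes == 2)[0]
                    p_vec = np.empty(gpos.size)
                    for gi, off in enumerate(gpos):
                        if off < config.overhang_len:
                            p_vec[gi] = 0.0
                        else:
                            k = offmap.get(int(off))
                            p = meth_mat[k, j] if k is not None else 0.0
                            p_vec[gi] = 0.0 if np.isnan(p) else p
                    if n_ctob:
                        arr = _batch_ctob_reads(
                            codes, n_ctob, p_vec, gpos, config, rng
                        )
                        for row_codes in arr:
                            bs_reads.append(
                                FastqRead(
                                    f"bs_{next(bs_counter):07d}",
                                    sm.barcode + decode_seq(row_codes),
                                    qual,
                                )
                            )
                    if n_top:
                        arr = _batch_top_reads(codes, n_top, config, rng)
                        for row_codes in arr:
                            bs_reads.append(
                                FastqRead(
                                    f"bs_{next(bs_counter):07d}",
                                    sm.barcode + decode_seq(row_codes),
                                    qual,
                                )
                            )

            # standard (unconverted) RAD reads for catalog construction
            n_rad = int(rng.poisson(config.rad_mean_coverage))
            if n_rad:
                copy_of = rng.integers(0, len(copies), size=n_rad)
                for ci, codes in enumerate(copies):
                    n_c = int((copy_of == ci).sum())
                    if not n_c:
                        continue
                    arr = np.broadcast_to(codes, (n_c, codes.size)).copy()
                    if config.seq_error_rate > 0:
                        err = rng.random(arr.shape) < config.seq_error_rate
                        kk = err.sum()
                        if kk:
                            arr[err] = (arr[err] + rng.integers(1, 4, size=kk)) % 4
                    for row_codes in arr:
                        rad_reads.append(
                            FastqRead(
                                f"rad_{next(rad_counter):07d}",
                                sm.barcode + decode_seq(row_codes),
                                qual,
                            )
                        )

    return Experiment(
        config=config,
        samples=samples,
        loci=loci,
        truth=truth,
        bs_reads=bs_reads,
        rad_reads=rad_reads,
    )


def write_truth(truth: TruthTable, outdir) -> None:
    """Write the truth table as two TSV files (lossless round-trip)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wide = pd.concat(
        [truth.positions, truth.meth.add_prefix("p_")], axis=1
    )
    wide.to_csv(outdir / "truth_positions.tsv", sep="\t", index=False)
    truth.genotypes.to_csv(outdir / "truth_genotypes.tsv", sep="\t", index=False)


def read_truth(outdir) -> TruthTable:
    outdir = Path(outdir)
    wide = pd.read_csv(outdir / "truth_positions.tsv", sep="\t")
    pos_cols = [c for c in wide.columns if not c.startswith("p_")]
    if pos_cols != POSITION_COLUMNS:
        raise ValueError("unexpected truth_positions.tsv schema")
    meth = wide[[c for c in wide.columns if c.startswith("p_")]].copy()
    meth.columns = [c[2:] for c in meth.columns]
    genotypes = pd.read_csv(outdir / "truth_genotypes.tsv", sep="\t")
    return TruthTable(positions=wide[pos_cols].copy(), meth=meth, genotypes=genotypes)
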