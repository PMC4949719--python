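"""End-to-end orchestration: demux → loci → refs → align → call → diff.

The in-memory :func:`run_pipeline` is the canonical path; the ``_dir``
variants serialize every stage artifact so individual stages can be re-run
from files via the command-line interface.  All stage randomness derives
from the single run seed, and sample iteration is always in sorted order, so
identical inputs and seed give byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import pandas as pd

from . import bsalign, demux, diffmeth, methcall, radloci, refbuild
from .ioutils import Sample, ensure_dir, read_fastq, read_sample_sheet, write_fastq, write_sample_sheet
from .simdata import Experiment, SimConfig, simulate_experiment, write_truth
from .util import stage_rng


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable threshold of the analysis, with field defaults.

    The defaults follow the published de novo settings: stack depth 20
    (100 was used for the deeper-sequenced diploid experiment), 7 mismatches
    to merge stacks into a locus, 9 to merge loci across individuals, at
    most 10 SNPs and 0.75 heterozygosity per catalog locus, 2 retained
    alleles, 1 alignment mismatch for diploids (3 for tetraploids), the
    first 4 read bases ignored, 25x minimum coverage in >= 2 individuals
    per group, and the 10% mean / 10% SD position prefilter.
    """

    seed: int = 0
    max_bc_mismatch: int = 1
    min_stack_depth: int = 20
    stack_merge_mm: int = 7
    catalog_merge_mm: int = 9
    max_snps: int = 10
    max_het: float = 0.75
    max_locus_stacks: int = 2
    max_alleles: int = 2
    max_mm: int = 1
    min_anchor: int = 20
    trim_head: int = 4
    keep_strands: tuple[str, ...] = ("CTOT", "CTOB")
    context: str | None = None
    min_cov: int = 25
    min_samples_per_group: int = 2
    min_mean: float = 0.10
    min_sd: float = 0.10
    qvalue_lambda: float = 0.5
    alpha: float = 0.05
    apply_variance_prefilter: bool = True

    @classmethod
    def for_ploidy(cls, ploidy: int, **overrides) -> "PipelineParams":
        """Defaults adjusted for ploidy (4 stacks/locus, 3 mismatches at 4x)."""
        if ploidy == 4:
            overrides.setdefault("max_locus_stacks", 4)
            overrides.setdefault("max_mm", 3)
        return cls(**overrides)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline parameters: {sorted(unknown)}")
        if "keep_strands" in d:
            d = dict(d, keep_strands=tuple(d["keep_strands"]))
        return cls(**d)


@dataclass
class PipelineResult:
    params: PipelineParams
    samples: list[Sample]
    demux_bs: demux.DemuxResult
    demux_rad: demux.DemuxResult
    catalog: radloci.Catalog
    refs: dict[str, tuple[refbuild.PseudoReference, refbuild.PseudoReference]]
    alignments: dict[str, list[bsalign.BsAlignment]]
    reports: dict[tuple[str, str], list[methcall.CytosineRecord]]
    matrix: diffmeth.MethylMatrix
    results: pd.DataFrame
    locus_summary: pd.DataFrame


def build_catalog_from_reads(
    rad_by_sample: dict[str, list], params: PipelineParams
) -> radloci.Catalog:
    """Stacks → per-sample loci → filtered catalog with ≤ max_alleles kept."""
    per_sample_loci = {}
    for name in sorted(rad_by_sample):
        stacks = radloci.build_stacks(
            [r.seq for r in rad_by_sample[name]], params.min_stack_depth, name
        )
        per_sample_loci[name] = radloci.merge_stacks_to_loci(
            stacks, params.stack_merge_mm, params.max_locus_stacks
        )
    catalog = radloci.build_catalog(per_sample_loci, params.catalog_merge_mm)
    catalog = radloci.filter_catalog(catalog, params.max_snps, params.max_het)
    return radloci.select_alleles(
        catalog, params.max_alleles, stage_rng(params.seed, 11)
    )


def run_pipeline(
    bs_reads,
    rad_reads,
    samples: list[Sample],
    params: PipelineParams,
    catalog: radloci.Catalog | None = None,
) -> PipelineResult:
    """Run the full reference-free analysis on in-memory reads.

    A pre-built ``catalog`` (e.g. imported from an external table) skips the
    RAD assembly stage.
    """
    bc_map = {s.barcode: s.name for s in samples}
    groups = {s.name: s.group for s in samples}
    group_names = tuple(dict.fromkeys(s.group for s in samples))
    if len(group_names) != 2:
        raise ValueError("the sample sheet must define exactly two groups")

    demux_bs = demux.demultiplex(bs_reads, bc_map, params.max_bc_mismatch)
    demux_rad = demux.demultiplex(rad_reads, bc_map, params.max_bc_mismatch)

    if catalog is None:
        catalog = build_catalog_from_reads(demux_rad.by_sample, params)

    refs = {}
    rng_refs = stage_rng(params.seed, 12)
    for name in sorted(groups):
        refs[name] = refbuild.build_pseudo_references(catalog, name, rng_refs)

    alignments: dict[str, list] = {}
    reports: dict[tuple[str, str], list] = {}
    for name in sorted(groups):
        reads = demux_bs.by_sample[name]
        alns = bsalign.align_reads(
            reads, refs[name], max_mm=params.max_mm, min_anchor=params.min_anchor
        )
        alignments[name] = alns
        kept = bsalign.strand_filter(alns, params.keep_strands)
        for ref in refs[name]:
            reports[(name, ref.copy)] = methcall.call_methylation(
                reads, kept, ref, params.trim_head
            )

    matrix = diffmeth.merge_reports(reports, groups, group_names)
    results = diffmeth.run_differential(
        matrix,
        context=params.context,
        min_cov=params.min_cov,
        min_samples_per_group=params.min_samples_per_group,
        apply_variance_prefilter=params.apply_variance_prefilter,
        min_mean=params.min_mean,
        min_sd=params.min_sd,
        qvalue_lambda=params.qvalue_lambda,
    )
    locus_summary = diffmeth.aggregate_by_locus(results, params.alpha)
    return PipelineResult(
        params=params,
        samples=samples,
        demux_bs=demux_bs,
        demux_rad=demux_rad,
        catalog=catalog,
        refs=refs,
        alignments=alignments,
        reports=reports,
        matrix=matrix,
        results=results,
        locus_summary=locus_summary,
    )


def simulate_to_dir(config: SimConfig, outdir) -> Experiment:
    """Simulate an experiment and write FASTQ, sample sheet and truth files."""
    outdir = ensure_dir(outdir)
    exp = simulate_experiment(config)
    write_fastq(exp.bs_reads, outdir / "bs_reads.fastq")
    write_fastq(exp.rad_reads, outdir / "rad_reads.fastq")
    write_sample_sheet(exp.samples, outdir / "samples.tsv")
    write_truth(exp.truth, outdir)
    with open(outdir / "sim_config.json", "w") as fh:
        cfg = dataclasses.asdict(config)
        json.dump(cfg, fh, indent=2, default=list)
    return exp


def write_result_dir(result: PipelineResult, outdir) -> None:
    """Serialize every stage artifact of a pipeline run."""
    outdir = ensure_dir(outdir)
    radloci.export_catalog(result.catalog, outdir / "catalog.tsv")
    refdir = ensure_dir(outdir / "refs")
    for name, pair in sorted(result.refs.items()):
        refbuild.write_fasta(pair, refdir / f"{name}.fasta")
        refbuild.write_offsets(pair[0], refdir / f"{name}.offsets.tsv")
    alndir = ensure_dir(outdir / "alignments")
    for name, alns in sorted(result.alignments.items()):
        with open(alndir / f"{name}.tsv", "w") as fh:
            fh.write("read_id\tlocus_id\tcopy\tstrand_class\tmismatches\tmapped\n")
            for a in alns:
                fh.write(
                    f"{a.read_id}\t{a.locus_id}\t{a.copy}\t{a.strand_class}\t"
                    f"{a.mismatches}\t{int(a.mapped)}\n"
                )
    cxdir = ensure_dir(outdir / "cx_reports")
    for (name, copy), records in sorted(result.reports.items()):
        methcall.write_cx_report(records, cxdir / f"{name}.copy{copy}.CX_report.tsv")
    result.results.to_csv(outdir / "results.tsv", sep="\t", index=False)
    result.locus_summary.to_csv(outdir / "locus_summary.tsv", sep="\t")
    manifest = {
        "params": dataclasses.asdict(result.params),
        "n_samples": len(result.samples),
        "n_catalog_loci": len(result.catalog),
        "read_counts": {
            "bs": result.demux_bs.counts,
            "rad": result.demux_rad.counts,
        },
        "n_positions_tested": int(len(result.results)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)


def run_dir(
    bs_fastq,
    rad_fastq,
    sample_sheet,
    params: PipelineParams,
    outdir,
    catalog_tsv=None,
) -> PipelineResult:
    """File-based end-to-end run (the CLI's ``run`` subcommand)."""
    samples = read_sample_sheet(sample_sheet)
    bs_reads = read_fastq(bs_fastq)
    rad_reads = read_fastq(rad_fastq) if rad_fastq else []
    catalog = radloci.import_catalog(catalog_tsv) if catalog_tsv else None
    if catalog is None and not rad_reads:
        raise ValueError("need either unconverted RAD reads or a catalog TSV")
    result = run_pipeline(bs_reads, rad_reads, samples, params, catalog=catalog)
    write_result_dir(result, outdir)
    return result
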