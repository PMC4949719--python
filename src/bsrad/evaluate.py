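"""Scoring pipeline output against simulation ground truth.

These helpers connect a catalog/matrix/result produced by the pipeline back
to the :class:`~bsrad.simdata.TruthTable` of the simulation that generated
the reads: catalog loci are re-identified by exact allele-sequence match, so
positions can be compared offset-by-offset.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .diffmeth import FLAG_SMP, FLAG_SNP, FLAG_SWAP, MethylMatrix
from .radloci import Catalog
from .simdata import TruthTable


def map_catalog_to_truth(catalog: Catalog, truth: TruthTable) -> dict[int, int]:
    """catalog locus id -> simulated locus index, by allele-sequence vote."""
    seq_to_locus: dict[str, int] = {}
    for row in truth.genotypes.itertuples():
        seq_to_locus.setdefault(row.sequence, row.locus)
    mapping = {}
    for loc in catalog.loci:
        votes = Counter(
            seq_to_locus[a]
            for al in loc.alleles.values()
            for a in al
            if a in seq_to_locus
        )
        if votes:
            mapping[loc.id] = votes.most_common(1)[0][0]
    return mapping


def catalog_recovery(catalog: Catalog, truth: TruthTable) -> float:
    """Fraction of simulated loci recovered with exact per-sample allele sets.

    A locus counts as recovered when one catalog locus maps to it and, for
    every sample, the catalog's retained alleles equal the true (retained)
    allele-copy sequences as a set.
    """
    mapping = map_catalog_to_truth(catalog, truth)
    inverse: dict[int, list] = {}
    for loc in catalog.loci:
        if loc.id in mapping:
            inverse.setdefault(mapping[loc.id], []).append(loc)

    gt = truth.genotypes[truth.genotypes["retained"]]
    true_alleles: dict[tuple[int, str], set] = {}
    for row in gt.itertuples():
        true_alleles.setdefault((row.locus, row.sample), set()).add(row.sequence)

    samples = sorted(gt["sample"].unique())
    n_loci = int(truth.genotypes["locus"].max()) + 1
    recovered = 0
    for li in range(n_loci):
        cands = inverse.get(li, [])
        if len(cands) != 1:
            continue
        loc = cands[0]
        if all(
            set(loc.alleles.get(s, ())) == true_alleles.get((li, s), set())
            for s in samples
        ):
            recovered += 1
    return recovered / n_loci


def _truth_row_lookup(truth: TruthTable) -> dict[tuple[int, int], int]:
    return {
        (row.locus, row.offset): k
        for k, row in enumerate(truth.positions.itertuples())
    }


def level_accuracy(
    matrix: MethylMatrix,
    truth: TruthTable,
    locus_map: dict[int, int],
    min_cov: int = 25,
) -> dict:
    """Per-(position, sample, copy) agreement of estimated levels with truth.

    Levels are compared per report column (sample x reference copy), whose
    coverage is a true read count; the pooled per-sample level is not used
    here because reads from homozygous loci legitimately appear in both
    copies, which would double-count them.  Returns rmse, the theoretical
    bound sqrt(mean p(1-p)/cov) + 0.01 (binomial sampling noise plus the
    incomplete-conversion allowance), mean bias and the number of
    comparisons.
    """
    lookup = _truth_row_lookup(truth)
    meth_truth = truth.meth.to_numpy()
    cols = {s: j for j, s in enumerate(truth.meth.columns)}

    cov = matrix.coverage
    lev = matrix.level
    errs, variances = [], []
    for idx, cov_row, lev_row in zip(cov.index, cov.to_numpy(), lev.to_numpy()):
        locus, offset, _ = idx
        tli = locus_map.get(locus)
        if tli is None:
            continue
        k = lookup.get((tli, offset))
        if k is None:
            continue
        for j, (s, _copy) in enumerate(cov.columns):
            c = cov_row[j]
            if not np.isfinite(c) or c < min_cov:
                continue
            p = meth_truth[k, cols[s]]
            if np.isnan(p) or np.isnan(lev_row[j]):
                continue
            errs.append(lev_row[j] - p)
            variances.append(p * (1.0 - p) / c)
    errs = np.asarray(errs)
    if errs.size == 0:
        return {"rmse": np.nan, "bound": np.nan, "bias": np.nan, "n": 0}
    return {
        "rmse": float(np.sqrt(np.mean(errs**2))),
        "bound": float(np.sqrt(np.mean(variances)) + 0.01),
        "bias": float(errs.mean()),
        "n": int(errs.size),
    }


def _diff_positions(truth: TruthTable) -> set[tuple[int, int]]:
    pos = truth.positions
    return {
        (row.locus, row.offset) for row in pos[pos["is_diff"]].itertuples()
    }


def detection_metrics(
    results: pd.DataFrame,
    truth: TruthTable,
    locus_map: dict[int, int],
    q_thresh: float = 0.05,
) -> dict:
    """Sensitivity and realized false-discovery proportion at a q cutoff.

    Sensitivity counts *all* planted differential positions in the
    denominator, so a planted position lost to filtering scores as a miss.
    """
    diff = _diff_positions(truth)
    n_planted = len(diff)
    is_diff = np.array(
        [
            (locus_map.get(r.locus), r.offset) in diff
            for r in results.itertuples()
        ]
    )
    sig = results["q"].to_numpy() < q_thresh
    n_hit = int((sig & is_diff).sum())
    n_disc = int(sig.sum())
    return {
        "sensitivity": n_hit / n_planted if n_planted else np.nan,
        "fdp": (n_disc - n_hit) / n_disc if n_disc else 0.0,
        "n_planted": n_planted,
        "n_discoveries": n_disc,
        "n_tested": int(len(results)),
    }


def type1_rate(
    results: pd.DataFrame,
    truth: TruthTable,
    locus_map: dict[int, int],
    alpha: float = 0.05,
) -> dict:
    """Fraction of null (non-planted) tested positions with p < alpha."""
    diff = _diff_positions(truth)
    null_p = np.array(
        [
            r.p
            for r in results.itertuples()
            if (locus_map.get(r.locus), r.offset) not in diff
        ]
    )
    return {
        "rate": float((null_p < alpha).mean()) if null_p.size else np.nan,
        "n_null": int(null_p.size),
    }


def classification_metrics(
    flags: pd.Series, truth: TruthTable, locus_map: dict[int, int]
) -> dict:
    """How planted SNPs were classified.

    Planted C→T SNPs must never surface as SMP candidates (they should be
    missing-by-genotype); planted context-changing SNPs must all be flagged
    as context swaps.
    """
    inv = {v: k for k, v in locus_map.items()}
    pos = truth.positions

    def flag_of(row):
        cat_locus = inv.get(row.locus)
        if cat_locus is None:
            return None
        key = (cat_locus, row.offset, "-")
        return flags.get(key)

    ct_rows = [flag_of(r) for r in pos[pos["snp_class"] == "ct"].itertuples()]
    ctx_rows = [
        flag_of(r) for r in pos[pos["snp_class"] == "context"].itertuples()
    ]
    ct_found = [f for f in ct_rows if f is not None]
    ctx_found = [f for f in ctx_rows if f is not None]
    return {
        "n_ct_planted": len(ct_rows),
        "n_ct_rows": len(ct_found),
        "ct_smp_candidates": sum(f == FLAG_SMP for f in ct_found),
        "ct_snp_missing": sum(f == FLAG_SNP for f in ct_found),
        "n_context_planted": len(ctx_rows),
        "n_context_rows": len(ctx_found),
        "context_swap_flagged": sum(f == FLAG_SWAP for f in ctx_found),
    }
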