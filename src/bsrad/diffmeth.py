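"""Position x sample methylation databases, SNP masking and group tests.

Per-sample CX reports are merged into three aligned tables (coverage, level,
context) with one column per sample x reference-copy, rows indexed by the
shared (locus, offset, strand) frame.  A position missing from a column
because that individual's reference carries no cytosine there (a genetic
variant) is distinguishable from a merely uncovered position: the former has
no context either.  Rows are then classified (SMP candidate / SNP-missing /
context swap), filtered on coverage and context, pre-filtered on mean and SD
of the methylation level, and group differences are assessed with a
two-sample Kolmogorov–Smirnov test followed by Storey q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FLAG_SMP = "SMP-candidate"
FLAG_SNP = "SNP-missing"
FLAG_SWAP = "context-swap"


@dataclass
class MethylMatrix:
    coverage: pd.DataFrame  # rows (locus, offset, strand), cols (sample, copy)
    meth: pd.DataFrame
    context: pd.DataFrame
    groups: dict[str, str]  # sample -> group label
    group_names: tuple[str, str]

    @property
    def level(self) -> pd.DataFrame:
        cov = self.coverage.where(self.coverage > 0)
        return self.meth / cov

    def sample_coverage(self) -> pd.DataFrame:
        """Per-sample coverage, both reference copies pooled."""
        return self.coverage.T.groupby(level=0).sum(min_count=1).T

    def sample_level(self) -> pd.DataFrame:
        """Coverage-weighted per-sample level, both copies pooled."""
        cov = self.sample_coverage()
        meth = self.meth.T.groupby(level=0).sum(min_count=1).T
        return meth / cov.where(cov > 0)

    def row_context(self) -> pd.Series:
        """One context per row (first non-missing column)."""
        return self.context.bfill(axis=1).iloc[:, 0]


def merge_reports(
    reports: dict[tuple[str, str], list],
    groups: dict[str, str],
    group_names: tuple[str, str] | None = None,
) -> MethylMatrix:
    """Outer-join per-(sample, copy) cytosine records on the position frame.

    ``reports`` maps (sample, copy) to lists of CytosineRecord.  Positions a
    column never reports (no cytosine in that reference copy) become missing
    in all three tables.
    """
    cov_cols, meth_cols, ctx_cols = {}, {}, {}
    for key, records in reports.items():
        idx = pd.MultiIndex.from_tuples(
            [(r.locus_id, r.offset, r.strand) for r in records],
            names=["locus", "offset", "strand"],
        )
        cov_cols[key] = pd.Series([r.coverage for r in records], index=idx, dtype=float)
        meth_cols[key] = pd.Series([r.meth_count for r in records], index=idx, dtype=float)
        ctx_cols[key] = pd.Series([r.context for r in records], index=idx, dtype=object)

    coverage = pd.DataFrame(cov_cols).sort_index()
    meth = pd.DataFrame(meth_cols).sort_index()
    context = pd.DataFrame(ctx_cols).sort_index()
    for df in (coverage, meth, context):
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "copy"])

    if group_names is None:
        seen = list(dict.fromkeys(groups.values()))
        if len(seen) != 2:
            raise ValueError("exactly two groups are required")
        group_names = (seen[0], seen[1])
    return MethylMatrix(coverage, meth, context, dict(groups), tuple(group_names))


def classify_positions(matrix: MethylMatrix) -> pd.Series:
    """Flag every row as SMP candidate, SNP-missing or context swap.

    SNP-missing: at least one sample x copy column carries no cytosine at the
    position (missing by genotype, not by coverage).  Context swap: all
    columns carry a cytosine but their reference contexts disagree.
    """
    missing_any = matrix.context.isna().any(axis=1)
    n_ctx = matrix.context.nunique(axis=1, dropna=True)
    flags = pd.Series(FLAG_SMP, index=matrix.context.index, name="flag")
    flags[n_ctx > 1] = FLAG_SWAP
    flags[missing_any] = FLAG_SNP
    return flags


def classify_position(matrix: MethylMatrix, row) -> str:
    """Classification flag for a single (locus, offset, strand) row."""
    return classify_positions(matrix).loc[row]


def filter_positions(
    matrix: MethylMatrix,
    context: str | None = None,
    min_cov: int = 25,
    min_samples_per_group: int = 2,
    exclude_swaps: bool = True,
    flags: pd.Series | None = None,
) -> pd.Series:
    """Boolean row mask applying the coverage / context / swap filters.

    Keeps rows where, in *each* group, at least ``min_samples_per_group``
    samples have pooled coverage >= ``min_cov``; optionally restricted to one
    context and purged of context-swap rows.
    """
    if flags is None:
        flags = classify_positions(matrix)
    cov = matrix.sample_coverage() >= min_cov
    by_group = cov.T.groupby(
        [matrix.groups[s] for s in cov.columns]
    ).sum().T
    mask = (by_group >= min_samples_per_group).all(axis=1)
    if context is not None:
        mask &= matrix.row_context() == context
    if exclude_swaps:
        mask &= flags != FLAG_SWAP
    return mask


def variance_prefilter(
    levels: pd.DataFrame, min_mean: float = 0.10, min_sd: float = 0.10
) -> pd.Series:
    """Keep rows whose level mean and population SD across samples are >= 10%."""
    mean = levels.mean(axis=1)
    sd = levels.std(axis=1, ddof=0)
    return (mean >= min_mean) & (sd >= min_sd)


def ks_2samp(x, y) -> tuple[float, float]:
    """Two-sample KS test (asymptotic p-value), as used for level comparisons."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def qvalues(pvals, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimator.

    pi0 = min(1, #{p > lam} / ((1 - lam) m)); q(i) is the running tail
    minimum of pi0 * m * p(i) / rank(i), returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = min(1.0, float((p > lam).sum()) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    q_sorted = np.empty(m)
    prev = pi0 * ps[-1]
    q_sorted[-1] = prev
    for i in range(m - 2, -1, -1):
        prev = min(prev, pi0 * m * ps[i] / (i + 1))
        q_sorted[i] = prev
    out = np.empty(m)
    out[order] = q_sorted
    return out


def run_differential(
    matrix: MethylMatrix,
    context: str | None = None,
    min_cov: int = 25,
    min_samples_per_group: int = 2,
    exclude_swaps: bool = True,
    exclude_snps: bool = True,
    apply_variance_prefilter: bool = True,
    min_mean: float = 0.10,
    min_sd: float = 0.10,
    qvalue_lambda: float = 0.5,
    per_copy: bool = False,
) -> pd.DataFrame:
    """Full between-group test over the filtered rows of a methylation matrix.

    Per-sample levels pool the two reference copies by coverage weighting
    (``per_copy=True`` instead treats each copy column as an observation).
    Returns one row per tested position: group means, difference
    (group1 − group2), KS D, p, Storey q and the classification flag.
    """
    flags = classify_positions(matrix)
    mask = filter_positions(
        matrix,
        context=context,
        min_cov=min_cov,
        min_samples_per_group=min_samples_per_group,
        exclude_swaps=exclude_swaps,
        flags=flags,
    )
    if exclude_snps:
        mask &= flags != FLAG_SNP

    if per_copy:
        cov = matrix.coverage
        lev = matrix.level
        col_groups = np.array([matrix.groups[s] for s, _ in cov.columns])
    else:
        cov = matrix.sample_coverage()
        lev = matrix.sample_level()
        col_groups = np.array([matrix.groups[s] for s in cov.columns])

    sel = lev.where(cov >= min_cov)[mask]
    if apply_variance_prefilter:
        keep = variance_prefilter(sel, min_mean=min_mean, min_sd=min_sd)
        sel = sel[keep]

    g1, g2 = matrix.group_names
    row_ctx = matrix.row_context()
    rows = []
    values = sel.to_numpy()
    for idx, row in zip(sel.index, values):
        x = row[(col_groups == g1) & ~np.isnan(row)]
        y = row[(col_groups == g2) & ~np.isnan(row)]
        d_stat, p = ks_2samp(x, y)
        rows.append(
            (
                *idx,
                row_ctx.loc[idx],
                len(x),
                len(y),
                float(x.mean()),
                float(y.mean()),
                float(x.mean() - y.mean()),
                d_stat,
                p,
                flags.loc[idx],
            )
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "locus",
            "offset",
            "strand",
            "context",
            f"n_{g1}",
            f"n_{g2}",
            f"mean_{g1}",
            f"mean_{g2}",
            "difference",
            "D",
            "p",
            "flag",
        ],
    )
    results["q"] = qvalues(results["p"].to_numpy(), lam=qvalue_lambda) if len(results) else []
    return results


def group_difference(levels_by_group: dict[str, np.ndarray], group_names) -> float:
    """Mean(group1) − mean(group2) of per-sample levels; lies in [−1, 1]."""
    g1, g2 = group_names
    return float(np.nanmean(levels_by_group[g1]) - np.nanmean(levels_by_group[g2]))


def reproducibility(
    rep1, rep2, tol: float = 0.10, min_cov: int = 25
) -> tuple[float | None, int]:
    """Fraction of shared positions whose levels agree within ``tol``.

    ``rep1``/``rep2`` are lists of CytosineRecord from two technical
    replicates of the same individual.  Only positions with coverage >=
    ``min_cov`` in both replicates are compared; returns (fraction, n), with
    fraction None when no position qualifies.
    """
    lv1 = {
        (r.locus_id, r.offset, r.strand): r.level
        for r in rep1
        if r.coverage >= min_cov
    }
    shared = [
        (lv1[k], r.level)
        for r in rep2
        if r.coverage >= min_cov and (k := (r.locus_id, r.offset, r.strand)) in lv1
    ]
    if not shared:
        return None, 0
    ok = sum(1 for a, b in shared if abs(a - b) <= tol)
    return ok / len(shared), len(shared)


def aggregate_by_locus(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-locus summary of tested positions and significant hits."""
    if results.empty:
        return pd.DataFrame(
            columns=["locus", "n_positions", "n_p_sig", "n_q_sig", "contexts"]
        ).set_index("locus")
    grouped = results.groupby("locus")
    out = pd.DataFrame(
        {
            "n_positions": grouped.size(),
            "n_p_sig": grouped["p"].apply(lambda s: int((s < alpha).sum())),
            "n_q_sig": grouped["q"].apply(lambda s: int((s < alpha).sum())),
            "contexts": grouped["context"].apply(
                lambda s: ",".join(sorted(set(s)))
            ),
        }
    )
    return out
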