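"""Merging, classification, filtering, KS testing and q-values."""

import numpy as np
import pandas as pd
import pytest

from bsrad.diffmeth import (
    FLAG_SMP,
    FLAG_SNP,
    FLAG_SWAP,
    aggregate_by_locus,
    classify_positions,
    filter_positions,
    group_difference,
    ks_2samp,
    merge_reports,
    qvalues,
    reproducibility,
    run_differential,
    variance_prefilter,
)
from bsrad.methcall import CytosineRecord

GROUPS = {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"}


def _rec(locus, off, ctx, cov, meth):
    return CytosineRecord(locus, off, "-", ctx, cov, meth)


def _matrix(reports):
    return merge_reports(reports, GROUPS, ("g1", "g2"))


def _uniform_reports(cov=30, meth_by_sample=None, ctx="CpG", offs=(5, 9)):
    """Same positions in every sample x copy; meth counts per sample."""
    reports = {}
    for s in GROUPS:
        for copy in "AB":
            reports[(s, copy)] = [
                _rec(0, off, ctx, cov, (meth_by_sample or {}).get(s, 0))
                for off in offs
            ]
    return reports


class TestMergeReports:
    def test_identical_reports_give_identical_columns(self):
        m = _matrix(_uniform_reports())
        assert m.coverage.shape == (2, 8)
        assert (m.coverage == 30).all().all()

    def test_private_position_missing_elsewhere(self):
        reports = _uniform_reports()
        reports[("a1", "A")] = reports[("a1", "A")] + [_rec(1, 3, "CHH", 10, 2)]
        m = _matrix(reports)
        row = m.coverage.loc[(1, 3, "-")]
        assert row[("a1", "A")] == 10
        assert row.drop(("a1", "A")).isna().all()

    def test_hand_computed_fixture(self):
        # 3 columns x 2 positions with known levels
        reports = {
            ("a1", "A"): [_rec(0, 5, "CpG", 10, 5), _rec(0, 8, "CHH", 4, 0)],
            ("a1", "B"): [_rec(0, 5, "CpG", 30, 30)],
            ("b1", "A"): [_rec(0, 5, "CpG", 20, 10)],
        }
        m = merge_reports(reports, {"a1": "g1", "b1": "g2"}, ("g1", "g2"))
        lev = m.level
        assert lev.loc[(0, 5, "-"), ("a1", "A")] == 0.5
        assert lev.loc[(0, 5, "-"), ("a1", "B")] == 1.0
        # coverage-weighted pooling: (5+30)/(10+30)
        assert m.sample_level().loc[(0, 5, "-"), "a1"] == pytest.approx(35 / 40)
        assert np.isnan(lev.loc[(0, 8, "-"), ("b1", "A")])


class TestClassifyPositions:
    def test_all_present_same_context_is_smp_candidate(self):
        flags = classify_positions(_matrix(_uniform_reports()))
        assert (flags == FLAG_SMP).all()

    def test_genotype_missing_is_snp(self):
        reports = _uniform_reports()
        # sample b2 carries T instead of the cytosine: no record at offset 5
        for copy in "AB":
            reports[("b2", copy)] = [
                r for r in reports[("b2", copy)] if r.offset != 5
            ]
        flags = classify_positions(_matrix(reports))
        assert flags.loc[(0, 5, "-")] == FLAG_SNP
        assert flags.loc[(0, 9, "-")] == FLAG_SMP

    def test_neighbouring_snp_changes_context(self):
        reports = _uniform_reports()
        for copy in "AB":
            reports[("b2", copy)] = [
                _rec(0, 5, "CHH", 30, 0),  # CpG -> CHH in this individual
                _rec(0, 9, "CpG", 30, 0),
            ]
        flags = classify_positions(_matrix(reports))
        assert flags.loc[(0, 5, "-")] == FLAG_SWAP


class TestFilterPositions:
    def test_default_thresholds_keep_covered_rows(self):
        m = _matrix(_uniform_reports(cov=30))
        mask = filter_positions(m, min_cov=25, min_samples_per_group=2)
        assert mask.all()

    def test_low_coverage_dropped(self):
        m = _matrix(_uniform_reports(cov=12))  # pooled 24 < 25
        mask = filter_positions(m, min_cov=25, min_samples_per_group=2)
        assert not mask.any()

    def test_toy_rule_application(self):
        # position kept iff >= 2 samples per group reach 25x pooled
        reports = _uniform_reports(cov=13)  # pooled 26
        for copy in "AB":
            reports[("a2", copy)] = [_rec(0, 5, "CpG", 5, 0), _rec(0, 9, "CpG", 13, 0)]
        m = _matrix(reports)
        mask = filter_positions(m, min_cov=25, min_samples_per_group=2)
        assert not mask.loc[(0, 5, "-")]  # only one g1 sample at 25x
        assert mask.loc[(0, 9, "-")]

    def test_swaps_excluded(self):
        reports = _uniform_reports()
        for copy in "AB":
            reports[("b2", copy)] = [
                _rec(0, 5, "CHH", 30, 0),
                _rec(0, 9, "CpG", 30, 0),
            ]
        m = _matrix(reports)
        mask = filter_positions(m, exclude_swaps=True)
        assert not mask.loc[(0, 5, "-")]
        mask2 = filter_positions(m, exclude_swaps=False)
        assert mask2.loc[(0, 5, "-")]

    def test_context_restriction(self):
        reports = _uniform_reports(ctx="CHG")
        m = _matrix(reports)
        assert not filter_positions(m, context="CpG").any()
        assert filter_positions(m, context="CHG").all()


class TestVariancePrefilter:
    def test_constant_rows_dropped(self):
        levels = pd.DataFrame(
            [[0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 1.0, 1.0]]
        )
        keep = variance_prefilter(levels)
        assert list(keep) == [False, False, True]

    def test_mean_and_sd_thresholds(self):
        row = pd.DataFrame([[0.0, 0.0, 1.0, 1.0]])
        assert variance_prefilter(row).iloc[0]  # mean .5, sd .5
        low_mean = pd.DataFrame([[0.0, 0.0, 0.0, 0.2]])  # mean .05
        assert not variance_prefilter(low_mean).iloc[0]


class TestKS:
    def test_identical_samples(self):
        d, p = ks_2samp([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_samples(self):
        d, _ = ks_2samp([0.0] * 5, [1.0] * 5)
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_2samp([], [0.5])

    def test_d_matches_bruteforce_ecdf_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.random(10)
            y = rng.random(10)
            d, _ = ks_2samp(x, y)
            # oracle: evaluate both ECDFs at every pooled point
            pooled = np.concatenate([x, y])
            d_brute = max(
                abs((x <= t).mean() - (y <= t).mean()) for t in pooled
            )
            assert d == pytest.approx(d_brute)


class TestQvalues:
    def test_all_ones(self):
        q = qvalues(np.ones(10))
        assert np.allclose(q, 1.0)

    def test_single_pvalue_is_pi0_times_p(self):
        # p > lambda: pi0 = 1
        assert qvalues([0.7])[0] == pytest.approx(0.7)
        # p <= lambda: pi0 = 0 under the fixed-lambda estimator
        assert qvalues([0.04])[0] == 0.0

    def test_matches_tailmin_enumeration(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.random(900), rng.random(100) * 1e-3])
        q = qvalues(p)
        # independent oracle: direct min-over-tail enumeration
        m = len(p)
        pi0 = min(1.0, (p > 0.5).sum() / (0.5 * m))
        order = np.argsort(p, kind="mergesort")
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(1, m + 1)
        q_oracle = np.array(
            [
                min(
                    pi0 * m * p[j] / ranks[j]
                    for j in range(m)
                    if p[j] >= p[i]
                )
                for i in range(m)
            ]
        )
        assert np.allclose(q, q_oracle)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.random(500)
        q = qvalues(p)
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])


class TestGroupDifference:
    def test_extremes(self):
        assert group_difference(
            {"g1": np.ones(3), "g2": np.zeros(3)}, ("g1", "g2")
        ) == pytest.approx(1.0)
        assert group_difference(
            {"g1": np.full(3, 0.4), "g2": np.full(3, 0.4)}, ("g1", "g2")
        ) == pytest.approx(0.0)

    def test_hand_value(self):
        d = group_difference(
            {"g1": np.array([0.2, 0.4]), "g2": np.array([0.1, 0.1])}, ("g1", "g2")
        )
        assert d == pytest.approx(0.3 - 0.1)

    def test_pipeline_difference_in_range(self, tiny_result):
        assert tiny_result.results["difference"].between(-1, 1).all()


class TestReproducibility:
    def test_identical_replicates(self):
        recs = [_rec(0, 5, "CpG", 30, 15), _rec(0, 9, "CpG", 30, 30)]
        frac, n = reproducibility(recs, recs)
        assert frac == 1.0 and n == 2

    def test_fifteen_percent_difference_not_reproducible(self):
        r1 = [_rec(0, 5, "CpG", 100, 50)]
        r2 = [_rec(0, 5, "CpG", 100, 65)]
        frac, n = reproducibility(r1, r2, tol=0.10)
        assert (frac, n) == (0.0, 1)

    def test_no_shared_positions_flagged(self):
        r1 = [_rec(0, 5, "CpG", 30, 15)]
        r2 = [_rec(0, 9, "CpG", 30, 15)]
        assert reproducibility(r1, r2) == (None, 0)

    def test_low_coverage_positions_ignored(self):
        r1 = [_rec(0, 5, "CpG", 10, 5), _rec(0, 9, "CpG", 30, 30)]
        r2 = [_rec(0, 5, "CpG", 10, 0), _rec(0, 9, "CpG", 40, 40)]
        frac, n = reproducibility(r1, r2, min_cov=25)
        assert (frac, n) == (1.0, 1)


class TestAggregateByLocus:
    def test_empty(self):
        out = aggregate_by_locus(pd.DataFrame(columns=["locus", "context", "p", "q"]))
        assert out.empty

    def test_hand_counts(self):
        results = pd.DataFrame(
            {
                "locus": [0, 0, 0, 3],
                "context": ["CpG", "CpG", "CHH", "CHG"],
                "p": [0.01, 0.02, 0.5, 0.03],
                "q": [0.04, 0.2, 0.9, 0.5],
            }
        )
        out = aggregate_by_locus(results)
        assert out.loc[0, "n_positions"] == 3
        assert out.loc[0, "n_p_sig"] == 2
        assert out.loc[0, "n_q_sig"] == 1
        assert out.loc[0, "contexts"] == "CHH,CpG"
        assert out.loc[3, "n_p_sig"] == 1


class TestRunDifferential:
    def test_planted_difference_detected(self, tiny_exp, tiny_result):
        from bsrad.evaluate import detection_metrics, map_catalog_to_truth

        lm = map_catalog_to_truth(tiny_result.catalog, tiny_exp.truth)
        met = detection_metrics(tiny_result.results, tiny_exp.truth, lm)
        assert met["sensitivity"] >= 0.75  # 4 planted positions, small n

    def test_per_copy_switch_changes_sample_counts(self, tiny_result):
        m = tiny_result.matrix
        pooled = run_differential(m, apply_variance_prefilter=False)
        per_copy = run_differential(m, apply_variance_prefilter=False, per_copy=True)
        g1 = f"n_{m.group_names[0]}"
        if len(pooled) and len(per_copy):
            assert per_copy[g1].max() >= pooled[g1].max()
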