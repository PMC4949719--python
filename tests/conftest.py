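import numpy as np
import pytest

from bsrad.pipeline import PipelineParams, run_pipeline
from bsrad.simdata import DEFAULT_METH_PRIOR, SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160328)


@pytest.fixture(scope="session")
def tiny_exp():
    """A small but complete experiment: 25 loci, 2 x 3 samples, 4 planted SMPs."""
    cfg = SimConfig(
        seed=7,
        n_loci=25,
        n_samples_per_group=3,
        n_diff_positions=4,
        mean_coverage=40,
        rad_mean_coverage=90,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def tiny_result(tiny_exp):
    params = PipelineParams(seed=7)
    return run_pipeline(
        tiny_exp.bs_reads, tiny_exp.rad_reads, tiny_exp.samples, params
    )


@pytest.fixture(scope="session")
def study_exp():
    """Study-scale simulation: 450 loci, 9 vs 9 individuals, 50x coverage,
    50 planted CpG differences of 0.8, animal-like (zero) CHH methylation so
    apparent CHH methylation estimates the conversion failure rate."""
    prior = dict(DEFAULT_METH_PRIOR)
    prior["CHH"] = (0.0, 1.0)
    cfg = SimConfig(
        seed=11,
        n_loci=450,
        n_samples_per_group=9,
        mean_coverage=50,
        rad_mean_coverage=100,
        n_diff_positions=50,
        diff_delta=0.8,
        meth_prior=prior,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def study_result(study_exp):
    params = PipelineParams(seed=11)
    return run_pipeline(
        study_exp.bs_reads, study_exp.rad_reads, study_exp.samples, params
    )


@pytest.fixture(scope="session")
def snp_exp():
    """Seeded simulation with planted C->T and context-changing SNPs only."""
    cfg = SimConfig(
        seed=5,
        n_loci=160,
        n_samples_per_group=3,
        snp_rate=0.0,
        n_ct_snps=100,
        n_context_snps=50,
        mean_coverage=30,
        rad_mean_coverage=80,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def snp_result(snp_exp):
    params = PipelineParams(seed=5)
    return run_pipeline(snp_exp.bs_reads, snp_exp.rad_reads, snp_exp.samples, params)
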