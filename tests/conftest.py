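import numpy as np
import pandas as pd
import pytest

from mremploy import instruments, simcohort
from mremploy.instruments import GwasRecord, HarmonisedSet
from mremploy.simcohort import Cohort, SimConfig


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(n_individuals=50_000, seed=0)


@pytest.fixture(scope="session")
def cohort(default_config) -> Cohort:
    return simcohort.generate_cohort(default_config)


@pytest.fixture(scope="session")
def exposure_records(default_config) -> list[GwasRecord]:
    return simcohort.generate_exposure_gwas(default_config, 300_000, seed=17)


def make_cohort(data: pd.DataFrame, snp_ids, alleles=None) -> Cohort:
    """Minimal Cohort wrapper around a hand-built table."""
    alleles = alleles or {s: ("A", "G") for s in snp_ids}
    k = len(snp_ids)
    return Cohort(data.reset_index(drop=True), list(snp_ids), alleles,
                  np.ones(k), np.full(k, 0.3), np.zeros(k),
                  SimConfig(n_individuals=max(len(data), 2), n_snps=max(k, 1)))


def make_hset(bx, sx, by, sy, ids=None) -> HarmonisedSet:
    bx = np.asarray(bx, float)
    ids = ids if ids is not None else [f"rs{i}" for i in range(len(bx))]
    return HarmonisedSet(list(ids), bx, np.asarray(sx, float),
                         np.asarray(by, float), np.asarray(sy, float),
                         {s: "kept" for s in ids})


def random_hset(rng: np.random.Generator, k: int = 20, theta: float = 0.05,
                sx_scale: float = 0.01, sy_scale: float = 0.02,
                alpha_mean: float = 0.0, alpha_sd: float = 0.0) -> HarmonisedSet:
    """Random two-sample summary set with known causal effect."""
    beta = rng.normal(0.1, 0.04, k)
    sx = np.full(k, sx_scale)
    sy = np.full(k, sy_scale)
    alpha = rng.normal(alpha_mean, alpha_sd, k) if (alpha_mean or alpha_sd) else 0.0
    bx = beta + rng.normal(0, sx)
    by = theta * beta + alpha + rng.normal(0, sy)
    return make_hset(bx, sx, by, sy)
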