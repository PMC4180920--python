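"""Shared fixtures: small seeded datasets reused across test modules."""

from dataclasses import replace

import numpy as np
import pytest

from multiline_gp.datatypes import GenotypeMatrix
from multiline_gp.scenarios import ExperimentData
from multiline_gp.simdata import default_three_line_config, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Calibrated three-line simulation at reduced size (shared, read-only)."""
    cfg = default_three_line_config(seed=11, n_train=150, n_validation=50)
    cfg = replace(cfg, n_snps=800, n_founders=120, n_qtl=150)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_experiment_data(small_dataset):
    return ExperimentData.from_simulation(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_genotypes(codes, lines=None, ids=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, p = codes.shape
    return GenotypeMatrix(
        ids=np.array(ids if ids is not None else [f"i{k}" for k in range(n)],
                     dtype=object),
        lines=np.array(lines if lines is not None else ["L"] * n, dtype=object),
        snp_ids=np.array([f"s{k}" for k in range(p)], dtype=object),
        codes=codes,
    )


@pytest.fixture()
def toy_genotypes():
    return make_genotypes


@pytest.fixture(scope="session")
def marker_sim():
    """Genotype design + polygenic trait for predictor equivalence checks.

    n_train = 200, n_val = 60, p = 1000, h^2 = 0.4; returns the pieces the
    marker models consume (centred/scaled training design, validation design
    in training scaling, phenotypes, variance components).
    """
    from multiline_gp.datatypes import VarianceComponents

    rng = np.random.default_rng(7)
    n, nv, p = 200, 60, 1000
    freq = rng.uniform(0.1, 0.9, p)
    x = rng.binomial(2, freq, size=(n + nv, p)).astype(float)
    keep = x[:n].std(axis=0) > 0
    x = x[:, keep]
    mean, sd = x[:n].mean(axis=0), x[:n].std(axis=0)
    z_train = (x[:n] - mean) / sd
    z_val = (x[n:] - mean) / sd
    beta = rng.normal(0.0, 0.05, x.shape[1])
    g = np.column_stack([z_train.T, z_val.T]).T @ beta
    h2 = 0.4
    var_g = float(np.var(g[:n]))
    var_e = var_g * (1 - h2) / h2
    y = g[:n] + rng.normal(0.0, np.sqrt(var_e), n)
    vc = VarianceComponents(genetic=var_g, residual=var_e, n_snps=x.shape[1])
    return {"z_train": z_train, "z_val": z_val, "y": y, "vc": vc,
            "g_val": g[n:], "h2": h2}
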