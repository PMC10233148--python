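"""Shared fixtures: one modest simulated breeding program reused across tests."""

import numpy as np
import pandas as pd
import pytest

from nirblup import (
    SimulationConfig,
    build_grm,
    edit_outliers,
    fit_blues,
    grm_condition,
    simulate_dataset,
)
from nirblup.io import blues_to_series


@pytest.fixture(scope="session")
def small_program():
    """200 lines, 400 markers, 4 years; both traits on every cohort line."""
    cfg = SimulationConfig(
        n_lines=200,
        n_markers=400,
        years=["2016", "2017", "2018", "2019"],
        seed=42,
    )
    geno, pheno, truth = simulate_dataset(cfg)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def small_blues(small_program):
    _, geno, pheno, truth = small_program
    pheno, _ = edit_outliers(pheno)
    ep = blues_to_series(fit_blues(pheno, "EP"))
    nir = blues_to_series(fit_blues(pheno, "NIR"))
    return ep, nir


@pytest.fixture(scope="session")
def small_grm(small_program):
    _, geno, _, _ = small_program
    return grm_condition(build_grm(geno))


def random_psd(rng: np.random.Generator, k: int, scale: float = 1.0) -> np.ndarray:
    """Random positive-definite k x k matrix for likelihood oracles."""
    A = rng.standard_normal((k, k + 2))
    M = A @ A.T / (k + 2) + 0.2 * np.eye(k)
    return scale * M


def random_grm(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random GRM-like PSD matrix with unit-scale diagonal."""
    m = 3 * n
    W = rng.standard_normal((n, m))
    W -= W.mean(axis=0)
    G = W @ W.T / m
    return G + 0.05 * np.eye(n)
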