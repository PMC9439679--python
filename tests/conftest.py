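"""Shared fixtures.

Heavy synthetic datasets are session-scoped; "small" variants (5 Mb
chromosome, reduced depth) keep unit tests fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from loopdelta.matrixio import balance
from loopdelta.simulate import (
    SimConfig,
    simulate_contact_matrix,
    simulate_expression_table,
    simulate_peaks,
    simulate_truth,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def truth(default_config):
    return simulate_truth(default_config)


@pytest.fixture(scope="session")
def matrix_a(truth, default_config):
    return balance(simulate_contact_matrix(truth, default_config, "A"))


@pytest.fixture(scope="session")
def matrix_b(truth, default_config):
    return balance(simulate_contact_matrix(truth, default_config, "B"))


@pytest.fixture(scope="session")
def genes_table(truth, default_config):
    return simulate_expression_table(truth, default_config)


@pytest.fixture(scope="session")
def peaks(truth, default_config):
    return simulate_peaks(truth, default_config)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        chrom_length_bp=5_000_000,
        depth=2_500_000,
        n_genes=80,
        n_stripe_genes=4,
        n_loops_shared=2,
        n_loops_A_only=2,
        n_loops_B_only=1,
        loop_max_dist_bp=600_000,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_truth, small_config):
    return balance(simulate_contact_matrix(small_truth, small_config, "A"))


def decay_only_config(seed: int = 0, **overrides) -> SimConfig:
    """Null scenario: pure power-law decay, no planted structure."""
    params = dict(
        seed=seed,
        compartment_strength=1.0,
        tad_insulation=0.0,
        n_loops_shared=0,
        n_loops_A_only=0,
        n_loops_B_only=0,
        n_stripe_genes=0,
        stripe_strength=1.0,
        n_switch_blocks=0,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def null_matrix():
    cfg = decay_only_config(seed=21)
    t = simulate_truth(cfg)
    return balance(simulate_contact_matrix(t, cfg, "A")), cfg
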