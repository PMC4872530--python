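"""Shared fixtures: all test data is generated, nothing is downloaded."""

from __future__ import annotations

import numpy as np
import pytest

from mitopaleo import fixtures
from mitopaleo.consensus import build_pileup, call_consensus
from mitopaleo.reference import load_reference
from mitopaleo.simulate import SimConfig, simulate_reads


@pytest.fixture(scope="session")
def reference() -> str:
    return load_reference()


@pytest.fixture(scope="session")
def pm1():
    return fixtures.pm1_haplotype()


@pytest.fixture(scope="session")
def contaminant():
    return fixtures.contaminant_haplotype()


@pytest.fixture(scope="session")
def mixture_panel(contaminant):
    return fixtures.mixture_panel(contaminant)


@pytest.fixture(scope="session")
def worldwide_panel():
    return fixtures.worldwide_panel()


@pytest.fixture(scope="session")
def clean_reads(pm1):
    """Noise-free 20x read set from the sample haplotype."""
    config = SimConfig(
        target_mean_depth=20,
        deamination_rate=0.0,
        seq_error=0.0,
        seed=1234,
    )
    return simulate_reads(pm1, config)


@pytest.fixture(scope="session")
def damaged_reads(pm1):
    """33x read set with default damage and sequencing error, no contamination."""
    return simulate_reads(pm1, SimConfig(seed=99))


@pytest.fixture(scope="session")
def damaged_consensus(damaged_reads):
    return call_consensus(build_pileup(damaged_reads))
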