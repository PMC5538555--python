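"""Shared fixtures: small seeded references, libraries, cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from retroped import dna
from retroped.consensus import default_library
from retroped.reference import build_reference
from retroped.simconfig import SimConfig, demo_pedigree


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=5, n_chromosomes=2, chrom_length=200_000,
                     n_decoy_te_copies=5, n_donor_elements=2)


@pytest.fixture(scope="session")
def small_reference(small_config, library):
    return build_reference(small_config, library)


@pytest.fixture(scope="session")
def small_pedigree():
    return demo_pedigree(n_offspring=8)


def random_codes(seed: int, n: int, gc: float = 0.42) -> np.ndarray:
    return dna.random_seq(np.random.default_rng(seed), n, gc)
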