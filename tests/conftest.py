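"""Shared fixtures: small simulated subjects, reused across test modules.

Expensive objects (simulated subjects, per-subject analyses) are
session-scoped so each is built once.
"""

import numpy as np
import pytest

from connsel import EffectSpec, make_design, make_split_scheme
from connsel.decoding import SubjectAnalysis
from connsel.layout import searchlight_layout, two_region_layout
from connsel.simulate import simulate_subject


@pytest.fixture(scope="session")
def scheme():
    return make_split_scheme(6, seed=0)


@pytest.fixture(scope="session")
def small_layout():
    return two_region_layout()


@pytest.fixture(scope="session")
def planted_subject(small_layout):
    """One subject with default planted structure on the reduced layout."""
    return simulate_subject(
        small_layout, make_design(6, seed=11), EffectSpec(seed=11))


@pytest.fixture(scope="session")
def planted_analysis(planted_subject):
    return SubjectAnalysis(planted_subject)


@pytest.fixture(scope="session")
def null_subject(small_layout):
    """No planted coupling or patterns: pure noise plus task activation."""
    return simulate_subject(
        small_layout, make_design(6, seed=12),
        EffectSpec(coupling_strength=0.0, pattern_snr=0.0, seed=12))


@pytest.fixture(scope="session")
def sl_layout():
    return searchlight_layout()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
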