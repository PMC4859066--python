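"""Shared fixtures: ground-truthed simulations reused across test modules.

Simulations are session-scoped because fragment generation at realistic
depth dominates test runtime; tests must not mutate them in place.
"""

from __future__ import annotations

import numpy as np
import pytest

from macckit import (
    MACCTrack,
    fit_macc,
    median_shift,
    simulate_genome,
    simulate_titration,
)
from macckit.pipeline import series_from_fragment_sets


def concat(mapping, chroms):
    return np.concatenate([np.asarray(mapping[c]) for c in chroms])


@pytest.fixture(scope="session")
def truth10k():
    return simulate_genome(n_bins=10_000, bin_size=300, seed=101)


@pytest.fixture(scope="session")
def sim10k(truth10k):
    """Default-depth (50) simulation of all three pools."""
    return simulate_titration(truth10k, depth=50.0, seed=202)


@pytest.fixture(scope="session")
def series10k(truth10k, sim10k):
    return {
        pool: series_from_fragment_sets(sets, truth10k.genome, truth10k.bin_size, None)
        for pool, sets in sim10k.fragment_sets.items()
    }


@pytest.fixture(scope="session")
def c_macc10k(series10k):
    return fit_macc(series10k["chromatin"], provenance="c-MACC")


@pytest.fixture(scope="session")
def h_macc10k(series10k):
    return fit_macc(series10k["histone_chip"], provenance="h-MACC")


@pytest.fixture(scope="session")
def shifted_tracks10k(c_macc10k, h_macc10k):
    return median_shift(c_macc10k), median_shift(h_macc10k)


def make_macc(values, bin_size=300, chrom="chr1", **flags) -> MACCTrack:
    """Small single-chromosome MACC track from a plain array."""
    return MACCTrack(bin_size, {chrom: np.asarray(values, dtype=float)}, **flags)
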