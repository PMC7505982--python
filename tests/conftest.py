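from __future__ import annotations

import numpy as np
import pytest

import xpsweep as x


@pytest.fixture(scope="session")
def layout_small():
    return x.make_genome_layout(2, [1_000_000, 2_000_000])


@pytest.fixture(scope="session")
def neutral_panel():
    """Two populations, one 2-Mb chromosome, no sweep; shared across tests."""
    layout = x.make_genome_layout(1, [2_000_000])
    haps = x.simulate_neutral_haplotypes(
        layout, [("A", 20), ("B", 20)], 2000, seed=11
    )
    return layout, haps


@pytest.fixture(scope="session")
def neutral_xpehh(neutral_panel):
    layout, haps = neutral_panel
    return layout, x.compute_xpehh(haps, ("A", "B"))


@pytest.fixture(scope="session")
def four_pop_tracks():
    """Four populations and all six ordered-pair XP-EHH tracks.

    The basis for trait-association tests: pairs are oriented alphabetically
    and the per-pair standardized score tracks are reused session-wide.
    """
    layout = x.make_genome_layout(1, [2_000_000])
    pops = ["A", "B", "C", "D"]
    haps = x.simulate_neutral_haplotypes(
        layout, [(p, 16) for p in pops], 2000, seed=7
    )
    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]
    tracks = {pair: x.compute_xpehh(haps, pair).track("std") for pair in pairs}
    return layout, pops, pairs, tracks


def random_peakset(layout, n, rng, size_lo=10_000, size_hi=100_000):
    sizes = rng.integers(size_lo, size_hi, size=n)
    return x.sample_random_regions(layout, sizes, rng)
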