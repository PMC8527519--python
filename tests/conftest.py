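"""Shared fixtures.

The three heavyweight fixtures (full, partial-balanced and basic+extra-cross
eight-founder designs at ~950 RILs, 100 iterations each on a five-chromosome
genome) are session-scoped because several statistical tests draw on the
same simulations.
"""

from __future__ import annotations

import numpy as np
import pytest

from magicpop import GenomeMap, run_design
from magicpop.design import (
    basic_design,
    full_design,
    partial_balanced_design,
)
from magicpop.sim import Individual, SegmentHaplotype

N_ITERATIONS = 100


@pytest.fixture(scope="session")
def gmap5():
    """Five chromosomes of 1.0-3.0 Morgans, 5 cM markers, 5 cM intervals."""
    return GenomeMap((100.0, 150.0, 200.0, 250.0, 300.0),
                     marker_spacing=5.0, interval=5.0)


def design1():
    """Full eight-founder design: 315 funnels, replicates (1,1,3), four
    terminal selfing generations; 945 RILs."""
    return full_design(8, replicates=(1, 1, 3), selfing=(0, 0, 4), name="design1")


def design2(seed=42):
    """One balanced funnel set (7 funnels), replicates (1,9,15); 945 RILs."""
    return partial_balanced_design(8, 1, seed=seed, replicates=(1, 9, 15),
                                   selfing=(0, 0, 4), name="design2")


def design5():
    """Basic design plus one random inter-crossing generation, replicates
    (1,4,4,15); 960 RILs."""
    return basic_design(8, replicates=(1, 4, 4, 15), selfing=(0, 0, 0, 4),
                        additional_cross=True, n_rils_target=960, name="design5")


@pytest.fixture(scope="session")
def design1_table(gmap5):
    return run_design(design1(), gmap5, N_ITERATIONS, seed=101, name="design1")


@pytest.fixture(scope="session")
def design2_table(gmap5):
    return run_design(design2(), gmap5, N_ITERATIONS, seed=202, name="design2")


@pytest.fixture(scope="session")
def design5_table(gmap5):
    return run_design(design5(), gmap5, N_ITERATIONS, seed=505, name="design5")


def make_individual(gmap: GenomeMap, hap1_segs, hap2_segs=None, id="x") -> Individual:
    """Build an individual from per-chromosome [(end, founder), ...] lists."""
    if hap2_segs is None:
        hap2_segs = hap1_segs
    h1 = SegmentHaplotype(tuple(list(c) for c in hap1_segs))
    h2 = SegmentHaplotype(tuple(list(c) for c in hap2_segs))
    return Individual(id, h1, h2)
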