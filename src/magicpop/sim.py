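"""Founder-labeled genome simulation through a crossing scheme.

Genomes are tracked as founder-labeled segments on a genetic map (cM,
0-based, half-open intervals), not as marker arrays: every individual carries
two haplotypes, each a per-chromosome list of ``(end, founder)`` records
tiling ``[0, L)``.  Meiosis follows Haldane's model — crossover counts are
Poisson with mean equal to the chromosome length in Morgans, crossover
positions are independent uniform, and the starting homolog is a fair coin —
so there is no crossover interference and no obligate chiasma.  Founders are
fully inbred: founder *i* is homozygous for label *i* everywhere.

Marker grids only enter when a simulated genome is discretized with
:func:`to_marker_labels`; segment tracking keeps breakpoints exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pedigree import PedigreeTable

__all__ = [
    "GenomeMap",
    "SegmentHaplotype",
    "Individual",
    "Population",
    "SimulationError",
    "meiosis",
    "cross",
    "self_",
    "founder_individual",
    "simulate_population",
    "to_marker_labels",
    "labels_at",
    "haldane_r",
]

_MORGAN_CM = 100.0


class SimulationError(ValueError):
    pass


def haldane_r(d_cm: float) -> float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / _MORGAN_CM))


@dataclass(frozen=True)
class GenomeMap:
    """Genetic map: chromosome lengths (cM), the marker spacing used when a
    population is discretized, and the interval size used when scoring
    recombinant haplotypes."""

    chrom_lengths: tuple[float, ...]
    marker_spacing: float = 1.0
    interval: float = 5.0

    def __post_init__(self):
        object.__setattr__(self, "chrom_lengths", tuple(float(c) for c in self.chrom_lengths))
        if not self.chrom_lengths or any(c <= 0 for c in self.chrom_lengths):
            raise SimulationError("chromosome lengths must be positive")
        if not 0 < self.marker_spacing <= self.interval:
            raise SimulationError("need 0 < marker_spacing <= interval")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    def markers(self, chrom: int) -> np.ndarray:
        """Marker positions 0, d, 2d, ... up to and including the chromosome
        end when it falls on the grid."""
        L = self.chrom_lengths[chrom]
        d = self.marker_spacing
        return np.arange(0.0, L + d * 1e-9, d)

    def interval_grid(self, chrom: int, interval: float | None = None) -> np.ndarray:
        """Evaluation grid for recombinant-haplotype scoring; the interval
        must be a multiple of the marker spacing (no silent rounding)."""
        d = self.interval if interval is None else float(interval)
        ratio = d / self.marker_spacing
        if abs(ratio - round(ratio)) > 1e-9 or d < self.marker_spacing:
            raise SimulationError(
                f"interval {d} cM is not a multiple of the marker spacing "
                f"{self.marker_spacing} cM"
            )
        L = self.chrom_lengths[chrom]
        return np.arange(0.0, L + d * 1e-9, d)


# a chromosome haplotype is a list of (end, founder); lists may be shared
# between individuals and must never be mutated in place.
Chrom = list


@dataclass(frozen=True)
class SegmentHaplotype:
    """One gamete: per chromosome, merged founder segments tiling [0, L)."""

    chroms: tuple

    def segments(self, chrom: int):
        """Yield (start, end, founder) triples for one chromosome."""
        start = 0.0
        for end, f in self.chroms[chrom]:
            yield start, end, f
            start = end

    def founders_on(self, chrom: int) -> set[int]:
        return {f for _, f in self.chroms[chrom]}


@dataclass(frozen=True)
class Individual:
    id: str
    hap1: SegmentHaplotype
    hap2: SegmentHaplotype

    def heterozygous_fraction(self, gmap: "GenomeMap") -> float:
        """Genome fraction where the two homologs carry different founders."""
        het = 0.0
        for c in range(gmap.n_chromosomes):
            b1 = list(self.hap1.segments(c))
            b2 = list(self.hap2.segments(c))
            i = j = 0
            cur = 0.0
            while i < len(b1) and j < len(b2):
                e = min(b1[i][1], b2[j][1])
                if b1[i][2] != b2[j][2]:
                    het += e - cur
                cur = e
                if b1[i][1] <= e:
                    i += 1
                if b2[j][1] <= e:
                    j += 1
        return het / sum(gmap.chrom_lengths)


@dataclass
class Population:
    """Final RILs of one simulated crossing scheme."""

    individuals: list[Individual]
    n_founders: int
    gmap: GenomeMap
    seed: object = None
    design: str | None = None
    iteration: int | None = None

    def __len__(self):
        return len(self.individuals)


def founder_individual(index: int, fid: str, gmap: GenomeMap) -> Individual:
    chroms = tuple([(L, index)] for L in gmap.chrom_lengths)
    hap = SegmentHaplotype(chroms)
    return Individual(fid, hap, hap)


# ---------------------------------------------------------------------------
# meiosis


def _recombine(h0: Chrom, h1: Chrom, cuts: Sequence[float], first: int, L: float) -> Chrom:
    """Merge two homolog segment lists along sorted crossover positions."""
    srcs = (h0, h1)
    idx = [0, 0]
    out: Chrom = []
    cur = 0.0
    w = first
    bounds = list(cuts) + [L]
    last = len(bounds) - 1
    for bi, b in enumerate(bounds):
        src = srcs[w]
        i = idx[w]
        while src[i][0] <= cur:
            i += 1
        while cur < b:
            e, f = src[i]
            seg_end = e if e < b else b
            if out and out[-1][1] == f:
                out[-1] = (seg_end, f)
            else:
                out.append((seg_end, f))
            cur = seg_end
            if e <= b:
                i += 1
            else:
                break
        idx[w] = i
        if bi != last:
            w ^= 1
    return out


def meiosis(parent: Individual, gmap: GenomeMap, rng: np.random.Generator) -> SegmentHaplotype:
    """One meiotic gamete of ``parent`` under the Haldane model."""
    lens = gmap.chrom_lengths
    ks = rng.poisson(np.multiply(lens, 1.0 / _MORGAN_CM))
    firsts = rng.integers(0, 2, size=len(lens))
    chroms = []
    h1, h2 = parent.hap1.chroms, parent.hap2.chroms
    if len(h1) != len(lens) or any(h[-1][0] != L for h, L in zip(h1, lens)):
        raise SimulationError(
            f"individual {parent.id!r} does not tile the genome map "
            f"(chromosome count or lengths differ)"
        )
    for c, L in enumerate(lens):
        k = ks[c]
        if k == 0:
            chroms.append(h1[c] if firsts[c] == 0 else h2[c])
        else:
            cuts = np.sort(rng.random(k) * L)
            chroms.append(_recombine(h1[c], h2[c], cuts.tolist(), int(firsts[c]), L))
    return SegmentHaplotype(tuple(chroms))


def cross(p1: Individual, p2: Individual, gmap: GenomeMap,
          rng: np.random.Generator, id: str = "") -> Individual:
    """Offspring from one independent gamete of each parent."""
    return Individual(id, meiosis(p1, gmap, rng), meiosis(p2, gmap, rng))


def self_(p: Individual, gmap: GenomeMap, rng: np.random.Generator,
          id: str = "") -> Individual:
    """Selfed offspring: two independent gametes from the same parent."""
    return Individual(id, meiosis(p, gmap, rng), meiosis(p, gmap, rng))


# ---------------------------------------------------------------------------
# pedigree execution


def simulate_population(ped: PedigreeTable, gmap: GenomeMap, seed=None) -> Population:
    """Execute a pedigree row by row and return the terminal individuals.

    Founders are assigned fixed homozygous labels 1..n in pedigree order.
    Deterministic given ``(pedigree, map, seed)``.
    """
    rng = np.random.default_rng(seed)
    individuals: dict[str, Individual] = {}
    founder_no = 0
    for row in ped.df.itertuples(index=False):
        if row.type == "founder":
            founder_no += 1
            individuals[row.id] = founder_individual(founder_no, row.id, gmap)
        else:
            try:
                p1 = individuals[row.parent1]
                p2 = individuals[row.parent2]
            except KeyError as e:  # pragma: no cover - caught by validation
                raise SimulationError(f"parent {e} simulated after child {row.id}") from e
            if row.type == "self":
                individuals[row.id] = self_(p1, gmap, rng, id=row.id)
            else:
                individuals[row.id] = cross(p1, p2, gmap, rng, id=row.id)
    terminals = [individuals[i] for i in ped.terminal_ids()]
    return Population(terminals, n_founders=founder_no, gmap=gmap, seed=seed)


# ---------------------------------------------------------------------------
# marker discretization


def labels_at(hap: SegmentHaplotype, chrom: int, positions: np.ndarray) -> np.ndarray:
    """Founder label of the segment containing each position (half-open
    convention; a position at the chromosome end takes the final segment)."""
    segs = hap.chroms[chrom]
    ends = np.fromiter((e for e, _ in segs), dtype=float, count=len(segs))
    founders = np.fromiter((f for _, f in segs), dtype=np.int64, count=len(segs))
    idx = np.searchsorted(ends, positions, side="right")
    return founders[np.minimum(idx, len(segs) - 1)]


def to_marker_labels(ind: Individual, gmap: GenomeMap) -> list[np.ndarray]:
    """Per chromosome, a (2, n_markers) founder-label matrix on the marker
    grid defined by the map's marker spacing."""
    out = []
    for c in range(gmap.n_chromosomes):
        pos = gmap.markers(c)
        out.append(np.vstack([labels_at(ind.hap1, c, pos), labels_at(ind.hap2, c, pos)]))
    return out
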