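"""Design-quality statistics for simulated or imported MAGIC populations.

A *recombinant haplotype* is the ordered pair of founder labels flanking a
breakpoint along a chromosome (``1_5`` = founder 1 then founder 5); with
``n`` founders there are ``n**2 - n`` of them, 56 for ``n = 8``.  Haplotypes
are detected on a marker grid: consecutive markers an interval ``d`` apart
whose labels differ contribute one haplotype, so fine-scale double crossovers
inside an interval are invisible — exactly the situation of real marker data.

The summary metrics per population are:

* ``total_rh_proportion`` — fraction of evaluated ``d``-intervals containing
  a founder switch, averaged over homologs and RILs;
* ``unique_rh_count`` — number of distinct ordered founder pairs observed
  per interval, averaged over intervals.  This is interval-resolved because
  a population-wide tally saturates at ``n**2 - n`` for any realistically
  sized population; resolving by interval is what makes the metric sensitive
  to replicate sharing and to locally fixed parents (the population-wide
  tally is available as :func:`observed_pair_count`);
* per-pair mean counts per RIL, founder genome proportions, the distribution
  of distinct founders per chromosome, and mean non-recombinant segment
  lengths.

Residual heterozygosity after finite selfing is handled by averaging the two
homologs (counts, proportions) or taking their union (founder tracts); pass
``homologs=1`` to score a single haplotype per RIL instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim import Population, labels_at

__all__ = [
    "RHRecords",
    "MetricsSummary",
    "recombinant_haplotypes",
    "unique_rh_count",
    "observed_pair_count",
    "founder_proportions",
    "founder_tracts",
    "segment_lengths",
    "unique_identical_bins",
    "interval_switch_proportions",
    "calls_recombinant_haplotypes",
    "prhr",
    "summarize_population",
    "pair_labels",
]


def pair_labels(n: int) -> list[str]:
    """The ``n**2 - n`` ordered founder pairs, as ``"1_2", "1_3", ...``."""
    return [f"{a}_{b}" for a in range(1, n + 1) for b in range(1, n + 1) if a != b]


@dataclass
class RHRecords:
    """Recombinant haplotypes detected on the interval grid.

    ``events`` has one row per detected haplotype with columns
    ``ril, homolog, chrom, interval, pos_cM, left, right``; ``pos_cM`` is the
    left marker of the switching interval.
    """

    events: pd.DataFrame
    n_rils: int
    n_founders: int
    n_intervals: int  # per homolog, summed over chromosomes
    interval: float
    n_homologs: int = 2
    intervals_per_chrom: tuple[int, ...] = ()

    @property
    def total_proportion(self) -> float:
        """Fraction of evaluated intervals with a founder switch, averaged
        over homologs and RILs."""
        return len(self.events) / (self.n_homologs * self.n_rils * self.n_intervals)

    def per_pair_mean(self) -> pd.Series:
        """Mean count of each ordered pair per RIL (homolog-averaged)."""
        n = self.n_founders
        counts = pd.Series(0.0, index=pair_labels(n), name="mean_count")
        if len(self.events):
            obs = self.events.groupby(["left", "right"]).size()
            for (a, b), c in obs.items():
                counts[f"{a}_{b}"] = c / (self.n_homologs * self.n_rils)
        return counts


def recombinant_haplotypes(pop: Population, interval: float | None = None,
                           homologs: int = 2) -> RHRecords:
    """Scan RIL haplotypes on markers spaced ``interval`` cM apart and record
    an ordered founder pair wherever consecutive labels differ.

    ``homologs=2`` scans both haplotypes of every RIL (default), ``homologs=1``
    only the first.
    """
    if homologs not in (1, 2):
        raise ValueError("homologs must be 1 or 2")
    gmap = pop.gmap
    grids = [gmap.interval_grid(c, interval) for c in range(gmap.n_chromosomes)]
    d = gmap.interval if interval is None else float(interval)
    n_intervals = sum(len(g) - 1 for g in grids)
    rows = []
    for r, ind in enumerate(pop.individuals):
        haps = (ind.hap1, ind.hap2)[:homologs]
        for h, hap in enumerate(haps):
            for c, grid in enumerate(grids):
                lab = labels_at(hap, c, grid)
                for i in np.nonzero(lab[1:] != lab[:-1])[0]:
                    rows.append((r, h, c, int(i), grid[i], int(lab[i]), int(lab[i + 1])))
    events = pd.DataFrame(
        rows, columns=["ril", "homolog", "chrom", "interval", "pos_cM", "left", "right"]
    )
    return RHRecords(events, n_rils=len(pop), n_founders=pop.n_founders,
                     n_intervals=n_intervals, interval=d, n_homologs=homologs,
                     intervals_per_chrom=tuple(len(g) - 1 for g in grids))


def unique_rh_count(records: RHRecords) -> float:
    """Mean number of distinct ordered founder pairs per evaluation interval
    (intervals without any switch contribute zero); at most ``n**2 - n``."""
    if not len(records.events):
        return 0.0
    distinct = records.events.drop_duplicates(["chrom", "interval", "left", "right"])
    return len(distinct) / records.n_intervals


def interval_switch_proportions(records: RHRecords) -> np.ndarray:
    """Per evaluation interval (all chromosomes concatenated), the fraction
    of scanned haplotypes with a founder switch in that interval.  The
    variance of this vector measures how unevenly recombination is spread
    over the population — parental sharing through replicates inflates it."""
    counts = np.zeros(records.n_intervals)
    offsets = np.concatenate([[0], np.cumsum(records.intervals_per_chrom)])
    if len(records.events):
        for (c, i), v in records.events.groupby(["chrom", "interval"]).size().items():
            counts[offsets[c] + i] = v
    return counts / (records.n_homologs * records.n_rils)


def observed_pair_count(records: RHRecords) -> int:
    """Distinct ordered founder pairs observed anywhere in the population."""
    if not len(records.events):
        return 0
    return len(records.events.drop_duplicates(["left", "right"]))


def founder_proportions(pop: Population, per_ril: bool = False):
    """Genome-length-weighted founder fractions, homolog-averaged per RIL.

    Returns the population mean vector (length ``n_founders``; sums to 1 and
    its founder-mean is exactly ``1/n``), or the per-RIL matrix when
    ``per_ril`` is true.
    """
    gmap = pop.gmap
    genome = sum(gmap.chrom_lengths)
    mat = np.zeros((len(pop), pop.n_founders))
    for r, ind in enumerate(pop.individuals):
        for hap in (ind.hap1, ind.hap2):
            for c in range(gmap.n_chromosomes):
                for start, end, f in hap.segments(c):
                    mat[r, f - 1] += end - start
    mat /= 2 * genome
    return mat if per_ril else mat.mean(axis=0)


def founder_tracts(pop: Population) -> pd.DataFrame:
    """Per chromosome, the population distribution of the number of distinct
    founders carried by a RIL (union of both homologs); rows sum to 1."""
    gmap = pop.gmap
    n = pop.n_founders
    counts = np.zeros((gmap.n_chromosomes, n))
    for ind in pop.individuals:
        for c in range(gmap.n_chromosomes):
            k = len(ind.hap1.founders_on(c) | ind.hap2.founders_on(c))
            counts[c, k - 1] += 1
    counts /= len(pop)
    return pd.DataFrame(
        counts,
        index=[f"chr{c + 1}" for c in range(gmap.n_chromosomes)],
        columns=[str(k) for k in range(1, n + 1)],
    )


def segment_lengths(pop: Population) -> np.ndarray:
    """Mean length (cM) of maximal single-founder segments per chromosome,
    averaged over homologs and RILs."""
    gmap = pop.gmap
    out = np.zeros(gmap.n_chromosomes)
    for c in range(gmap.n_chromosomes):
        acc = 0.0
        for ind in pop.individuals:
            for hap in (ind.hap1, ind.hap2):
                acc += gmap.chrom_lengths[c] / len(hap.chroms[c])
        out[c] = acc / (2 * len(pop))
    return out


def unique_identical_bins(events: pd.DataFrame, bin_width: float,
                          position_col: str = "pos_cM"):
    """Classify recombinant haplotypes as unique or identical.

    Haplotypes of the same ordered founder pair falling in the same
    non-overlapping bin (anchored at position 0 of each chromosome) are
    identical; the rest are unique.  Returns ``(multiplicity_histogram,
    unique_proportion)`` where the histogram maps multiplicity class to the
    number of distinct (chromosome, bin, pair) keys in it.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not len(events):
        return {}, float("nan")
    keys = pd.DataFrame({
        "chrom": events["chrom"].to_numpy(),
        "bin": np.floor(events[position_col].to_numpy() / bin_width).astype(int),
        "left": events["left"].to_numpy(),
        "right": events["right"].to_numpy(),
    })
    mult = keys.groupby(["chrom", "bin", "left", "right"]).size()
    hist = {int(k): int(v) for k, v in mult.value_counts().sort_index().items()}
    unique_prop = float((mult == 1).sum() / len(mult))
    return hist, unique_prop


def calls_recombinant_haplotypes(calls: pd.DataFrame) -> pd.DataFrame:
    """Recombinant haplotypes from an imported founder-call matrix.

    ``calls`` is wide: columns ``chr``, ``pos_cM`` then one column per RIL
    holding founder indices (blank/NaN = missing call).  For each RIL and
    chromosome, consecutive non-missing calls that differ contribute one
    event positioned at the left marker.  Returns an events frame compatible
    with :func:`unique_identical_bins`.
    """
    for col in ("chr", "pos_cM"):
        if col not in calls.columns:
            raise ValueError(f"founder-call matrix lacks column {col!r}")
    ril_cols = [c for c in calls.columns if c not in ("chr", "pos_cM")]
    rows = []
    for chrom, sub in calls.groupby("chr", sort=False):
        sub = sub.sort_values("pos_cM")
        pos = sub["pos_cM"].to_numpy(dtype=float)
        for ril in ril_cols:
            v = pd.to_numeric(sub[ril], errors="coerce").to_numpy(dtype=float)
            ok = ~np.isnan(v)
            p, lab = pos[ok], v[ok].astype(int)
            for i in np.nonzero(lab[1:] != lab[:-1])[0]:
                rows.append((ril, chrom, p[i], int(lab[i]), int(lab[i + 1])))
    return pd.DataFrame(rows, columns=["ril", "chrom", "pos_cM", "left", "right"])


def prhr(observed_count: float, true_count: float) -> float:
    """Proportion of recombinant haplotypes recovered: the haplotype count
    observed in a marker dataset divided by the true (simulated) count."""
    if true_count <= 0:
        raise ZeroDivisionError("PRHR is undefined for a zero true count")
    return observed_count / true_count


# ---------------------------------------------------------------------------
# one-call summary


@dataclass
class MetricsSummary:
    """All per-iteration design-quality statistics of one population."""

    total_rh_proportion: float
    unique_rh_count: float
    per_pair_mean: pd.Series
    founder_proportions: np.ndarray
    tract_distribution: pd.DataFrame
    mean_segment_length: np.ndarray
    n_rils: int
    interval: float

    def to_row(self) -> dict:
        """Flatten to a single CSV-friendly record."""
        row: dict = {
            "n_rils": self.n_rils,
            "interval_cM": self.interval,
            "total_rh_proportion": self.total_rh_proportion,
            "unique_rh_count": self.unique_rh_count,
        }
        for i, p in enumerate(self.founder_proportions, start=1):
            row[f"founder_prop_{i}"] = p
        for c, v in enumerate(self.mean_segment_length, start=1):
            row[f"mean_segment_cM_chr{c}"] = v
        for chrom in self.tract_distribution.index:
            for k in self.tract_distribution.columns:
                row[f"tract_{chrom}_k{k}"] = self.tract_distribution.loc[chrom, k]
        for pair, v in self.per_pair_mean.items():
            row[f"pair_{pair}"] = v
        return row


def summarize_population(pop: Population, interval: float | None = None,
                         homologs: int = 2) -> MetricsSummary:
    rec = recombinant_haplotypes(pop, interval, homologs=homologs)
    return MetricsSummary(
        total_rh_proportion=rec.total_proportion,
        unique_rh_count=unique_rh_count(rec),
        per_pair_mean=rec.per_pair_mean(),
        founder_proportions=founder_proportions(pop),
        tract_distribution=founder_tracts(pop),
        mean_segment_length=segment_lengths(pop),
        n_rils=len(pop),
        interval=rec.interval,
    )
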