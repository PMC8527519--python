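"""Expansion of a MAGIC design into an explicit crossing scheme.

A pedigree here is a table of individuals, one row each, with the two parent
ids, a generation label (``2way``, ``4way``, ..., ``addx`` for the optional
extra inter-crossing round, with selfing rows labelled ``<gen>.self<k>``),
and a row type (``founder`` / ``cross`` / ``self``).  The table is
topologically ordered: parents always appear before their children, and every
final RIL traces back to the founders.

Crosses are deduplicated within a generation: all funnels that share the
two-way cross (1x2) draw on the same cross.  ``replicates[g]`` progeny are
retained per cross at generation ``g+1``, and when a cross's parents are
themselves replicated, the cross is instantiated once per replicate pair
(replicate *i* of one parent with replicate *i* of the other) — this is what
turns, e.g., 7 funnels with nine four-way replicates into 63 eight-way
crosses.  Selfing is by single seed descent: one progeny per self generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, DesignError, _generation, _leaves

__all__ = [
    "PedigreeTable",
    "PedigreeError",
    "build_scheme",
    "cross_counts",
    "count_rils",
    "read_pedigree",
    "write_pedigree",
]

COLUMNS = ["id", "parent1", "parent2", "generation", "type"]


class PedigreeError(ValueError):
    """Pedigree schema or ordering violation."""


@dataclass
class PedigreeTable:
    """Validated crossing-scheme table (founders first, parents before
    children)."""

    df: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {missing}")
        seen: set[str] = set()
        for row_no, row in enumerate(df.itertuples(index=False), start=1):
            rid = row.id
            if rid in seen:
                raise PedigreeError(f"row {row_no}: duplicate id {rid!r}")
            p1, p2 = row.parent1, row.parent2
            if row.type == "founder":
                if p1 or p2:
                    raise PedigreeError(f"row {row_no}: founder {rid!r} has parents")
            else:
                if not p1 or not p2:
                    raise PedigreeError(f"row {row_no}: {rid!r} lacks a parent")
                for p in (p1, p2):
                    if p == rid:
                        raise PedigreeError(f"row {row_no}: {rid!r} is its own parent (cycle)")
                    if p not in seen:
                        raise PedigreeError(
                            f"row {row_no}: parent {p!r} of {rid!r} is undefined or "
                            f"appears after its child"
                        )
                if row.type == "self" and p1 != p2:
                    raise PedigreeError(f"row {row_no}: self row {rid!r} has two distinct parents")
            seen.add(rid)

    @property
    def founders(self) -> list[str]:
        return self.df.loc[self.df["type"] == "founder", "id"].tolist()

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    def terminal_ids(self) -> list[str]:
        used = set(self.df["parent1"]) | set(self.df["parent2"])
        return [i for i in self.df["id"] if i not in used]

    def __len__(self):
        return len(self.df)


# ---------------------------------------------------------------------------
# scheme construction


def _sort_key(node):
    return (_leaves(node), repr(node))


def build_scheme(design: DesignSpec, seed=None) -> PedigreeTable:
    """Expand a design into an explicit pedigree.

    Deterministic given ``(design, seed)``; the seed only affects the random
    pairing of the additional crossing generation.
    """
    rng = np.random.default_rng(seed)
    n = design.n_founders
    rows: list[tuple] = []

    founder_ids = [f"F{i}" for i in range(1, n + 1)]
    for fid in founder_ids:
        rows.append((fid, "", "", "founders", "founder"))

    # effective individuals available for crossing, per (canonical) subtree
    eff: dict = {i: [founder_ids[i - 1]] for i in range(1, n + 1)}

    def self_chain(pid: str, n_self: int, gen_label: str) -> str:
        cur = pid
        for k in range(1, n_self + 1):
            sid = f"{cur}s"
            rows.append((sid, cur, cur, f"{gen_label}.self{k}", "self"))
            cur = sid
        return cur

    n_funnel_gens = max(f.n_generations for f in design.funnels)

    for g in range(1, n_funnel_gens + 1):
        label = f"{2 ** g}way"
        reps = design.replicates[g - 1]
        selfs = design.selfing[g - 1]
        nodes = {}
        for f in design.funnels:
            def collect(t):
                if isinstance(t, int):
                    return
                if _generation(t) == g:
                    nodes[t] = None
                collect(t[0])
                collect(t[1])
            collect(f.tree)
        cross_no = 0
        for node in sorted(nodes, key=_sort_key):
            lefts = eff[node[0]]
            rights = eff[node[1]]
            n_inst = min(len(lefts), len(rights))
            progeny: list[str] = []
            for i in range(n_inst):
                cross_no += 1
                p1, p2 = lefts[i], rights[i]
                for r in range(1, reps + 1):
                    pid = f"{label}_{cross_no:03d}_{r}"
                    rows.append((pid, p1, p2, label, "cross"))
                    progeny.append(self_chain(pid, selfs, label))
            eff[node] = progeny

    if design.additional_cross:
        label = "addx"
        reps = design.replicates[-1]
        selfs = design.selfing[-1]
        pool: list[str] = []
        for f in design.funnels:
            pool.extend(eff[f.tree])
        if len(pool) < 2:
            raise DesignError("additional crossing needs at least two final-funnel progeny")
        n_extra = math.ceil(design.n_rils_target / reps)
        pairs = _pair_additional(pool, n_extra, rng)
        for j, (p1, p2) in enumerate(pairs, start=1):
            for r in range(1, reps + 1):
                pid = f"{label}_{j:03d}_{r}"
                rows.append((pid, p1, p2, label, "cross"))
                self_chain(pid, selfs, label)

    df = pd.DataFrame(rows, columns=COLUMNS)
    return PedigreeTable(df)


def _pair_additional(pool: Sequence[str], n_pairs: int,
                     rng: np.random.Generator) -> list[tuple[str, str]]:
    """Randomly pair final-funnel progeny for the extra crossing generation:
    a uniform draw of distinct unordered pairs of distinct individuals
    (self-crosses excluded, full-sib crosses allowed).  Only if more crosses
    are requested than distinct pairs exist are pairs reused."""
    m = len(pool)
    all_pairs = [(pool[i], pool[j]) for i in range(m) for j in range(i + 1, m)]
    out: list[tuple[str, str]] = []
    while len(out) < n_pairs:
        take = min(n_pairs - len(out), len(all_pairs))
        idx = rng.choice(len(all_pairs), size=take, replace=False)
        out.extend(all_pairs[i] for i in sorted(idx))
    return out


# ---------------------------------------------------------------------------
# summaries


def cross_counts(ped: PedigreeTable) -> tuple[dict[str, int], int]:
    """Distinct crosses per crossing generation and their total.

    A cross is a distinct unordered parent pair within a generation; selfing
    rows are excluded.  Returns ``(per_generation, total)``.
    """
    df = ped.df
    crosses = df[df["type"] == "cross"]
    per_gen: dict[str, int] = {}
    for gen, sub in crosses.groupby("generation", sort=False):
        pairs = {frozenset((a, b)) for a, b in zip(sub["parent1"], sub["parent2"])}
        per_gen[gen] = len(pairs)
    return per_gen, sum(per_gen.values())


def count_rils(ped: PedigreeTable) -> int:
    """Number of terminal individuals (rows that are nobody's parent)."""
    return len(ped.terminal_ids())


# ---------------------------------------------------------------------------
# i/o


_FOUNDER_PARENT = {"", "0", "NA", "na", "NaN", "nan", "None"}


def read_pedigree(path) -> PedigreeTable:
    """Read a pedigree from TSV/CSV (columns ``id, parent1, parent2`` with
    optional ``generation`` and ``type``).  Blank, ``NA`` or ``0`` parents
    denote founders; missing generation/type columns are inferred."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "parent1", "parent2"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree file {path} lacks column {col!r}")
    for col in ("parent1", "parent2"):
        df[col] = df[col].map(lambda v: "" if v.strip() in _FOUNDER_PARENT else v.strip())
    df["id"] = df["id"].str.strip()
    if "type" not in df.columns:
        df["type"] = [
            "founder" if not p1 and not p2 else ("self" if p1 == p2 else "cross")
            for p1, p2 in zip(df["parent1"], df["parent2"])
        ]
    if "generation" not in df.columns:
        depth: dict[str, int] = {}
        gens = []
        for row in df.itertuples(index=False):
            if row.type == "founder":
                depth[row.id] = 0
                gens.append("founders")
            else:
                d = max(depth.get(row.parent1, 0), depth.get(row.parent2, 0)) + 1
                depth[row.id] = d
                gens.append(f"gen{d}")
        df["generation"] = gens
    return PedigreeTable(df[COLUMNS].copy())


def write_pedigree(ped: PedigreeTable, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    ped.df.to_csv(path, sep=sep, index=False)
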