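"""Funnel combinatorics for MAGIC population designs.

A *funnel* is a complete crossing tree that combines every founder into a
single individual, e.g. ``((1x2)x(3x4))x((5x6)x(7x8))`` for eight founders
(written ``12345678`` for short).  Because the direction of a cross is
irrelevant, the two subtrees below any internal node may be swapped without
changing the crossing scheme: a funnel is therefore an equivalence class of
founder orderings, and the number of distinct funnels for a power-of-two
number of founders ``n`` is ``n! / 2**(n-1)``.

This module provides canonical funnel representatives, enumeration of the
full funnel space, founder-pair balance profiles, exhaustive enumeration of
the minimal balanced funnel sets for eight founders, a randomized search for
balanced sets at other founder counts, and random (unbalanced) funnel
sampling.  Designs built from these primitives are expanded into explicit
crossing schemes by :mod:`magicpop.pedigree`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Funnel",
    "DesignSpec",
    "DesignError",
    "InvalidFunnelError",
    "InfeasibleDesignError",
    "BalanceSearchError",
    "canonical_funnel",
    "count_full_funnels",
    "enumerate_full_funnels",
    "balance_profile",
    "is_balanced",
    "enumerate_balanced_sets_8",
    "count_balanced_set_orbits_8",
    "find_balanced_sets",
    "sample_unbalanced",
    "minimal_balanced_set_size",
    "basic_design",
    "full_design",
    "partial_balanced_design",
    "partial_unbalanced_design",
    "custom_design",
]

MIN_FOUNDERS = 3
MAX_FOUNDERS = 128


class DesignError(ValueError):
    """Base class for design construction errors."""


class InvalidFunnelError(DesignError):
    """A founder sequence is not a permutation of 1..n."""


class InfeasibleDesignError(DesignError):
    """The requested balanced design cannot exist (divisibility violated)."""


class BalanceSearchError(DesignError):
    """The randomized balanced-set search failed to reach exact balance."""


# ---------------------------------------------------------------------------
# trees
#
# A funnel is stored as a nested tuple: a leaf is a founder index (int >= 1),
# an internal node is a pair ``(left, right)``.  The crossing generation of a
# node is 0 for leaves and 1 + max(child generations) otherwise; with an odd
# number of items at some generation the unpaired individual simply advances,
# so for non-power-of-two founder counts the two children of a node may sit at
# different generations.


def _n_leaves(tree) -> int:
    if isinstance(tree, int):
        return 1
    return _n_leaves(tree[0]) + _n_leaves(tree[1])


def _leaves(tree) -> tuple[int, ...]:
    if isinstance(tree, int):
        return (tree,)
    return _leaves(tree[0]) + _leaves(tree[1])


def _min_leaf_any(tree) -> int:
    if isinstance(tree, int):
        return tree
    return min(_min_leaf_any(tree[0]), _min_leaf_any(tree[1]))


def _generation(tree) -> int:
    if isinstance(tree, int):
        return 0
    return 1 + max(_generation(tree[0]), _generation(tree[1]))


def _canonicalize(tree):
    """Sort children at every node: larger subtree first, then smaller
    minimum leaf.  Under the left-to-right pairing rule two children of equal
    size always have identical shapes, so this yields a unique representative
    of the swap-equivalence class."""
    if isinstance(tree, int):
        return tree
    a = _canonicalize(tree[0])
    b = _canonicalize(tree[1])
    ka = (-_n_leaves(a), _min_leaf_any(a))
    kb = (-_n_leaves(b), _min_leaf_any(b))
    return (a, b) if ka <= kb else (b, a)


def _tree_from_order(order: Sequence[int]):
    """Build the crossing tree for a founder ordering: adjacent items are
    paired at each generation and an unpaired trailing item advances."""
    items: list = list(order)
    while len(items) > 1:
        nxt = [(items[i], items[i + 1]) for i in range(0, len(items) - 1, 2)]
        if len(items) % 2:
            nxt.append(items[-1])
        items = nxt
    return items[0]


def _shape(tree):
    """Tree with every leaf replaced by 1 (used for symmetry counting)."""
    if isinstance(tree, int):
        return 1
    return (_shape(tree[0]), _shape(tree[1]))


class Funnel:
    """Canonical representative of a crossing scheme over founders ``1..n``.

    Two :class:`Funnel` objects compare equal iff they describe the same
    crossing scheme (i.e. the same unordered crossing tree).
    """

    __slots__ = ("tree", "n", "_hash")

    def __init__(self, tree, _canonical: bool = False):
        if not _canonical:
            tree = _canonicalize(tree)
        leaves = _leaves(tree)
        n = len(leaves)
        if sorted(leaves) != list(range(1, n + 1)):
            raise InvalidFunnelError(
                f"funnel leaves {leaves} are not a permutation of 1..{n}"
            )
        object.__setattr__(self, "tree", tree)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "_hash", hash(tree))

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("Funnel is immutable")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_order(cls, order: Sequence[int]) -> "Funnel":
        return cls(_tree_from_order(list(order)))

    @classmethod
    def from_text(cls, text: str) -> "Funnel":
        """Parse ``"1234"``, ``"1-2-3-4"``, ``"1 2 3 4"`` or
        ``"((1x2)x(3x4))"`` into a funnel."""
        s = text.strip()
        if "(" in s:
            tree, rest = _parse_tree(s.replace("×", "x"))
            if rest.strip():
                raise InvalidFunnelError(f"trailing text in funnel {text!r}")
            return cls(tree)
        if "-" in s:
            order = [int(t) for t in s.split("-")]
        elif any(c.isspace() for c in s) or "," in s:
            order = [int(t) for t in s.replace(",", " ").split()]
        else:
            if not s.isdigit():
                raise InvalidFunnelError(f"cannot parse funnel {text!r}")
            order = [int(c) for c in s]
        return cls.from_order(order)

    # -- views --------------------------------------------------------------
    @property
    def order(self) -> tuple[int, ...]:
        """Founder indices at the leaves, left to right."""
        return _leaves(self.tree)

    @property
    def n_generations(self) -> int:
        """Number of crossing generations (``ceil(log2 n)``)."""
        return _generation(self.tree)

    def pairs_by_generation(self) -> dict[int, list[tuple[int, int]]]:
        """Unordered founder pairs brought together at each crossing
        generation: within a two-way cross at generation 1, and for deeper
        nodes all founder pairs spanning the two merged subtrees."""
        out: dict[int, list[tuple[int, int]]] = {}

        def walk(t):
            if isinstance(t, int):
                return
            g = _generation(t)
            pairs = out.setdefault(g, [])
            for a in _leaves(t[0]):
                for b in _leaves(t[1]):
                    pairs.append((a, b) if a < b else (b, a))
            walk(t[0])
            walk(t[1])

        walk(self.tree)
        return out

    def text(self, nested: bool = False) -> str:
        if nested:
            def fmt(t):
                if isinstance(t, int):
                    return str(t)
                return f"({fmt(t[0])}x{fmt(t[1])})"
            return fmt(self.tree)
        if self.n <= 9:
            return "".join(str(i) for i in self.order)
        return "-".join(str(i) for i in self.order)

    # -- dunder -------------------------------------------------------------
    def __eq__(self, other):
        return isinstance(other, Funnel) and self.tree == other.tree

    def __hash__(self):
        return self._hash

    def __lt__(self, other):
        return self.order < other.order

    def __repr__(self):
        return f"Funnel({self.text()!r})"

    def __str__(self):
        return self.text()


def _parse_tree(s: str):
    s = s.lstrip()
    if s.startswith("("):
        left, rest = _parse_tree(s[1:])
        rest = rest.lstrip()
        if not rest.startswith("x"):
            raise InvalidFunnelError(f"expected 'x' in funnel near {rest!r}")
        right, rest = _parse_tree(rest[1:])
        rest = rest.lstrip()
        if not rest.startswith(")"):
            raise InvalidFunnelError(f"unbalanced parentheses near {rest!r}")
        return (left, right), rest[1:]
    i = 0
    while i < len(s) and s[i].isdigit():
        i += 1
    if i == 0:
        raise InvalidFunnelError(f"expected founder index near {s!r}")
    return int(s[:i]), s[i:]


def canonical_funnel(order: Sequence[int] | str | Funnel) -> Funnel:
    """Map a founder ordering to the canonical representative of its
    equivalence class; all orderings obtained by swapping the two subtrees
    below any internal node map to the same :class:`Funnel`."""
    if isinstance(order, Funnel):
        return order
    if isinstance(order, str):
        return Funnel.from_text(order)
    return Funnel.from_order(order)


# ---------------------------------------------------------------------------
# counting and enumeration


def _symmetric_nodes(shape) -> int:
    if isinstance(shape, int):
        return 0
    s = _symmetric_nodes(shape[0]) + _symmetric_nodes(shape[1])
    if shape[0] == shape[1]:
        s += 1
    return s


def count_full_funnels(n: int) -> int:
    """Number of distinct funnels for ``n`` founders.

    For power-of-two ``n`` this is ``n!/2**(n-1)``; in general it is
    ``n!/2**s`` where ``s`` counts the internal nodes of the crossing tree
    whose two child subtrees have identical shape (all ``n - 1`` of them when
    ``n`` is a power of two).
    """
    if not isinstance(n, int) or n < 2:
        raise DesignError(f"founder count must be an integer >= 2, got {n}")
    if n > MAX_FOUNDERS:
        raise DesignError(f"founder count {n} exceeds the supported maximum {MAX_FOUNDERS}")
    shape = _shape(_tree_from_order(range(1, n + 1)))
    s = _symmetric_nodes(shape)
    count, rem = divmod(math.factorial(n), 2 ** s)
    assert rem == 0
    return count


def _enum_labelled(shape, founders: tuple[int, ...]) -> Iterator:
    """All canonical trees of the given shape over the given founder set."""
    if isinstance(shape, int):
        yield founders[0]
        return
    k = _n_leaves(shape[0])
    if shape[0] == shape[1]:
        # canonical: smallest founder goes in the left subtree
        first, rest = founders[0], founders[1:]
        for combo in itertools.combinations(rest, k - 1):
            left = (first,) + combo
            right = tuple(f for f in rest if f not in combo)
            for lt in _enum_labelled(shape[0], left):
                for rt in _enum_labelled(shape[1], right):
                    yield (lt, rt)
    else:
        for combo in itertools.combinations(founders, k):
            right = tuple(f for f in founders if f not in combo)
            for lt in _enum_labelled(shape[0], combo):
                for rt in _enum_labelled(shape[1], right):
                    yield (lt, rt)


def enumerate_full_funnels(n: int, lazy: bool = False):
    """All distinct funnels for ``n`` founders, each exactly once.

    Returns a list unless ``lazy`` is true, in which case an iterator is
    returned; a list is refused for spaces above one million funnels (the
    16-founder space alone has ``16!/2**15`` members).
    """
    total = count_full_funnels(n)
    shape = _shape(_tree_from_order(range(1, n + 1)))
    gen = (Funnel(t, _canonical=True) for t in _enum_labelled(shape, tuple(range(1, n + 1))))
    if lazy:
        return gen
    if total > 1_000_000:
        raise DesignError(
            f"{total} funnels for n={n} will not be materialized; pass lazy=True"
        )
    return list(gen)


# ---------------------------------------------------------------------------
# balance


def balance_profile(funnels: Sequence[Funnel]) -> dict[int, dict[tuple[int, int], int]]:
    """Per crossing generation, co-occurrence counts of unordered founder
    pairs across a funnel set.  Pairs never brought together at a generation
    are absent from that generation's map (count zero)."""
    funnels = [canonical_funnel(f) for f in funnels]
    if not funnels:
        raise DesignError("empty funnel list")
    n = funnels[0].n
    if any(f.n != n for f in funnels):
        raise DesignError("funnels mix different founder counts")
    profile: dict[int, dict[tuple[int, int], int]] = {}
    for f in funnels:
        for g, pairs in f.pairs_by_generation().items():
            gp = profile.setdefault(g, {})
            for p in pairs:
                gp[p] = gp.get(p, 0) + 1
    return profile


def is_balanced(funnels: Sequence[Funnel]) -> bool:
    """True iff every founder appears equally often across the funnels and
    every founder pair has the same co-occurrence count within each crossing
    generation (a pair absent at a generation counts as zero)."""
    funnels = [canonical_funnel(f) for f in funnels]
    if not funnels:
        raise DesignError("empty funnel list")
    n = funnels[0].n
    founder_counts = [0] * (n + 1)
    for f in funnels:
        for i in f.order:
            founder_counts[i] += 1
    if len(set(founder_counts[1:])) != 1:
        return False
    n_pairs = n * (n - 1) // 2
    profile = balance_profile(funnels)
    for gp in profile.values():
        counts = list(gp.values())
        if len(gp) < n_pairs and counts:
            return False  # some pair has count 0 while others do not
        if len(set(counts)) > 1:
            return False
    return True


# ---------------------------------------------------------------------------
# balanced 7-funnel sets for eight founders
#
# The two-way level of a minimal balanced set must place every founder pair
# exactly once, i.e. the seven matchings form a 1-factorization of the
# complete graph K8.  Each matching's four pairs are then grouped into two
# four-way quads (three ways per funnel); the set is balanced iff every pair
# occurs exactly twice at the four-way level, the eight-way count of four per
# pair then being automatic (each pair meets exactly once per funnel).


def _k8_matchings() -> list[list[tuple[int, int]]]:
    def rec(verts):
        if not verts:
            yield []
            return
        a = verts[0]
        for i in range(1, len(verts)):
            b = verts[i]
            for m in rec(verts[1:i] + verts[i + 1:]):
                yield [(a, b)] + m

    return list(rec(list(range(1, 9))))


@lru_cache(maxsize=1)
def _k8_factorizations() -> tuple:
    pair_index = {}
    k = 0
    for i in range(1, 9):
        for j in range(i + 1, 9):
            pair_index[(i, j)] = k
            k += 1
    matchings = _k8_matchings()
    bits = []
    for m in matchings:
        b = 0
        for e in m:
            b |= 1 << pair_index[e]
        bits.append(b)
    by_partner: dict[int, list] = {x: [] for x in range(2, 9)}
    for m, b in zip(matchings, bits):
        for (a, c) in m:
            if a == 1:
                by_partner[c].append((m, b))
    out = []

    def extend(partner, used, acc):
        if partner == 9:
            out.append(tuple(acc))
            return
        for m, b in by_partner[partner]:
            if not (b & used):
                acc.append(m)
                extend(partner + 1, used | b, acc)
                acc.pop()

    extend(2, 0, [])
    return tuple(out)


def _quad_groupings(matching):
    p1, p2, p3, p4 = matching
    for qa, qb in (((p1, p2), (p3, p4)), ((p1, p3), (p2, p4)), ((p1, p4), (p2, p3))):
        cross_pairs = []
        for x, y in (qa, qb):
            for a in x:
                for b in y:
                    cross_pairs.append((a, b) if a < b else (b, a))
        yield (qa, qb), cross_pairs


@lru_cache(maxsize=1)
def enumerate_balanced_sets_8() -> tuple[frozenset, ...]:
    """Exhaustively enumerate the minimal balanced funnel sets for eight
    founders: unordered sets of seven funnels whose founder-pair profile is
    exactly (1, 2, 4) per pair at the two-, four- and eight-way generations.

    Returns the sets as frozensets of canonical :class:`Funnel` objects (720
    sets, counted without quotienting by founder relabeling).
    """
    pair_index = {}
    k = 0
    for i in range(1, 9):
        for j in range(i + 1, 9):
            pair_index[(i, j)] = k
            k += 1
    sets = []
    for fac in _k8_factorizations():
        options = [
            [(quads, [pair_index[p] for p in pairs]) for quads, pairs in _quad_groupings(m)]
            for m in fac
        ]
        counts = [0] * 28
        chosen: list = [None] * 7

        def rec(i):
            if i == 7:
                funnels = []
                for (qa, qb) in chosen:
                    order = qa[0] + qa[1] + qb[0] + qb[1]
                    funnels.append(Funnel.from_order(order))
                sets.append(frozenset(funnels))
                return
            for quads, pairs in options[i]:
                ok = True
                for p in pairs:
                    counts[p] += 1
                    if counts[p] > 2:
                        ok = False
                if ok:
                    chosen[i] = quads
                    rec(i + 1)
                for p in pairs:
                    counts[p] -= 1

        rec(0)
    return tuple(sets)


def count_balanced_set_orbits_8() -> int:
    """Number of minimal balanced 8-founder funnel sets counted up to founder
    relabeling (orbits of the 720 sets under permutations of the founders)."""
    sets = {s: i for i, s in enumerate(enumerate_balanced_sets_8())}
    seen = [False] * len(sets)
    # transpositions (i, i+1) generate S8
    orbits = 0
    for s, i in sets.items():
        if seen[i]:
            continue
        orbits += 1
        stack = [s]
        seen[i] = True
        while stack:
            cur = stack.pop()
            for a in range(1, 8):
                swapped = frozenset(
                    Funnel.from_order(
                        [a + 1 if x == a else a if x == a + 1 else x for x in f.order]
                    )
                    for f in cur
                )
                j = sets[swapped]  # relabeling preserves balance
                if not seen[j]:
                    seen[j] = True
                    stack.append(swapped)
    return orbits


# ---------------------------------------------------------------------------
# balanced-set construction


def _pairs_per_generation(n: int) -> dict[int, int]:
    f = Funnel.from_order(range(1, n + 1))
    return {g: len(p) for g, p in f.pairs_by_generation().items()}


def minimal_balanced_set_size(n: int) -> int:
    """Smallest number of funnels that satisfies the necessary divisibility
    condition for exact balance: at every crossing generation the pair slots
    contributed by the set must split evenly over all C(n, 2) founder pairs.
    For power-of-two ``n`` this is ``n - 1``."""
    n_pairs = n * (n - 1) // 2
    per_gen = _pairs_per_generation(n)
    f = 1
    while f <= n_pairs:
        if all((f * m) % n_pairs == 0 for m in per_gen.values()):
            return f
        f += 1
    raise InfeasibleDesignError(
        f"no funnel-set size up to {n_pairs} satisfies the balance divisibility "
        f"condition for n={n}"
    )


def _random_funnel(n: int, rng: np.random.Generator) -> Funnel:
    return Funnel.from_order(rng.permutation(np.arange(1, n + 1)).tolist())


def _imbalance(funnels: Sequence[Funnel], n: int) -> float:
    """Sum over generations of the variance of pair co-occurrence counts
    (zero iff the set is exactly balanced, given equal founder use)."""
    n_pairs = n * (n - 1) // 2
    profile = balance_profile(funnels)
    total = 0.0
    for gp in profile.values():
        counts = np.zeros(n_pairs)
        counts[: len(gp)] = np.fromiter(gp.values(), dtype=float, count=len(gp))
        total += counts.var()
    return total


def _anneal_balanced(n: int, n_funnels: int, rng: np.random.Generator,
                     max_iters: int = 200_000, restarts: int = 8) -> list[Funnel]:
    best_energy = math.inf
    for _ in range(restarts):
        state = [_random_funnel(n, rng) for _ in range(n_funnels)]
        energy = _imbalance(state, n)
        temp0 = max(energy, 1.0)
        for it in range(max_iters):
            if energy == 0.0:
                return state
            temp = temp0 * (1.0 - it / max_iters) + 1e-3
            i = int(rng.integers(n_funnels))
            old = state[i]
            if rng.random() < 0.5:
                state[i] = _random_funnel(n, rng)
            else:
                order = list(old.order)
                a, b = rng.choice(n, size=2, replace=False)
                order[a], order[b] = order[b], order[a]
                state[i] = Funnel.from_order(order)
            new_energy = _imbalance(state, n)
            if new_energy <= energy or rng.random() < math.exp((energy - new_energy) / temp):
                energy = new_energy
            else:
                state[i] = old
        best_energy = min(best_energy, energy)
    raise BalanceSearchError(
        f"no exactly balanced set of {n_funnels} funnels found for n={n} "
        f"(best residual imbalance {best_energy:.3g}); an unbalanced result is "
        f"never returned silently"
    )


def find_balanced_sets(n: int, n_sets: int = 1, seed=None) -> list[Funnel]:
    """Return ``n_sets`` minimal balanced funnel sets as one flat funnel list.

    For four founders the unique minimal set is the full design {1234, 1324,
    1423}; for eight founders sets are drawn from the exhaustive enumeration
    and, when more than one is requested, combined so that no funnel is
    reused; for other founder counts a seeded annealing search over funnel
    replacements and founder swaps is run and only an exactly balanced result
    is accepted.
    """
    if not 4 <= n <= 16:
        raise DesignError(f"balanced designs are supported for 4..16 founders, got {n}")
    if n_sets < 1:
        raise DesignError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    size = minimal_balanced_set_size(n)
    if n == 4:
        if n_sets > 1:
            raise InfeasibleDesignError(
                "only three funnels exist for four founders; a second "
                "non-overlapping balanced set is impossible"
            )
        funnels = [Funnel.from_text(t) for t in ("1234", "1324", "1423")]
    elif n == 8:
        all_sets = enumerate_balanced_sets_8()
        for _ in range(1000):
            order = rng.permutation(len(all_sets))
            chosen: list[frozenset] = []
            used: set[Funnel] = set()
            for idx in order:
                s = all_sets[idx]
                if used.isdisjoint(s):
                    chosen.append(s)
                    used.update(s)
                    if len(chosen) == n_sets:
                        break
            if len(chosen) == n_sets:
                break
        else:
            raise InfeasibleDesignError(
                f"could not assemble {n_sets} pairwise non-overlapping balanced "
                f"sets for n=8"
            )
        funnels = sorted(f for s in chosen for f in s)
    else:
        funnels = _anneal_balanced(n, n_sets * size, rng)
    assert is_balanced(funnels)
    return funnels


# ---------------------------------------------------------------------------
# random funnel sampling


def sample_unbalanced(n: int, n_funnels: int, seed=None) -> list[Funnel]:
    """Uniformly sample ``n_funnels`` distinct funnels for ``n`` founders.

    All equivalence classes have the same size, so canonicalizing uniform
    random founder orderings samples classes uniformly; for small spaces the
    full enumeration is used directly.
    """
    total = count_full_funnels(n)
    if not 1 <= n_funnels <= total:
        raise DesignError(
            f"requested {n_funnels} distinct funnels but only {total} exist for n={n}"
        )
    rng = np.random.default_rng(seed)
    if total <= 100_000:
        space = sorted(enumerate_full_funnels(n))
        idx = rng.choice(total, size=n_funnels, replace=False)
        return [space[i] for i in sorted(idx)]
    out: list[Funnel] = []
    seen: set[Funnel] = set()
    while len(out) < n_funnels:
        f = _random_funnel(n, rng)
        if f not in seen:
            seen.add(f)
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# design specifications


DESIGN_TYPES = ("full", "partial_balanced", "partial_unbalanced", "basic", "custom")


@dataclass(frozen=True)
class DesignSpec:
    """A MAGIC design: founders, funnels, and the per-generation crossing
    schedule.

    ``replicates[g]`` is the number of seeds retained from each cross at
    crossing generation ``g + 1`` and ``selfing[g]`` the number of selfing
    generations applied to those progeny before the next cross; both vectors
    have one entry per crossing generation, plus one for the additional
    crossing generation when ``additional_cross`` is set.  The additional
    generation randomly inter-crosses the final-funnel progeny until
    ``n_rils_target`` RILs can be produced.
    """

    n_founders: int
    design_type: str
    funnels: tuple[Funnel, ...]
    replicates: tuple[int, ...]
    selfing: tuple[int, ...]
    additional_cross: bool = False
    n_funnel_sets: int = 0
    n_rils_target: int | None = None
    name: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "funnels", tuple(canonical_funnel(f) for f in self.funnels))
        object.__setattr__(self, "replicates", tuple(int(r) for r in self.replicates))
        object.__setattr__(self, "selfing", tuple(int(s) for s in self.selfing))
        self.validate()

    @property
    def n_crossing_generations(self) -> int:
        base = max(f.n_generations for f in self.funnels)
        return base + (1 if self.additional_cross else 0)

    def validate(self) -> None:
        n = self.n_founders
        if not MIN_FOUNDERS <= n <= MAX_FOUNDERS:
            raise DesignError(
                f"number of founders must be between {MIN_FOUNDERS} and "
                f"{MAX_FOUNDERS}, got {n}"
            )
        if self.design_type not in DESIGN_TYPES:
            raise DesignError(f"unknown design type {self.design_type!r}")
        if not self.funnels:
            raise DesignError("a design needs at least one funnel")
        if any(f.n != n for f in self.funnels):
            raise DesignError("funnel founder count does not match n_founders")
        if len(set(self.funnels)) != len(self.funnels):
            raise DesignError("duplicate funnels in design")
        g = self.n_crossing_generations
        if len(self.replicates) != g or len(self.selfing) != g:
            raise DesignError(
                f"replicates and selfing vectors must have length {g} "
                f"(one per crossing generation), got {len(self.replicates)} "
                f"and {len(self.selfing)}"
            )
        if any(r < 1 for r in self.replicates):
            raise DesignError("replicates must be positive integers")
        if any(s < 0 for s in self.selfing):
            raise DesignError("selfing generations must be non-negative")
        if self.design_type == "basic" and len(self.funnels) != 1:
            raise DesignError("a basic design has exactly one funnel")
        if self.design_type == "full" and len(self.funnels) != count_full_funnels(n):
            raise DesignError(
                f"a full design for n={n} needs {count_full_funnels(n)} funnels"
            )
        if self.additional_cross and self.n_rils_target is None:
            raise DesignError(
                "additional_cross requires n_rils_target to size the extra "
                "crossing generation"
            )


def _default_schedule(n_gens: int, replicates, selfing, final_selfing: int = 4):
    if replicates is None:
        replicates = (1,) * n_gens
    if selfing is None:
        selfing = (0,) * (n_gens - 1) + (final_selfing,)
    return tuple(replicates), tuple(selfing)


def basic_design(n: int, replicates=None, selfing=None, additional_cross=False,
                 n_rils_target=None, name=None) -> DesignSpec:
    """Single funnel in founder order 1..n (the classic MAGIC pedigree)."""
    funnel = Funnel.from_order(range(1, n + 1))
    g = funnel.n_generations + (1 if additional_cross else 0)
    replicates, selfing = _default_schedule(g, replicates, selfing)
    return DesignSpec(n, "basic", (funnel,), replicates, selfing,
                      additional_cross=additional_cross,
                      n_rils_target=n_rils_target, name=name)


def full_design(n: int, replicates=None, selfing=None, name=None) -> DesignSpec:
    funnels = tuple(sorted(enumerate_full_funnels(n)))
    g = max(f.n_generations for f in funnels)
    replicates, selfing = _default_schedule(g, replicates, selfing)
    return DesignSpec(n, "full", funnels, replicates, selfing, name=name)


def partial_balanced_design(n: int, n_sets: int = 1, seed=None, replicates=None,
                            selfing=None, name=None) -> DesignSpec:
    funnels = tuple(find_balanced_sets(n, n_sets, seed))
    g = max(f.n_generations for f in funnels)
    replicates, selfing = _default_schedule(g, replicates, selfing)
    return DesignSpec(n, "partial_balanced", funnels, replicates, selfing,
                      n_funnel_sets=n_sets, name=name)


def partial_unbalanced_design(n: int, n_funnels: int, seed=None, replicates=None,
                              selfing=None, name=None) -> DesignSpec:
    funnels = tuple(sample_unbalanced(n, n_funnels, seed))
    g = max(f.n_generations for f in funnels)
    replicates, selfing = _default_schedule(g, replicates, selfing)
    return DesignSpec(n, "partial_unbalanced", funnels, replicates, selfing, name=name)


def custom_design(funnels: Sequence, replicates=None, selfing=None,
                  additional_cross=False, n_rils_target=None, name=None) -> DesignSpec:
    funnels = tuple(canonical_funnel(f) for f in funnels)
    n = funnels[0].n
    g = max(f.n_generations for f in funnels) + (1 if additional_cross else 0)
    replicates, selfing = _default_schedule(g, replicates, selfing)
    return DesignSpec(n, "custom", funnels, replicates, selfing,
                      additional_cross=additional_cross,
                      n_rils_target=n_rils_target, name=name)
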