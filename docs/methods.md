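# Methods

`magicpop` creates MAGIC (multiparental advanced generation inter-cross)
crossing designs, expands them into explicit pedigrees, simulates
founder-labeled recombinant inbred line (RIL) populations through those
pedigrees, and scores the resulting recombination landscape.  This note
records the models, the conventions, and the design choices made where the
problem left genuine freedom.

## Funnels and their equivalence

A funnel over `n` founders is a complete crossing tree: for `n = 8`,
two-way crosses `(1x2) (3x4) (5x6) (7x8)`, two four-way crosses, one
eight-way cross.  Because the direction of a cross carries no information,
swapping the two subtrees below any internal node yields the same crossing
scheme; a funnel is the equivalence class under all such swaps.  With `n` a
power of two a class has `2^(n-1)` member orderings, so the full design has
`n!/2^(n-1)` funnels — 3 for four founders, 315 for eight.

Funnels are stored canonically: at every node the subtree with more leaves
comes first, and between equal-sized subtrees the one containing the
smaller founder index.  Two `Funnel` objects therefore compare equal
exactly when they describe the same scheme.

**Non-power-of-two founder counts.**  The crossing tree is built by pairing
adjacent individuals left to right at each generation, an unpaired
individual advancing unchanged.  This fixes a tree shape per `n`, under
which only nodes whose two child subtrees have identical shape can swap, so
the number of distinct funnels is `n!/2^s` with `s` the number of such
symmetric nodes.  This closed form replaces brute-force canonicalization of
all `n!` orderings (intractable beyond `n ≈ 10`); the two agree for every
`n ≤ 8`, which the test suite checks by enumeration.

## Balanced funnel sets

A funnel set is balanced when every founder is used equally often and every
unordered founder pair is brought together equally often at each crossing
generation.  Because any pair meets exactly once per funnel, a minimal
balanced 8-founder set of seven funnels must realize per-pair counts
(1, 2, 4) at the two-, four- and eight-way generations, and the seven
two-way levels must form a 1-factorization of the complete graph K8.
`enumerate_balanced_sets_8` therefore enumerates the 6240 one-factorizations
of K8 and, per factorization, backtracks over the three possible four-way
groupings of each matching with count pruning.  The eight-way condition is
then automatic.  This finds exactly 720 sets in about a second.  The 720
count unordered sets of canonical funnels *without* quotienting by founder
relabeling; under relabeling they collapse to a single orbit (all 720 are
renamings of one scheme), which `count_balanced_set_orbits_8` reports.

Minimal balanced sets for eight founders are pairwise combinable when they
share no funnel; `find_balanced_sets(8, k)` assembles `k` non-overlapping
sets by randomized greedy selection from the 720.  For four founders the
unique minimal set is the full design `{1234, 1324, 1423}`.  For other
founder counts no enumeration is attempted: a seeded simulated-annealing
search over funnel replacements and founder swaps minimizes the summed
per-generation variance of pair counts and accepts **only** exact balance
(imbalance zero); failure raises an error rather than returning a silently
unbalanced set.  The necessary divisibility condition (pair slots per
generation must split evenly over all C(n,2) pairs) is exposed as
`minimal_balanced_set_size`; note it forces 15 funnels for n = 6, not n−1.

## Pedigree expansion

`build_scheme` turns a design into a table of individuals (id, parents,
generation label, row type), founders first, parents always before
children.  Conventions:

* **Cross deduplication.**  Funnels sharing a subtree share its cross: the
  315-funnel full design uses C(8,2) = 28 two-way and C(8,2)·C(6,2)/2 = 210
  four-way crosses.
* **Replicates.**  `replicates[g]` seeds are retained per cross at crossing
  generation `g+1`; each replicate is an independent meiosis.  When a
  cross's parents are themselves replicated, the cross is instantiated once
  per replicate pair (replicate *i* × replicate *i*), so one balanced set
  (7 funnels) with replicates (1, 9, 15) yields 28/14/63 crosses and
  63 × 15 = 945 RILs.
* **Selfing** is single seed descent: `selfing[g]` chained self rows per
  progeny, the chain's terminal being the individual used downstream.
* **Additional crossing generation.**  The final-funnel progeny are
  inter-crossed at random: a uniform draw of distinct unordered pairs of
  distinct individuals, with `ceil(n_rils_target / final_replicates)`
  crosses.  Full-sib pairs are *not* avoided: engineered sib avoidance
  (e.g. shuffled-pass pairing in which every individual participates
  equally) measurably inflates haplotype diversity relative to plain random
  pairing, and plain pairing is what an unstructured extra generation
  means here.  With 16 eight-way progeny, a 960-RIL target and 15 seeds
  per cross this gives the 64 extra crosses of the basic-plus-extra-cross
  reference design.

## Recombination model

Meiosis follows Haldane's model: per chromosome the crossover count is
Poisson with mean `L/100` (length in Morgans), crossover positions are
i.i.d. uniform, the starting homolog is a fair coin, and the homolog
alternates at each crossover.  There is no interference and no obligate
chiasma; inter-crossover distances are exponential with mean 100 cM and
two-locus recombinant fractions follow `r(d) = (1 − e^(−2d/100))/2`.  The
no-obligate-chiasma choice matters only for very short chromosomes and is
asserted nowhere; the test suite checks the Poisson mean, the exponential
gaps, and the closed-form recombinant fractions by Monte Carlo.

Genomes are tracked as founder-labeled segments — per chromosome an ordered
list of `(end, founder)` records tiling `[0, L)` in merged form (adjacent
segments always carry different founders).  This is mathematically
equivalent to tracking founder identity at a dense marker grid but keeps
breakpoints exact and is much cheaper; `to_marker_labels` discretizes on
demand and can only ever hide, never create, breakpoints.  Founders are
fully inbred (homozygous); heterozygous founders are out of scope.
Coordinates are cM, 0-based, half-open; a marker at position `L` takes the
final segment's label.

Randomness: one master seed; per-design and per-iteration substreams are
spawned deterministically (`numpy` `SeedSequence`), so iterations can be
computed in any order with identical results, and a whole run is
reproducible byte for byte.

## Metrics

Scored on a marker grid with interval `d` (default 5 cM; `d` must be a
multiple of the marker spacing — misalignment is an error, never silent
rounding):

* **Total recombinant-haplotype proportion** — fraction of `d`-intervals
  whose flanking founder labels differ, averaged over homologs and RILs.
* **Unique recombinant haplotypes** — with `n` founders there are
  `n² − n` ordered flanking-founder pairs (56 for `n = 8`).  The metric is
  the number of distinct ordered pairs observed *per interval*, averaged
  over intervals.  A population-wide tally saturates at `n² − n` for any
  realistic population size and cannot discriminate designs; the
  interval-resolved count is what responds to replicate sharing and to
  locally fixed parents (an extra selfing generation *raises* total
  recombination yet *lowers* this metric, because selfed parents are
  locally homozygous and their gametes locally less diverse).  The
  population-wide tally remains available as `observed_pair_count`.
* **Per-pair mean counts** per RIL; in single-funnel (basic) designs the
  eight two-way ordered pairs run about twice the level of the other 48,
  because two-way crosses recombine the largest founder genome blocks.
* **Founder genome proportions** — genome-length-weighted, homolog-averaged;
  the founder-mean is exactly `1/n` by construction (segments tile the
  genome), while per-founder deviations measure design skew.
* **Founder tracts** — distinct founders per chromosome per RIL (union of
  homologs) and **mean non-recombinant segment length** per chromosome.

Residual heterozygosity after finite selfing (about 6% after four
generations) is handled by averaging the two homologs for proportions and
counts and by union for tracts; `homologs=1` scores a single haplotype per
RIL instead.  Recombinant haplotypes of the same ordered pair falling in
the same fixed-width bin (anchored at position 0 of each chromosome) are
classified *identical*, otherwise *unique* (`unique_identical_bins`); PRHR
(proportion of recombinant haplotypes recovered) is the observed haplotype
count divided by the true simulated count, and is monotone non-increasing
under grid coarsening because nested grids can only hide switches.

A note on spread: the variance of the per-interval switch proportion across
intervals (see `interval_switch_proportions`) is the quantity that
separates designs sharply — roughly 2×10⁻⁴ for the full design, 3×10⁻⁴ for
one balanced set with heavy replication, and 4×10⁻³ for the
basic-plus-extra-cross design, because replicate sharing concentrates the
same breakpoints in many RILs.  Across-iteration variance of the means is
two orders of magnitude smaller and orders the designs the same way.

## Reference designs and problem sizes

The comparisons in the tests and in `scripts/acceptance.py` use a fictitious
genome of five chromosomes of 1.0, 1.5, 2.0, 2.5, 3.0 Morgans, 5 cM marker
spacing and 5 cM scoring intervals, and eight-founder designs sized to
~1000 RILs: the full design (315 funnels, replicates (1,1,3), selfing
(0,0,4), 945 RILs), one balanced funnel set (replicates (1,9,15), 945
RILs), and the basic design with one extra inter-crossing generation
(replicates (1,4,4,15), selfing (0,0,0,4), 960 RILs).  Summary statistics
are averaged over 100 simulation iterations; at that depth the Monte-Carlo
standard error of the total proportion is below 0.001 and of the unique
count below 0.2.

## What the simulations do and do not show

The simulator emulates idealized populations: a uniform recombination rate
along each chromosome (no hot or cold spots), no interference, fully inbred
founders, no genotyping error, no missing data, no selection or segregation
distortion, and founder identity observable directly rather than inferred
from biallelic markers through an HMM.  Passing tests therefore validate
the combinatorics, the pedigree bookkeeping and the neutral recombination
model — they do not predict absolute haplotype counts in a real population,
where marker informativeness and inference error reduce recovery
substantially.  Founder-call matrices produced by external inference tools
can be scored with the same metrics via `calls_recombinant_haplotypes`.

## Known limitations

* Balanced-set construction beyond 4, 5 and 8 founders relies on annealing;
  for 16 founders reaching exact balance may exceed the default search
  budget and then errors out (by design).  A constructive search for 16
  founders is future work.
* The full design is only materializable for `n ≤ 8`; larger spaces are
  exposed lazily.
* Unstructured and semi-structured schemes are supported only through
  user-supplied pedigrees.
* Chromosomes are modelled independently; there is no obligate crossover,
  so a very short chromosome can pass through meiosis unrecombined more
  often than some organisms show in practice.
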