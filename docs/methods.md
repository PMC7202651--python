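# Methods

This note documents the models, conventions and numerical choices behind
`morphoclade`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what
the validation suite does and does not demonstrate.

## Character matrices and cell semantics

A matrix is a taxa × characters grid of state *sets*. Three cell kinds are
distinguished throughout:

- **scored monomorphic** — one integer state code;
- **scored polymorphic** — two or more codes, read as "any member state"
  (the convention used when ontogenetically variable characters are scored
  as multi-states);
- **missing (`?`) and inapplicable (`-`)** — no codes of their own.

For parsimony scoring, missing and inapplicable cells are both treated as
full wildcards over the observed state universe of their column; for MORD
distances both are "unscored" and excluded from pairwise comparability.
Treating inapplicable like missing is deliberate: standard parsimony
software conflates them by default, and no separate step-cost model for
inapplicability is attempted here. Polymorphic cells cost nothing to match
any member state; the alternative "polymorphism as extra steps" costing is
out of scope.

Character ids are 1-based in input-file order and survive every taxon or
character subsetting, so synapomorphy reports and character-subset files
always cite the original numbering. State codes are used as printed, never
remapped. NEXUS reading is delegated to dendropy (both `{}` and `()`
polymorphism delimiters are accepted); the writer emits `{}`, replaces
label whitespace with underscores, and can embed a provenance comment line.

## Tree length and ensemble indices

Length on a fixed binary tree is Fitch optimization generalized to
ambiguity sets, implemented over per-column integer bitmasks so all
characters are scored in one vectorized pass (state codes up to 62). The
tree is rooted on the pendant edge of the smallest leaf purely for
traversal; length is invariant to that choice.

Per-character bounds:

- **m<sub>i</sub>** (minimum over all trees) is computed exactly as (size of
  a minimum hitting set of the scored cells' state sets) − 1, by
  enumeration over subsets of the observed universe (universes in
  morphological data are tiny, so this is cheap and exact).
- **g<sub>i</sub>** (maximum, equivalently the star-tree score) resolves
  each ambiguous cell to whichever member state is most frequent among the
  monomorphic scored cells, ties to the lowest code, then counts scored
  cells minus the largest resolved class. The resolution rule is
  deterministic and matches common CI/RI implementations.

CI = Σm/L and RI = (Σg − L)/(Σg − Σm) are reported with explicit undefined
flags (`None`) when L = 0 or Σg = Σm. Because conventions differ on whether
parsimony-uninformative characters are included, `consistency_index` takes
an `informative_only` flag that removes characters with m<sub>i</sub> =
g<sub>i</sub> from both numerator and denominator; both variants are thus
available side by side.

Synapomorphy mapping picks one most-parsimonious reconstruction per
character by a unit-cost Sankoff backtrace on the tree rooted at the
outgroup. Ties are broken toward change (ACCTRAN-style acceleration) by
default, away from change with `mode="deltran"`; either way the number of
reported changes per character equals its Fitch step count, so listed
changes always sum to L.

## Heuristic search protocol

The search replicates the traditional protocol of parsimony packages:

1. per replicate, a random taxon addition order (seeded generator), a
   greedy Wagner build (each taxon inserted on the branch minimizing the
   resulting length, ties to the earliest branch in a deterministic edge
   ordering);
2. TBR branch swapping: every branch is bisected and the two fragments
   reconnected across all attachment-branch pairs; strictly shorter trees
   restart the pool, equal-length trees accumulate up to
   `hold_per_replicate`;
3. replicate pools are merged, trimmed to the best length, deduplicated by
   bipartition set and capped at `max_trees` with an overflow flag.

Defaults (1000 replicates, hold 1000, max 99 999 trees, 5000 bootstrap
replicates, Bremer depth 10) mirror a full empirical analysis; tests and
bootstrap inner searches scale them down by configuration, never by code
changes. MPT *counts* are reported as lower bounds whenever the overflow
flag is set, because held-tree counts are search-implementation artifacts;
tree length, CI and RI are the binding outputs.

One property of TBR worth stating explicitly: a single move preserves every
bipartition internal to each fragment, so the one-move neighborhood at
n = 5 contains 12 distinct alternative topologies (the 2(n−3)(2n−7) bound),
not all 14. Optimality does not suffer — the fuzz suite verifies that
Wagner + TBR search finds the globally minimal length on every enumerable
instance tried — but single-move reachability is bounded.

**Bootstrap** resamples characters with replacement to the original count
and scores a bipartition when it appears in the replicate's strict
consensus ("absolute frequencies"). Each replicate runs a scaled-down inner
search (default 10 addition replicates, hold 10) — running thousands of
full searches is cluster-scale and changes support values only marginally;
the inner effort is a config knob.

**Bremer decay** accumulates, by TBR from the MPT pool, every tree within
`bremer_max_decay` extra steps (up to `bremer_hold` trees); the decay of a
consensus clade is the smallest extra length at which an accumulated tree
lacks it. Clades surviving to the depth limit are reported censored
("k+"), a lower bound. This accumulation approach is deterministic and
directly verifiable against exhaustive topology enumeration at small n,
which the tests do.

All tie-breaking (edge order, tree order, dictionary insertion) is
deterministic, so a fixed seed gives byte-identical outputs.

## Disparity pipeline

MORD between two OTUs is the mean per-character dissimilarity over
characters scored in both; for exclusively unordered characters each
per-character dissimilarity is already in [0,1] (0 if the state sets
intersect, 1 otherwise), so no further range rescaling is needed. Sharing
a state counts as no observable difference; an optional
`partial_overlap_score` (e.g. 0.5) charges overlapping-but-unequal sets
instead. Pairs with zero comparable characters are flagged incomputable
and block ordination with a clear error rather than a silent imputation.

PCoA is classical scaling: double-center −½D², `eigh`, keep eigenvalues
above 1e−8 (relative), scores = eigenvectors × √eigenvalue, per-axis sign
fixed by making the first nonzero loading positive. Negative eigenvalues
from non-Euclidean distances are handled by the Cailliez correction (the
smallest additive constant on distances, from the standard 2n × 2n
companion eigenproblem) or the Lingoes correction (additive constant on
squared distances); the default is Cailliez, matching the default
behavior of the R function this pipeline mirrors, and because the applied
correction is not always reported in published analyses the orchestrated
run writes corrected and uncorrected tables side by side.

Foote partial disparity uses the first min(10, available) axes and divides
each OTU's squared distance from the *grand* centroid by N − 1, N the
total OTU count in the disparity sample. With a per-group n − 1
denominator the group values could not partition total disparity — the
published percentage column could not sum to 100 — so the N − 1 reading is
used. The grand centroid is subtracted explicitly even though PCoA scores
are centered, guarding subsetted or re-imported ordinations. The disparity
sample itself (e.g. one sub-clade only; juveniles in or out) is defined
entirely by the group-map input file, never by code.

## The synthetic-data generator

`simulate` emulates the structure of an empirical morphological matrix:

- **Trees.** Yule (pure birth) trees rescaled to unit root-to-tip height,
  so `rate` means expected changes per tree depth and is comparable across
  sizes; or uniform-topology trees (sequential random edge insertion,
  which is exactly uniform over labelled unrooted topologies) with i.i.d.
  exponential branch lengths (default mean 0.1).
- **Characters.** Independent k-state symmetric Markov (Mk) characters,
  root state uniform; default k = 2, default rate 0.3 — a low-homoplasy
  regime for unit-height trees (≈1 expected change per character across
  the whole tree).
- **Degradation.** Exactly ⌊f·cells⌋ uniformly chosen cells become
  missing, and a disjoint ⌊g·cells⌋ scored cells each gain one extra
  uniformly drawn distinct state (polymorphism as a state union, the way
  ontogenetically variable characters are scored, rather than as a
  resampling).
- **Clean-signal matrices.** One block of identical binary characters per
  internal edge; on the generating tree CI = RI = 1 and the tree is the
  unique most parsimonious topology, giving fixtures with exactly known
  answers.

Every operation draws from its own named generator derived from
(seed, operation tag), so stages can be re-run independently with
identical results and the seed is recorded in the NEXUS provenance
comment.

What the generator does **not** emulate: rate heterogeneity across
characters, correlated characters, ascertainment ("variable characters
only") bias, hierarchically structured inapplicability, or non-random
missingness concentrated in fragmentary taxa. Passing tests therefore
demonstrate algorithmic correctness and behavior under the stated noise
model, not robustness to every pathology of real fossil matrices.

## Validation design and problem sizes

The suite validates each fast path against an independent oracle: bitmask
Fitch against an explicit unit-cost Sankoff dynamic program (500 fuzzed
column/tree pairs at n ≤ 8); Wagner + TBR search against exhaustive
enumeration of all 10 395 eight-taxon topologies (50 fuzzed matrices,
length and, where no overflow, topology-set agreement); PCoA against a
known Euclidean configuration (distances recovered to 1e−9) and against
an independent library implementation; Bremer decay against full
enumeration on a constructed six-taxon case; and the distributional
claims of the generator against closed forms (two-taxon Mk transition
probability, uniformity over the 15 five-leaf topologies) at binomial
99% confidence.

Tree recovery is measured as Robinson–Foulds distance (bipartition
symmetric difference) between the strict consensus of found MPTs and the
generating tree. On clean-signal matrices (20 random 8-taxon trees, 5
internal edges × 20 characters = 100 characters) recovery is exact. On Mk
matrices recovery is reported as a rate over a degradation grid; note
that random Yule/uniform trees routinely contain internal edges short
enough that no character marks them, so *exact* consensus recovery of Mk
matrices plateaus well below 100% at any rate — the recovery experiment
is therefore read as a trend (more degradation, worse recovery), not as
a guarantee.

Sizes used by the default test and acceptance runs (8 taxa for anything
touching exhaustive enumeration, tens to hundreds of characters, hundreds
of bootstrap replicates with a 2-replicate inner search) were chosen so
the whole validation cycle completes in minutes on a single core while
every check retains its discriminating power; all are configuration
values, and the full empirical-scale protocol remains the default of
`SearchConfig`.

## Known limitations

- Characters are unordered and equally weighted; ordered, Dollo,
  irreversible or implied-weighted analyses are out of scope.
- The search is plain Wagner + TBR; ratchet/sectorial acceleration is not
  implemented, so very large matrices (≫50 taxa) take correspondingly
  long.
- Exhaustive search refuses more than 9 taxa by design.
- Bremer accumulation bounded by `bremer_hold` may censor decay values on
  large flat landscapes (reported explicitly as "k+").
- MORD with heavily non-overlapping taxon pairs can leave the distance
  matrix non-Euclidean; corrections restore embeddability but inflate all
  distances, which is why corrected and uncorrected disparity tables are
  both emitted.
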