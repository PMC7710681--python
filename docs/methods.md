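# Methods

## Data model

A character matrix holds binary polarity-coded characters (rows) scored
for taxa (columns). Six cell codes are recognised: `0` (plesiomorphic),
`1` (apomorphic), `?` (no information), `1?`/`0?` (polarity argued from an
ambiguous description), and `0*` (scored plesiomorphic, but the derived
condition also occurs within the species). Downstream computation never
sees the qualified codes: `apply_polarity_policy` reduces them first.

* **as-argued** (default): `1?→1`, `0?→0`, `0*→0`, `?→missing`. The `0*`
  reading follows the systematist's logic that a deviation arising within
  a species is not evidence for grouping that species with taxa fixed for
  the derived state.
* **conservative**: all four qualified codes become missing — a
  sensitivity mode for asking how much the argued polarities matter.

Taxon labels are normalised to genus-abbreviated epithets (`L_sarsi`),
with a lookup table to full binomina, so that labels survive Newick and
NEXUS round trips unquoted. Delimited files are character-rows ×
taxon-columns (the layout of a published character table) with a
`taxa_as_rows` flag for the transpose. NEXUS output uses
`DATATYPE=STANDARD SYMBOLS="01" MISSING=?`; since qualified codes are not
representable in standard NEXUS, the writer emits the as-argued symbol in
the CHARACTERS block and preserves the original codes, character
descriptions and convergence annotations in a private `MORPHOCLAD` block,
making the round trip lossless while remaining readable by other NEXUS
consumers.

## Parsimony

Character length on a rooted tree is computed by the two-state unit-cost
Sankoff recursion (equivalent to Fitch/Hartigan counting), vectorised over
characters. Polytomies are hard: a multifurcation is costed as drawn.
Missing leaves are unconstrained.

**Root semantics.** The hypothetical all-plesiomorphic ancestor is
modelled *above* the ingroup's most recent common ancestor, joined by a
virtual root edge: per character the length is
`min(cost0(MRCA), cost1(MRCA) + 1)`. This matters for a character derived
in every taxon: it costs one origin, placed on the root edge — the
group-level autapomorphy reading — rather than one origin per root child,
which a hard root-state constraint at the MRCA would produce. A
consequence worth noting: on a star tree a character with k derived and z
plesiomorphic taxa costs `min(k, z+1)`, not k, because an origin on the
root edge plus z reversals can undercut k parallel origins.

**Reconstruction.** Origins (0→1) and reversals (1→0) are mapped to edges
by a top-down pass. Ties are broken by the placement policy:
`delay-changes` (default) keeps the parent's state, pushing changes toward
the leaves so repeated derived states appear as independent origins;
`accelerate-changes` adopts the derived state as early as possible,
favouring an origin plus later reversals. The default matches the
argumentation convention that secondary re-gain of a lost structure is
improbable. Missing leaves inherit the parent state under delay, so they
never spawn spurious changes. A character is *convergent* when its origin
count exceeds one.

**Indices.** `CI = Σm / s` and `RI = (Σg − Σs) / (Σg − Σm)` with m = 1
per informative character and g the star-tree cost `min(k, z+1)` under
the root semantics above. A zero-step denominator yields `nan` (flagged
undefined, not an exception).

## Exact search

`branch_and_bound` enumerates rooted binary topologies by stepwise taxon
insertion, taxa ordered by decreasing derived-state count so conflict
surfaces early. Subtree costs are memoised on subtree structure (partial
trees in a search share almost all their subtrees). The bound is the
partial tree's length plus, per character not yet represented by a placed
derived taxon but derived in some remaining taxon, one unavoidable future
origin. The incumbent is seeded with the length of the argumentation
cladogram, whose binary resolutions can never beat the global optimum by
construction. All co-optimal trees are retained up to a cap of 10,000;
beyond that the count is still exact. Unconstrained exact search is
limited to 15 taxa; a backbone cladogram (whose clades every returned
tree must display, enforced incrementally during insertion) lifts the
limit. If a wall-clock budget expires the incumbent set is returned with
`exhausted=False`. On the packaged 12-taxon matrix the exact search
examines a few thousand partial trees and finishes in about a second.

## Argumentation

`group_by_synapomorphy` proposes one clade per distinct derived taxon set
of size ≥ 2. A character with missing cells joins an existing proposal
when its observed derived taxa are a subset and the difference is exactly
taxa unscored for it (the smallest such proposal wins); this is how a
character unknown in one species still supports the group the remaining
species define. A `strict` mode instead demotes such characters to
unplaced. Singleton derived sets are autapomorphies; an all-taxa derived
set is reported as the group-level autapomorphy of the whole ingroup.

`arbitrate` selects a compatible subset greedily. A proposal's weight is
its own supporting characters plus those of every *conflict-free*
proposal nested with it — the corroborating context of the groups it sits
inside or contains. Conflicted proposals cannot lend weight, otherwise a
proposal could borrow support from two proposals that exclude each other.
Ties are broken toward the lower minimum character id. The published
arbitration between two equally supported nine-species groupings rests on
an anatomical plausibility judgement a program cannot make; the tie rule
encodes that outcome deterministically and is documented as an editorial
choice. Rejected proposals' characters become convergences, with their
independent origins read off the final cladogram by reconstruction. A
proposal that conflicts with nothing is always accepted.

`build_cladogram` assembles the unique minimal rooted tree displaying
exactly the accepted clades; taxa in no accepted clade join the root
polytomy. On the packaged matrix the pipeline reproduces the reference
topology exactly and its 43 steps equal the branch-and-bound minimum —
phrased throughout as "consistent with minimum steps": the source
analysis argues clade by clade and never claims global optimality.

## Keys

A dichotomous key is a numbered couplet graph; validity means: two leads
per couplet, all targets resolvable, all couplets reachable and acyclic,
and every taxon the target of exactly one lead (hence couplets = taxa −
1). Leads are free text — published keys routinely use characters absent
from the phylogenetic matrix — with an optional `(char_id, state)`
predicate; `check_predicates` verifies predicated leads against a matrix.
The packaged key preserves the printed lead order and wording, including
one couplet whose second lead overlaps a later criterion; the
transcription does not repair the logic. `generate_key` builds a key
greedily, choosing at each node the character (scored, non-missing, and
variable across the remaining taxa) that splits them most evenly, ties to
the lowest id; two taxa no usable character separates raise an error
naming the pair.

## Synthetic data

The generator emulates the structure of a desk-scale morphological
matrix. Each character's origin is a uniformly drawn non-root edge of a
random rooted binary tree (uniform sequential leaf addition); all leaves
below the edge are derived. With probability `homoplasy_fraction` a
second origin is drawn on an edge disjoint from the first — convergence
is simulated only as parallel gain, never as reversal, matching the
convergence-only reading of homoplasy in this style of analysis. Missing
and uncertainty codes are applied cell-wise at their rates. Defaults
(12 taxa, 39 characters, homoplasy 0.1, missing 0.005, uncertainty 0.005)
mirror the packaged matrix: 4/39 convergent characters and a handful of
qualified cells. The root edge is excluded from draws so all-derived
rows arise only via `allow_root_origin`; `cover_all_clades` dedicates the
first characters to one origin per nontrivial clade, the regime in which
argumentation provably recovers the generating tree.

What the generator does not emulate: correlated characters, reversals,
rate heterogeneity among lineages, and non-random missingness
(real missing cells concentrate in poorly described species). Passing
recovery tests therefore shows algorithmic correctness under the stated
generative model, not robustness to those real-data pathologies.

Identical configurations give byte-identical outputs; all randomness runs
through one seeded generator.

## Problem sizes and numerical choices

Tests and the acceptance script run the 12-taxon packaged matrix (exact
search ≈ 1 s), brute-force cross-checks on 5–7-taxon synthetic instances
(the 7-taxon space has 10,395 rooted binary trees), and 20-replicate
recovery experiments at 8 taxa — sizes chosen so the full suite completes
in well under a minute while every guarantee is still exercised at a
nontrivial scale. All integer quantities (lengths, origin counts, RF
distances) are computed exactly; the only floating-point outputs are CI
and RI. Deterministic iteration order (matrix taxon order) everywhere
makes results bit-reproducible.

## Known limitations

* Binary characters only: no multistate, ordered, or continuous
  characters, and no Sankoff cost matrices.
* No statistical inference: likelihood/Bayesian models, bootstrap and
  implied weighting are out of scope.
* The arbitration weight is a deterministic stand-in for a biological
  plausibility judgement; alternative weightings can reverse
  individually narrow decisions (the `strict` missing mode and the
  `conservative` polarity policy expose the main sensitivity axes).
* Exact search beyond ~15 taxa requires a backbone; no heuristic
  (ratchet/TBR) search is provided.
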