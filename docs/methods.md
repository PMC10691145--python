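# Methods

## Model

A gene cluster is modeled as a PQ-tree over signed gene leaves: P-node
children may be permuted freely, Q-node children kept or reversed as a
block, and each node carries a *color* — a unique identifier assigned in
preorder that survives reordering and is the only device used to match a
node with its copy in a derived tree.  The divergence from a tree ordered
as a reference gene order to a target gene order is the minimum, over all
legal reorderings (plus up to d_T leaf deletions and d_S target-character
deletions), of a sum of per-node violations.

Positions in signed strings are 1-based with inclusive slices throughout
the API.

### Node signs

The sign of an internal node is the majority sign of its leaves; an exact
tie counts as both signs.  On the derived side the majority is taken over
the *surviving* leaves with their derived (target) signs — this is
precisely what the general engine's positive-leaf count (`pos`) encodes:
`pos ≥ (span − k_T)/2` is consistent with `+`, `pos ≤ (span − k_T)/2`
with `−`, both at a tie.  Where a tie leaves a choice, the engines
minimize over one consistent sign choice per child within each node's
violation (the general engine commits to a single sign per child
derivation, so the constrained engine and the brute-force scorer
enumerate tie assignments the same way to stay exactly equal).  The
stand-alone change-of-signed-order predicate in `jump.py` instead applies
the tie pair by pair, which is the natural reading for that isolated
test; the engines do not call it directly.

### Break-points

A pair of children consecutive in the derived order is free exactly when
its signed order is preserved — same relative order with both signs kept,
or reversed order with both signs negated — *and* every child originally
between the two is wholly deleted in the derivation (equivalently: the
pair is adjacent in the deletion-reduced original child string).  Break-
points can be counted on either string; the counts coincide because the
color mapping is one-to-one.

### Jump violation

Reordering a P-node's children is priced by the minimum weight vertex
cover of the graph whose edges join child pairs that changed their signed
order, with weight (span − 1)/2 per child — single leaves jump for free,
larger blocks cost more.  The cover is computed exactly by branch and
bound on the highest-degree vertex, with a deterministic tie-break (the
lexicographically smallest optimal vertex set).  Child weights use the
child's full original span even when some of its leaves are deleted, so
the same unit has the same price in every derivation.

### Flip events

A node is *flipped* when its surviving children appear in exactly
reversed order and each of them is flipped (for leaves: the strand sign
is reversed).  Flip accounting is mandatory, not optional: a flipped
Q-node always pays δ_flip and is always refunded the flip penalties of
its surviving leaf and Q-node children (P-node children carry no flip
penalty and are excluded).  The refund is applied only when the node
actually flipped as a unit; children that all flip individually while the
order stays forward are charged but not refunded, matching the general
engine's two-run Q-mapping.

## Engines

### Constrained engine (permutations, no deletions)

Gene identifiers are unique and nothing may be deleted, so each node
derives a unique target interval: leaves anchor at their label's
position, internal nodes must tile their children's intervals
contiguously (any order for P, forward or reverse for Q).  One postorder
pass resolves intervals and sums the violations.  Traced runs expose each
node's interval, children sum, break-point, jump, flip and correction
terms.

### General engine (deletions)

A postorder DP stores, per node, start index, tree-deletions k_T,
string-deletions k_S and positive-leaf count pos, the minimum divergence
of deriving the window `S2[i : i−1+span−k_T+k_S]` — the window end is
derived, never stored.  Leaf entries allow the mapped character anywhere
inside the leaf's window, charging ρ_S per surplus character, so that
leading and trailing deletions compose correctly through the recursion.
A deleted-leaf entry charges ρ_T (plus ρ_S per window character).  Every
deleted character is charged exactly once, in the entry of the child
whose window contains it.

**P-mapping** walks over subsets: the state records which children are
mapped or deleted, the last mapped child and its committed sign, the
deletion counts, pos, and the set U of mapped children left *outside*
the vertex cover together with their signs.  Appending a child either
adds it to the cover (paying its weight immediately) or requires it to
have no changed-signed-order edge to any member of U.  This is a
reparameterization of guessing a candidate cover up front: tracking the
uncovered set makes cover validity checkable locally, because an edge's
existence depends only on the pair's relative derived order, which is
fixed the moment the later child is appended.  Between-block deletions
bridge the appended pair (break-point only if the signed order changed);
children never used are deleted flat at completion.  Windows are tiled
left to right, so the first mapped child starts at the window's first
character.

**Q-mapping** runs two directional scans (given order, reversed order);
a scan step maps the next chosen child and deletes the skipped block
flat.  Derivations whose leading children are deleted are seeded by
initializing each possible first *mapped* child with the prefix deleted
flat — the natural completion of the scan scheme, verified against the
brute-force scorer.

**Flip surfaces.**  Every node keeps two tables: the minimum over
derivations in which it did not flip as a unit, and the minimum over
those in which it did (scored with its own flip charge and refund).  The
flipped surface of a Q-node is built from the children's flipped
surfaces in the reversed scan, refunding leaf/Q children as they are
appended; a P-node's flipped surface restricts appends to decreasing
original index with flipped children.  The general runs track a flag and
route all-children-flipped-reversed completions to the flipped surface
only.  Without this split, a flipped Q-node whose children are P-nodes
(refund smaller than the charge) could be scored as if the flip event
were optional, undercutting the definition.

**Windows.**  The final answer minimizes over every start index, budget
use and pos at the root; characters outside the chosen window are not
charged.  This best-window convention matches the final stage of the
general algorithm and is shared by the brute-force scorer.

### Polynomial-space P-mapping

With the jump penalty disabled, the subset table is replaced by
counting: an 8-dimension-equivalent sparse walk DP counts event
sequences (map a child, bridge over a deleted block, delete a window
character; leftover slots closed by flat deletions at completion) of
length exactly γ over an allowed child set, keyed by exact rational
score; the inclusion–exclusion alternating sum over excluded-child
subsets isolates sequences that use every child exactly once, and the
reported value is the smallest score with a positive count.  Exact-score
counts are used instead of at-most-score counts; the cumulative form is
recovered trivially and the reachable keys *are* the score set, so no
score grid or floating-point indexing is needed.  Counts are Python
integers (arbitrary precision).  Redundant event orders (e.g. a child
deleted mid-walk versus at completion) may inflate counts but never
under-state a derivation's score, and the optimal derivation always has
an exactly priced sequence, so the minimum is exact; non-negativity of
every alternating sum is asserted at run time.  Flipped-surface counts
come from a restricted run (flipped child derivations, decreasing
original index); since flip status changes no P-node score, the
non-flipped counts are the difference of the two runs.

## Parameters

| Parameter | Meaning | Default |
|---|---|---|
| δ_ord | per signed break-point at a Q-node | 1.5 |
| δ_flip | flip of a leaf or Q-node | 0.5 |
| ρ_T del | per deleted leaf | 1 |
| ρ_S del | per deleted target character | 1 |
| d_T, d_S | deletion budgets | 0 |
| jump | P-node jump violation on/off | on |

The stronger order penalty reflects how strongly colinear order is
conserved in prokaryotic gene clusters relative to strand flips.  All
penalties are parsed and carried as exact rationals; scores never touch
floating point, so reported values are exact and reproducible.

## Synthetic data

The generator draws a random PQ-tree (4–7 leaves, out-degree ≤ 4, P/Q
equiprobable, ~30 % reverse-strand genes — a small, well-structured
cluster) and derives a target by logged legal events: P-child shuffles,
structural flips of leaves or Q-subtrees, leaf deletions, and insertions
of foreign genes (which require the matching string-deletion budget).
It emulates the rearrangement process the model scores — it does not
emulate gene duplication, unequal gene content beyond the requested
deletions/insertions, or any sequence-level signal, so passing tests
demonstrate algorithmic correctness on model-generated data, not
biological calibration of the penalties.

## Verification

The engines are verified against an independent brute-force scorer that
enumerates every derivation explicitly (all deletion subsets, all child
orderings, all embeddings of the frontier into the target) and scores it
by direct application of the per-node definitions.  The default suite
checks, among others: identity derivations cost 0 (500 random trees);
the general engine equals the constrained engine on 200 permutation
instances; both equal the brute-force optimum on a seeded grid of 1000
instances with up to 6 leaves, budgets ≤ 2 and penalties drawn from
{0, ½, 1, 1½, 3}; the inclusion–exclusion engine equals the subset
engine with jump disabled on the same grid; scores are non-increasing in
the budgets; and the exact vertex cover matches exhaustive subset search
on 300 random weighted graphs with up to 12 vertices.  These sizes keep
the full suite within a few seconds while exercising every recursion
case (the instance grid is seeded and can be enlarged freely).

## Degenerate inputs and numeric choices

Single-leaf trees, fully deleted subtrees (priced flat at ρ_T · span),
empty windows, and duplicate gene labels in the target (general engine
only) are supported; the constrained engine requires signed permutations
over a common alphabet and raises otherwise.  Internal nodes must have
at least two children — a one-child internal node would be semantically
a no-op.  Exhaustive gene-mapping enumeration refuses more than 10⁵
mappings; inside the engines mappings are always unique because colors
are.  Ties between equal-score derivations are broken deterministically
(first-found in a fixed processing order; lexicographically smallest
vertex set for covers).

## Known limitations

Duplicated genes in the *reference* (tree leaves with equal labels are
allowed, but each leaf is its own color; true paralog handling is not
modeled), gene fusions, and affine deletion costs are out of scope.  The
constrained engine reports per-node traces; the general engine reports
the optimum with budgets and window but no per-node trace.  The
polynomial-space engine cannot price jump violations — covering edges
between non-adjacent walk steps has no local counting analogue — and
refuses to run with the jump penalty enabled.  One printed value in the
published definition-level walkthrough of the six-gene example (a total
of 2 at zero flip penalty) is inconsistent with the majority-sign rule
those definitions state, under which the root contributes two signed
break-points and the total is 3; the engines and the brute-force scorer
agree on 3, and the algorithm-level trace of the same tree reproduces
every printed per-node value.
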