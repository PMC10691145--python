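# pqdiverge

Structure-informed genome rearrangement divergence between a PQ-tree model
of a gene cluster and a target gene order.

## The problem

Prokaryotic gene clusters (often operons) are shuffled by evolution, but
not arbitrarily: colinearly co-dependent sub-operons tend to stay in
order, while independently assembled components move as blocks.  A
PQ-tree captures this learned structure — the children of a **P-node**
may appear in any order (block-interchange-like events), the children of
a **Q-node** only in the given or reversed order (reversal-like events),
and leaves are signed genes.  Given a PQ-tree ordered as a reference gene
order S₁ and a target signed gene order S₂, `pqdiverge` computes the
minimum total penalty of reordering the tree so that its frontier equals
S₂ (or, with deletion budgets d_T and d_S, a windowed subsequence of S₂).

Per internal node x mapped to its reordered copy x′, the penalty is:

* **P-node:** `d_SBP(S(x), S(x′)) + Δ_jump(x, x′)` — the signed
  break-point distance between the child color strings, plus the minimum
  weight vertex cover of the graph joining child pairs that changed their
  signed order, with weight `(span − 1)/2` per child (single genes move
  for free, big blocks are expensive).
* **Q-node:** `δ_ord · d_SBP(S(x), S(x′)) + isFlipped(x, x′) · δ_flip −
  FlipCorrection(x, x′)` — order changes cost δ_ord per signed
  break-point; flipping the whole node as one reversal costs δ_flip once,
  with the individually charged flip penalties of its children refunded.
* **Leaves:** a strand flip costs δ_flip; deletions cost ρ_T del per
  leaf and ρ_S del per target character.

Three engines compute the optimum:

* `cttsd_diverge` — permutations, no deletions (interval-resolution DP);
* `ttsd_diverge` — the general dynamic program with deletion budgets
  (subset DP over P-node children, two directional scans per Q-node);
* `ttsd_diverge(..., p_mapper=p_mapping_inclusion_exclusion)` — a
  polynomial-space variant that replaces the exponential subset table by
  inclusion–exclusion counting (requires the jump penalty disabled).

A brute-force reference scorer (`brute_force_diverge`) and a seeded
instance generator (`simulate`) back the test suite.

## Worked example

The six-gene cluster `(P (P +a (Q +b +c) +d) +e +f)` — frontier
`+a +b +c +d +e +f` — against the target `+f -c -b -a -d -e`, with
δ_ord = δ_flip = 3:

```bash
pqdiverge cttsd --tree tree.pq --target target.txt \
    --delta-q-ord 3 --delta-q-flip 3 --trace
```

prints (abridged):

```json
{
  "score": "15",
  "trace": {
    "3": {"kind": "Q", "start": 2, "end": 3, "children_dist": "6",
           "flip_penalty": "3", "flip_correction": "6", "score": "3"},
    "1": {"kind": "P", "start": 2, "end": 5, "d_sbp": 1, "jump": "0",
           "score": "10"},
    "0": {"kind": "P", "start": 1, "end": 6, "d_sbp": 2, "score": "15"}
  }
}
```

Reading it: the Q-node `(b c)` maps to `-c -b` — both leaves flipped (3
each), the node flips as one unit (+3) and refunds its children (−6),
so the whole reversal costs 3.  The inner P-node pays its children (9)
plus one signed break-point between the moved block and `d`; moving
single-gene units is free, so the jump term is 0.  The root adds two more
break-points, for a total divergence of 15.

With deletion budgets the general engine applies; `--both-strands` also
scores the reversed-and-negated target and keeps the smaller divergence.
Default penalties are δ_ord = 1.5, δ_flip = 0.5, ρ_T = ρ_S = 1, with
budgets 0.

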