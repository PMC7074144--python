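# Methods

## Problem and model

`ancorder` reconstructs ancestral *gene orders* on a rooted phylogeny of
small organellar genomes. Each genome is abstracted as the ordered list of
its annotated gene names with strand, allowing duplicated names — the
natural representation for chloroplasts, where inverted-repeat genes such
as YCF68 or YCF1 occur in several copies and most between-species
differences are copy-number changes rather than content changes. The
evolutionary model admits four gene-level operations: insertion, deletion,
duplication and inversion of a single gene or a contiguous block. No
permutation assumption is made: genomes may differ in length and carry
repeated or missing genes, which is what rules out classical rearrangement
solvers built on signed permutations.

The method is a parsimony-flavoured consensus, not a likelihood model: at
each step it chooses the local ancestor that explains the two sister
genomes with the fewest rearrangement operations, using nearby resolved
lineages ("cousins") to break ties.

## The bottom-up procedure

1. **Labeling.** Internal nodes are labeled `a`, `b`, …, `z`, `aa`, … in
   post-order (children before parents, in the order written in the
   Newick source). The labeling is deterministic and idempotent.
2. **Cherry selection.** Among internal nodes whose two children are both
   resolved (leaves or previously inferred ancestors), the pair of
   children with the smallest gene-level edit distance is processed
   first; ties go to the lexicographically smallest pair of child ids.
3. **Cousin ordering.** Every other currently resolved lineage is ranked
   by (i) number of tree edges to the cherry node, (ii) the smaller edit
   distance to either sister, (iii) node id.
4. **Gene investigation.** The two sisters are globally aligned at the
   gene level. Matched columns (same name and strand) enter the ancestor
   γ directly. For each conflict column, cousins are consulted in rank
   order: a gene present in one sister is kept if the first cousin that is
   informative at the homologous column carries it, and dropped (recorded
   as an insertion on the carrying branch) if that cousin lacks it; a
   cousin showing a third pattern passes the vote to the next cousin. A
   mismatch column is resolved for whichever sister the first informative
   cousin sides with. When every cousin shows a third pattern — or there
   are no cousins — the disputed gene is excluded from γ, since positing
   it would cost one extra event in every other lineage.
5. **Copy-number reconciliation.** For each gene whose copy count differs
   between the sisters (counts c₁, c₂), the ancestral count is decided by
   `resolve_copy_number`: the first cousin whose count equals c₁ or c₂
   settles it; failing an exact match, presence in the first cousin plus
   presence in exactly one sister keeps that sister's count; otherwise
   min(c₁, c₂). γ is then adjusted to that count, preferentially adding
   back copies from the sister that supports the target count and
   dropping copies that entered γ by vote rather than by match.
6. **Ancestor update.** γ replaces the cherry and the loop repeats until
   the root. Each parent→child branch receives an event ledger computed
   from the γ-to-child alignment: gap-in-parent columns are insertions,
   gap-in-child columns deletions, mismatch columns a paired
   deletion+insertion, plus per-gene copy-number changes. The accounting
   identity |child| = |parent| + insertions − deletions (in gene copies)
   holds on every branch by construction.

### Inversions

Before column voting, maximal inverted regions between the two sisters
are detected: runs of positions where one genome equals the other read
right-to-left with every strand flipped, found by an anti-diagonal
dynamic-programming scan. Single-gene flips are not called inversions
(`min_inversion_len = 2`): they are indistinguishable from strand
re-annotation and surface as ordinary mismatch columns instead.
Overlapping candidates keep the longer region, ties to the smaller start.

Each detected region is oriented by the first cousin that prefers one
sister's block over the other's (total matched genes against the cousin);
the disagreeing sister is rewritten into the ancestral orientation before
alignment, and the inversion is charged to its branch. Inversions change
no copy counts, so they are neutral for the accounting identity. The
harder case of indels *inside* an inversion zone is handled by
`resolve_inverted_region`, which re-applies the per-gene cousin vote in
the region's coordinate frame after rewriting the non-reference slice
(reverse + strand flip) into the reference frame.

## Alignment primitives

Two primitives operate on `(name, strand)` symbols. Copy identity is
deliberately not part of the matching key — two copies of YCF68 match
each other — and which copy pairs with which is decided positionally by
the alignment.

* **Gestalt pattern matching** (Ratcliff/Obershelp, as implemented by
  `difflib.SequenceMatcher` with the junk heuristic disabled):
  recursively take the longest common contiguous block (ties to the
  smallest start in A, then in B), recurse on both flanks, and report the
  similarity ratio 2·M/(|A|+|B|), M the total matched symbols.
* **Needleman–Wunsch global alignment** with a deterministic traceback
  (diagonal over gap-in-B over gap-in-A). The general-purpose default
  scoring is match +1, mismatch −1, gap −1. The *distance* used for
  cherry selection and cousin ranking is the edit distance under
  unit costs (match 0, mismatch −1, gap −1), whose optimal score is
  exactly minus the minimum number of substitutions and indels; this
  makes `gene_order_distance` a true metric (symmetric, triangle
  inequality), which a match-rewarding scoring does not guarantee — a
  score-optimal alignment under match +1 can contain more edit columns
  than the minimum (e.g. `aabc` vs `bcccaa`).

## Simulator

The forward simulator provides ground truth that real data cannot: the
gene order at every internal node. Defaults emulate a quiet plastid
history — a 160-gene root, optional two-copy genes standing in for
inverted-repeat duplicates, Poisson event counts per branch with means
well below one (insertion 0.2, deletion 0.2, duplication 0.5, inversion
0.1, inversion lengths 2–6), tandem duplication, insertions drawing novel
names from the pool so they are recognisable in the truth. A fixed-count
mode, a per-branch event cap, a deletions-hit-only-duplicated-genes mode
and an insert-existing-names mode support scripted scenarios (pure
copy-number evolution, reinsertion hard cases). Events within a branch
apply in the fixed order insertion → deletion → duplication → inversion,
and the raw operation log is recorded per branch, so every history can be
replayed exactly from the root.

What the simulator does *not* emulate: genome circularity, the physical
inverted-repeat structure (duplicates are independent copies, not a
mirrored repeat), intergenic content, annotation error, and
lineage-heterogeneous rates. Recovery results on simulated data therefore
speak to the algorithm's logic, not to annotation-induced noise in real
genomes.

## Numerical and design choices

* "Matches in position" is interpreted through alignment columns, not
  absolute indices: sister genomes of unequal length have no shared
  coordinate system, and the alignment supplies the homology map.
* Conflict lookup aligns each cousin against the sister that *carries*
  the disputed gene (for indel conflicts) — the only genome in which the
  disputed position exists — and against the longer sister for
  substitution conflicts. Alignments are cached per (cousin, sister).
* All tie-breaks (cherry choice, cousin order, traceback, Gestalt block
  choice, overlapping inversions) are fixed and documented above, so two
  runs on the same input produce byte-identical outputs.
* Polytomies are rejected by default; an option resolves them into a
  left-leaning caterpillar, since the procedure consumes binary cherries.
* Gene names are uppercased on ingest; annotation pipelines are
  inconsistent about case and name identity is the whole basis of
  matching.
* Degenerate inputs: empty genomes are rejected at parse time; deletion
  events in the simulator never empty a genome; the Gestalt ratio is
  undefined (error) for two empty sequences.
* The root is inferred without cousins (none remain), so conflicts at the
  topmost cherry fall back to exclusion/minimum; this is the standard
  outgroup-free ambiguity and the main known source of root copy-count
  error under sparse-event simulation.

## Test problem sizes

Property suites run at sizes chosen to be exhaustive where exhaustion is
feasible: all sequence pairs of length ≤ 6 over a 3-symbol alphabet
(deduplicated up to joint relabeling, ~2×10⁵ pairs) for the
alignment-vs-brute-force equivalence; every single inversion of length
2–10 at every placement on genomes of length up to 30; 100 seeded
replicates of a 6-leaf, ~68-gene copy-number-only history for root
recovery. These sizes keep the full suite under a minute while covering
the regimes the method targets.

## Limitations

* The voting is local and greedy; it does not optimise a global tree-wide
  parsimony score. What it aims for is agreement with careful manual
  consensus reconstruction on quiet genomes, not optimality.
* Root-adjacent events are not always recoverable (no cousins at the
  root; see above).
* Inversion detection requires the region to match exactly after
  reversal; inversions overlapping other events on the same branch may be
  reported as separate indel/mismatch events instead.
* The comparison module scores any two reconstructions against each
  other; it does not implement other tools' inference.
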