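# Methods

## Model and assumptions

The pipeline treats a risk register as a directed influence system and
estimates nothing: every stage is a deterministic graph/matrix
computation on expert-elicited inputs. The modelling assumptions are
therefore all about what the inputs mean.

**Relation network.** Screening assumes an undirected simple graph: a
relation between two risks is one link regardless of direction, there
are no self-relations, and importance is adequately summarized by degree
(no betweenness/eigenvector variants — degree is what the elicitation
protocol defines). When only a per-risk degree table is available (the
usual situation with published case studies, which print degrees but not
the underlying expert matrix), degrees are consumed as given; the
package does not try to reconstruct a graph from them.

**SSIM semantics.** The SSIM is taken as a single consensus judgement:
one symbol per unordered pair, upper triangle authoritative. `V`/`A`
record a one-way "leads to" relation, `X` mutual influence, `O` no
direct relation. `O` is *not* a claim of unreachability — the
transitivity check may legitimately connect the pair; this is precisely
the distinction the derived-cell flags preserve.

**Transitive closure.** The final reachability matrix is the boolean
fixpoint `M* = M ∨ M² ∨ M⁴ ∨ …` (repeated boolean squaring; the
contract is the unique smallest transitively closed superset, verified
in tests against an independent matrix-power oracle and networkx).
Cells switched on by closure carry a `derived` flag instead of a third
"1\*" symbol: published tables print plain 1s, and a boolean matrix plus
a flag matrix keeps the algebra clean while preserving the audit trail.

**Level partition.** Standard iterative extraction: among remaining
elements, every `i` with `R(i) ∩ A(i) = R(i)` is assigned the current
level simultaneously (no tie-breaking), then removed. Level 1 is the
first extraction — the most dependent, least driving tier. Because
domain write-ups use both directions of "highest/lowest level", reports
also expose the reversed *depth* numbering (root drivers at depth 1).
On a genuinely closed matrix every iteration extracts at least one
element (each terminal strongly connected component of the remaining
subgraph qualifies), so a stalled iteration is diagnosed as an unclosed
input and raised as an error rather than silently repaired. The number
of levels is always emitted by the algorithm, never assumed: on the
bundled case study the scheme produces six levels, with the two root
tiers split as {R63, R87} then {R62} because the sanctions risk R62
drives the exchange-rate risk R63 one-way.

**Hierarchy digraph.** Mutually reachable elements are grouped
(strongly connected components of the final matrix); the between-group
edges are the transitive reduction of the condensation, which for a DAG
is unique. Edges point from driver groups to more dependent groups, so
an edge g → h implies level(h) < level(g) under top-numbering.
Re-closing the reduced digraph reproduces the off-group part of the
final matrix exactly; this round-trip is asserted in tests. Note the
reduction keeps only shortest chains: a group that reaches the top
through intermediates gets no direct edge to the top.

## Tunable parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| selection cutoff | explicit threshold, or quantile in (0, 1) | minimum degree for a key risk; ties at the cutoff are included (≥), making selection monotone in the cutoff |
| quantile method | `linear` (numpy interpolation) | how the quantile cutoff is interpolated when quantile mode is used |
| MICMAC midpoint | `auto` = n/2 | low/high split for both power axes; "high" is strict `>` |
| glyph tolerance | on | digit `0` → letter `O`, case folding, each substitution warned |
| `--strict` | off | promotes collected warnings (glyphs, element-set mismatch, unclosed input) to errors |

The bundled case study uses the explicit cutoff 36 because that is the
cutoff its published 17-risk key set realizes; no standard quartile
convention of the printed 102-degree distribution yields exactly that
set, so the "upper quartile" phrasing of the source protocol is exposed
as configuration rather than hard-coded. On the case-study powers the
MICMAC quadrants are invariant to any midpoint strictly between the
power clusters (3, 13) — asserted for integer midpoints 4–12 — so the
n/2 default is not load-bearing.

## Synthetic data: what it emulates, what it does not

`generate_hierarchy(n, k_groups, density, seed)` plants the object ISM
is supposed to recover: a random partition of n elements into k
nonempty strongly connected groups (random composition, minimum size 1)
and a random DAG over the groups (each forward pair carries an edge with
probability `density`). `hierarchy_to_ssim` induces the SSIM of a
perfectly consistent expert panel, in two regimes: *dense* (every
planted relation emitted, including transitively implied ones, so the
initial matrix is already closed) and *sparse* (only a spanning chain of
`X` within groups and one representative `V`/`A` per
transitive-reduction edge, so the closure step has real work to do).
Both closures provably equal the planted reachability, and the test
suite checks recovery of groups, level ordering and between-group
reachability on 100+ random instances.

`generate_degree_profile` emulates the shape of real screening tables: a
bulk of integer degrees uniform on 5–39 (the range observed in a
~100-risk register) plus `round(n × tail_fraction)` tail scores uniform
on 42–55, with the 39/42 gap guaranteeing that a quantile cutoff in the
gap isolates the tail. Default `tail_fraction` 0.17 mirrors a 17-of-102
key set.

Deliberately **not** modelled: expert disagreement or noise in the SSIM
(the consensus-matrix assumption), weighted or probabilistic relations,
and register semantics (synthetic names/segments are generic labels).
A green recovery suite therefore establishes algorithmic correctness on
self-consistent inputs, not robustness to inconsistent elicitation.

## Numerical and degenerate-input conventions

- All matrices are boolean numpy arrays; no floating point enters the
  core, so there are no tolerances to tune.
- Element order is preserved verbatim from the input everywhere; all
  outputs are code-labelled so order never carries meaning.
- Duplicate codes, non-binary adjacency entries, non-square layouts and
  missing SSIM cells are hard errors with the offending code/cell named.
- Self-relations in adjacency input are dropped with a warning.
- A matrix passed to MICMAC that is not closed is warned about and
  closed first; the same situation in level partitioning is an error,
  because a wrong partition would be silent.
- Reports serialize with sorted keys; two runs on identical inputs are
  byte-identical (timestamps live only in logging).

## Known limitations

- Single consensus SSIM only: no aggregation of multiple expert
  matrices, no fuzzy/total-ISM variants, no DEMATEL.
- Degree-only centrality, by design of the screening protocol.
- MICMAC uses the final reachability matrix directly (no iterated
  indirect-influence powers beyond the closure).
- The conceptual-consistency review that a human panel performs on the
  drawn hierarchy is out of scope; the package guarantees structural
  consistency (closure, acyclicity of the condensation, level/order
  invariants) only.
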