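# ismrisk

Semi-quantitative risk assessment for large risk registers: network-based
screening, interpretive structural modelling (ISM), and MICMAC
classification, packaged as a Python library and a CLI.

## The problem

Risk registers in complex systems — the motivating case is a national
blood supply chain with 102 identified risks across 22 chain segments —
are too large for pairwise multi-criteria methods, and classical scoring
ignores how risks cause one another. This package implements a
three-stage pipeline for exactly that situation:

1. **Screening (degree centrality).** Risks are nodes of a relation
   network elicited from experts; the degree of risk *i*,
   *d(i) = |{j : i ~ j}|*, counts its relations. Key risks are those with
   *d(i) ≥ c* for an explicit cutoff *c* or an upper quantile of the
   degree distribution.
2. **ISM.** Over the key risks, experts fill a structural
   self-interaction matrix (SSIM): for each ordered pair (i, j) one of
   **V** (*i* leads to *j*), **A** (*j* leads to *i*), **X** (mutual),
   **O** (none). The SSIM maps to a binary initial reachability matrix
   *M* (with unit diagonal); the final matrix *M\** is its transitive
   closure, computed as the boolean fixpoint *M\* = M ∨ M² ∨ …* .
   Iterative level partitioning then extracts, among remaining elements,
   every *i* with *R(i) ∩ A(i) = R(i)* (reachability set contained in
   antecedent set) as the current level; level 1 is the most dependent
   tier. Strongly connected groups, their condensation and its
   transitive reduction give the hierarchy digraph.
3. **MICMAC.** Driving power = row sum of *M\**, dependence power =
   column sum; a midpoint (default *n*/2) splits each axis, classifying
   every risk as *autonomous*, *dependent*, *linkage* or *independent*
   (root driver).

A synthetic-instance generator plants a known hierarchy (groups + an
acyclic between-group DAG), induces the SSIM a consistent expert panel
would produce, and lets every stage be verified against the planted
truth.

## Worked example

The package bundles the blood-supply-chain case study (102-risk
register, degree table, and the expert SSIM over the 17 key risks).

```sh
ismrisk fixtures --case-study --outdir bundle
ismrisk run --degrees bundle/bsc_degrees.csv --ssim bundle/bsc_ssim.csv --threshold 36
```

prints

```
key risks (17; cutoff 36):
  R98, R5, R7, R13, R11, R87, R100, R102, R1, R16, R20, R40, R49, R67, R35, R62, R63
level 1: R40
level 2: R35
level 3: R1, R16
level 4: R5, R7, R11, R13, R20, R49, R67, R98, R100, R102
level 5: R63, R87
level 6: R62
autonomous: (none)
dependent: R1, R16, R35, R40
linkage: R5, R7, R11, R13, R20, R49, R67, R98, R100, R102
independent: R62, R63, R87
warnings: 1
  - SSIM cell (R11, R5): glyph '0' read as 'O'
```

Reading the output: 17 of the 102 risks clear the degree cutoff 36, led
by R98 (low employee productivity, degree 51). The ISM hierarchy has six
levels. At the top (level 1) sits R40 — insufficient response to
hospital demand — the most dependent outcome risk, fed by R35 (improper
blood inventory) and then R1/R16 (collection estimate, late delivery).
Ten risks (software, equipment, maintenance, supplier and workforce
problems) form one mutually reachable *linkage* block in the middle: high
driving **and** high dependence, so disturbances there amplify. At the
bottom, the *independent* root drivers — R62 economic/political effects
of sanctions, R63 exchange-rate changes, R87 earthquake — influence
nearly everything while depending on almost nothing; R62 additionally
drives R63, putting it alone on the deepest level. No risk is
autonomous. The warning records that one printed SSIM cell used the
digit `0` for the letter `O` and was canonicalized.

Library equivalent:

```python
from ismrisk import SelectionRule, datasets, level_partition, micmac, \
    select_key_risks, ssim_to_initial, transitive_closure

degrees = datasets.load_bsc_degrees()
selected = select_key_risks(degrees, SelectionRule.explicit(36))   # 17 codes
final = transitive_closure(ssim_to_initial(datasets.load_bsc_ssim()))
levels = level_partition(final)          # levels.as_lists(), levels.audit
quadrants = micmac(final)                # quadrants.to_frame()
```

Other subcommands: `centrality` (adjacency → degree table, GraphML/DOT
export), `select`, `ism` (SSIM → matrices, levels, hierarchy digraph),
`micmac`, `simulate` (planted synthetic hierarchy), `fixtures`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline on the bundled case-study inputs — selection at the
cutoff, SSIM conversion and transitive closure — and writes anchor cells
of the computed final reachability matrix (cells that must be filled, or
left empty, by the transitivity check) as JSON.

## Layout

- `src/ismrisk/register.py` — risk register I/O and validation
- `src/ismrisk/network.py` — relation network, degree centrality, selection
- `src/ismrisk/ism.py` — SSIM, reachability matrices, closure, levels, hierarchy
- `src/ismrisk/micmac.py` — driving/dependence powers and quadrants
- `src/ismrisk/synth.py` — planted-hierarchy and degree-profile generators
- `src/ismrisk/pipeline.py`, `src/ismrisk/cli.py` — orchestration and CLI
- `src/ismrisk/data/` — bundled case-study tables
- `docs/methods.md` — modelling assumptions and numerical conventions
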