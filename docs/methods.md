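# Methods

## Graph model

A molecule enters as a hydrogen-suppressed skeleton: one vertex per heavy
atom, one edge per covalent bond, bond order and aromaticity discarded.
This is the convention under which the chlorpromazine reference counts
(21 vertices, 23 edges) hold exactly, and it makes every index a function
of connectivity alone. Graphs must be simple and connected; a
disconnected input is a hard error because every eccentricity, and hence
every index, would be infinite. Input formats are a minimal edge-list
dialect (1-based integer ids, whitespace-separated pairs, `#` comments) —
chosen because structures in this literature are published as drawings
and transcribed by hand — and SMILES via the optional RDKit backend. The
two routes are cross-checked against each other in the tests.

Distances are one breadth-first search per vertex (networkx);
eccentricities are the per-source BFS maxima. The vertex eccentricity
partition {ξ: count} and the edge partition {(ξ_u, ξ_v): count}, with
unordered keys stored (min, max) since every index term is symmetric in
the endpoints, are the summaries all edge-sum indices are computed from.

## The two conventions

The reproduced study's own arithmetic deviates from the literature
definitions in two places, and both behaviours are kept, explicitly
labelled, instead of silently fixing either:

* **M₁\*\***: defined in the literature as Σ_v ξ(v)² (`standard`), but the
  study's worked example computes Σ_k (n_k·k)² — the square of each
  eccentricity class's count-times-value (`paper_faithful`; 5978 vs 1192
  for chlorpromazine). The paper-faithful form is a function of the
  partition, not vertex-additive, which is why the partition appears in
  the operation's signature.
* **eccentric ABC**: literature term √((ξ_u+ξ_v−2)/(ξ_u ξ_v))
  (`standard`), worked example √(ξ_u+ξ_v−2)/(ξ_u ξ_v) with the root over
  the numerator only (`paper_faithful`; 1.6352 vs 11.335). The
  paper-faithful term never exceeds the standard one (ξ_u ξ_v ≥ 1).

The library default is `standard` (mathematically conventional); the
reproduction pipeline pins `paper_faithful`, without which the printed
index table cannot be matched. All other indices agree under both. The
summation domain "v ∈ E(G)" in the study's M₁\*\* definition is read as a
typo for V(G) in standard mode, as every cited source defines it over
vertices. The study's further claim that M₁\* equals ζ(G) is false in
general (332 ≠ 156 on its own worked example); only the correct identity
M₁\* = Σ_v d(v)ξ(v) is asserted.

Average eccentricity is computed as an exact rational (ζ/n via
`fractions.Fraction`) so the invariant avec·n = ζ holds exactly; it is
stored as a float in the index vector. Full precision is kept internally
everywhere; 4-decimal rounding is display-only, matching the source
tables (which sometimes truncate rather than round — GA₄ of
chlorpromazine is 22.94507, printed 22.9450 — so print-comparisons use a
one-unit-in-the-last-place tolerance of 1e-4).

## Regression

Both model forms are ordinary least squares on the design [1, x] or
[1, x, x²] via `numpy.linalg.lstsq`. Reported statistics: R² = 1 −
SSE/SST, r = √R² (non-negative by construction — the source tables print
positive r even for negative slopes, whose sign lives in β), the overall
F = (R²/k)/((1−R²)/(n−k−1)), and its upper tail under F(k, n−k−1)
(`scipy.stats.f.sf`; the test suite checks it against quadrature of a
hand-written F density). Exact fits (1−R² < 1e-12) report R² = 1 with
F = ∞ and p = 0 rather than overflowing. Significance screening uses the
study's stated thresholds — p ≤ 0.05, F > 2.5 (strict), r > 0.7 (strict)
— with no multiple-testing correction, as none was applied in the source.
Rank-deficient designs (constant predictor, < 3 distinct x for the
quadratic) are errors in the single-fit API and degenerate records, not
batch failures, in the 8×8 grid API.

## Embedded data and its audit

The thirteen-drug property and index tables are shipped verbatim as CSV
resources, anomalies included. The available rendering of the source
tables runs digits together in places; transcription of the ambiguous
cells chose the grouping maximising internal arithmetic consistency
(avec = ζ/n for an integer n; M₁\* ≈ 2·avec·m and M₂\* ≈ avec²·m with m
implied by GA₄ ≈ m, since each GA₄ term lies in (0,1] and is near 1).
Every such cell is listed in `dataset.UNCERTAIN_CELLS`. The complexity
column is additionally cross-validated by reproducing the published
complexity ~ GA₄ regression statistics (r = 0.6602, F = 8.498) from it.

`validate_consistency()` audits what is printed: (i) each drug's avec
must equal ζ/n for some integer n at the printed precision (accepting
both rounding and truncation) — drug c fails (ζ = 218, avec = 8.75);
(ii) printed edge-partition classes must satisfy |ξ_u − ξ_v| ≤ 1, which
holds for adjacent vertices in any graph; (iii) the printed quadratic
correlation table must dominate the linear one entrywise, since OLS on
nested designs cannot lose variance explained — the avec ~ boiling-point
pair fails (0.1554 quadratic vs 0.2119 linear). These are reported, never
repaired, and the reproduction tests do not assert agreement with rows
the audit marks as internally impossible. Only the chlorpromazine
structure is printed in the source; the other twelve drug graphs exist
only as figures and are not reconstructable, so the full index table is
data, not a computed reproduction.

## Synthetic data

`random_molecular_graph` grows a random spanning tree by uniform
attachment under a degree cap (default 4, carbon valence in a
hydrogen-suppressed skeleton) and then closes 0–5 rings between
non-adjacent vertices with spare valence, over 3–60 vertices — the size
and shape regime of the drug skeletons studied. It emulates connectivity
statistics only: no element identities, valence rules beyond the cap, or
aromaticity, so passing tests demonstrate correctness of the graph
machinery, not chemical realism. `random_regression_data` draws x uniform
on [0, 10] and y = α + βx + γx² + N(0, σ²); the default σ = 1 against
slopes of order 1 gives the moderate signal-to-noise regime in which the
3-standard-error parameter-recovery test (n = 200) is meaningful. Each
generator derives one named stream per operation from its integer seed
(`numpy.random.default_rng` seeded with [seed, stream-label]); no global
state.

The distance oracle is a deliberately independent dense Floyd–Warshall
(O(n³) relaxation on an adjacency matrix, no code shared with the BFS
route); tests require elementwise equality with BFS on 200 synthetic
graphs up to n = 60, and equality of all indices recomputed from oracle
distances.

## Problem sizes and numerical choices

The suite uses 200-graph oracle sweeps (n ≤ 60), 120-example property
sweeps for structural invariants, and n = 200 regression recovery — sizes
at which every check is exact or sampling-theory-bounded while the whole
suite completes in a few seconds. Floating-point comparisons use 1e-12
absolute slack for identities that are exact in real arithmetic, and the
print-precision tolerance above for comparisons against typeset numbers.
Tie-breaks: edge-partition keys sorted (min, max); CSV column order fixed
to (ζ, avec, M₁\*, M₁\*\*, M₂\*, GA₄, ABC, Hₑ).

## Limitations

* Only connected simple graphs; no bond orders, charges, stereochemistry
  or 3D information — by construction these indices cannot see them.
* The twelve non-chlorpromazine index rows are trusted transcription, not
  recomputation; their middle columns carry transcription uncertainty
  (flagged).
* r, F and p describe in-sample fit of 13 observations; no
  cross-validation or out-of-sample assessment is attempted, matching the
  scope of the reproduced analysis.
* Cubic and multivariate models are out of scope.
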