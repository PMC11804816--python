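# eccqspr

Eccentricity-based topological indices of molecular graphs, and QSPR
regression of drug properties on them.

## What this is for

In quantitative structure–property relationship (QSPR) modelling, a
molecule is reduced to its hydrogen-suppressed graph *G* — heavy atoms as
vertices, covalent bonds as edges, bond order ignored — and numerical
graph invariants ("topological indices") are used as predictors of
physicochemical properties. This package implements the family of indices
built on the vertex **eccentricity**

> ξ(v) = max<sub>u</sub> d(v, u),

the largest shortest-path distance from v to any other vertex:

| index | definition |
|---|---|
| total eccentricity | ζ(G) = Σ<sub>v</sub> ξ(v) |
| average eccentricity | avec(G) = ζ(G)/n |
| first Zagreb ecc. | M₁\*(G) = Σ<sub>uv∈E</sub> [ξ(u)+ξ(v)] |
| second Zagreb ecc. | M₁\*\*(G) = Σ<sub>v</sub> ξ(v)² |
| third Zagreb ecc. | M₂\*(G) = Σ<sub>uv∈E</sub> ξ(u)ξ(v) |
| geometric–arithmetic | GA₄(G) = Σ<sub>uv∈E</sub> 2√(ξ(u)ξ(v)) / (ξ(u)+ξ(v)) |
| eccentric ABC | ABC(G) = Σ<sub>uv∈E</sub> √((ξ(u)+ξ(v)−2) / (ξ(u)ξ(v))) |
| eccentric harmonic | H<sub>e</sub>(G) = Σ<sub>uv∈E</sub> 2 / (ξ(u)+ξ(v)) |

and fits linear (Y = α + β·EI) and quadratic (Y = α + β·EI + γ·EI²)
ordinary-least-squares models of eight physicochemical properties —
boiling point, melting point, enthalpy, flash point, molar refractivity,
complexity, molecular weight, refractive index — on each index, reporting
r = √R², R², the overall F statistic and its p-value.

The package ships the printed data of a published QSPR study of thirteen
anti-schizophrenia drugs (property table, index table, and the
chlorpromazine worked example) as fixtures, recomputes everything that is
recomputable, and audits the printed tables for internal inconsistencies
rather than correcting them silently. Two arithmetic conventions are
supported for M₁\*\* and the eccentric ABC index (`standard` and
`paper_faithful`); see `docs/methods.md` for why.

Intended users: cheminformatics / chemical graph theory researchers who
want a tested reference implementation of eccentric indices, and anyone
auditing or extending descriptor-based QSPR studies.

## Worked example

```python
>>> import eccqspr as E
>>> g, printed = E.dataset.chlorpromazine_fixture()
>>> g.n, g.m
(21, 23)
>>> E.vertex_ecc_partition(E.eccentricities(g))
{9: 5, 8: 6, 7: 5, 6: 3, 5: 2}
>>> E.compute_all(g, "paper_faithful").rounded(4)
{'zeta': 156, 'avec': 7.4286, 'm1_star': 332, 'm1_dstar': 5978,
 'm2_star': 1221, 'ga4': 22.9451, 'abc': 1.6352, 'he': 3.2715,
 'convention': 'paper_faithful'}
```

Chlorpromazine's 21-atom skeleton has two vertices of eccentricity 5
(the graph's radius) up to five of eccentricity 9 (the diameter); summing
them gives ζ = 156, and the edge-partition sums give the remaining
indices. (GA₄ is exactly 22.94507; the source table truncates it to
22.9450.)

Regressing complexity on GA₄ across the thirteen drugs:

```python
>>> E.fit_linear(E.dataset.load_paper_indices()["ga4"],
...              E.dataset.load_properties()["C"]).as_record()
{'model': 'linear', 'alpha': -81.899..., 'beta': 20.492..., 'gamma': None,
 'r': 0.6601884819052668, 'r2': 0.4358488316403808,
 'f': 8.498319983958678, 'p': 0.014057967504337002, 'n': 13,
 'p_ok': True, 'f_ok': True, 'r_ok': False, 'overall': False}
```

The fit is significant by the p ≤ 0.05 and F > 2.5 screens but misses the
r > 0.7 correlation threshold — GA₄ is the best of the eight indices at
predicting complexity, yet still a moderate predictor.

The same pipeline is available from the shell:

```bash
eccqspr reproduce --out reproduction/   # printed vs recomputed tables + anomaly report
eccqspr indices --format smiles 'CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21'
eccqspr validate-fixtures               # audit of the embedded printed tables
```

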