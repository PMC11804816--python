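"""Eccentricity-based topological indices.

Eight descriptors of a connected molecular graph, all functions of the vertex
eccentricities xi(v) (see :mod:`eccqspr.molgraph`):

======================  =====================================================
total eccentricity      zeta(G) = sum_v xi(v)
average eccentricity    avec(G) = zeta(G) / n
first Zagreb ecc.       M1*(G)  = sum_{uv in E} [xi(u) + xi(v)]
second Zagreb ecc.      M1**(G) = sum_v xi(v)^2                   (standard)
third Zagreb ecc.       M2*(G)  = sum_{uv in E} xi(u) xi(v)
geometric-arithmetic    GA4(G)  = sum_{uv in E} 2 sqrt(xi(u) xi(v)) / (xi(u)+xi(v))
eccentric ABC           ABC(G)  = sum_{uv in E} sqrt((xi(u)+xi(v)-2) / (xi(u) xi(v)))
eccentric harmonic      He(G)   = sum_{uv in E} 2 / (xi(u) + xi(v))
======================  =====================================================

The degree-based harmonic index H(G) = sum_{uv} 2/(d(u)+d(v)) is provided for
completeness.

Two conventions
---------------
The published source tables this package reproduces were computed with
nonstandard arithmetic for two of the indices, so every affected operation
takes a ``convention`` argument:

* ``"standard"`` (default) — the literature definitions above.
* ``"paper_faithful"`` — the arithmetic actually used in the source tables:
  M1** is computed on the vertex eccentricity partition as
  sum_k (n_k * k)^2, the squared product of each eccentricity value with its
  multiplicity, and the ABC square root covers the numerator only:
  sqrt(xi(u)+xi(v)-2) / (xi(u) xi(v)).

Neither behaviour is silently "corrected": ``standard`` preserves the
mathematics, ``paper_faithful`` reproduces the printed tables.  All other
indices are identical under both conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from fractions import Fraction
from typing import Mapping

from .molgraph import (
    MolecularGraph,
    eccentricities,
    edge_ecc_partition,
    vertex_ecc_partition,
)

__all__ = [
    "CONVENTIONS",
    "IndexVector",
    "total_eccentricity",
    "average_eccentricity",
    "first_zagreb_ecc",
    "second_zagreb_ecc",
    "third_zagreb_ecc",
    "geometric_arithmetic_ecc",
    "atom_bond_connectivity_ecc",
    "eccentric_harmonic",
    "harmonic_degree",
    "compute_all",
    "INDEX_COLUMNS",
]

CONVENTIONS = ("standard", "paper_faithful")

#: column order used in CSV output and in the regression tables
INDEX_COLUMNS = ("zeta", "avec", "m1_star", "m1_dstar", "m2_star",
                 "ga4", "abc", "he")


def _check_convention(conv: str) -> None:
    if conv not in CONVENTIONS:
        raise ValueError(f"unknown convention {conv!r}; expected one of {CONVENTIONS}")


@dataclass(frozen=True)
class IndexVector:
    """The eight eccentric index values of one graph under one convention."""

    zeta: int
    avec: float
    m1_star: int
    m1_dstar: int
    m2_star: int
    ga4: float
    abc: float
    he: float
    convention: str = "standard"

    def as_dict(self) -> dict:
        return asdict(self)

    def rounded(self, ndigits: int = 4) -> dict:
        """Display form: floats rounded to ``ndigits`` decimal places."""
        out = {}
        for k, v in self.as_dict().items():
            out[k] = round(v, ndigits) if isinstance(v, float) else v
        return out


def total_eccentricity(ecc: Mapping[int, int]) -> int:
    """zeta(G): the sum of all vertex eccentricities."""
    if not ecc:
        raise ValueError("empty eccentricity vector")
    return sum(ecc.values())


def average_eccentricity(ecc: Mapping[int, int]) -> Fraction:
    """avec(G) = zeta(G)/n as an exact rational (so avec * n == zeta exactly)."""
    return Fraction(total_eccentricity(ecc), len(ecc))


def first_zagreb_ecc(edge_part: Mapping[tuple[int, int], int]) -> int:
    """M1*(G): edge sum of endpoint eccentricities.

    Equals sum_v d(v) xi(v), since xi(u) occurs once per edge incident to u.
    """
    return sum(count * (a + b) for (a, b), count in edge_part.items())


def second_zagreb_ecc(ecc: Mapping[int, int], part: Mapping[int, int] | None = None,
                      convention: str = "standard") -> int:
    """M1**(G), the squared-eccentricity Zagreb index.

    ``standard``: sum over vertices of xi(v)^2.  ``paper_faithful``: sum over
    distinct eccentricity values k of (n_k * k)^2 where n_k is the number of
    vertices with eccentricity k — a partition-level quantity, not a
    vertex-additive one, which is why the vertex partition is part of the
    signature.
    """
    _check_convention(convention)
    if part is None:
        part = vertex_ecc_partition(ecc)
    if convention == "standard":
        return sum(n_k * k * k for k, n_k in part.items())
    return sum((n_k * k) ** 2 for k, n_k in part.items())


def third_zagreb_ecc(edge_part: Mapping[tuple[int, int], int]) -> int:
    """M2*(G): edge sum of endpoint eccentricity products."""
    return sum(count * a * b for (a, b), count in edge_part.items())


def geometric_arithmetic_ecc(edge_part: Mapping[tuple[int, int], int]) -> float:
    """GA4(G): edge sum of 2 sqrt(xi_u xi_v) / (xi_u + xi_v).

    Each term is the geometric-to-arithmetic mean ratio of the endpoint
    eccentricities, hence lies in (0, 1]; GA4 <= m with equality iff every
    edge has equal endpoint eccentricities.
    """
    return sum(count * 2.0 * math.sqrt(a * b) / (a + b)
               for (a, b), count in edge_part.items())


def atom_bond_connectivity_ecc(edge_part: Mapping[tuple[int, int], int],
                               convention: str = "standard") -> float:
    """Eccentric ABC index.

    ``standard`` per-edge term: sqrt((xi_u + xi_v - 2) / (xi_u xi_v)).
    ``paper_faithful``: sqrt(xi_u + xi_v - 2) / (xi_u xi_v), the square root
    taken over the numerator only.  Since xi_u xi_v >= 1 the paper-faithful
    term never exceeds the standard one.
    """
    _check_convention(convention)
    total = 0.0
    for (a, b), count in edge_part.items():
        if convention == "standard":
            term = math.sqrt((a + b - 2) / (a * b))
        else:
            term = math.sqrt(a + b - 2) / (a * b)
        total += count * term
    return total


def eccentric_harmonic(edge_part: Mapping[tuple[int, int], int]) -> float:
    """He(G): edge sum of 2 / (xi_u + xi_v)."""
    return sum(count * 2.0 / (a + b) for (a, b), count in edge_part.items())


def harmonic_degree(g: MolecularGraph) -> float:
    """Degree-based harmonic index H(G) = sum over edges of 2/(d(u)+d(v))."""
    return sum(2.0 / (g.degree(u) + g.degree(v)) for u, v in g.edges)


def compute_all(g: MolecularGraph, convention: str = "standard") -> IndexVector:
    """All eight indices of ``g`` from a single eccentricity computation."""
    _check_convention(convention)
    ecc = eccentricities(g)
    vpart = vertex_ecc_partition(ecc)
    epart = edge_ecc_partition(g, ecc)
    return IndexVector(
        zeta=total_eccentricity(ecc),
        avec=float(average_eccentricity(ecc)),
        m1_star=first_zagreb_ecc(epart),
        m1_dstar=second_zagreb_ecc(ecc, vpart, convention),
        m2_star=third_zagreb_ecc(epart),
        ga4=geometric_arithmetic_ecc(epart),
        abc=atom_bond_connectivity_ecc(epart, convention),
        he=eccentric_harmonic(epart),
        convention=convention,
    )
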