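"""Embedded study data: thirteen anti-schizophrenia drugs.

Ships the source study's printed tables as package resources:

* ``properties.csv`` — eight physicochemical properties per drug (ids a-m):
  boiling point, melting point, enthalpy, flash point, molar refractivity,
  complexity, molecular weight, refractive index.
* ``paper_indices.csv`` — the eight eccentric index values per drug as
  printed (the paper-faithful convention), anomalies included.
* ``printed_correlations_{linear,quadratic}.csv`` — the printed 8x8
  index-by-property correlation tables.
* ``chlorpromazine.edgelist`` — the heavy-atom skeleton of chlorpromazine
  (drug a), the one structure whose worked example is fully printed.

Printed values are stored verbatim and never corrected; internal
inconsistencies are surfaced by :func:`validate_consistency` instead.  The
source tables were transcribed from a rendering with ambiguous digit
grouping in places; :data:`UNCERTAIN_CELLS` flags the cells whose grouping
was resolved by arithmetic-plausibility checks rather than read directly.
"""

from __future__ import annotations

from importlib import resources
from math import floor

import pandas as pd

from .molgraph import MolecularGraph, read_edge_list

__all__ = [
    "CHLORPROMAZINE_SMILES",
    "CHLORPROMAZINE_VERTEX_PARTITION",
    "CHLORPROMAZINE_EDGE_PARTITION",
    "UNCERTAIN_CELLS",
    "load_properties",
    "load_paper_indices",
    "load_printed_correlations",
    "chlorpromazine_fixture",
    "validate_consistency",
]

CHLORPROMAZINE_SMILES = "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21"

#: printed vertex eccentricity partition {eccentricity: #vertices} of drug a
CHLORPROMAZINE_VERTEX_PARTITION = {5: 2, 6: 3, 7: 5, 8: 6, 9: 5}

#: printed edge eccentricity partition {(xi_u, xi_v): #edges} of drug a
CHLORPROMAZINE_EDGE_PARTITION = {(5, 5): 1, (5, 6): 3, (6, 7): 5,
                                 (7, 8): 7, (8, 9): 7}

#: (table, drug id, column) cells whose digit grouping in the available
#: rendering was ambiguous; the transcription chosen maximises internal
#: arithmetic consistency (avec = zeta/n for integer n, M1* ~ 2*avec*m,
#: M2* ~ avec^2*m with m implied by the GA4 column).
UNCERTAIN_CELLS = tuple(
    [("indices", d, col) for d in "bcdefghijklm"
     for col in ("m1_star", "m1_dstar", "m2_star")]
    + [("indices", "b", "avec"), ("indices", "g", "avec")]
    + [("properties", "h", "MW"), ("properties", "h", "R")]
)


def _resource(name: str):
    return resources.files("eccqspr.data").joinpath(name)


def load_properties() -> pd.DataFrame:
    """Physicochemical property table, indexed by drug id a-m."""
    with resources.as_file(_resource("properties.csv")) as path:
        df = pd.read_csv(path, index_col="id")
    return df


def load_paper_indices() -> pd.DataFrame:
    """Printed eccentric index table, indexed by drug id a-m.

    Values are exactly as printed (paper-faithful convention for the
    second Zagreb and ABC columns), including internal inconsistencies.
    """
    with resources.as_file(_resource("paper_indices.csv")) as path:
        df = pd.read_csv(path, index_col="id")
    return df


def load_printed_correlations(model: str = "linear") -> pd.DataFrame:
    """Printed 8x8 correlation comparison table for one model kind."""
    if model not in ("linear", "quadratic"):
        raise ValueError(f"model must be 'linear' or 'quadratic', got {model!r}")
    with resources.as_file(_resource(f"printed_correlations_{model}.csv")) as path:
        df = pd.read_csv(path, index_col="index")
    return df


def chlorpromazine_fixture() -> tuple[MolecularGraph, dict]:
    """The chlorpromazine graph plus its printed reference data.

    The graph is built from the embedded edge list (no cheminformatics
    backend needed); the dict carries the SMILES and the printed vertex and
    edge eccentricity partitions so that tests can compare computation
    against print rather than trusting either alone.
    """
    with resources.as_file(_resource("chlorpromazine.edgelist")) as path:
        g = read_edge_list(path)
    printed = {
        "smiles": CHLORPROMAZINE_SMILES,
        "vertex_partition": dict(CHLORPROMAZINE_VERTEX_PARTITION),
        "edge_partition": dict(CHLORPROMAZINE_EDGE_PARTITION),
        "n": 21,
        "m": 23,
    }
    return g, printed


# -- printed-table audit ---------------------------------------------------

def _decimals(text: str) -> int:
    return len(text.split(".")[1]) if "." in text else 0


def _avec_consistent(zeta: int, avec_text: str, n_max: int = 60) -> bool:
    """Is there an integer order n with zeta/n printing as ``avec_text``?

    Both round-to-nearest and truncation at the printed number of decimals
    are accepted, since the source table uses both.
    """
    printed = float(avec_text)
    nd = _decimals(avec_text)
    scale = 10 ** nd
    for n in range(2, n_max + 1):
        exact = zeta / n
        if round(exact, nd) == printed or floor(exact * scale) / scale == printed:
            return True
    return False


def validate_consistency() -> list[dict]:
    """Audit the embedded printed tables; returns a list of anomaly records.

    Checks performed:

    * average eccentricity: for each drug, the printed avec must equal
      zeta/n for some integer order n (printed precision);
    * edge eccentricity adjacency: every printed edge-partition key
      (xi_u, xi_v) must satisfy |xi_u - xi_v| <= 1;
    * nested models: the printed quadratic correlation must be at least the
      printed linear correlation for every index/property pair (a quadratic
      OLS fit can never explain less variance than the linear fit it nests).

    An empty list means no anomalies; the embedded tables are known to
    produce a non-empty report.
    """
    anomalies: list[dict] = []
    idx = load_paper_indices()
    # avec vs zeta: re-read avec as text to know the printed precision
    with resources.as_file(_resource("paper_indices.csv")) as path:
        raw = pd.read_csv(path, index_col="id", dtype=str)
    for drug in idx.index:
        zeta = int(idx.loc[drug, "zeta"])
        avec_text = raw.loc[drug, "avec"]
        if not _avec_consistent(zeta, avec_text):
            anomalies.append({
                "kind": "avec_inconsistent",
                "drug": drug,
                "detail": f"zeta={zeta} with printed avec={avec_text} "
                          f"implies a non-integer number of vertices",
            })
    for (a, b) in CHLORPROMAZINE_EDGE_PARTITION:
        if abs(a - b) > 1:
            anomalies.append({
                "kind": "edge_adjacency_violation",
                "drug": "a",
                "detail": f"printed edge class ({a},{b}) violates |xi_u - xi_v| <= 1",
            })
    lin = load_printed_correlations("linear")
    quad = load_printed_correlations("quadratic")
    for index_name in lin.index:
        for prop in lin.columns:
            r_lin, r_quad = lin.loc[index_name, prop], quad.loc[index_name, prop]
            if r_quad < r_lin:
                anomalies.append({
                    "kind": "nested_model_violation",
                    "cell": (index_name, prop),
                    "detail": f"printed quadratic r={r_quad} < linear r={r_lin}; "
                              f"impossible for nested OLS models",
                })
    return anomalies
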