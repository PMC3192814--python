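"""Substrate–product network reconstruction from reaction lists.

Metabolic networks are rebuilt here the way curated small-molecule networks
are assembled from reaction databases: reactions involving macromolecules or
R-group (unspecified-residue) compounds are dropped outright, currency
metabolites (ATP, NAD, water, ions, ...) are struck from the remaining
substrate/product sets, and every surviving substrate is connected to every
surviving product of the same reaction by an undirected edge. The resulting
graph is simple (no self-loops, no parallel edges) and its degree histogram
is summarised by a log-log least-squares power-law fit N = a * D**-b.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Reaction",
    "MetaboliteAnnotation",
    "PowerLawFit",
    "ReactionParseError",
    "MissingAnnotationError",
    "InsufficientDataError",
    "parse_reactions",
    "read_annotations",
    "filter_reactions",
    "build_network",
    "compute_degrees",
    "degree_histogram",
    "fit_power_law",
    "write_edge_list",
    "write_degree_table",
    "write_powerlaw_json",
]


class ReactionParseError(ValueError):
    """A reaction line could not be parsed; the message names the line."""


class MissingAnnotationError(KeyError):
    """A metabolite referenced by a reaction has no annotation row."""


class InsufficientDataError(ValueError):
    """Too few distinct degrees to fit a power law."""


@dataclass(frozen=True)
class Reaction:
    """One metabolic reaction as unordered substrate and product sets.

    Stoichiometric coefficients and reversibility are deliberately ignored:
    the downstream graph is undirected and duplicate mentions of a metabolite
    on one side carry no information for substrate–product connectivity.
    """

    id: str
    substrates: frozenset[str]
    products: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise ValueError("reaction id must be non-blank")
        for side in (self.substrates, self.products):
            for met in side:
                if not met or not met.strip():
                    raise ValueError(f"blank metabolite id in reaction {self.id!r}")

    @property
    def metabolites(self) -> frozenset[str]:
        return self.substrates | self.products


@dataclass(frozen=True)
class MetaboliteAnnotation:
    """Curation flags for one metabolite.

    All flags are explicit; a missing annotation row is an error rather than
    an implicit "not currency / not macromolecule".
    """

    id: str
    is_macromolecule: bool = False
    has_r_group: bool = False
    is_currency: bool = False
    smiles: str | None = None


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of N = a * D**-b on log-log axes."""

    a: float
    b: float
    r_squared: float
    degrees_used: tuple[int, ...]

    def predict(self, degree: float) -> float:
        return self.a * degree ** (-self.b)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "r_squared": self.r_squared,
            "degrees_used": list(self.degrees_used),
        }


# ---------------------------------------------------------------------------
# Parsing


def _parse_side(text: str, lineno: int) -> frozenset[str]:
    names = [t.strip() for t in text.split(" + ")]
    names = [n for n in names if n]
    if not names:
        raise ReactionParseError(f"line {lineno}: empty reaction side")
    return frozenset(names)


def parse_reactions(path: str | Path) -> list[Reaction]:
    """Parse a tab-separated reaction list.

    Each non-blank, non-comment line is ``RID<TAB>A + B = C + D``; ``" + "``
    separates species within a side and ``" = "`` separates the two sides.
    Lines starting with ``#`` are comments.
    """
    reactions: list[Reaction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" not in line:
                raise ReactionParseError(f"line {lineno}: expected '<id>\\t<equation>'")
            rid, equation = line.split("\t", 1)
            if " = " not in equation:
                raise ReactionParseError(f"line {lineno}: no ' = ' separator")
            lhs, rhs = equation.split(" = ", 1)
            reactions.append(
                Reaction(
                    id=rid.strip(),
                    substrates=_parse_side(lhs, lineno),
                    products=_parse_side(rhs, lineno),
                )
            )
    return reactions


def read_annotations(path: str | Path) -> list[MetaboliteAnnotation]:
    """Read the annotation table (TSV with header id, is_macromolecule,
    has_r_group, is_currency, smiles)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "is_macromolecule", "has_r_group", "is_currency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")

    def as_bool(v: str) -> bool:
        return str(v).strip().lower() in {"1", "true", "yes"}

    out = []
    for row in df.itertuples(index=False):
        out.append(
            MetaboliteAnnotation(
                id=row.id,
                is_macromolecule=as_bool(row.is_macromolecule),
                has_r_group=as_bool(row.has_r_group),
                is_currency=as_bool(row.is_currency),
                smiles=(getattr(row, "smiles", "") or None),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Filtering


def filter_reactions(
    reactions: Sequence[Reaction],
    annotations: Iterable[MetaboliteAnnotation],
    currency_overrides: Mapping[str, Iterable[str]] | None = None,
) -> list[Reaction]:
    """Apply the screening criteria to a reaction list.

    1. Reactions containing a macromolecule or an R-group metabolite are
       removed entirely.
    2. Currency metabolites are removed from the substrate and product sets
       of the remaining reactions. ``currency_overrides`` maps a reaction id
       to currency metabolite ids that should be *kept* in that reaction —
       the per-reaction exception for currency species that participate as
       genuine substrates or products.
    3. Reactions left with an empty side are removed.

    Idempotent: filtering an already-filtered list is a no-op.
    """
    ann = {a.id: a for a in annotations}
    overrides = {rid: frozenset(kept) for rid, kept in (currency_overrides or {}).items()}

    kept_reactions: list[Reaction] = []
    for rxn in reactions:
        for met in rxn.metabolites:
            if met not in ann:
                raise MissingAnnotationError(
                    f"metabolite {met!r} (reaction {rxn.id!r}) has no annotation"
                )
        if any(ann[m].is_macromolecule or ann[m].has_r_group for m in rxn.metabolites):
            continue
        keep_here = overrides.get(rxn.id, frozenset())

        def survives(met: str) -> bool:
            return (not ann[met].is_currency) or met in keep_here

        subs = frozenset(m for m in rxn.substrates if survives(m))
        prods = frozenset(m for m in rxn.products if survives(m))
        if not subs or not prods:
            continue
        kept_reactions.append(Reaction(rxn.id, subs, prods))
    return kept_reactions


# ---------------------------------------------------------------------------
# Graph construction and degree statistics


def build_network(reactions: Sequence[Reaction]) -> nx.Graph:
    """Build the undirected substrate–product graph.

    Every substrate of a reaction is linked to every product of the same
    reaction (complete bipartite expansion per reaction); self-pairs are
    dropped and edges are deduplicated across reactions. Metabolites that
    yield no edge (e.g. only appear in identity reactions) are not nodes.
    """
    g = nx.Graph()
    for rxn in reactions:
        for s in rxn.substrates:
            for p in rxn.products:
                if s != p:
                    g.add_edge(s, p)
    return g


def compute_degrees(network: nx.Graph) -> pd.DataFrame:
    """Degree table: one row per node, columns (id, degree)."""
    rows = sorted(network.degree(), key=lambda t: t[0])
    return pd.DataFrame(rows, columns=["id", "degree"])


def degree_histogram(table: pd.DataFrame) -> list[tuple[int, int]]:
    """Histogram of the degree table as (degree, count) pairs, ascending,
    omitting degrees with zero count."""
    if table.empty:
        raise ValueError("degree table is empty")
    counts = table["degree"].value_counts().sort_index()
    return [(int(d), int(c)) for d, c in counts.items()]


def fit_power_law(hist: Sequence[tuple[int, int]]) -> PowerLawFit:
    """Ordinary least squares of log10(count) on log10(degree).

    Returns the prefactor ``a = 10**intercept``, the exponent ``b = -slope``
    and the r-squared of the log-log regression. Degree-0 or count-0 entries
    are excluded (their logarithm is undefined); at least three distinct
    degrees must remain.
    """
    pts = [(d, c) for d, c in hist if d > 0 and c > 0]
    if len({d for d, _ in pts}) < 3:
        raise InsufficientDataError(
            f"power-law fit needs >=3 distinct degrees with nonzero counts, got {len(pts)}"
        )
    x = np.log10([d for d, _ in pts])
    y = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(
        a=float(10.0**intercept),
        b=float(-slope),
        r_squared=float(r2),
        degrees_used=tuple(d for d, _ in pts),
    )


# ---------------------------------------------------------------------------
# Export


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Two-column TSV of lexicographically ordered node pairs."""
    edges = sorted(tuple(sorted(e)) for e in network.edges())
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def write_degree_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_powerlaw_json(fit: PowerLawFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
        fh.write("\n")
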