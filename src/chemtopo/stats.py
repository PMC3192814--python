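"""Topology–chemistry statistics: degree grouping, rank tests, binned
correlations, and early/late metabolome classification.

The central pattern is Table-style summarisation: metabolites are grouped by
degree interval (e.g. degree 1 / 2–6 / >6 for hubs vs leaves), each group's
property mean ± standard error is reported, group differences are tested
with rank statistics (Kruskal–Wallis across k groups, Mann–Whitney for two),
and the trend across ordered groups is quantified as a Pearson correlation of
the group means against the ordinal group index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DegreeInterval",
    "GroupScheme",
    "GroupSummary",
    "DEGREE_SCHEME_HUBS",
    "DEGREE_SCHEME_WIDE",
    "group_by_degree",
    "kruskal_wallis",
    "mann_whitney",
    "binned_correlation",
    "classify_age",
]


@dataclass(frozen=True)
class DegreeInterval:
    """Inclusive integer degree interval; ``upper=None`` means unbounded."""

    label: str
    lower: int
    upper: int | None = None

    def contains(self, degree: int) -> bool:
        return degree >= self.lower and (self.upper is None or degree <= self.upper)


class GroupScheme:
    """Ordered, disjoint degree intervals."""

    def __init__(self, intervals: Sequence[DegreeInterval]):
        if not intervals:
            raise ValueError("scheme needs at least one interval")
        for prev, cur in zip(intervals, intervals[1:]):
            if prev.upper is None or cur.lower <= prev.upper:
                raise ValueError("intervals must be disjoint and ascending")
        self.intervals = tuple(intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def assign(self, degree: int) -> str | None:
        for iv in self.intervals:
            if iv.contains(degree):
                return iv.label
        return None

    @classmethod
    def from_edges(cls, spec: Sequence[tuple[str, int, int | None]]) -> "GroupScheme":
        return cls([DegreeInterval(*row) for row in spec])


# The two grouping conventions used for hub analyses of small-molecule
# networks: a tight scheme for sparse networks and a wide one for dense ones.
DEGREE_SCHEME_HUBS = GroupScheme.from_edges(
    [("degree 1", 1, 1), ("degree 2-6", 2, 6), ("degree >6", 7, None)]
)
DEGREE_SCHEME_WIDE = GroupScheme.from_edges(
    [("degree 1-3", 1, 3), ("degree 4-15", 4, 15), ("degree >15", 16, None)]
)


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    se: float
    values: tuple[float, ...] = ()

    @property
    def empty(self) -> bool:
        return self.n == 0


def group_by_degree(
    degrees: Mapping[str, int] | pd.DataFrame,
    values: Mapping[str, float] | pd.Series,
    scheme: GroupScheme,
) -> list[GroupSummary]:
    """Group a per-metabolite property by degree interval.

    ``degrees`` is an id->degree mapping or a (id, degree) DataFrame;
    ``values`` maps ids to property values. Missing (NaN) property values are
    excluded pairwise. Each summary carries n, mean and the standard error
    sd/sqrt(n) (0 by convention for n=1); empty groups are flagged with n=0.
    """
    if isinstance(degrees, pd.DataFrame):
        degrees = dict(zip(degrees["id"], degrees["degree"]))
    if isinstance(values, pd.Series):
        values = values.to_dict()

    buckets: dict[str, list[float]] = {iv.label: [] for iv in scheme}
    for met, deg in degrees.items():
        v = values.get(met, math.nan)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        label = scheme.assign(int(deg))
        if label is not None:
            buckets[label].append(float(v))

    out = []
    for iv in scheme:
        vals = buckets[iv.label]
        if not vals:
            out.append(GroupSummary(iv.label, 0, math.nan, math.nan))
            continue
        arr = np.asarray(vals)
        se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        out.append(GroupSummary(iv.label, len(arr), float(arr.mean()), se, tuple(vals)))
    return out


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square (k-1 df) p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.all(a == arrays[0][0]) for a in arrays):
        return 0.0, 1.0  # scipy rejects all-identical data; H is 0 by definition
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney test.

    Returns ``U = min(U_a, U_b)`` with tie handling and the two-sided
    normal-approximation p-value (continuity-corrected), the convention of
    mainstream statistics packages.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u_a = float(res.statistic)
    u = min(u_a, len(a) * len(b) - u_a)
    return u, float(res.pvalue)


def binned_correlation(summaries: Sequence[GroupSummary]) -> tuple[float, float]:
    """Pearson correlation of group means against the ordinal group index.

    Empty groups are skipped (the index remains the surviving groups' rank);
    at least three non-empty groups are required. The x-coordinate is the
    group rank 1..k rather than an interval midpoint because unbounded top
    groups ("degree >6") have none. A zero-variance set of means is reported
    as R = 0 with a warning.
    """
    means = [s.mean for s in summaries if not s.empty]
    if len(means) < 3:
        raise ValueError("need >=3 non-empty groups for a binned correlation")
    x = np.arange(1, len(means) + 1, dtype=float)
    y = np.asarray(means)
    if np.allclose(y, y[0]):
        warnings.warn("zero variance in group means; correlation undefined, reporting 0")
        return 0.0, 1.0
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def classify_age(
    network_nodes: Iterable[str],
    enzyme_metabolite_map: Mapping[str, Iterable[str]],
    enzyme_ages: Mapping[str, int],
    aerobic: Iterable[str],
    oldest_class: int | None = None,
) -> tuple[set[str], set[str]]:
    """Partition network metabolites into early and late evolutionary members.

    Early candidates are the metabolites of the oldest enzyme age class minus
    aerobic metabolites; early members are the candidates present in the
    network, late members are the rest of the network. Age classes are
    ordinals where a *smaller* number means older (class 1 = traceable to
    eubacterial genomes); ``oldest_class`` defaults to the minimum observed.
    """
    nodes = set(network_nodes)
    for enz in enzyme_metabolite_map:
        if enz not in enzyme_ages:
            raise KeyError(f"enzyme {enz!r} has no age annotation")
    if oldest_class is None:
        if not enzyme_ages:
            raise ValueError("no enzyme ages supplied")
        oldest_class = min(enzyme_ages.values())
    candidates: set[str] = set()
    for enz, mets in enzyme_metabolite_map.items():
        if enzyme_ages[enz] == oldest_class:
            candidates.update(mets)
    candidates -= set(aerobic)
    early = candidates & nodes
    late = nodes - early
    return early, late


def summary_table(
    degrees: Mapping[str, int] | pd.DataFrame,
    properties: pd.DataFrame,
    scheme: GroupScheme,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Table-style report: per descriptor, the group means ± SE plus the
    Kruskal–Wallis H and p over the groups."""
    if columns is None:
        columns = [c for c in properties.columns if c != "id"]
    props = properties.set_index("id") if "id" in properties.columns else properties
    rows = []
    for col in columns:
        sums = group_by_degree(degrees, props[col], scheme)
        row: dict[str, object] = {"descriptor": col}
        for s in sums:
            row[f"{s.label} mean"] = s.mean
            row[f"{s.label} se"] = s.se
            row[f"{s.label} n"] = s.n
        filled = [list(s.values) for s in sums if s.n > 0]
        if len(filled) >= 2 and sum(len(g) for g in filled) >= 3:
            h, p = kruskal_wallis(*filled)
        else:
            h, p = math.nan, math.nan
        row["H"] = h
        row["p"] = p
        rows.append(row)
    return pd.DataFrame(rows)
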