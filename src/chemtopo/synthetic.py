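"""Synthetic fixtures with the statistical structure the pipeline assumes.

Every generator is a pure function of its configuration and seed and emits
its own ground truth next to the data, so each pipeline stage can be tested
end-to-end without any database download:

* reaction sets with known numbers of macromolecule-contaminated, R-group,
  currency-only and clean reactions, plus the surviving reaction/edge counts;
* molecule sets built from a small fragment grammar spanning a polarity
  gradient (alkyl backbones decorated with hydroxyl/amine/carboxyl/phosphate
  groups);
* concentrations generated as −LogC linear in polarity descriptors plus
  Gaussian noise — log-normal concentrations, as observed for real
  metabolomes — with decoy descriptors appended as independent noise;
* degree-linked property tables where polarity tracks degree at a chosen
  strength; and age/aerobic annotations with a known early/late partition.

Each generator seeds its own salted random stream, so passing the same seed
to two different generators never couples their draws (descriptor noise and
concentration noise stay independent even at equal seeds).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import MetaboliteAnnotation, Reaction

__all__ = [
    "SynthConfig",
    "ReactionSetTruth",
    "DEFAULT_TRUE_BETA",
    "DEFAULT_TRUE_INTERCEPT",
    "gen_reaction_set",
    "gen_molecule_set",
    "gen_descriptor_panels",
    "gen_concentration_data",
    "gen_degree_linked_network",
    "gen_age_annotations",
    "write_reaction_files",
]

# Default generating coefficients for −LogC: the reference polarity equation,
# so recovery studies are a direct analogue of fitting real concentrations.
DEFAULT_TRUE_INTERCEPT = 6.105
DEFAULT_TRUE_BETA: dict[str, float] = {
    "logp": 0.431,
    "fnsa3": 15.595,
    "fpsa3": 16.727,
    "rpcg": -5.333,
}


@dataclass(frozen=True)
class SynthConfig:
    """Reaction-set generator configuration.

    The fractions partition the *reaction* list: ``frac_macromolecule`` and
    ``frac_rgroup`` of reactions are contaminated with a macromolecule or an
    R-group compound (deleted by the filter); half of ``frac_currency``
    becomes currency-only reactions (sides emptied by currency removal); the
    remainder are clean reactions, of which every second one additionally
    carries currency species on its sides (stripped, sides stay non-empty).
    """

    n_metabolites: int = 60
    n_reactions: int = 40
    frac_currency: float = 0.2
    frac_macromolecule: float = 0.1
    frac_rgroup: float = 0.1
    mlr_beta: tuple[float, ...] = (
        DEFAULT_TRUE_INTERCEPT,
        *DEFAULT_TRUE_BETA.values(),
    )
    noise_sigma: float = 0.5
    n_descriptor_decoys: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_currency, self.frac_macromolecule, self.frac_rgroup)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("fractions must be in [0, 1]")
        if sum(fr) >= 1:
            raise ValueError("fractions must sum to < 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class ReactionSetTruth:
    """Generated reaction set plus its by-construction ground truth."""

    reactions: tuple[Reaction, ...]
    annotations: tuple[MetaboliteAnnotation, ...]
    n_deleted_contaminated: int
    n_removed_currency_only: int
    expected_reaction_ids: frozenset[str]
    expected_edges: frozenset[tuple[str, str]]

    @property
    def expected_n_reactions(self) -> int:
        return len(self.expected_reaction_ids)

    @property
    def expected_n_edges(self) -> int:
        return len(self.expected_edges)


def gen_reaction_set(config: SynthConfig) -> ReactionSetTruth:
    """Generate a reaction list with embedded filter cases and ground truth."""
    rng = np.random.default_rng([1, config.seed])
    n_macro_rxn = round(config.n_reactions * config.frac_macromolecule)
    n_rgroup_rxn = round(config.n_reactions * config.frac_rgroup)
    n_curr_only = round(config.n_reactions * config.frac_currency / 2)
    n_clean = config.n_reactions - n_macro_rxn - n_rgroup_rxn - n_curr_only
    if n_clean < 1:
        raise ValueError("infeasible config: no clean reactions left")

    # metabolite pool: enough clean species to build reactions from, plus a
    # few of each special kind when the mix calls for them
    n_clean_met = config.n_metabolites
    n_currency = max(2, round(config.n_metabolites * config.frac_currency / 2))
    n_macro_met = 2 if n_macro_rxn else 0
    n_rgroup_met = 2 if n_rgroup_rxn else 0
    if n_clean_met < 6:
        raise ValueError("infeasible config: too few metabolites")

    clean_ids = [f"M{i:04d}" for i in range(n_clean_met)]
    currency_ids = [f"CUR{i:02d}" for i in range(n_currency)]
    macro_ids = [f"MACRO{i}" for i in range(n_macro_met)]
    rgroup_ids = [f"RGRP{i}" for i in range(n_rgroup_met)]

    annotations = (
        [MetaboliteAnnotation(m) for m in clean_ids]
        + [MetaboliteAnnotation(m, is_currency=True) for m in currency_ids]
        + [MetaboliteAnnotation(m, is_macromolecule=True) for m in macro_ids]
        + [MetaboliteAnnotation(m, has_r_group=True) for m in rgroup_ids]
    )

    def pick_side(pool: Sequence[str], lo: int = 1, hi: int = 3) -> frozenset[str]:
        k = int(rng.integers(lo, hi + 1))
        return frozenset(rng.choice(pool, size=min(k, len(pool)), replace=False))

    reactions: list[Reaction] = []
    expected_ids: set[str] = set()
    expected_edges: set[tuple[str, str]] = set()
    rid = 0

    def next_id() -> str:
        nonlocal rid
        rid += 1
        return f"R{rid:04d}"

    for i in range(n_clean):
        subs = pick_side(clean_ids)
        prods = pick_side([m for m in clean_ids if m not in subs])
        rxn_id = next_id()
        if config.frac_currency > 0 and i % 2 == 1 and currency_ids:
            subs_full = subs | pick_side(currency_ids, 1, 2)
            prods_full = prods | pick_side(currency_ids, 1, 2)
        else:
            subs_full, prods_full = subs, prods
        reactions.append(Reaction(rxn_id, subs_full, prods_full))
        expected_ids.add(rxn_id)
        for s in subs:
            for p in prods:
                if s != p:
                    expected_edges.add((s, p) if s < p else (p, s))

    for _ in range(n_macro_rxn):
        subs = pick_side(clean_ids) | {str(rng.choice(macro_ids))}
        reactions.append(Reaction(next_id(), subs, pick_side(clean_ids)))
    for _ in range(n_rgroup_rxn):
        prods = pick_side(clean_ids) | {str(rng.choice(rgroup_ids))}
        reactions.append(Reaction(next_id(), pick_side(clean_ids), prods))
    for _ in range(n_curr_only):
        reactions.append(
            Reaction(next_id(), pick_side(currency_ids, 1, 2), pick_side(currency_ids, 1, 2))
        )

    order = rng.permutation(len(reactions))
    reactions = [reactions[i] for i in order]
    return ReactionSetTruth(
        reactions=tuple(reactions),
        annotations=tuple(annotations),
        n_deleted_contaminated=n_macro_rxn + n_rgroup_rxn,
        n_removed_currency_only=n_curr_only,
        expected_reaction_ids=frozenset(expected_ids),
        expected_edges=frozenset(expected_edges),
    )


def write_reaction_files(truth: ReactionSetTruth, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the generated reactions and annotations in the pipeline's TSV
    formats; returns (reaction_path, annotation_path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rxn_path = out / "reactions.tsv"
    with open(rxn_path, "w") as fh:
        fh.write("# synthetic reaction list\n")
        for r in truth.reactions:
            lhs = " + ".join(sorted(r.substrates))
            rhs = " + ".join(sorted(r.products))
            fh.write(f"{r.id}\t{lhs} = {rhs}\n")
    ann_path = out / "annotations.tsv"
    with open(ann_path, "w") as fh:
        fh.write("id\tis_macromolecule\thas_r_group\tis_currency\tsmiles\n")
        for a in truth.annotations:
            fh.write(
                f"{a.id}\t{int(a.is_macromolecule)}\t{int(a.has_r_group)}"
                f"\t{int(a.is_currency)}\t{a.smiles or ''}\n"
            )
    return rxn_path, ann_path


# ---------------------------------------------------------------------------
# Molecules along a polarity gradient

_POLAR_FRAGMENTS = ("O", "N", "C(=O)O", "OP(=O)(O)O")  # hydroxyl, amine, acid, phosphate


def _assemble(chain_len: int, decorations: Sequence[str]) -> str:
    """Alkyl backbone with polar fragments attached as branches."""
    branches: list[list[str]] = [[] for _ in range(chain_len)]
    for i, frag in enumerate(decorations):
        branches[i % chain_len].append(frag)
    parts = []
    for carbon_branches in branches:
        parts.append("C" + "".join(f"({b})" for b in carbon_branches))
    return "".join(parts)


def gen_molecule_set(n: int, seed: int = 0) -> pd.DataFrame:
    """Generate ``n`` molecules spanning a polarity gradient.

    Molecules are alkyl chains (2–8 carbons) carrying 0–4 polar decorations
    (hydroxyl, amine, carboxyl, phosphate); the polar-group count rises
    through the set, so group means of any polarity descriptor are ordered
    by construction. Columns: id, smiles, n_polar_groups.
    """
    if n < 4:
        raise ValueError("need n >= 4 to span a gradient")
    rng = np.random.default_rng([2, seed])
    rows = []
    for i in range(n):
        n_polar = min(4, (i * 5) // n)
        chain = int(rng.integers(2, 9))
        decorations = [
            _POLAR_FRAGMENTS[int(rng.integers(0, len(_POLAR_FRAGMENTS)))]
            for _ in range(n_polar)
        ]
        rows.append(
            {
                "id": f"MOL{i:04d}",
                "smiles": _assemble(chain, decorations),
                "n_polar_groups": n_polar,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Concentrations from descriptors


def gen_descriptor_panels(n: int, n_decoys: int = 16, seed: int = 0) -> pd.DataFrame:
    """Synthetic descriptor table with realistic marginal ranges.

    The four polarity descriptors follow the distributions small-molecule
    panels show in practice (logp roughly normal; the CPSA fractions bounded
    with their defining signs; rpcg in (0, 1]); decoy columns are independent
    standard-normal noise. Indexed by metabolite id.
    """
    rng = np.random.default_rng([3, seed])
    df = pd.DataFrame(
        {
            "logp": rng.normal(0.0, 1.5, n),
            "fnsa3": rng.uniform(-0.5, -0.05, n),
            "fpsa3": rng.uniform(0.02, 0.40, n),
            "rpcg": rng.uniform(0.05, 1.0, n),
        },
        index=[f"MET{i:04d}" for i in range(n)],
    )
    for j in range(n_decoys):
        df[f"decoy_{j + 1:02d}"] = rng.normal(0.0, 1.0, n)
    df.index.name = "id"
    return df


def gen_concentration_data(
    panels: pd.DataFrame,
    beta: Mapping[str, float] | None = None,
    intercept: float = DEFAULT_TRUE_INTERCEPT,
    noise_sigma: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Concentrations generated as −LogC linear in descriptors plus noise.

    ``−LogC_i = intercept + Σ beta_k x_ik + ε_i`` with ε ~ N(0, sigma²);
    concentrations are ``10**(−(−LogC))`` and therefore always positive
    (log-normal). Returns a table (id, concentration, neg_log_c).
    """
    beta = dict(DEFAULT_TRUE_BETA if beta is None else beta)
    missing = [k for k in beta if k not in panels.columns]
    if missing:
        raise KeyError(f"panels missing true descriptors: {missing}")
    rng = np.random.default_rng([4, seed])
    x = panels[list(beta)].to_numpy(dtype=float)
    b = np.array([beta[k] for k in beta])
    neg_log_c = intercept + x @ b + rng.normal(0.0, noise_sigma, len(panels))
    return pd.DataFrame(
        {
            "id": panels.index,
            "concentration": 10.0 ** (-neg_log_c),
            "neg_log_c": neg_log_c,
        }
    )


# ---------------------------------------------------------------------------
# Degree-linked properties


def gen_degree_linked_network(
    n: int, strength: float = 1.0, seed: int = 0, m: int = 2
) -> tuple[nx.Graph, pd.DataFrame]:
    """Scale-free network whose hubs carry the most polar molecules.

    The graph comes from a preferential-attachment process; each node gets a
    logp value such that the rank correlation between degree and −logp is
    controlled by ``strength`` (1 = perfectly anti-ordered, 0 = independent).
    Returns the graph and a table (id, degree, logp).
    """
    if n < 20:
        raise ValueError("need n >= 20")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng([5, seed])
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(0, 2**31 - 1)))
    degrees = np.array([g.degree(i) for i in range(n)], dtype=float)
    deg_rank = sps_rank(degrees + rng.uniform(0, 1e-6, n))
    score = strength * deg_rank + (1.0 - strength) * rng.permutation(n)
    logp_values = np.sort(rng.normal(1.0, 1.5, n))[::-1]  # descending
    order = np.argsort(score)  # low score (low degree) first -> high logp
    logp = np.empty(n)
    logp[order] = logp_values
    table = pd.DataFrame(
        {"id": [f"N{i:04d}" for i in range(n)], "degree": degrees.astype(int), "logp": logp}
    )
    g = nx.relabel_nodes(g, {i: f"N{i:04d}" for i in range(n)})
    return g, table


def sps_rank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    ranks = np.empty(len(x))
    ranks[order] = np.arange(len(x), dtype=float)
    return ranks


# ---------------------------------------------------------------------------
# Age annotations


@dataclass(frozen=True)
class AgeTruth:
    enzyme_metabolite_map: dict[str, frozenset[str]]
    enzyme_ages: dict[str, int]
    aerobic: frozenset[str]
    expected_early: frozenset[str]
    expected_late: frozenset[str]


def gen_age_annotations(
    network_nodes: Sequence[str],
    frac_early: float = 0.4,
    frac_aerobic: float = 0.05,
    seed: int = 0,
) -> AgeTruth:
    """Enzyme age classes and aerobic flags with a known early/late split.

    Age class 1 is the oldest. A ``frac_early`` share of network nodes is
    attached to oldest-class enzymes; ``frac_aerobic`` of those candidates
    are marked aerobic (and hence excluded from the early set). The expected
    partition is emitted for assertion.
    """
    nodes = sorted(set(network_nodes))
    rng = np.random.default_rng([6, seed])
    n_candidates = round(len(nodes) * frac_early)
    candidates = set(rng.choice(nodes, size=n_candidates, replace=False))
    n_aer = round(n_candidates * frac_aerobic)
    aerobic = (
        frozenset(rng.choice(sorted(candidates), size=n_aer, replace=False))
        if n_aer
        else frozenset()
    )
    rest = [m for m in nodes if m not in candidates]

    enzyme_map: dict[str, frozenset[str]] = {}
    enzyme_ages: dict[str, int] = {}
    for i, chunk in enumerate(_chunks(sorted(candidates), 3)):
        enz = f"ENZ_OLD{i:03d}"
        enzyme_map[enz] = frozenset(chunk)
        enzyme_ages[enz] = 1
    for i, chunk in enumerate(_chunks(rest, 3)):
        enz = f"ENZ_NEW{i:03d}"
        enzyme_map[enz] = frozenset(chunk)
        enzyme_ages[enz] = int(rng.integers(2, 6))
    expected_early = frozenset((candidates - set(aerobic)) & set(nodes))
    return AgeTruth(
        enzyme_metabolite_map=enzyme_map,
        enzyme_ages=enzyme_ages,
        aerobic=aerobic,
        expected_early=expected_early,
        expected_late=frozenset(set(nodes) - expected_early),
    )


def _chunks(seq: Sequence[str], size: int):
    for i in range(0, len(seq), size):
        yield seq[i : i + size]
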