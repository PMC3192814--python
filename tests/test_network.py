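"""Reaction parsing, screening filters, graph construction and power-law fits."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from chemtopo.network import (
    InsufficientDataError,
    MetaboliteAnnotation,
    MissingAnnotationError,
    Reaction,
    ReactionParseError,
    build_network,
    compute_degrees,
    degree_histogram,
    filter_reactions,
    fit_power_law,
    parse_reactions,
)


def ann(met, **flags):
    return MetaboliteAnnotation(met, **flags)


class TestParse:
    def test_basic_line(self, write_reactions):
        rxns = parse_reactions(write_reactions(["R1\tA + B = C"]))
        assert rxns == [Reaction("R1", frozenset("AB"), frozenset("C"))]

    def test_identity_reaction_accepted(self, write_reactions):
        (rxn,) = parse_reactions(write_reactions(["R2\tC = C"]))
        assert rxn.substrates == rxn.products == frozenset("C")

    def test_comments_and_blank_lines_skipped(self, write_reactions):
        rxns = parse_reactions(
            write_reactions(["# header", "R1\tA = B", "", "R2\tB = C"])
        )
        assert [r.id for r in rxns] == ["R1", "R2"]

    def test_duplicate_mentions_collapse(self, write_reactions):
        (rxn,) = parse_reactions(write_reactions(["R1\tA + A + B = C + C"]))
        assert rxn.substrates == frozenset("AB") and rxn.products == frozenset("C")

    @pytest.mark.parametrize("bad", ["R1\tA + B C", "R1\t = B", "no_tab_here"])
    def test_malformed_line_names_line_number(self, write_reactions, bad):
        with pytest.raises(ReactionParseError, match="line 1"):
            parse_reactions(write_reactions([bad]))


class TestFilter:
    def test_macromolecule_reaction_deleted(self):
        rxns = [Reaction("X", frozenset("A"), frozenset("P"))]
        anns = [ann("A", is_macromolecule=True), ann("P")]
        assert filter_reactions(rxns, anns) == []

    def test_rgroup_reaction_deleted(self):
        rxns = [Reaction("X", frozenset("A"), frozenset("P"))]
        anns = [ann("A"), ann("P", has_r_group=True)]
        assert filter_reactions(rxns, anns) == []

    def test_currency_stripped_from_sides(self):
        rxns = [Reaction("Y", frozenset({"ATP", "G"}), frozenset({"ADP", "G6P"}))]
        anns = [ann("ATP", is_currency=True), ann("ADP", is_currency=True), ann("G"), ann("G6P")]
        (out,) = filter_reactions(rxns, anns)
        assert out.substrates == frozenset({"G"}) and out.products == frozenset({"G6P"})

    def test_all_currency_reaction_removed(self):
        rxns = [Reaction("Z", frozenset({"H2O"}), frozenset({"H+"}))]
        anns = [ann("H2O", is_currency=True), ann("H+", is_currency=True)]
        assert filter_reactions(rxns, anns) == []

    def test_currency_override_keeps_named_ids(self):
        rxns = [Reaction("Y", frozenset({"ATP", "G"}), frozenset({"ADP"}))]
        anns = [ann("ATP", is_currency=True), ann("ADP", is_currency=True), ann("G")]
        (out,) = filter_reactions(rxns, anns, currency_overrides={"Y": ["ATP", "ADP"]})
        assert out.substrates == frozenset({"ATP", "G"})
        assert out.products == frozenset({"ADP"})

    def test_missing_annotation_names_metabolite(self):
        with pytest.raises(MissingAnnotationError, match="'B'"):
            filter_reactions([Reaction("R", frozenset("A"), frozenset("B"))], [ann("A")])

    def test_filtering_is_idempotent(self):
        rxns = [
            Reaction("R1", frozenset({"ATP", "G"}), frozenset({"ADP", "G6P"})),
            Reaction("R2", frozenset({"H2O"}), frozenset({"X"})),
        ]
        anns = [
            ann("ATP", is_currency=True),
            ann("ADP", is_currency=True),
            ann("H2O", is_currency=True),
            ann("G"),
            ann("G6P"),
            ann("X"),
        ]
        once = filter_reactions(rxns, anns)
        assert filter_reactions(once, anns) == once


class TestBuildNetwork:
    def test_complete_bipartite_expansion(self):
        g = build_network(
            [
                Reaction("1", frozenset({"A", "B"}), frozenset({"C"})),
                Reaction("2", frozenset({"C"}), frozenset({"D"})),
            ]
        )
        assert {tuple(sorted(e)) for e in g.edges()} == {("A", "C"), ("B", "C"), ("C", "D")}
        assert g.degree("C") == 3

    def test_self_pair_excluded(self):
        g = build_network([Reaction("1", frozenset("A"), frozenset("A"))])
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_edges_deduplicated_across_reactions(self):
        rxns = [
            Reaction("1", frozenset("A"), frozenset("C")),
            Reaction("2", frozenset("A"), frozenset("C")),
        ]
        assert build_network(rxns).number_of_edges() == 1

    @given(
        hst.lists(
            hst.tuples(
                hst.sets(hst.sampled_from("ABCDEFG"), min_size=1, max_size=3),
                hst.sets(hst.sampled_from("ABCDEFG"), min_size=1, max_size=3),
            ),
            min_size=1,
            max_size=8,
        ),
        hst.randoms(),
    )
    def test_order_invariance_handshake_and_edge_bound(self, sides, rnd):
        rxns = [
            Reaction(f"R{i}", frozenset(s), frozenset(p)) for i, (s, p) in enumerate(sides)
        ]
        g = build_network(rxns)
        shuffled = list(rxns)
        rnd.shuffle(shuffled)
        canon = lambda graph: {tuple(sorted(e)) for e in graph.edges()}
        assert canon(build_network(shuffled)) == canon(g)
        degrees = compute_degrees(g)
        assert degrees["degree"].sum() == 2 * g.number_of_edges()
        assert g.number_of_edges() <= sum(len(r.substrates) * len(r.products) for r in rxns)


class TestDegrees:
    def test_triangle_all_degree_two(self):
        g = build_network(
            [
                Reaction("1", frozenset("A"), frozenset("B")),
                Reaction("2", frozenset("B"), frozenset("C")),
                Reaction("3", frozenset("C"), frozenset("A")),
            ]
        )
        assert set(compute_degrees(g)["degree"]) == {2}

    def test_star_degrees_and_histogram(self):
        rxns = [Reaction(f"R{i}", frozenset("H"), frozenset({f"L{i}"})) for i in range(5)]
        table = compute_degrees(build_network(rxns))
        assert dict(zip(table["id"], table["degree"]))["H"] == 5
        assert degree_histogram(table) == [(1, 5), (5, 1)]

    def test_bipartite_example_degrees(self):
        g = build_network(
            [
                Reaction("1", frozenset({"A", "B"}), frozenset({"C"})),
                Reaction("2", frozenset({"C"}), frozenset({"D"})),
            ]
        )
        got = dict(zip(*compute_degrees(g).to_dict(orient="list").values()))
        assert got == {"A": 1, "B": 1, "C": 3, "D": 1}

    def test_histogram_counts_sum_to_node_count(self):
        import pandas as pd

        table = pd.DataFrame({"id": list("abcd"), "degree": [1, 1, 1, 3]})
        hist = degree_histogram(table)
        assert hist == [(1, 3), (3, 1)]
        assert sum(c for _, c in hist) == len(table)


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        # counts are exactly 100 * d^-2 for d in {1, 2, 4, 8}
        fit = fit_power_law([(1, 100.0), (2, 25.0), (4, 6.25), (8, 1.5625)])
        assert math.isclose(fit.b, 2.0, rel_tol=1e-10)
        assert math.isclose(fit.a, 100.0, rel_tol=1e-10)
        assert math.isclose(fit.r_squared, 1.0, abs_tol=1e-12)

    def test_constant_counts_give_zero_exponent(self):
        fit = fit_power_law([(1, 7), (2, 7), (4, 7), (8, 7)])
        assert math.isclose(fit.b, 0.0, abs_tol=1e-12)
        assert math.isclose(fit.r_squared, 1.0, abs_tol=1e-12) or fit.r_squared >= 0

    def test_noisy_fit_matches_normal_equations_oracle(self, rng):
        degrees = np.array([1, 2, 3, 5, 8, 13, 21])
        counts = 500 * degrees**-1.7 * np.exp(rng.normal(0, 0.1, degrees.size))
        fit = fit_power_law(list(zip(degrees, counts)))
        # independent oracle: closed-form normal equations on log-log points
        x, y = np.log10(degrees), np.log10(counts)
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
        intercept = y.mean() - slope * x.mean()
        assert math.isclose(fit.b, -slope, rel_tol=1e-10)
        assert math.isclose(fit.a, 10**intercept, rel_tol=1e-10)

    def test_insufficient_distinct_degrees_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_power_law([(1, 10), (2, 5)])
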