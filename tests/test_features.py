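import itertools
import math

import numpy as np
import pandas as pd
import pytest

from synlet.features import (
    FeatureSpec,
    assemble_feature_matrix,
    build_overlay_catalog,
    build_sl_dependent_catalog,
    coexpression_correlation,
    comembership_count,
    overlay_value,
    phylo_profile_mi,
    read_gmt,
    topological_overlap,
    write_feature_matrix,
    read_feature_matrix,
)
from synlet.networks import GenePair, WeightedNetwork

from conftest import random_network


def net_of(name, edges):
    n = WeightedNetwork(name)
    for a, b, w in edges:
        n.add_edge(a, b, w)
    return n


def brute_force_overlay(n1, n2, pair):
    """Exhaustive enumeration over all intermediates and leg orderings."""
    a, b = pair.a, pair.b
    best = None
    for c in n1.nodes | n2.nodes:
        if c in (a, b):
            continue
        for first, second in ((n1, n2), (n2, n1)):
            w1 = first.get(a, c)
            w2 = second.get(c, b)
            if w1 is not None and w2 is not None:
                v = w1 * w2
                if best is None or v > best:
                    best = v
    return best


class TestOverlayValue:
    def test_strongest_transitive_link(self):
        n1 = net_of("n1", [("A", "C", 0.5), ("A", "D", 0.8)])
        n2 = net_of("n2", [("C", "B", 0.6), ("D", "B", 0.2)])
        assert overlay_value(n1, n2, GenePair("A", "B")) == pytest.approx(0.30)

    def test_no_common_neighbor_is_missing(self):
        n1 = net_of("n1", [("A", "C", 1.0)])
        n2 = net_of("n2", [("D", "B", 1.0)])
        assert overlay_value(n1, n2, GenePair("A", "B")) is None

    def test_identity_weights(self):
        n1 = net_of("n1", [("A", "C", 1.0)])
        n2 = net_of("n2", [("C", "B", 1.0)])
        assert overlay_value(n1, n2, GenePair("A", "B")) == 1.0

    def test_direct_edge_never_contributes(self):
        n1 = net_of("n1", [("A", "B", 5.0)])
        n2 = net_of("n2", [("A", "B", 5.0)])
        assert overlay_value(n1, n2, GenePair("A", "B")) is None

    def test_symmetry_in_networks_and_endpoints(self):
        rng = np.random.default_rng(21)
        genes, n1 = random_network(rng, 30, 120, "a")
        _, n2 = random_network(rng, 30, 120, "b")
        for _ in range(50):
            i, j = rng.choice(30, 2, replace=False)
            p = GenePair(genes[i], genes[j])
            v = overlay_value(n1, n2, p)
            assert v == overlay_value(n2, n1, p)
            assert v == overlay_value(n1, n2, GenePair(genes[j], genes[i]))

    def test_monotone_in_added_edges(self):
        rng = np.random.default_rng(22)
        genes, n1 = random_network(rng, 20, 60, "a")
        _, n2 = random_network(rng, 20, 60, "b")
        pair = GenePair(genes[0], genes[1])
        before = overlay_value(n1, n2, pair)
        # add a strong positive two-leg path; value must not decrease
        n1.add_edge(genes[0], genes[5], 1.0)
        n2.add_edge(genes[5], genes[1], 1.0)
        after = overlay_value(n1, n2, pair)
        assert after is not None
        assert before is None or after >= before


class TestOverlayCatalog:
    def test_fourteen_networks_one_exclusion_gives_ninety(self):
        names = [f"net{i}" for i in range(14)]
        specs = build_overlay_catalog(names, exclusions=[("net1", "net2")])
        assert len(specs) == 90

    def test_two_networks_single_spec(self):
        assert len(build_overlay_catalog(["a", "b"])) == 1

    def test_choose_two_minus_exclusions(self):
        specs = build_overlay_catalog(list("abcd"), exclusions=[("a", "b")])
        assert len(specs) == 5

    def test_unknown_exclusion_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_overlay_catalog(["a", "b"], exclusions=[("a", "z")])

    def test_sl_dependent_catalog_sizes(self):
        assert len(build_sl_dependent_catalog([f"n{i}" for i in range(14)])) == 15
        assert len(build_sl_dependent_catalog(["n0"])) == 2
        assert len(build_sl_dependent_catalog([])) == 1
        kinds = {s.kind for s in build_sl_dependent_catalog(["n0"])}
        assert kinds == {"sl_dependent_overlay"}


class TestDirectFeatures:
    def test_pearson_identical_and_negated(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 4], [-1.0, -2, -3, -4]],
            index=["a", "b", "c"],
        )
        assert coexpression_correlation(expr, GenePair("a", "b")) == pytest.approx(1.0)
        assert coexpression_correlation(expr, GenePair("a", "c")) == pytest.approx(-1.0)

    def test_pearson_hand_value(self):
        expr = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 4]], index=["a", "b"])
        got = coexpression_correlation(expr, GenePair("a", "b"))
        assert got == pytest.approx(3 / math.sqrt(2 * 42 / 9), abs=1e-6)
        assert got == pytest.approx(0.982, abs=1e-3)

    def test_pearson_missing_rules(self):
        expr = pd.DataFrame([[1.0, np.nan, 3, np.nan], [1.0, 2, np.nan, 4]], index=["a", "b"])
        assert coexpression_correlation(expr, GenePair("a", "b")) is None  # <3 shared
        assert coexpression_correlation(expr, GenePair("a", "z")) is None  # absent gene

    def test_tom_triangle(self):
        net = net_of("n", [("A", "B", 0.5), ("A", "C", 1.0), ("B", "C", 1.0)])
        assert topological_overlap(net, GenePair("A", "B")) == pytest.approx(0.75)

    def test_tom_isolated_linked_pair(self):
        net = net_of("n", [("A", "B", 1.0)])
        assert topological_overlap(net, GenePair("A", "B")) == pytest.approx(1.0)

    def test_tom_absent_gene_missing(self):
        net = net_of("n", [("A", "B", 1.0)])
        assert topological_overlap(net, GenePair("A", "Z")) is None

    def test_comembership(self):
        member = {"a": {"P1", "P2", "P3"}, "b": {"P2", "P3", "P4"}, "c": {"P9"}, "d": {"P9"}}
        assert comembership_count(member, GenePair("a", "b")) == 2
        assert comembership_count(member, GenePair("a", "c")) == 0
        assert comembership_count(member, GenePair("c", "d")) == 1
        assert comembership_count(member, GenePair("a", "zz")) == 0

    def test_phylo_mi_identical_balanced(self):
        prof = pd.DataFrame([[1, 1, 0, 0], [1, 1, 0, 0]], index=["a", "b"])
        assert phylo_profile_mi(prof, GenePair("a", "b")) == pytest.approx(math.log(2))

    def test_phylo_mi_independent_and_constant(self):
        prof = pd.DataFrame([[1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 1, 1]], index=["a", "b", "c"])
        assert phylo_profile_mi(prof, GenePair("a", "b")) == pytest.approx(0.0)
        assert phylo_profile_mi(prof, GenePair("a", "c")) == pytest.approx(0.0)

    def test_phylo_mi_length_mismatch(self):
        profiles = {"a": np.array([1, 0]), "b": np.array([1, 0, 1])}
        with pytest.raises(ValueError):
            phylo_profile_mi(profiles, GenePair("a", "b"))


class TestAssembleMatrix:
    def test_shape_and_column_order(self):
        n1 = net_of("n1", [("A", "B", 0.5), ("A", "C", 0.4)])
        n2 = net_of("n2", [("C", "B", 0.6)])
        catalog = [
            FeatureSpec("direct_n1", "direct", ("n1",), "edge_weight"),
            FeatureSpec("O(n1, n2)", "overlay", ("n1", "n2")),
        ]
        pairs = [GenePair("A", "B"), GenePair("A", "C"), GenePair("B", "C")]
        m = assemble_feature_matrix(catalog, {"n1": n1, "n2": n2}, pairs)
        assert m.shape == (3, 2)
        assert list(m.columns) == ["direct_n1", "O(n1, n2)"]
        assert m.loc[("A", "B"), "O(n1, n2)"] == pytest.approx(0.24)

    def test_all_missing_column_kept_as_nan(self):
        n1 = net_of("n1", [("A", "B", 0.5)])
        n2 = net_of("n2", [("X", "Y", 0.5)])
        catalog = [FeatureSpec("O(n1, n2)", "overlay", ("n1", "n2"))]
        m = assemble_feature_matrix(catalog, {"n1": n1, "n2": n2}, [GenePair("A", "B")])
        assert m["O(n1, n2)"].isna().all()

    def test_unresolvable_source_named_in_error(self):
        catalog = [FeatureSpec("x", "direct", ("nope",), "edge_weight")]
        with pytest.raises(ValueError, match="nope"):
            assemble_feature_matrix(catalog, {}, [GenePair("A", "B")])

    def test_direct_plus_overlay_column_count(self):
        nets = {f"n{i}": net_of(f"n{i}", [("A", "B", 0.5)]) for i in range(14)}
        catalog = [
            FeatureSpec(f"direct_n{i}", "direct", (f"n{i}",), "edge_weight")
            for i in range(14)
        ] + build_overlay_catalog(sorted(nets))
        m = assemble_feature_matrix(catalog, nets, [GenePair("A", "B")])
        assert m.shape[1] == 14 + 91

    def test_matrix_round_trip_preserves_missing(self, tmp_path):
        idx = pd.MultiIndex.from_tuples([("a", "b"), ("a", "c")], names=["geneA", "geneB"])
        m = pd.DataFrame({"f1": [1.5, np.nan], "f2": [np.nan, -0.25]}, index=idx)
        write_feature_matrix(m, tmp_path / "m.tsv")
        back = read_feature_matrix(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back, m)

    def test_gmt_reader(self, tmp_path):
        (tmp_path / "g.gmt").write_text("P1\tdesc\ta\tb\nP2\tdesc\tb\tc\n")
        mem = read_gmt(tmp_path / "g.gmt")
        assert mem == {"a": {"P1"}, "b": {"P1", "P2"}, "c": {"P2"}}
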