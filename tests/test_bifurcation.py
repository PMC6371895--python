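"""Junction coding, divergence classes, and split-reach correction."""

import itertools

import pytest

from streamclass.bifurcation import (
    assign_bifurcation_classes,
    assign_divergence_classes,
    code_junction,
    correct_split_reaches,
    detect_nonsensical_junctions,
)
from streamclass.network import strahler_combine, upstream_of

from conftest import build_network, chain


class TestJunctionCoding:
    @pytest.mark.parametrize("down, ups, rendered", [
        (2, [1, 2], "2.12"),           # ascending for two tributaries
        (5, [5, 1, 1], "5.511"),       # mainstem first, remainder descending
        (1, [], "1_0"),                # no upstream confluence
        (3, [3], "3_0"),               # single upstream: mid-channel split
        (4, [1, 2, 3, 4], "4.4321"),
    ])
    def test_rendering_rules(self, down, ups, rendered):
        assert code_junction(down, ups).rendered == rendered

    def test_more_than_four_keeps_largest_four(self):
        code = code_junction(5, [1, 1, 2, 3, 5])
        assert code.upstream_orders == (5, 3, 2, 1)
        assert code.rendered == "5.5321"

    def test_double_digit_orders_render_as_tokens(self):
        assert code_junction(12, [10, 3]).rendered == "12.3-10"
        assert code_junction(12, [12, 10, 3]).rendered == "12.12-10-3"

    def test_invalid_orders_rejected(self):
        with pytest.raises(ValueError):
            code_junction(0, [1, 2])
        with pytest.raises(ValueError):
            code_junction(2, [0, 1])

    def test_sort_mode_override(self):
        assert code_junction(2, [1, 2], sort_mode="descending").rendered == "2.21"
        assert code_junction(5, [5, 1, 1], sort_mode="ascending").rendered == "5.115"

    def test_rendering_injective_over_small_orders(self):
        """No two distinct (downstream, multiset) pairs render identically
        for orders <= 6 and <= 4 tributaries."""
        seen = {}
        for down in range(1, 7):
            for n_trib in range(0, 5):
                for ups in itertools.combinations_with_replacement(
                        range(1, 7), n_trib):
                    code = code_junction(down, list(ups)).rendered
                    key = (down, tuple(sorted(ups)) if len(ups) > 1 else ())
                    if code in seen:
                        assert seen[code] == key
                    seen[code] = key


def _diamond(flag_main="main", flag_sec="secondary", with_rejoin_trib=False):
    """parent 1 -> {2 (main), 3 (secondary)} -> rejoin 4 -> outlet 5."""
    reaches = [
        {"comid": 1, "strahler_order": 2},
        {"comid": 2, "strahler_order": 2, "divergence_flag": flag_main},
        {"comid": 3, "strahler_order": 2, "divergence_flag": flag_sec},
        {"comid": 4, "strahler_order": 2},
        {"comid": 5, "strahler_order": 2},
    ]
    edges = [(1, 2), (1, 3), (2, 4), (3, 4), (4, 5)]
    return build_network(reaches, edges)


class TestDivergenceClasses:
    def test_flagged_diamond(self):
        div = assign_divergence_classes(_diamond())
        assert div[2] == "D1" and div[3] == "D2"
        assert div[4] == "DU"        # both channels re-merge here
        assert div[5] == "none"

    def test_unflagged_diamond_is_generic_divergence(self):
        div = assign_divergence_classes(_diamond("none", "none"))
        # rejoin order 2 fed by two order-2 reaches without flags: order
        # arithmetic is inconsistent, hence the generic class D
        assert div[4] == "D"

    def test_dendritic_network_all_none(self, dendritic_network):
        div = assign_divergence_classes(dendritic_network)
        assert set(div.values()) == {"none"}

    def test_generated_network_has_all_four_labels(self, generated_network):
        div = assign_divergence_classes(generated_network)
        assert set(div.values()) - {"none"} == {"D1", "D2", "DU", "D"}


class TestNonsensicalJunctions:
    def test_five_five_to_five_flagged(self):
        net = build_network(
            [{"comid": 1, "strahler_order": 5},
             {"comid": 2, "strahler_order": 5},
             {"comid": 3, "strahler_order": 5}],
            [(1, 3), (2, 3)])
        assert detect_nonsensical_junctions(net) == {3}

    def test_consistent_junction_not_flagged(self):
        net = build_network(
            [{"comid": 1, "strahler_order": 1},
             {"comid": 2, "strahler_order": 2},
             {"comid": 3, "strahler_order": 2}],
            [(1, 3), (2, 3)])
        assert detect_nonsensical_junctions(net) == set()

    def test_enumeration_matches_strahler_consistency_oracle(self):
        """All (downstream, pair) combinations with orders <= 4 agree with a
        brute-force restatement of the Strahler rule."""
        for down in range(1, 5):
            for o1 in range(1, 5):
                for o2 in range(1, 5):
                    net = build_network(
                        [{"comid": 1, "strahler_order": o1},
                         {"comid": 2, "strahler_order": o2},
                         {"comid": 3, "strahler_order": down}],
                        [(1, 3), (2, 3)])
                    flagged = 3 in detect_nonsensical_junctions(net)
                    m = max(o1, o2)
                    expected = m + 1 if o1 == o2 else m
                    assert flagged == (down != expected)
                    assert expected == strahler_combine([o1, o2])


class TestBifurcationAssignment:
    def test_totality_on_generated_network(self, generated_network):
        table = assign_bifurcation_classes(generated_network)
        assert len(table) == len(generated_network)
        assert (table["bif_class"].astype(str) != "").all()
        assert table["div_class"].isin(["D1", "D2", "DU", "D", "none"]).all()

    def test_codes_match_independent_traversal(self, dendritic_network):
        """On a dendritic network the coded classes equal a brute-force
        recomputation straight from the from-to table."""
        net = dendritic_network
        table = assign_bifurcation_classes(net).set_index("comid")
        order = dict(zip(net.reaches["comid"], net.reaches["strahler_order"]))
        up = {c: [] for c in net.comids}
        for u, v in net.edges:
            up[v].append(u)
        for comid in net.comids:
            ups = sorted(order[u] for u in up[comid])
            if len(ups) <= 1:
                expected = f"{order[comid]}_0"
            elif len(ups) == 2:
                expected = f"{order[comid]}." + "".join(map(str, ups))
            else:
                rest = sorted(ups, reverse=True)
                if order[comid] in rest:
                    rest.remove(order[comid])
                    rest = [order[comid]] + rest
                expected = f"{order[comid]}." + "".join(map(str, rest))
            assert table.loc[comid, "bif_class"] == expected

    def test_integer_part_equals_strahler_order(self, dendritic_network):
        table = assign_bifurcation_classes(dendritic_network)
        order = dict(zip(dendritic_network.reaches["comid"],
                         dendritic_network.reaches["strahler_order"]))
        for row in table.itertuples():
            head = row.bif_class.split(".")[0].split("_")[0]
            assert int(head) == order[row.comid]

    def test_upstream_downstream_counts(self, generated_network):
        table = assign_bifurcation_classes(generated_network).set_index("comid")
        for comid in list(generated_network.comids)[::37]:
            assert table.loc[comid, "upstream_count"] == \
                len(upstream_of(generated_network, comid))


class TestSplitCorrection:
    def _split_chain(self):
        # order-2 junction feeding a 3-piece split unit
        reaches = [
            {"comid": 1, "strahler_order": 1},
            {"comid": 2, "strahler_order": 1},
            {"comid": 3, "strahler_order": 2, "eco_unit_id": "U1"},
            {"comid": 4, "strahler_order": 2, "eco_unit_id": "U1"},
            {"comid": 5, "strahler_order": 2, "eco_unit_id": "U1"},
        ]
        edges = [(1, 3), (2, 3), (3, 4), (4, 5)]
        return build_network(reaches, edges)

    def test_unit_inherits_upstream_most_class(self):
        net = self._split_chain()
        table = assign_bifurcation_classes(net)
        before = table.set_index("comid")["bif_class"]
        assert before[3] == "2.11" and before[4] == "2_0" and before[5] == "2_0"
        after = correct_split_reaches(net, table).set_index("comid")["bif_class"]
        assert after[3] == after[4] == after[5] == "2.11"

    def test_idempotent(self):
        net = self._split_chain()
        once = correct_split_reaches(net, assign_bifurcation_classes(net))
        twice = correct_split_reaches(net, once)
        assert once.equals(twice)

    def test_singleton_unit_unchanged(self):
        net = chain([1, 2])
        net.reaches.loc[net.reaches["comid"] == 2, "eco_unit_id"] = "U9"
        table = assign_bifurcation_classes(net)
        assert correct_split_reaches(net, table).equals(table)

    def test_disconnected_unit_skipped_with_warning(self):
        net = build_network(
            [{"comid": 1, "eco_unit_id": "U1"},
             {"comid": 2},
             {"comid": 3, "eco_unit_id": "U1"}],
            [(1, 2), (2, 3)])
        table = assign_bifurcation_classes(net)
        with pytest.warns(UserWarning, match="U1"):
            out = correct_split_reaches(net, table)
        assert out["bif_class"].equals(table["bif_class"])

    def test_multiset_of_unit_head_classes_preserved(self, generated_network):
        table = assign_bifurcation_classes(generated_network)
        corrected = correct_split_reaches(generated_network, table)
        units = table.loc[table["eco_unit_id"].notna(), "eco_unit_id"].unique()
        assert len(units) > 0
        for unit in units:
            sub = corrected.loc[corrected["eco_unit_id"] == unit, "bif_class"]
            assert sub.nunique() == 1
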