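"""Network I/O, cleaning, merging, stoplist filtering and decomposition."""

import networkx as nx
import pytest

from nettopo import generators, netio
from tests.conftest import random_clean_graph


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadEdgeList:
    def test_basic_two_edges(self, tmp_path):
        net = netio.read_edge_list(write(tmp_path, "n.tsv", "A\tB\nB\tC\n"))
        assert set(net.nodes) == {"A", "B", "C"}
        assert net.number_of_edges() == 2

    def test_duplicates_and_loops_preserved_raw(self, tmp_path):
        net = netio.read_edge_list(write(tmp_path, "n.tsv", "A\tA\nA\tB\nA\tB\n"))
        assert set(net.nodes) == {"A", "B"}
        assert net.number_of_edges() == 3  # raw multiset kept for audit
        assert netio.clean_network(net).number_of_edges() == 1

    def test_comments_isolated_nodes_whitespace(self, tmp_path):
        net = netio.read_edge_list(
            write(tmp_path, "n.tsv", "# header\n A \t B \nC\n\n")
        )
        assert set(net.nodes) == {"A", "B", "C"}
        assert net.degree("C") == 0

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            netio.read_edge_list(tmp_path / "absent.tsv")


class TestReadSif:
    def test_fan_out_line(self, tmp_path):
        net = netio.read_sif(write(tmp_path, "n.sif", "A pp B C\n"))
        assert set(net.nodes) == {"A", "B", "C"}
        assert {frozenset(e) for e in net.edges()} == {
            frozenset({"A", "B"}), frozenset({"A", "C"})}

    def test_single_node_line(self, tmp_path):
        net = netio.read_sif(write(tmp_path, "n.sif", "A\n"))
        assert set(net.nodes) == {"A"} and net.number_of_edges() == 0

    def test_two_token_line_rejected(self, tmp_path):
        with pytest.raises(netio.ParseError, match="relation but no target"):
            netio.read_sif(write(tmp_path, "n.sif", "A pp\n"))

    def test_sif_and_edgelist_renderings_agree(self, tmp_path):
        net = generators.generate_barabasi_albert(40, 2, seed=3)
        netio.write_sif(net, tmp_path / "n.sif")
        netio.write_edge_list(net, tmp_path / "n.tsv")
        from_sif = netio.clean_network(netio.read_sif(tmp_path / "n.sif"))
        from_el = netio.clean_network(netio.read_edge_list(tmp_path / "n.tsv"))
        assert netio.networks_equal(from_sif, from_el)
        assert netio.networks_equal(from_sif, net)


TABLE = (
    "Source molecule\tInteraction\tTarget molecule\tAlias\tRole\tReference\tNotes\n"
    "EGFR\tactivates\tPLC\t\t\tref1\t\n"
    "PLC\tcleaves\tPIP2\t\t\tref2\t\n"
)


class TestInteractionTable:
    def test_two_rows(self, tmp_path):
        net = netio.read_interaction_table(write(tmp_path, "t.tsv", TABLE))
        assert set(net.nodes) == {"EGFR", "PLC", "PIP2"}
        assert net.number_of_edges() == 2

    def test_missing_column(self, tmp_path):
        bad = "Source molecule\tInteraction\n A\tx\n"
        with pytest.raises(netio.SchemaError, match="target molecule"):
            netio.read_interaction_table(write(tmp_path, "t.tsv", bad))

    def test_empty_endpoint_rejected(self, tmp_path):
        bad = TABLE + "\tbinds\tACTIN\t\t\t\t\n"
        with pytest.raises(netio.ParseError, match="row 4"):
            netio.read_interaction_table(write(tmp_path, "t.tsv", bad))

    def test_duplicate_rows_collapse_references_pooled(self, tmp_path):
        text = TABLE + "EGFR\tactivates\tPLC\t\t\tref3\t\n"
        clean = netio.clean_network(netio.read_interaction_table(write(tmp_path, "t.tsv", text)))
        assert clean.number_of_edges() == 2
        refs = {rec.reference for rec in clean["EGFR"]["PLC"]["records"]}
        assert refs == {"ref1", "ref3"}

    def test_node_count_matches_column_union(self, tmp_path):
        # 26-row synthetic table; oracle = set union over the two name columns
        rows = [(f"S{i % 7}", "binds", f"T{i % 5}") for i in range(26)]
        text = "source molecule,interaction,target molecule\n" + "\n".join(
            ",".join(r) for r in rows)
        net = netio.read_interaction_table(write(tmp_path, "t.csv", text))
        expected = {r[0] for r in rows} | {r[2] for r in rows}
        assert set(net.nodes) == expected


class TestCleanMerge:
    def test_clean_removes_loops_and_duplicates(self):
        raw = nx.MultiGraph(name="x")
        raw.add_edges_from([("A", "A"), ("A", "B"), ("B", "A")])
        clean = netio.clean_network(raw)
        assert set(clean.nodes) == {"A", "B"}
        assert {frozenset(e) for e in clean.edges()} == {frozenset({"A", "B"})}

    def test_clean_keeps_nodes_isolated_by_loop_removal(self):
        raw = nx.MultiGraph()
        raw.add_edge("L", "L")
        assert set(netio.clean_network(raw).nodes) == {"L"}

    def test_clean_idempotent_on_random_multigraphs(self):
        import numpy as np
        for seed in range(30):
            rng = np.random.default_rng(seed)
            raw = nx.MultiGraph()
            labels = [f"n{i}" for i in range(8)]
            raw.add_nodes_from(labels)
            for _ in range(25):
                u, v = rng.choice(labels, 2)  # loops and duplicates allowed
                raw.add_edge(str(u), str(v))
            clean = netio.clean_network(raw)
            # oracle: distinct non-loop unordered pairs by exhaustive enumeration
            expected = {frozenset((u, v)) for u, v in raw.edges() if u != v}
            assert {frozenset(e) for e in clean.edges()} == expected
            assert netio.networks_equal(netio.clean_network(clean), clean)

    def test_merge_union_and_idempotence(self):
        a = netio.network("a", edges=[("A", "B")])
        b = netio.network("b", edges=[("B", "C")])
        merged = netio.merge_networks([a, b], "ab")
        assert set(merged.nodes) == {"A", "B", "C"}
        assert merged.number_of_edges() == 2
        assert netio.networks_equal(netio.merge_networks([a, a], "aa"), a)

    def test_merge_order_independent_and_matches_set_union(self):
        nets = [random_clean_graph(seed, max_nodes=15) for seed in range(5)]
        fwd = netio.merge_networks(nets, "m")
        rev = netio.merge_networks(nets[::-1], "m")
        assert netio.networks_equal(fwd, rev)
        all_nodes = set().union(*(set(n.nodes) for n in nets))
        all_edges = set().union(*({frozenset(e) for e in n.edges()} for n in nets))
        assert set(fwd.nodes) == all_nodes
        assert {frozenset(e) for e in fwd.edges()} == all_edges

    def test_merge_empty_list_rejected(self):
        with pytest.raises(ValueError):
            netio.merge_networks([], "x")


class TestStoplist:
    def test_star_filter_leaves_isolated_nodes(self):
        star = netio.network("s", edges=[("spermatozoa", leaf) for leaf in "ABCD"])
        out = netio.remove_nodes(star, netio.Stoplist.from_iterable(["spermatozoa"]))
        assert set(out.nodes) == set("ABCD")
        assert out.number_of_edges() == 0
        dropped = netio.remove_nodes(
            star, netio.Stoplist.from_iterable(["spermatozoa"]), drop_isolated=True)
        assert dropped.number_of_nodes() == 0

    def test_disjoint_stoplist_is_identity(self):
        net = netio.network("n", edges=[("A", "B")])
        out = netio.remove_nodes(net, netio.Stoplist.from_iterable(["membrane"]))
        assert netio.networks_equal(out, net)

    def test_matching_is_exact_label_not_substring(self):
        net = netio.network("n", edges=[("membrane", "membrane receptor")])
        out = netio.remove_nodes(net, netio.Stoplist.from_iterable(["membrane"]))
        assert set(out.nodes) == {"membrane receptor"}

    def test_random_filter_matches_bruteforce(self):
        for seed in range(20):
            net = random_clean_graph(seed)
            stop = frozenset(list(net.nodes)[::3])
            out = netio.remove_nodes(net, netio.Stoplist(terms=stop))
            survivors = {frozenset(e) for e in net.edges()
                         if not (set(e) & stop)}
            assert {frozenset(e) for e in out.edges()} == survivors
            assert set(out.nodes) == set(net.nodes) - stop

    def test_read_stoplist(self, tmp_path):
        p = tmp_path / "stop.txt"
        p.write_text("# nonspecific\nspermatozoa\n membrane \n\n")
        assert netio.read_stoplist(p).terms == {"spermatozoa", "membrane"}


class TestComponents:
    def test_two_disjoint_triangles(self, fixtures):
        comps = netio.connected_components(fixtures["two_triangles"])
        assert [c.number_of_nodes() for c in comps] == [3, 3]
        # tie broken by smallest member label: {A,B,C} before {X,Y,Z}
        assert min(comps[0].nodes) == "A"

    def test_generated_ba_single_component(self, ba_128):
        assert len(netio.connected_components(ba_128)) == 1

    def test_two_component_fixture_sizes(self, fixtures):
        comps = netio.connected_components(fixtures["two_component_125_3"])
        assert [c.number_of_nodes() for c in comps] == [125, 3]
        mc = netio.main_component(fixtures["two_component_125_3"])
        assert mc.number_of_nodes() == 125
        assert mc.graph["name"] == "MC_two_component_125_3"

    def test_component_partition_properties(self):
        for seed in range(25):
            net = random_clean_graph(seed)
            comps = netio.connected_components(net)
            assert sum(c.number_of_nodes() for c in comps) == net.number_of_nodes()
            assert sum(c.number_of_edges() for c in comps) == net.number_of_edges()
            node_sets = [set(c.nodes) for c in comps]
            assert set().union(*node_sets) == set(net.nodes)
            sizes = [len(s) for s in node_sets]
            assert sizes == sorted(sizes, reverse=True)
            # oracle for the main component size
            expected_max = max(len(c) for c in nx.connected_components(net))
            assert netio.main_component(net).number_of_nodes() == expected_max

    def test_main_component_of_empty_network_rejected(self):
        with pytest.raises(ValueError):
            netio.main_component(nx.Graph(name="empty"))


class TestRoundTrip:
    def test_single_edge_and_isolated_node_rendering(self, tmp_path):
        net = netio.network("n", edges=[("A", "B")], nodes=["C"])
        netio.write_edge_list(net, tmp_path / "n.tsv")
        assert (tmp_path / "n.tsv").read_text() == "A\tB\nC\n"

    @pytest.mark.parametrize("fmt", ["edgelist", "sif"])
    def test_write_read_identity_random_networks(self, fmt, tmp_path):
        for seed in range(50):
            net = random_clean_graph(seed, max_nodes=20)
            path = tmp_path / f"net_{seed}.{fmt}"
            if fmt == "edgelist":
                netio.write_edge_list(net, path)
                back = netio.clean_network(netio.read_edge_list(path))
            else:
                netio.write_sif(net, path)
                back = netio.clean_network(netio.read_sif(path))
            assert netio.networks_equal(net, back)
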