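import itertools

import networkx as nx
import numpy as np
import pytest

from nrnet.errors import ConfigurationError, DataError
from nrnet.motifs import (
    CENSUS_CODES,
    COMPLETE_CODES,
    LINEAR_CODES,
    MotifOccurrenceTable,
    census_hub_motifs,
    cross_network_conservation,
    enumerate_configurations,
    hub_local_network,
    make_triad,
    npu_code,
    signs_for_code,
)
from nrnet.network import SignedNetwork


def signed_graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, j, w in edges:
        g.add_edge(i, j, weight=w, sign="positive" if w > 0 else "negative")
    return SignedNetwork(graph=g, name="net")


class TestNPUCode:
    @pytest.mark.parametrize(
        "signs,code",
        [
            (("positive", "positive", "absent"), "021"),
            (("absent", "absent", "absent"), "003"),
            (("positive", "positive", "positive"), "030"),
            (("negative", "negative", "negative"), "300"),
            ((-1, 1, 0), "111"),
            ((1, -1, -1), "210"),
        ],
    )
    def test_examples(self, signs, code):
        assert npu_code(signs) == code

    def test_order_invariance(self):
        for perm in itertools.permutations((-1, 1, 0)):
            assert npu_code(perm) == "111"

    def test_signs_for_code_round_trips(self):
        for code in ("003", "012", "102", *CENSUS_CODES):
            assert npu_code(signs_for_code(code)) == code

    def test_malformed_code_rejected(self):
        with pytest.raises(ConfigurationError):
            signs_for_code("041")


class TestTopologyAndCoherence:
    def test_all_positive_triangle_is_coherent_complete(self):
        t = make_triad(("A", "B", "C"), (1, 1, 1))
        assert t.code == "030"
        assert t.topology == "complete"
        assert t.coherence == "coherent"

    def test_one_negative_triangle_is_incoherent(self):
        t = make_triad(("A", "B", "C"), (-1, 1, 1))
        assert t.code == "120"
        assert t.topology == "complete"
        assert t.coherence == "incoherent"

    def test_linear_motif_has_no_coherence_and_a_centre(self):
        # edges A-B and A-C present: A is the centre
        t = make_triad(("A", "B", "C"), (1, 1, 0))
        assert t.code == "021"
        assert t.topology == "linear"
        assert t.coherence == "n/a"
        assert t.centre == "A"

    def test_complete_triads_split_four_four_by_sign_product(self):
        """All 8 signed triangles: coherence == (product of signs > 0)."""
        coherent = 0
        for signs in itertools.product((-1, 1), repeat=3):
            t = make_triad(("A", "B", "C"), signs)
            expected = "coherent" if np.prod(signs) > 0 else "incoherent"
            assert t.coherence == expected
            coherent += t.coherence == "coherent"
        assert coherent == 4

    def test_empty_and_single_edge_topologies(self):
        assert make_triad(("A", "B", "C"), (0, 0, 0)).topology == "empty"
        assert make_triad(("A", "B", "C"), (1, 0, 0)).topology == "one_edge"


class TestEnumerateConfigurations:
    def test_combinatorial_census(self):
        census = enumerate_configurations()
        assert census.total_configurations == 27
        assert census.n_distinct_codes == 10
        assert census.configurations_per_code["111"] == 6
        assert census.linear_configurations == 12
        assert census.complete_configurations == 8

    def test_per_code_counts_sum_to_total(self):
        census = enumerate_configurations()
        assert sum(census.configurations_per_code.values()) == 27
        assert (
            sum(census.configurations_per_code[c] for c in LINEAR_CODES) == 12
        )
        assert (
            sum(census.configurations_per_code[c] for c in COMPLETE_CODES) == 8
        )


class TestHubLocalNetwork:
    def test_path_truncated_at_distance_two(self):
        net = signed_graph([("H", "A", 0.5), ("A", "B", 0.4), ("B", "C", 0.3)])
        local = hub_local_network(net, "H")
        assert local.nodes == {"H", "A", "B"}

    def test_isolated_hub(self):
        net = signed_graph([("A", "B", 0.5)], nodes=["H"])
        local = hub_local_network(net, "H")
        assert local.nodes == {"H"}
        assert local.graph.number_of_edges() == 0

    def test_triangle_kept_whole(self):
        net = signed_graph([("H", "A", 0.5), ("A", "B", 0.4), ("H", "B", 0.3)])
        local = hub_local_network(net, "H")
        assert local.nodes == {"H", "A", "B"}
        assert local.graph.number_of_edges() == 3

    def test_absent_hub_is_data_error(self):
        with pytest.raises(DataError):
            hub_local_network(signed_graph([("A", "B", 0.5)]), "H")


def brute_force_census(local, require_hub=True):
    """Independent exhaustive enumeration over all C(n, 3) node triples."""
    counts = {code: 0 for code in CENSUS_CODES}
    for triple in itertools.combinations(sorted(local.nodes), 3):
        if require_hub and local.hub not in triple:
            continue
        signs = []
        for u, v in itertools.combinations(triple, 2):
            if local.graph.has_edge(u, v):
                signs.append(1 if local.graph.edges[u, v]["weight"] > 0 else -1)
            else:
                signs.append(0)
        if sum(1 for s in signs if s != 0) < 2:
            continue
        counts[npu_code(signs)] += 1
    return counts


class TestCensusHubMotifs:
    def test_two_spoke_star_is_one_021(self):
        net = signed_graph([("H", "A", 0.5), ("H", "B", 0.4)])
        counts, records = census_hub_motifs(hub_local_network(net, "H"))
        assert counts == {**{c: 0 for c in CENSUS_CODES}, "021": 1}
        assert records[0].centre == "H"

    def test_positive_triangle_is_one_030(self):
        net = signed_graph([("H", "A", 0.5), ("A", "B", 0.4), ("H", "B", 0.3)])
        counts, _ = census_hub_motifs(hub_local_network(net, "H"))
        assert counts["030"] == 1
        assert sum(counts.values()) == 1

    def test_counts_match_exhaustive_oracle_on_random_graphs(self):
        """Census equals independent brute-force enumeration on random
        signed graphs with up to 15 nodes."""
        rng = np.random.default_rng(0)
        for trial in range(25):
            n = int(rng.integers(4, 16))
            p = rng.uniform(0.1, 0.5)
            edges = [
                (f"N{i}", f"N{j}", float(rng.choice([-0.4, 0.4])))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < p
            ]
            net = signed_graph(edges, nodes=[f"N{i}" for i in range(n)])
            local = hub_local_network(net, "N0")
            for require_hub in (True, False):
                counts, records = census_hub_motifs(local, require_hub=require_hub)
                assert counts == brute_force_census(local, require_hub)
                # conservation: total == number of qualifying triples
                assert sum(counts.values()) == len(records)

    def test_node_relabelling_invariance(self):
        edges = [("H", "A", 0.5), ("A", "B", -0.4), ("H", "B", 0.3), ("H", "C", 0.2)]
        net1 = signed_graph(edges)
        mapping = {"H": "hub", "A": "x", "B": "y", "C": "z"}
        net2 = signed_graph([(mapping[i], mapping[j], w) for i, j, w in edges])
        c1, _ = census_hub_motifs(hub_local_network(net1, "H"))
        c2, _ = census_hub_motifs(hub_local_network(net2, "hub"))
        assert c1 == c2


def table(network_id, cohort, triads, hub="H"):
    records = [make_triad(genes, signs) for genes, signs in triads]
    counts = {c: 0 for c in CENSUS_CODES}
    for r in records:
        counts[r.code] += 1
    return MotifOccurrenceTable(
        hub=hub, network_id=network_id, cohort=cohort, counts=counts, records=records
    )


class TestCrossNetworkConservation:
    def make_tables(self, presence):
        """presence: dict network -> (cohort, list of (genes, signs))"""
        return [table(nid, cohort, triads) for nid, (cohort, triads) in presence.items()]

    def test_six_of_eight_spanning_cohorts_is_reported(self):
        triad = (("H", "A", "B"), (1, 1, 0))
        presence = {}
        for k in range(8):
            cohort = "tcga" if k < 4 else "metabric"
            triads = [triad] if k < 6 else []
            presence[f"net{k}"] = (cohort, triads)
        conserved = cross_network_conservation(self.make_tables(presence), 6)
        assert len(conserved) == 1
        assert conserved[0].genes == ("A", "B", "H")
        assert conserved[0].n_networks == 6
        assert set(conserved[0].cohorts) == {"tcga", "metabric"}
        assert conserved[0].per_network["net0"] == "Present(linear, 021)"
        assert conserved[0].per_network["net7"] == "Absent"

    def test_single_cohort_presence_not_reported(self):
        triad = (("H", "A", "B"), (1, 1, 0))
        presence = {f"net{k}": ("tcga", [triad]) for k in range(5)}
        presence["net5"] = ("metabric", [])
        conserved = cross_network_conservation(self.make_tables(presence), 5)
        assert conserved == []

    def test_varying_code_reported_once_with_per_network_types(self):
        linear = (("H", "A", "B"), (1, 1, 0))
        complete = (("H", "A", "B"), (1, 1, 1))
        presence = {
            "net0": ("tcga", [linear]),
            "net1": ("metabric", [complete]),
        }
        conserved = cross_network_conservation(self.make_tables(presence), 2)
        assert len(conserved) == 1
        assert conserved[0].per_network["net0"] == "Present(linear, 021)"
        assert conserved[0].per_network["net1"] == "Present(complete, 030)"

    def test_min_networks_beyond_supply_rejected(self):
        presence = {
            "net0": ("tcga", []),
            "net1": ("metabric", []),
        }
        with pytest.raises(ConfigurationError):
            cross_network_conservation(self.make_tables(presence), 3)


class TestPlantedTriadRecovery:
    def test_surviving_planted_triads_keep_their_codes(self):
        """Whenever every pair of a planted triad survives thresholding
        with its planted sign, the census reports the triple with the
        planted NPU code."""
        import pandas as pd

        from nrnet.network import (
            rank_edges,
            shrinkage_partial_correlations,
            threshold_top_fraction,
        )
        from nrnet.preprocess import ExpressionMatrix
        from nrnet.simulate import plant_precision_matrix, sample_residuals

        checked = 0
        for seed in range(10):
            st = plant_precision_matrix(
                50, hub_count=1, hub_degree=4,
                triads=[(0, 20, 21, "030"), (0, 22, 23, "111")],
                base_weight=0.3, seed=seed,
            )
            x = sample_residuals(st.precision, 150, seed=seed + 2000)
            m = ExpressionMatrix(
                values=pd.DataFrame(
                    x.T, index=st.gene_ids, columns=[f"S{j}" for j in range(150)]
                )
            )
            net = threshold_top_fraction(
                rank_edges(shrinkage_partial_correlations(m)), 0.01
            )
            idx = {g: i for i, g in enumerate(st.gene_ids)}
            local = hub_local_network(net, st.hub_genes[0])
            _, records = census_hub_motifs(local)
            found = {r.key: r.code for r in records}
            for a, b, c, code in st.planted_triads:
                survived = True
                for u, v in itertools.combinations((a, b, c), 2):
                    key = (min(idx[u], idx[v]), max(idx[u], idx[v]))
                    want = st.edge_signs.get(key, 0)
                    if net.graph.has_edge(u, v):
                        got = 1 if net.graph.edges[u, v]["weight"] > 0 else -1
                    else:
                        got = 0
                    if got != want:
                        survived = False
                if survived:
                    checked += 1
                    assert found.get(frozenset((a, b, c))) == code
        assert checked >= 5  # the scenario keeps most triads above threshold
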