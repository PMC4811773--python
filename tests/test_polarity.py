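"""Synapse flow centrality, axon/dendrite splits, segregation index and
cable-space synapse clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arbortwig.polarity import (
    PolarityWarning,
    axon_dendrite_split,
    cluster_condensed_graph,
    cluster_synapses,
    clustering_segregation,
    flow_cable_metrics,
    segregation_index,
    synapse_density,
    synapse_flow_centrality,
    synapse_io_nodes,
)
from arbortwig.skeleton import (
    Skeleton,
    SkeletonError,
    SkeletonNode,
    geodesic_distance,
    subtree_nodes,
)
from arbortwig.synthgen import generate_textbook_neuron

from conftest import chain_skeleton, make_random_tree, synapses_on


def brute_force_flow(skeleton, connectors):
    """Literal pair enumeration: an input-output pair contributes to
    centrifugal(v) when the input lies outside subtree(v) and the output
    inside, and to centripetal(v) in the mirrored case."""
    inputs, outputs = synapse_io_nodes(skeleton, connectors)
    subtrees = {v: subtree_nodes(skeleton, v) for v in skeleton.node_ids}
    cf = {v: 0 for v in skeleton.node_ids}
    cp = {v: 0 for v in skeleton.node_ids}
    for i in inputs:
        for o in outputs:
            for v in skeleton.node_ids:
                inside = subtrees[v]
                if i not in inside and o in inside:
                    cf[v] += 1
                elif i in inside and o not in inside:
                    cp[v] += 1
    return cf, cp


class TestFlowCentrality:
    def test_chain_input_then_output(self):
        skel = chain_skeleton([1.0, 1.0])  # R(1) - A(2, input) - B(3, output)
        conns = synapses_on("chain", input_nodes=[2], output_nodes=[3])
        flow = synapse_flow_centrality(skel, conns)
        assert flow.centrifugal == {1: 0, 2: 0, 3: 1}
        assert flow.centripetal == {1: 0, 2: 0, 3: 0}

    def test_no_outputs_all_zero(self):
        skel = chain_skeleton([1.0, 1.0])
        flow = synapse_flow_centrality(
            skel, synapses_on("chain", input_nodes=[2, 3], output_nodes=[])
        )
        assert all(v == 0 for v in flow.centrifugal.values())
        assert all(v == 0 for v in flow.centripetal.values())

    def test_root_centrifugal_is_zero(self, rng):
        skel = make_random_tree(rng, 30)
        conns = synapses_on(
            "rand",
            [int(n) for n in rng.choice(skel.node_ids, 8)],
            [int(n) for n in rng.choice(skel.node_ids, 5)],
        )
        flow = synapse_flow_centrality(skel, conns)
        assert flow.centrifugal[skel.root] == 0

    def test_matches_pair_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 50))
            skel = make_random_tree(rng, n)
            n_in = int(rng.integers(0, 12))
            n_out = int(rng.integers(0, 9))
            conns = synapses_on(
                "rand",
                [int(x) for x in rng.choice(skel.node_ids, n_in)],
                [int(x) for x in rng.choice(skel.node_ids, n_out)],
            )
            flow = synapse_flow_centrality(skel, conns)
            cf, cp = brute_force_flow(skel, conns)
            assert flow.centrifugal == cf
            assert flow.centripetal == cp


class TestSplit:
    def test_chain_splits_at_output(self):
        skel = chain_skeleton([1.0, 1.0])
        conns = synapses_on("chain", [2], [3])
        flow = synapse_flow_centrality(skel, conns)
        split = axon_dendrite_split(flow, skel, conns)
        assert split.split_node == 3
        assert split.axon == frozenset({3})
        assert split.dendrite == frozenset({1, 2})

    def test_textbook_neuron_recovered(self):
        recon, truth = generate_textbook_neuron(seed=5)
        skel = recon.skeletons["textbook"]
        flow = synapse_flow_centrality(skel, recon.connectors)
        split = axon_dendrite_split(flow, skel, recon.connectors)
        assert split.split_node == truth.split_node
        assert set(split.axon) == truth.axon_nodes
        assert split.segregation == pytest.approx(1.0)
        metrics = flow_cable_metrics(flow, skel)
        assert metrics["linker_cable_um"] == pytest.approx(
            truth.linker_cable_um, rel=1e-9
        )

    def test_no_outputs_is_undefined(self):
        skel = chain_skeleton([1.0, 1.0])
        conns = synapses_on("chain", [2, 3], [])
        flow = synapse_flow_centrality(skel, conns)
        with pytest.raises(SkeletonError, match="split undefined"):
            axon_dendrite_split(flow, skel, conns)

    def test_mixed_cable_warns_unsegregated(self, rng):
        # inputs and outputs interleaved uniformly along one cable
        skel = chain_skeleton([0.5] * 60)
        ids = skel.node_ids
        inputs = [int(n) for n in rng.choice(ids, 60)]
        outputs = [int(n) for n in rng.choice(ids, 60)]
        conns = synapses_on("chain", inputs, outputs)
        flow = synapse_flow_centrality(skel, conns)
        with pytest.warns(PolarityWarning, match="unsegregated"):
            split = axon_dendrite_split(flow, skel, conns)
        assert split.segregation < 0.05

    def test_flow_metrics_flag_when_no_outputs(self):
        skel = chain_skeleton([1.0])
        flow = synapse_flow_centrality(skel, synapses_on("chain", [2], []))
        metrics = flow_cable_metrics(flow, skel)
        assert metrics["linker_cable_um"] == 0.0
        assert metrics["linker_defined"] is False


class TestSegregationIndex:
    def test_pure_clusters_fully_segregated(self):
        assert segregation_index([(10, 1.0), (10, 0.0)]) == pytest.approx(1.0)

    def test_globally_mixed_is_zero(self):
        assert segregation_index([(10, 0.5), (10, 0.5)]) == pytest.approx(0.0)
        assert segregation_index([(30, 0.3), (70, 0.3)]) == pytest.approx(0.0)

    def test_partially_mixed_value(self):
        # independent evaluation of the entropy formulas
        p = 0.8
        S_i = -(p * math.log(p) + (1 - p) * math.log(1 - p))
        expected = 1.0 - S_i / math.log(2)
        H = segregation_index([(10, 0.8), (10, 0.2)])
        assert H == pytest.approx(expected)
        assert H == pytest.approx(0.278, abs=5e-4)

    def test_log_base_invariance_and_merging(self):
        clusters = [(12, 0.75), (20, 0.15), (8, 0.5)]
        H = segregation_index(clusters)
        # log-base change rescales S and S_norm identically
        scale = 1.0 / math.log(2)

        def entropy2(p):
            if p <= 0 or p >= 1:
                return 0.0
            return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))

        total = sum(n for n, _ in clusters)
        S2 = sum(n * entropy2(p) for n, p in clusters) / total
        p_all = sum(n * p for n, p in clusters) / total
        H2 = 1.0 - S2 / entropy2(p_all)
        assert H == pytest.approx(H2)
        # merging every cluster into one yields H = 0
        assert segregation_index([(total, p_all)]) == pytest.approx(0.0)

    def test_pure_arbor_undefined(self):
        with pytest.raises(SkeletonError, match="undefined"):
            segregation_index([(5, 1.0), (3, 1.0)])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=500),
                st.floats(min_value=0.0, max_value=1.0),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_bounded_and_relabeling_invariant(self, clusters):
        total = sum(n for n, _ in clusters)
        p_all = sum(n * p for n, p in clusters) / total
        if p_all <= 0.0 or p_all >= 1.0:
            with pytest.raises(SkeletonError):
                segregation_index(clusters)
            return
        H = segregation_index(clusters)
        assert -1e-9 <= H <= 1.0 + 1e-9
        assert segregation_index(list(reversed(clusters))) == pytest.approx(H)

    def test_invalid_clusters_rejected(self):
        with pytest.raises(SkeletonError):
            segregation_index([])
        with pytest.raises(SkeletonError):
            segregation_index([(0, 0.5)])


class TestSynapseDensity:
    def test_single_synapse_unit_density(self):
        skel = chain_skeleton([1.0, 1.0])
        conns = synapses_on("chain", [2], [])
        for lam in (0.5, 3.0, 50.0):
            d = synapse_density(skel, conns, lam)
            assert d[2] == pytest.approx(1.0)

    def test_one_bandwidth_away(self):
        skel = chain_skeleton([3.0])
        d = synapse_density(skel, synapses_on("chain", [2], []), 3.0)
        assert d[1] == pytest.approx(math.exp(-0.5))

    def test_presynaptic_multiplicity(self):
        skel = chain_skeleton([1.0])
        conns = synapses_on("chain", [], [2], posts_per_output=3)
        d = synapse_density(skel, conns, 5.0)
        assert d[2] == pytest.approx(3.0)

    def test_matches_double_loop(self, rng):
        skel = make_random_tree(rng, 40)
        ids = skel.node_ids
        conns = synapses_on(
            "rand",
            [int(n) for n in rng.choice(ids, 20)],
            [int(n) for n in rng.choice(ids, 10)],
        )
        lam = 4.0
        d = synapse_density(skel, conns, lam)
        inputs, outputs = synapse_io_nodes(skel, conns, presyn_per_target=True)
        syn = inputs + outputs
        for i in ids:
            expected = sum(
                math.exp(-geodesic_distance(skel, i, j) ** 2 / (2 * lam**2))
                for j in syn
            )
            assert d[i] == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_bandwidth(self, rng):
        skel = make_random_tree(rng, 30)
        conns = synapses_on(
            "rand", [int(n) for n in rng.choice(skel.node_ids, 10)], []
        )
        d_small = synapse_density(skel, conns, 2.0)
        d_large = synapse_density(skel, conns, 8.0)
        assert all(d_large[i] >= d_small[i] - 1e-12 for i in skel.node_ids)


def two_group_chain():
    """61-node chain, 1 µm spacing; synapse groups at both ends, 40 µm gap."""
    skel = chain_skeleton([1.0] * 60)
    conns = synapses_on("chain", [2, 3, 4, 5, 6, 55, 56, 57, 58, 59], [])
    return skel, conns


class TestClustering:
    def test_single_synapse_single_cluster(self):
        skel = chain_skeleton([1.0, 1.0])
        clustering = cluster_synapses(skel, synapses_on("chain", [2], []), 3.0)
        assert len(clustering.clusters) == 1
        assert clustering.clusters[0]["synapses"] == [2]

    def test_two_groups_small_bandwidth(self):
        skel, conns = two_group_chain()
        clustering = cluster_synapses(skel, conns, 3.0)
        memberships = sorted(
            sorted(c["synapses"]) for c in clustering.clusters
        )
        assert memberships == [[2, 3, 4, 5, 6], [55, 56, 57, 58, 59]]

    def test_large_bandwidth_merges_everything(self):
        skel, conns = two_group_chain()
        clustering = cluster_synapses(skel, conns, 200.0)
        assert len(clustering.clusters) == 1

    def test_every_synapse_in_exactly_one_cluster(self, rng):
        skel = make_random_tree(rng, 50)
        conns = synapses_on(
            "rand",
            [int(n) for n in rng.choice(skel.node_ids, 15)],
            [int(n) for n in rng.choice(skel.node_ids, 5)],
        )
        clustering = cluster_synapses(skel, conns, 5.0)
        all_syn = sorted(
            s for c in clustering.clusters for s in c["synapses"]
        )
        inputs, outputs = synapse_io_nodes(skel, conns, presyn_per_target=True)
        assert all_syn == sorted(inputs + outputs)

    def test_deterministic(self):
        skel, conns = two_group_chain()
        a = cluster_synapses(skel, conns, 3.0)
        b = cluster_synapses(skel, conns, 3.0)
        assert [c["peak"] for c in a.clusters] == [c["peak"] for c in b.clusters]

    def test_segregation_over_clusters(self):
        skel = chain_skeleton([1.0] * 60)
        conns = synapses_on(
            "chain", [2, 3, 4, 5, 6], [55, 56, 57, 58, 59]
        )
        clustering = cluster_synapses(skel, conns, 3.0)
        assert clustering_segregation(clustering, skel, conns) == pytest.approx(
            1.0
        )


class TestCondensedGraph:
    def test_single_cluster_isolated_node(self):
        skel = chain_skeleton([1.0])
        clustering = cluster_synapses(skel, synapses_on("chain", [2], []), 3.0)
        g = cluster_condensed_graph(clustering, skel)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_three_peaks_on_chain_form_path(self):
        skel = chain_skeleton([1.0] * 80)
        conns = synapses_on(
            "chain",
            [2, 3, 4, 40, 41, 42, 78, 79, 80],
            [],
        )
        clustering = cluster_synapses(skel, conns, 3.0)
        assert len(clustering.clusters) == 3
        g = cluster_condensed_graph(clustering, skel)
        degrees = sorted(d for _n, d in g.degree())
        assert degrees == [1, 1, 2]  # path, no shortcut edge

    def test_symmetric_two_branch_arbor(self):
        # central entry, two branches, two synapse groups per branch
        nodes = [SkeletonNode(1, None, (0.0, 0.0, 0.0))]
        nid = 2
        branch_nodes = {}
        for branch, direction in (("a", 1.0), ("b", -1.0)):
            parent = 1
            ids = []
            for k in range(1, 41):
                nodes.append(
                    SkeletonNode(nid, parent, (direction * k * 1000.0, 0, 0))
                )
                parent = nid
                ids.append(nid)
                nid += 1
            branch_nodes[branch] = ids
        skel = Skeleton("dbd", nodes)
        syn = (
            branch_nodes["a"][4:7]
            + branch_nodes["a"][34:37]
            + branch_nodes["b"][4:7]
            + branch_nodes["b"][34:37]
        )
        conns = synapses_on("dbd", syn, [])
        clustering = cluster_synapses(skel, conns, 3.0)
        assert len(clustering.clusters) == 4
        g = cluster_condensed_graph(clustering, skel)
        assert g.number_of_edges() == 3  # a tree mirroring the arbor
        degrees = sorted(d for _n, d in g.degree())
        assert degrees == [1, 1, 2, 2]
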