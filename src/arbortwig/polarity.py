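"""Synaptic polarity of an arbor: flow centrality, axon/dendrite split,
segregation index, and cable-space synapse-density clustering.

Synapse flow centrality (SFC) counts, for every skeleton node v, the
input-output synapse pairs whose connecting path crosses v.  The
*centrifugal* flavor counts pairs with the input proximal to v and the
output distal; the *centripetal* flavor the reverse.  Since the tree path
between any two nodes passing through v must enter and leave v's subtree,
both flavors reduce to a product of synapse counts inside and outside the
subtree rooted at v.  The most proximal node with maximal centrifugal SFC
generalizes the textbook axon/dendrite boundary; the segregation index H
then scores how cleanly inputs and outputs separate across compartments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .skeleton import (
    Connector,
    Skeleton,
    SkeletonError,
    cable_length,
    geodesic_matrix,
    subtree_nodes,
)

UNSEGREGATED_H = 0.05
DEFAULT_BANDWIDTH_UM = 10.0


class PolarityWarning(UserWarning):
    pass


@dataclass
class FlowRecord:
    """Per-node centrifugal/centripetal synapse-path counts."""

    skeleton_id: str
    centrifugal: dict[int, int]
    centripetal: dict[int, int]
    n_inputs: int
    n_outputs: int

    def total(self, node_id: int) -> int:
        return self.centrifugal[node_id] + self.centripetal[node_id]


@dataclass
class PolaritySplit:
    split_node: int
    axon: frozenset[int]
    dendrite: frozenset[int]
    linker_cable_um: float
    segregation: float


@dataclass
class SynapseClustering:
    bandwidth_um: float
    density: dict[int, float]
    clusters: list[dict]  # {"peak": node, "nodes": set, "synapses": list}

    def cluster_of(self, node_id: int) -> int | None:
        for i, cl in enumerate(self.clusters):
            if node_id in cl["nodes"]:
                return i
        return None


def synapse_io_nodes(
    skeleton: Skeleton,
    connectors: list[Connector],
    presyn_per_target: bool = False,
) -> tuple[list[int], list[int]]:
    """Input (postsynaptic) and output (presynaptic) relation nodes.

    Each postsynaptic relation counts once.  A presynaptic connector
    counts once by default; with ``presyn_per_target`` it is repeated
    once per postsynaptic partner, the multiplicity used by the density
    estimator.
    """
    inputs: list[int] = []
    outputs: list[int] = []
    sid = skeleton.skeleton_id
    for conn in connectors:
        if conn.presynaptic.skeleton_id == sid:
            mult = len(conn.postsynaptic) if presyn_per_target else 1
            outputs.extend([conn.presynaptic.node_id] * mult)
        for rel in conn.postsynaptic:
            if rel.skeleton_id == sid:
                inputs.append(rel.node_id)
    return inputs, outputs


def synapse_flow_centrality(
    skeleton: Skeleton,
    connectors: list[Connector],
    presyn_per_target: bool = False,
) -> FlowRecord:
    """Compute centrifugal and centripetal SFC at every node.

    With I(v), O(v) the input/output counts inside subtree(v) and I, O
    the totals: centrifugal(v) = (I - I(v)) * O(v) and centripetal(v) =
    I(v) * (O - O(v)).  Synapses attached exactly at v count as inside
    subtree(v).  A neuron lacking inputs or outputs yields all zeros.
    """
    inputs, outputs = synapse_io_nodes(skeleton, connectors, presyn_per_target)
    in_count: dict[int, int] = {nid: 0 for nid in skeleton}
    out_count: dict[int, int] = {nid: 0 for nid in skeleton}
    for nid in inputs:
        in_count[nid] += 1
    for nid in outputs:
        out_count[nid] += 1
    # Accumulate subtree sums leaf-to-root.
    in_sub = dict(in_count)
    out_sub = dict(out_count)
    for nid in reversed(skeleton.topo_order()):
        p = skeleton.parent(nid)
        if p is not None:
            in_sub[p] += in_sub[nid]
            out_sub[p] += out_sub[nid]
    I, O = len(inputs), len(outputs)
    centrifugal = {v: (I - in_sub[v]) * out_sub[v] for v in skeleton}
    centripetal = {v: in_sub[v] * (O - out_sub[v]) for v in skeleton}
    return FlowRecord(
        skeleton_id=skeleton.skeleton_id,
        centrifugal=centrifugal,
        centripetal=centripetal,
        n_inputs=I,
        n_outputs=O,
    )


def flow_cable_metrics(
    flow: FlowRecord, skeleton: Skeleton
) -> dict[str, float | bool]:
    """Cable (µm) at the maximal centrifugal and centripetal SFC values.

    The maximal-centrifugal plateau measures the axon-dendrite linker;
    the maximal-centripetal plateau the main dendritic shafts (only
    meaningful for arbors with dendritic outputs).  When a flavor's
    maximum is zero the metric is 0 and flagged undefined.
    """
    out: dict[str, float | bool] = {}
    for name, values in (
        ("linker", flow.centrifugal),
        ("dendritic_shaft", flow.centripetal),
    ):
        peak = max(values.values(), default=0)
        if peak <= 0:
            out[f"{name}_cable_um"] = 0.0
            out[f"{name}_defined"] = False
        else:
            nodes = [v for v, c in values.items() if c == peak]
            out[f"{name}_cable_um"] = cable_length(skeleton, nodes)
            out[f"{name}_defined"] = True
    return out


def axon_dendrite_split(
    flow: FlowRecord, skeleton: Skeleton, connectors: list[Connector]
) -> PolaritySplit:
    """Split the arbor at the most proximal maximal-centrifugal-SFC node.

    The axon is the subtree hanging from the split node; everything else
    is dendrite.  Ties among maximizers resolve toward the root (smallest
    cable distance to root), then by smallest node id.  The segregation
    index of the resulting two compartments is attached as a success
    check; values below 0.05 trigger an 'unsegregated arbor' warning.
    """
    peak = max(flow.centrifugal.values(), default=0)
    if peak <= 0:
        raise SkeletonError(
            "maximum centrifugal flow is zero: axon/dendrite split undefined"
        )
    maximizers = [v for v, c in flow.centrifugal.items() if c == peak]
    split_node = min(maximizers, key=lambda v: (skeleton.depth_nm(v), v))
    axon = frozenset(subtree_nodes(skeleton, split_node))
    dendrite = frozenset(set(skeleton.node_ids) - axon)
    linker_cable = cable_length(skeleton, maximizers)
    inputs, outputs = synapse_io_nodes(skeleton, connectors)
    clusters = []
    for comp in (axon, dendrite):
        n_in = sum(1 for nid in inputs if nid in comp)
        n_out = sum(1 for nid in outputs if nid in comp)
        if n_in + n_out > 0:
            clusters.append((n_in + n_out, n_in / (n_in + n_out)))
    H = segregation_index(clusters)
    if H < UNSEGREGATED_H:
        warnings.warn(
            f"unsegregated arbor (H = {H:.4f} < {UNSEGREGATED_H})",
            PolarityWarning,
            stacklevel=2,
        )
    return PolaritySplit(
        split_node=split_node,
        axon=axon,
        dendrite=dendrite,
        linker_cable_um=linker_cable,
        segregation=H,
    )


def segregation_index(clusters: list[tuple[int, float]]) -> float:
    """Entropy-based input/output segregation index H in [0, 1].

    ``clusters`` holds (N_i, p_i) pairs: synapse count and input fraction
    per cluster.  Each cluster contributes the binary entropy
    S_i = -(p_i log p_i + (1-p_i) log(1-p_i)); the arbor entropy S is the
    synapse-count-weighted mean of the S_i, and S_norm is the same
    entropy at the whole-arbor input fraction.  H = 1 - S/S_norm: 0 for a
    fully mixed arbor, 1 for complete input/output separation.  Natural
    logs; 0*log(0) = 0.  Undefined (raises) when the whole arbor is pure
    input or pure output.
    """
    if not clusters:
        raise SkeletonError("segregation index needs at least one cluster")
    total = 0
    weighted_in = 0.0
    S = 0.0
    for N_i, p_i in clusters:
        if N_i <= 0:
            raise SkeletonError(f"cluster synapse count must be > 0, got {N_i}")
        if not 0.0 <= p_i <= 1.0:
            raise SkeletonError(f"input fraction out of [0,1]: {p_i}")
        total += N_i
        weighted_in += N_i * p_i
        S += N_i * _binary_entropy(p_i)
    S /= total
    S_norm = _binary_entropy(weighted_in / total)
    if S_norm == 0.0:
        raise SkeletonError(
            "segregation undefined: arbor has only inputs or only outputs"
        )
    return 1.0 - S / S_norm


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log(p) + (1.0 - p) * math.log(1.0 - p))


# ---------------------------------------------------------------------------
# Cable-space synapse-density clustering
# ---------------------------------------------------------------------------


def synapse_density(
    skeleton: Skeleton,
    connectors: list[Connector],
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM,
) -> dict[int, float]:
    """Gaussian synapse density at every node, measured along the cable.

    d(i) = sum over synapse nodes j of exp(-delta_ij^2 / (2 lambda^2)),
    with delta the geodesic (cable) distance.  The synapse multiset uses
    per-target multiplicity for presynaptic sites: a polyadic connector's
    presynaptic node is counted once per postsynaptic partner.
    """
    if bandwidth_um <= 0:
        raise ValueError("bandwidth must be positive")
    inputs, outputs = synapse_io_nodes(
        skeleton, connectors, presyn_per_target=True
    )
    syn_nodes = inputs + outputs
    node_ids = skeleton.node_ids
    if not syn_nodes:
        return {nid: 0.0 for nid in node_ids}
    uniq = sorted(set(syn_nodes))
    mult = np.array([syn_nodes.count(u) for u in uniq], dtype=float)
    dmat = geodesic_matrix(skeleton, uniq, node_ids)  # uniq x all nodes, µm
    dens = mult @ np.exp(-(dmat**2) / (2.0 * bandwidth_um**2))
    return {nid: float(d) for nid, d in zip(node_ids, dens)}


def synapse_clusters(
    density: dict[int, float],
    skeleton: Skeleton,
    connectors: list[Connector],
) -> SynapseClustering:
    """Partition synapses into density basins via discrete gradient ascent.

    From every synapse-bearing node, repeatedly step to the neighbor
    (parent or child) with the largest positive density difference until
    none remains; nodes reaching the same terminus form one basin.  Ties
    between equal-density neighbors break toward the neighbor closer to
    the root, then toward the smaller node id, making basins
    deterministic.  On an exact density plateau (equal values to within
    1e-12 relative) the walk continues root-ward, so a flat maximum
    drains to a single terminus instead of fragmenting.
    """
    inputs, outputs = synapse_io_nodes(
        skeleton, connectors, presyn_per_target=True
    )
    syn_nodes = inputs + outputs
    terminus_cache: dict[int, int] = {}

    def ascend(start: int) -> int:
        path = []
        nid = start
        while nid not in terminus_cache:
            path.append(nid)
            best = None
            best_key = None
            tol = 1e-12 * max(1.0, abs(density[nid]))
            for nb in skeleton.neighbors(nid):
                diff = density[nb] - density[nid]
                if diff <= tol:
                    continue
                key = (-diff, skeleton.depth_nm(nb), nb)
                if best_key is None or key < best_key:
                    best, best_key = nb, key
            if best is None:
                # plateau: drain root-ward through equal-density neighbors
                here = (skeleton.depth_nm(nid), nid)
                for nb in skeleton.neighbors(nid):
                    if abs(density[nb] - density[nid]) <= tol and (
                        skeleton.depth_nm(nb),
                        nb,
                    ) < here:
                        best = nb
                        break
            if best is None:
                terminus_cache[nid] = nid
                break
            nid = best
        term = terminus_cache[nid]
        for p in path:
            terminus_cache[p] = term
        return term

    basins: dict[int, list[int]] = {}
    for nid in sorted(set(syn_nodes)):
        basins.setdefault(ascend(nid), []).append(nid)
    clusters = []
    for peak in sorted(basins):
        members = basins[peak]
        member_set = set(members)
        clusters.append(
            {
                "peak": peak,
                "nodes": member_set,
                "synapses": [n for n in syn_nodes if n in member_set],
            }
        )
    # infer bandwidth not stored in density dict; caller holds it
    return SynapseClustering(
        bandwidth_um=float("nan"), density=dict(density), clusters=clusters
    )


def cluster_synapses(
    skeleton: Skeleton,
    connectors: list[Connector],
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM,
) -> SynapseClustering:
    """Convenience wrapper: density estimation followed by basin ascent."""
    density = synapse_density(skeleton, connectors, bandwidth_um)
    clustering = synapse_clusters(density, skeleton, connectors)
    clustering.bandwidth_um = bandwidth_um
    return clustering


def clustering_segregation(
    clustering: SynapseClustering,
    skeleton: Skeleton,
    connectors: list[Connector],
) -> float:
    """Segregation index H over the clusters of a synapse clustering."""
    inputs, outputs = synapse_io_nodes(skeleton, connectors)
    pairs = []
    for cl in clustering.clusters:
        n_in = sum(1 for nid in inputs if nid in cl["nodes"])
        n_out = sum(1 for nid in outputs if nid in cl["nodes"])
        if n_in + n_out:
            pairs.append((n_in + n_out, n_in / (n_in + n_out)))
    return segregation_index(pairs)


def cluster_condensed_graph(
    clustering: SynapseClustering, skeleton: Skeleton
) -> nx.Graph:
    """Graph of cluster peaks preserving the arbor's inter-cluster topology.

    One node per cluster; two clusters are adjacent iff the skeleton path
    between their peaks traverses no third cluster's peak.
    """
    peaks = [cl["peak"] for cl in clustering.clusters]
    g = nx.Graph()
    g.add_nodes_from(range(len(peaks)))
    peak_index = {p: i for i, p in enumerate(peaks)}
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            path = skeleton.path_between(peaks[i], peaks[j])
            interior = path[1:-1]
            if not any(p in peak_index for p in interior):
                g.add_edge(i, j)
    return g
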