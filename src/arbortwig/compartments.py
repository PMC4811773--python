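"""Backbone/twig arbor decomposition and twig-level statistics.

In *Drosophila* larval neurons the microtubule-containing core of an arbor
(the backbone) carries few postsynaptic sites; most input arrives on small
microtubule-free terminal branches ("twigs") that sprout from the backbone.
The boundary is annotated with a 'microtubules end' tag on the last
microtubule-containing node; everything strictly distal to that node is one
twig.  Short twigs without presynaptic sites are spine-like.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .skeleton import (
    Connector,
    Skeleton,
    SkeletonError,
    TagSet,
    cable_length,
    geodesic_distance,
    geodesic_matrix,
    subtree_nodes,
)

MT_END_TAG = "microtubules end"
SPINE_DEPTH_UM = 3.0
PROXIMITY_THRESHOLD_UM = 3.0


@dataclass
class TwigRecord:
    """One microtubule-free terminal branch.

    ``base`` is the backbone node carrying the boundary tag; ``members``
    are strictly distal to it.  ``cable`` includes the base-to-first-member
    edge (that cable is itself microtubule-free); ``max_depth`` is the
    largest cable distance from the base to any member.
    """

    base: int
    members: frozenset[int]
    cable_um: float = 0.0
    max_depth_um: float = 0.0
    inputs: int = 0
    outputs: int = 0
    is_spine: bool = False


@dataclass
class CompartmentLabels:
    """Partition of one skeleton's nodes into backbone and twigs."""

    skeleton_id: str
    twigs: list[TwigRecord]
    backbone: frozenset[int]

    def label(self, node_id: int) -> str:
        return "backbone" if node_id in self.backbone else "twig"

    @property
    def twig_nodes(self) -> set[int]:
        out: set[int] = set()
        for twig in self.twigs:
            out |= twig.members
        return out

    def twig_of(self, node_id: int) -> int | None:
        """Index of the twig containing ``node_id``, or None for backbone."""
        for i, twig in enumerate(self.twigs):
            if node_id in twig.members:
                return i
        return None


def split_backbone_twigs(skeleton: Skeleton, tags: TagSet) -> CompartmentLabels:
    """Decompose an arbor at its 'microtubules end' tags.

    Each tagged node that is not itself inside another tag's distal
    subtree spawns one twig made of its strict descendants; nested tags
    are ignored.  The tagged node stays backbone and records the twig
    base.  A tag at a leaf yields no twig (empty distal set); a tag at
    the root is an error since the whole arbor would become twig.
    """
    tagged = tags.nodes_with(MT_END_TAG)
    if skeleton.root in tagged:
        raise SkeletonError(
            "root tagged 'microtubules end': whole arbor would be a twig"
        )
    # Effective tags: drop those lying strictly inside another tag's subtree.
    tag_set = set(tagged)
    claimed: set[int] = set()
    twigs: list[TwigRecord] = []
    # Process in pre-order so outermost tags claim their subtree first.
    for nid in skeleton.topo_order():
        if nid not in tag_set or nid in claimed:
            continue
        members = subtree_nodes(skeleton, nid) - {nid}
        if not members:
            continue
        claimed |= members
        twigs.append(TwigRecord(base=nid, members=frozenset(members)))
    backbone = frozenset(set(skeleton.node_ids) - claimed)
    return CompartmentLabels(
        skeleton_id=skeleton.skeleton_id, twigs=twigs, backbone=backbone
    )


def _relations_on(
    connectors: list[Connector], skeleton_id: str
) -> tuple[list[int], list[int]]:
    """(postsynaptic relation nodes, presynaptic connector nodes) on one
    skeleton; presynaptic connectors count once each."""
    post_nodes: list[int] = []
    pre_nodes: list[int] = []
    for conn in connectors:
        if conn.presynaptic.skeleton_id == skeleton_id:
            pre_nodes.append(conn.presynaptic.node_id)
        for rel in conn.postsynaptic:
            if rel.skeleton_id == skeleton_id:
                post_nodes.append(rel.node_id)
    return post_nodes, pre_nodes


def twig_statistics(
    labels: CompartmentLabels,
    skeleton: Skeleton,
    connectors: list[Connector],
) -> list[TwigRecord]:
    """Fill per-twig cable, depth and synapse counts; updates ``labels``.

    Cable sums every edge whose child node is a twig member, which
    includes the base-to-first-member edge.  Depth is geodesic (cable)
    distance from the base, never Euclidean.
    """
    post_nodes, pre_nodes = _relations_on(connectors, labels.skeleton_id)
    out: list[TwigRecord] = []
    for twig in labels.twigs:
        members = sorted(twig.members)
        cable = cable_length(skeleton, members)
        depths = geodesic_matrix(skeleton, [twig.base], members)[0]
        rec = replace(
            twig,
            cable_um=cable,
            max_depth_um=float(depths.max()) if members else 0.0,
            inputs=sum(1 for n in post_nodes if n in twig.members),
            outputs=sum(1 for n in pre_nodes if n in twig.members),
        )
        out.append(rec)
    labels.twigs = out
    return out


def classify_spines(
    twigs: list[TwigRecord], spine_depth_um: float = SPINE_DEPTH_UM
) -> list[TwigRecord]:
    """Flag spine-like twigs: max depth < 3 µm and no presynaptic site."""
    out = []
    for twig in twigs:
        out.append(
            replace(
                twig,
                is_spine=(twig.max_depth_um < spine_depth_um)
                and twig.outputs == 0,
            )
        )
    return out


def compartment_input_fractions(
    labels: CompartmentLabels, connectors: list[Connector]
) -> dict[str, float]:
    """Fractions of postsynaptic sites on spine twigs, other twigs, backbone.

    The three fractions sum to one; a skeleton with zero postsynaptic
    relations has no defined fractions and raises.
    """
    post_nodes, _ = _relations_on(connectors, labels.skeleton_id)
    if not post_nodes:
        raise SkeletonError(
            f"skeleton {labels.skeleton_id!r} has no postsynaptic relations"
        )
    spine_nodes: set[int] = set()
    other_twig_nodes: set[int] = set()
    for twig in labels.twigs:
        (spine_nodes if twig.is_spine else other_twig_nodes).update(twig.members)
    n = len(post_nodes)
    n_spine = sum(1 for nid in post_nodes if nid in spine_nodes)
    n_other = sum(1 for nid in post_nodes if nid in other_twig_nodes)
    return {
        "spine_twigs": n_spine / n,
        "other_twigs": n_other / n,
        "backbone": (n - n_spine - n_other) / n,
    }


def crop_twigs(
    skeleton: Skeleton,
    labels: CompartmentLabels,
    connectors: list[Connector],
    depth_um: float,
) -> tuple[list[tuple[Connector, str, int]], set[int]]:
    """Retain synapse relations up to a given cable depth into each twig.

    Backbone relations are always retained; a twig relation at node u
    survives iff the geodesic distance from the twig base to u is at most
    ``depth_um``.  Depth 0 therefore keeps exactly the backbone synapse
    set, emulating a backbone-only reconstruction.  Returns the retained
    relations as (connector, 'pre'|'post', node) plus the retained node
    set.
    """
    if depth_um < 0:
        raise ValueError("crop depth must be non-negative")
    node_depth: dict[int, float] = {}
    kept_nodes = set(labels.backbone)
    for twig in labels.twigs:
        members = sorted(twig.members)
        depths = geodesic_matrix(skeleton, [twig.base], members)[0]
        for nid, d in zip(members, depths):
            node_depth[nid] = d
            if d <= depth_um:
                kept_nodes.add(nid)
    retained: list[tuple[Connector, str, int]] = []
    sid = labels.skeleton_id
    for conn in connectors:
        if (
            conn.presynaptic.skeleton_id == sid
            and conn.presynaptic.node_id in kept_nodes
        ):
            retained.append((conn, "pre", conn.presynaptic.node_id))
        for rel in conn.postsynaptic:
            if rel.skeleton_id == sid and rel.node_id in kept_nodes:
                retained.append((conn, "post", rel.node_id))
    return retained, kept_nodes


def proximity_to_landmarks(
    skeleton: Skeleton,
    sites: list[int],
    landmarks: set[int],
    threshold_um: float = PROXIMITY_THRESHOLD_UM,
) -> tuple[list[float], float]:
    """Geodesic distance from each site to its nearest landmark.

    Used e.g. for presynaptic-site-to-mitochondrion or twig-synapse-to-
    backbone distances along the arbor.  Returns per-site distances (µm)
    and the fraction of sites within ``threshold_um``.
    """
    if not landmarks:
        raise SkeletonError("empty landmark set")
    if not sites:
        return [], float("nan")
    dmat = geodesic_matrix(skeleton, sites, sorted(landmarks))
    dists = dmat.min(axis=1)
    frac = float((dists <= threshold_um).mean())
    return [float(d) for d in dists], frac
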