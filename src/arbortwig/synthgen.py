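"""Seeded generators of synthetic arbors, circuits and error-prone
reconstructions.

The generators emulate the empirical regularities of first-instar larval
neurons: a microtubule-containing backbone decorated with short
microtubule-free twigs (exponential depth, median ~1 µm, truncated at
16 µm) that host ~80% of postsynaptic sites; presynaptic sites mostly
within 3 µm of backbone; mitochondria near presynaptic sites; circuits
with planted synapse-count/twig-span structure; and simulated annotators
that miss twigs, truncate them, and add false branches.  Every generator
is a pure function of its parameters and seed, and returns the planted
ground truth alongside the data so downstream estimators can be checked
against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .compartments import CompartmentLabels, split_backbone_twigs
from .skeleton import (
    Connector,
    PartnerRelation,
    Reconstruction,
    Skeleton,
    SkeletonError,
    SkeletonNode,
    TagSet,
)

NM = 1.0
UM = 1000.0


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic-neuron generator (defaults = study regime)."""

    backbone_cable_um: float = 150.0
    backbone_branch_rate_per_um: float = 0.02
    twig_rate_per_um: float = 0.6
    twig_depth_median_um: float = 1.0
    twig_depth_max_um: float = 16.0
    twig_depth_min_um: float = 0.2
    twig_branch_prob: float = 0.25
    node_spacing_nm: float = 300.0
    n_inputs: int = 200
    n_outputs: int = 60
    twig_input_fraction: float = 0.8
    presyn_near_backbone_fraction: float = 0.9
    mito_near_presyn_fraction: float = 0.97
    posts_per_output: int = 2

    def validate(self) -> None:
        if self.backbone_cable_um <= 0 and self.twig_rate_per_um > 0:
            raise SkeletonError("twigs require nonzero backbone cable")
        for frac in (
            self.twig_input_fraction,
            self.presyn_near_backbone_fraction,
            self.mito_near_presyn_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise SkeletonError(f"fraction out of [0,1]: {frac}")
        if min(
            self.backbone_branch_rate_per_um,
            self.twig_rate_per_um,
            self.node_spacing_nm,
        ) < 0:
            raise SkeletonError("rates and spacing must be non-negative")


@dataclass
class PlantedTwig:
    base: int
    members: set[int]
    depth_um: float


@dataclass
class NeuronTruth:
    """Ground truth planted by :func:`generate_neuron`."""

    skeleton_id: str
    backbone_nodes: set[int]
    twigs: list[PlantedTwig]
    input_nodes: list[int]
    output_nodes: list[int]
    mito_nodes: list[int]
    twig_input_count: int


class _Builder:
    """Incremental skeleton builder with fresh node ids."""

    def __init__(self, skeleton_id: str, root_pos: np.ndarray):
        self.skeleton_id = skeleton_id
        self.nodes: list[SkeletonNode] = [
            SkeletonNode(node_id=1, parent_id=None, position=tuple(root_pos))
        ]
        self.pos: dict[int, np.ndarray] = {1: root_pos}
        self._next = 2

    def add(self, parent: int, position: np.ndarray) -> int:
        nid = self._next
        self._next += 1
        self.nodes.append(
            SkeletonNode(nid, parent_id=parent, position=tuple(position))
        )
        self.pos[nid] = position
        return nid

    def chain(
        self,
        parent: int,
        direction: np.ndarray,
        cable_um: float,
        spacing_nm: float,
    ) -> list[int]:
        """Straight chain of total length exactly ``cable_um``."""
        total_nm = cable_um * UM
        n_full = int(total_nm // spacing_nm)
        lengths = [spacing_nm] * n_full
        rem = total_nm - n_full * spacing_nm
        if rem > 1e-9 or not lengths:
            lengths.append(rem if rem > 1e-9 else total_nm)
        out = []
        cur = parent
        p = self.pos[parent].copy()
        for step in lengths:
            p = p + direction * step
            cur = self.add(cur, p)
            out.append(cur)
        return out

    def build(self) -> Skeleton:
        return Skeleton(self.skeleton_id, self.nodes)


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _truncated_exp(
    rng: np.random.Generator, median_um: float, max_um: float, min_um: float
) -> float:
    scale = median_um / math.log(2.0)
    while True:
        d = rng.exponential(scale)
        if min_um <= d <= max_um:
            return d


def generate_neuron(
    params: SynthParams, seed: int, skeleton_id: str = "n1"
) -> tuple[Reconstruction, NeuronTruth]:
    """Generate one twig-bearing arbor with synapses and tags.

    The skeleton's root is tagged 'soma'; each twig hangs below a
    'microtubules end'-tagged base node whose only descendants are the
    twig members, so the backbone/twig decomposition is recoverable
    exactly.  Synaptic partners are single-node placeholder skeletons,
    one per connector, mirroring how partner sites are seeded during
    reconstruction.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    b = _Builder(skeleton_id, np.zeros(3))
    spacing = params.node_spacing_nm
    backbone_nodes: set[int] = {1}

    # grow backbone as a branching set of straight-ish segments
    tips = [(1, _unit(rng))]
    cable_left_um = params.backbone_cable_um
    step_um = spacing / UM
    while cable_left_um > 1e-9 and tips:
        idx = int(rng.integers(len(tips)))
        nid, direction = tips[idx]
        direction = direction + rng.normal(scale=0.15, size=3)
        direction /= np.linalg.norm(direction)
        step = min(step_um, cable_left_um)
        new = b.add(nid, b.pos[nid] + direction * step * UM)
        backbone_nodes.add(new)
        cable_left_um -= step
        tips[idx] = (new, direction)
        if rng.random() < params.backbone_branch_rate_per_um * step:
            tips.append((new, _unit(rng)))

    # plant twigs on interior backbone nodes
    candidates = sorted(backbone_nodes - {1})
    n_twigs = rng.poisson(params.twig_rate_per_um * params.backbone_cable_um)
    n_twigs = min(n_twigs, len(candidates))
    twig_attach = rng.choice(candidates, size=n_twigs, replace=False)
    twigs: list[PlantedTwig] = []
    tags = TagSet()
    tags.add(1, "soma")
    for attach in sorted(int(a) for a in twig_attach):
        depth = _truncated_exp(
            rng,
            params.twig_depth_median_um,
            params.twig_depth_max_um,
            params.twig_depth_min_um,
        )
        direction = _unit(rng)
        # base: a short microtubule stub off the backbone, then the twig
        base = b.add(attach, b.pos[attach] + direction * min(spacing, 150.0))
        backbone_nodes.add(base)
        tags.add(base, "microtubules end")
        members = b.chain(base, direction, depth, spacing)
        if len(members) > 2 and rng.random() < params.twig_branch_prob:
            mid_idx = len(members) // 2
            mid = members[mid_idx]
            # side branch stays strictly shallower than the main chain tip
            mid_depth = min((mid_idx + 1) * spacing / UM, depth)
            side_len = (depth - mid_depth) * rng.uniform(0.2, 0.7)
            if side_len > 0.1:
                members = members + b.chain(mid, _unit(rng), side_len, spacing)
        twigs.append(
            PlantedTwig(base=base, members=set(members), depth_um=depth)
        )

    skel = b.build()
    twig_pool = sorted(set().union(*(t.members for t in twigs))) if twigs else []
    backbone_pool = sorted(backbone_nodes)

    recon = Reconstruction(skeletons={skeleton_id: skel})
    recon.tags[skeleton_id] = tags

    def _placeholder(prefix: str, i: int, pos: np.ndarray) -> str:
        pid = f"{prefix}{i}"
        recon.skeletons[pid] = Skeleton(
            pid, [SkeletonNode(1, None, tuple(pos))]
        )
        return pid

    # postsynaptic sites (inputs)
    input_nodes: list[int] = []
    twig_inputs = 0
    for i in range(params.n_inputs):
        on_twig = bool(twig_pool) and rng.random() < params.twig_input_fraction
        pool = twig_pool if on_twig else backbone_pool
        nid = int(pool[rng.integers(len(pool))])
        input_nodes.append(nid)
        twig_inputs += int(on_twig)
        pos = b.pos[nid] + rng.normal(scale=50.0, size=3)
        partner = _placeholder("pre_ph", i, pos)
        recon.connectors.append(
            Connector(
                connector_id=f"cin{i}",
                position=tuple(pos),
                presynaptic=PartnerRelation(partner, 1),
                postsynaptic=(PartnerRelation(skeleton_id, nid),),
            )
        )

    # presynaptic sites (outputs)
    deep_twig_pool = [
        n
        for t in twigs
        if t.depth_um > 3.5
        for n in sorted(t.members)
    ]
    output_nodes: list[int] = []
    for i in range(params.n_outputs):
        near = rng.random() < params.presyn_near_backbone_fraction
        if near or not deep_twig_pool:
            nid = int(backbone_pool[rng.integers(len(backbone_pool))])
        else:
            nid = int(deep_twig_pool[rng.integers(len(deep_twig_pool))])
        output_nodes.append(nid)
        pos = b.pos[nid] + rng.normal(scale=50.0, size=3)
        posts = tuple(
            PartnerRelation(_placeholder(f"post_ph{i}_", j, pos), 1)
            for j in range(params.posts_per_output)
        )
        recon.connectors.append(
            Connector(
                connector_id=f"cout{i}",
                position=tuple(pos),
                presynaptic=PartnerRelation(skeleton_id, nid),
                postsynaptic=posts,
            )
        )

    # mitochondria near presynaptic sites
    mito_nodes = []
    for nid in output_nodes:
        if rng.random() < params.mito_near_presyn_fraction:
            tags.add(nid, "mitochondrion")
            mito_nodes.append(nid)

    truth = NeuronTruth(
        skeleton_id=skeleton_id,
        backbone_nodes=backbone_nodes,
        twigs=twigs,
        input_nodes=input_nodes,
        output_nodes=output_nodes,
        mito_nodes=mito_nodes,
        twig_input_count=twig_inputs,
    )
    return recon, truth


# ---------------------------------------------------------------------------
# Textbook (fully polarized) neuron
# ---------------------------------------------------------------------------


@dataclass
class TextbookTruth:
    split_node: int
    axon_nodes: set[int]
    linker_cable_um: float


def generate_textbook_neuron(
    linker_um: float = 10.0,
    n_inputs: int = 20,
    n_outputs: int = 12,
    spacing_nm: float = 500.0,
    seed: int = 0,
    skeleton_id: str = "textbook",
) -> tuple[Reconstruction, TextbookTruth]:
    """Fully polarized arbor: input-only dendrite, bare linker, output-only
    axon.

    The linker is planted with exactly ``linker_um`` of cable attaining
    the maximal centrifugal flow, so the axon/dendrite split point, axon
    node set and linker cable are all known in advance (and H = 1).
    """
    rng = np.random.default_rng(seed)
    b = _Builder(skeleton_id, np.zeros(3))
    tags = TagSet()
    tags.add(1, "soma")
    # dendrite: a Y below the root
    trunk = b.chain(1, np.array([1.0, 0, 0]), 5.0, spacing_nm)
    d_branch = trunk[-1]
    leg1 = b.chain(d_branch, np.array([0.6, 1.0, 0]) / np.linalg.norm([0.6, 1.0, 0]), 8.0, spacing_nm)
    leg2 = b.chain(d_branch, np.array([0.6, -1.0, 0]) / np.linalg.norm([0.6, -1.0, 0]), 8.0, spacing_nm)
    dendrite_sites = leg1 + leg2
    # linker: n_seg equal edges totalling linker_um, ending at the axon root
    n_seg = max(2, int(round(linker_um * UM / spacing_nm)))
    seg = linker_um / n_seg
    cur = d_branch
    linker_nodes = []
    direction = np.array([1.0, 0, 0])
    for _ in range(n_seg):
        cur = b.add(cur, b.pos[cur] + direction * seg * UM)
        linker_nodes.append(cur)
    axon_root = linker_nodes[-1]  # carries the first output; a branch point
    a_leg1 = b.chain(axon_root, np.array([1.0, 0.8, 0]) / np.linalg.norm([1.0, 0.8, 0]), 6.0, spacing_nm)
    a_leg2 = b.chain(axon_root, np.array([1.0, -0.8, 0]) / np.linalg.norm([1.0, -0.8, 0]), 6.0, spacing_nm)

    skel = b.build()
    recon = Reconstruction(skeletons={skeleton_id: skel})
    recon.tags[skeleton_id] = tags

    def _placeholder(prefix: str, i: int, pos) -> str:
        pid = f"{prefix}{i}"
        recon.skeletons[pid] = Skeleton(pid, [SkeletonNode(1, None, tuple(pos))])
        return pid

    for i in range(n_inputs):
        nid = dendrite_sites[int(rng.integers(len(dendrite_sites)))]
        pos = b.pos[nid]
        recon.connectors.append(
            Connector(
                f"tin{i}",
                tuple(pos),
                presynaptic=PartnerRelation(_placeholder("tpre", i, pos), 1),
                postsynaptic=(PartnerRelation(skeleton_id, nid),),
            )
        )
    # one output pinned at the axon root, the rest split over both legs
    out_sites = [axon_root] + [
        (a_leg1 + a_leg2)[int(rng.integers(len(a_leg1) + len(a_leg2)))]
        for _ in range(n_outputs - 1)
    ]
    # ensure outputs land on both legs so no single child subtree holds all
    out_sites[1] = a_leg1[0]
    out_sites[2 % len(out_sites)] = a_leg2[0]
    for i, nid in enumerate(out_sites):
        pos = b.pos[nid]
        recon.connectors.append(
            Connector(
                f"tout{i}",
                tuple(pos),
                presynaptic=PartnerRelation(skeleton_id, nid),
                postsynaptic=(PartnerRelation(_placeholder("tpost", i, pos), 1),),
            )
        )
    axon_set = set(linker_nodes) | set(a_leg1) | set(a_leg2)
    truth = TextbookTruth(
        split_node=linker_nodes[0],
        axon_nodes=axon_set,
        linker_cable_um=linker_um,
    )
    return recon, truth


# ---------------------------------------------------------------------------
# Homolog pairs
# ---------------------------------------------------------------------------


def generate_homolog_pair(
    params: SynthParams, jitter_um: float, seed: int
) -> tuple[
    tuple[Reconstruction, NeuronTruth], tuple[Reconstruction, NeuronTruth]
]:
    """A neuron and its mirror-image homolog with positional jitter.

    The homolog shares the original's topology (mirrored across x = 0)
    with node positions displaced by a smooth random deformation field of
    amplitude ``jitter_um`` (a sum of low-frequency sinusoids, so nearby
    nodes move together and local cable is nearly preserved) and synapse
    placement re-drawn under the same parameters, emulating developmental
    variability between hemisegmental homologs.  Zero jitter yields
    mirror-identical cable.
    """
    if jitter_um < 0:
        raise SkeletonError("jitter must be non-negative")
    left, truth_l = generate_neuron(params, seed, skeleton_id="left")
    rng = np.random.default_rng(seed + 1)
    # smooth deformation: 3 random plane waves, wavelength ~20 µm
    n_waves = 3
    amps = rng.normal(size=(n_waves, 3))
    amps *= jitter_um * UM / (np.linalg.norm(amps, axis=1, keepdims=True) * math.sqrt(n_waves))
    kvecs = rng.normal(size=(n_waves, 3))
    kvecs *= (2 * np.pi / (20.0 * UM)) / np.linalg.norm(kvecs, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)

    def displace(pos: np.ndarray) -> np.ndarray:
        if jitter_um == 0:
            return pos
        wiggle = sum(
            a * math.sin(float(k @ pos) + ph)
            for a, k, ph in zip(amps, kvecs, phases)
        )
        return pos + wiggle

    lskel = left.skeletons["left"]
    mirrored_nodes = []
    for nid in lskel.topo_order():
        node = lskel.node(nid)
        x, y, z = node.position
        pos = displace(np.array([-x, y, z]))
        mirrored_nodes.append(replace(node, position=tuple(pos)))
    rskel = Skeleton("right", mirrored_nodes)
    right = Reconstruction(skeletons={"right": rskel})
    rtags = TagSet()
    for nid, labels in left.tags["left"].items():
        for lab in labels:
            if lab in ("soma", "microtubules end"):
                rtags.add(nid, lab)
    right.tags["right"] = rtags
    truth_r = NeuronTruth(
        skeleton_id="right",
        backbone_nodes=set(truth_l.backbone_nodes),
        twigs=[
            PlantedTwig(t.base, set(t.members), t.depth_um)
            for t in truth_l.twigs
        ],
        input_nodes=[],
        output_nodes=[],
        mito_nodes=[],
        twig_input_count=0,
    )
    _replace_synapses(right, truth_r, params, rng)
    return (left, truth_l), (right, truth_r)


def _replace_synapses(
    recon: Reconstruction,
    truth: NeuronTruth,
    params: SynthParams,
    rng: np.random.Generator,
) -> None:
    sid = truth.skeleton_id
    skel = recon.skeletons[sid]
    twig_pool = (
        sorted(set().union(*(t.members for t in truth.twigs)))
        if truth.twigs
        else []
    )
    backbone_pool = sorted(truth.backbone_nodes)
    for i in range(params.n_inputs):
        on_twig = bool(twig_pool) and rng.random() < params.twig_input_fraction
        pool = twig_pool if on_twig else backbone_pool
        nid = int(pool[rng.integers(len(pool))])
        truth.input_nodes.append(nid)
        truth.twig_input_count += int(on_twig)
        pos = skel.position(nid)
        pid = f"{sid}_pre_ph{i}"
        recon.skeletons[pid] = Skeleton(pid, [SkeletonNode(1, None, tuple(pos))])
        recon.connectors.append(
            Connector(
                f"{sid}_cin{i}",
                tuple(pos),
                presynaptic=PartnerRelation(pid, 1),
                postsynaptic=(PartnerRelation(sid, nid),),
            )
        )
    for i in range(params.n_outputs):
        nid = int(backbone_pool[rng.integers(len(backbone_pool))])
        truth.output_nodes.append(nid)
        pos = skel.position(nid)
        pid = f"{sid}_post_ph{i}"
        recon.skeletons[pid] = Skeleton(pid, [SkeletonNode(1, None, tuple(pos))])
        recon.connectors.append(
            Connector(
                f"{sid}_cout{i}",
                tuple(pos),
                presynaptic=PartnerRelation(sid, nid),
                postsynaptic=(PartnerRelation(pid, 1),),
            )
        )


# ---------------------------------------------------------------------------
# Circuits with planted connectivity
# ---------------------------------------------------------------------------


@dataclass
class PlantedEdge:
    pre: str
    post: str
    m: int
    n_b: int


@dataclass
class CircuitPlan:
    """Roster of neurons plus planted edges (synapse count, twig span)."""

    neurons: list[str]
    edges: list[PlantedEdge]

    @staticmethod
    def sample_spans(
        neurons: list[str],
        edge_specs: list[tuple[str, str, int]],
        span_dist: dict[int, dict[int, float]],
        seed: int,
    ) -> "CircuitPlan":
        """Draw each edge's n_b from a twig-span distribution p(n_b; m)."""
        rng = np.random.default_rng(seed)
        edges = []
        for pre, post, m in edge_specs:
            pmf = span_dist[m]
            nbs = sorted(pmf)
            probs = np.array([pmf[k] for k in nbs], dtype=float)
            n_b = int(rng.choice(nbs, p=probs / probs.sum()))
            edges.append(PlantedEdge(pre, post, m, n_b))
        return CircuitPlan(neurons=neurons, edges=edges)


@dataclass
class CircuitTruth:
    neuron_truths: dict[str, NeuronTruth]
    labels: dict[str, CompartmentLabels]
    edges: list[PlantedEdge]
    edge_twig_indices: dict[tuple[str, str], list[int]]


def generate_circuit(
    plan: CircuitPlan, params: SynthParams, seed: int
) -> tuple[Reconstruction, CircuitTruth]:
    """Realize a circuit plan as skeletons plus connectors.

    Each planted edge (pre, post, m, n_b) is realized as m monadic
    connectors from a backbone node of the source onto the target: all m
    land on exactly n_b distinct twigs (each receiving at least one), or
    all on backbone when n_b = 0.  Wiring-graph weights and per-edge twig
    spans recovered from the output therefore equal the plan exactly.
    """
    rng = np.random.default_rng(seed)
    recon = Reconstruction()
    truths: dict[str, NeuronTruth] = {}
    labels: dict[str, CompartmentLabels] = {}
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(plan.neurons))
    quiet = replace(params, n_inputs=0, n_outputs=0)
    for name, s in zip(plan.neurons, sub_seeds):
        sub, truth = generate_neuron(quiet, int(s), skeleton_id=name)
        recon.skeletons.update(sub.skeletons)
        recon.connectors.extend(sub.connectors)
        recon.tags.update(sub.tags)
        truths[name] = truth
        labels[name] = split_backbone_twigs(
            sub.skeletons[name], sub.tags[name]
        )
    edge_twig_indices: dict[tuple[str, str], list[int]] = {}
    cid = 0
    for edge in plan.edges:
        if edge.n_b > edge.m:
            raise SkeletonError(f"infeasible edge: n_b {edge.n_b} > m {edge.m}")
        post_truth = truths[edge.post]
        usable = [t for t in post_truth.twigs if t.members]
        if edge.n_b > len(usable):
            raise SkeletonError(
                f"infeasible edge {edge.pre}->{edge.post}: wants "
                f"{edge.n_b} twigs, target has {len(usable)}"
            )
        pre_pool = sorted(truths[edge.pre].backbone_nodes)
        post_backbone = sorted(post_truth.backbone_nodes)
        if edge.n_b == 0:
            target_nodes = [
                int(post_backbone[rng.integers(len(post_backbone))])
                for _ in range(edge.m)
            ]
            edge_twig_indices[(edge.pre, edge.post)] = []
        else:
            chosen = rng.choice(len(usable), size=edge.n_b, replace=False)
            edge_twig_indices[(edge.pre, edge.post)] = sorted(
                int(c) for c in chosen
            )
            slots = list(chosen) + [
                chosen[rng.integers(len(chosen))]
                for _ in range(edge.m - edge.n_b)
            ]
            target_nodes = []
            for t_idx in slots:
                members = sorted(usable[int(t_idx)].members)
                target_nodes.append(int(members[rng.integers(len(members))]))
        for nid in target_nodes:
            pre_node = int(pre_pool[rng.integers(len(pre_pool))])
            pos = recon.skeletons[edge.pre].position(pre_node)
            recon.connectors.append(
                Connector(
                    f"ce{cid}",
                    tuple(pos),
                    presynaptic=PartnerRelation(edge.pre, pre_node),
                    postsynaptic=(PartnerRelation(edge.post, nid),),
                )
            )
            cid += 1
    return recon, CircuitTruth(
        neuron_truths=truths,
        labels=labels,
        edges=list(plan.edges),
        edge_twig_indices=edge_twig_indices,
    )


# ---------------------------------------------------------------------------
# Error-prone annotator simulation
# ---------------------------------------------------------------------------


@dataclass
class CorruptionTruth:
    deleted_twigs: dict[str, list[int]]  # skeleton -> planted twig indices
    truncated_twigs: dict[str, list[int]]
    false_branches: dict[str, int]
    kept_twigs: dict[str, list[int]]


def corrupt_reconstruction(
    gold: Reconstruction,
    truths: dict[str, NeuronTruth],
    q: float,
    truncate_frac: float = 0.0,
    r: float = 0.0,
    k_bar: float = 0.0,
    seed: int = 0,
) -> tuple[Reconstruction, CorruptionTruth]:
    """Simulate an error-prone annotator over a gold reconstruction.

    Each twig survives independently with probability ``q`` (false
    negatives); surviving twigs are truncated to a random fraction of
    their depth with probability ``truncate_frac``; false branches are
    added at rate ``r`` per µm of twig cable, each a short neurite stub
    carrying Poisson(``k_bar``) spurious postsynaptic relations (false
    positives).  Connector relations onto removed nodes are dropped.
    Node ids and positions of retained structure are unchanged, so
    gold-vs-test matching recovers the planted deletions exactly.
    """
    if not 0.0 <= q <= 1.0:
        raise SkeletonError(f"twig recall q out of [0,1]: {q}")
    rng = np.random.default_rng(seed)
    removed: dict[str, set[int]] = {}
    ct = CorruptionTruth({}, {}, {}, {})
    new_skeletons: dict[str, Skeleton] = {}
    new_tags: dict[str, TagSet] = {}
    spur_connectors: list[Connector] = []
    spur_id = 0
    for sid, skel in gold.skeletons.items():
        truth = truths.get(sid)
        if truth is None:  # placeholder partner skeletons pass through
            new_skeletons[sid] = skel
            if sid in gold.tags:
                new_tags[sid] = gold.tags[sid]
            continue
        gone: set[int] = set()
        ct.deleted_twigs[sid] = []
        ct.truncated_twigs[sid] = []
        ct.kept_twigs[sid] = []
        for ti, twig in enumerate(truth.twigs):
            if rng.random() > q:
                gone |= twig.members
                ct.deleted_twigs[sid].append(ti)
                continue
            ct.kept_twigs[sid].append(ti)
            if truncate_frac and rng.random() < truncate_frac:
                keep_depth = twig.depth_um * rng.uniform(0.3, 0.9)
                from .skeleton import geodesic_matrix

                members = sorted(twig.members)
                depths = geodesic_matrix(skel, [twig.base], members)[0]
                cut = {
                    n for n, d in zip(members, depths) if d > keep_depth
                }
                # removal must stay a full distal subtree: drop descendants
                cut = {
                    n
                    for n in twig.members
                    if any(a in cut for a in _ancestors_within(skel, n, twig.members))
                    or n in cut
                }
                if cut:
                    gone |= cut
                    ct.truncated_twigs[sid].append(ti)
        removed[sid] = gone
        kept_nodes = [
            skel.node(n) for n in skel.topo_order() if n not in gone
        ]
        new_skel = Skeleton(sid, kept_nodes)
        # false branches on surviving twig cable
        twig_cable = sum(
            t.depth_um
            for ti, t in enumerate(truth.twigs)
            if ti in ct.kept_twigs[sid]
        )
        n_false = int(rng.poisson(r * twig_cable)) if r > 0 else 0
        ct.false_branches[sid] = n_false
        if n_false:
            surviving_twig_nodes = sorted(
                set().union(
                    *(
                        truth.twigs[ti].members
                        for ti in ct.kept_twigs[sid]
                    )
                )
                - gone
            ) or sorted(set(new_skel.node_ids))
            builder_nodes = list(kept_nodes)
            next_id = max(skel.node_ids) + 1
            other_skels = [s for s in truths if s != sid] or [sid]
            for _ in range(n_false):
                attach = int(
                    surviving_twig_nodes[
                        rng.integers(len(surviving_twig_nodes))
                    ]
                )
                direction = _unit(rng)
                n_steps = 4
                prev = attach
                prev_pos = np.asarray(skel.node(attach).position)
                branch_ids = []
                for k in range(n_steps):
                    # step well beyond the 600 nm match radius
                    prev_pos = prev_pos + direction * 800.0
                    builder_nodes.append(
                        SkeletonNode(next_id, prev, tuple(prev_pos))
                    )
                    branch_ids.append(next_id)
                    prev = next_id
                    next_id += 1
                for k in range(int(rng.poisson(k_bar))):
                    node = branch_ids[int(rng.integers(len(branch_ids)))]
                    src = other_skels[int(rng.integers(len(other_skels)))]
                    src_pool = sorted(truths[src].backbone_nodes)
                    src_node = int(src_pool[rng.integers(len(src_pool))])
                    pos = builder_nodes[-1].position
                    spur_connectors.append(
                        Connector(
                            f"spur{spur_id}",
                            pos,
                            presynaptic=PartnerRelation(src, src_node),
                            postsynaptic=(PartnerRelation(sid, node),),
                        )
                    )
                    spur_id += 1
            new_skel = Skeleton(sid, builder_nodes)
        new_skeletons[sid] = new_skel
        if sid in gold.tags:
            ts = TagSet()
            for nid, labels_ in gold.tags[sid].items():
                if nid not in gone:
                    for lab in labels_:
                        ts.add(nid, lab)
            new_tags[sid] = ts
    # drop connector relations that touch removed nodes
    new_connectors: list[Connector] = []
    for conn in gold.connectors:
        pre = conn.presynaptic
        if pre.skeleton_id in removed and pre.node_id in removed[pre.skeleton_id]:
            continue
        posts = tuple(
            rel
            for rel in conn.postsynaptic
            if not (
                rel.skeleton_id in removed
                and rel.node_id in removed[rel.skeleton_id]
            )
        )
        new_connectors.append(replace(conn, postsynaptic=posts))
    new_connectors.extend(spur_connectors)
    test = Reconstruction(
        skeletons=new_skeletons, connectors=new_connectors, tags=new_tags
    )
    return test, ct


def _ancestors_within(
    skeleton: Skeleton, node: int, pool: set[int]
) -> list[int]:
    out = []
    nid = skeleton.parent(node)
    while nid is not None and nid in pool:
        out.append(nid)
        nid = skeleton.parent(nid)
    return out
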