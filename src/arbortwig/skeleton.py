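"""Skeleton data model, SWC and sidecar I/O, and tree geometry primitives.

A skeleton is a rooted tree of spatially embedded nodes, the standard unit
of manual EM reconstruction.  Internally all coordinates and edge lengths
are stored in nanometres; every public function that reports a length does
so in micrometres, matching how arbor statistics are conventionally quoted.

Synapses are polyadic *connectors*: a point object with exactly one
presynaptic relation and any number of postsynaptic relations, each
carrying a 1-5 confidence score.  Biological compartment identity (soma,
microtubule boundaries, mitochondria, finished ends) is expressed through
free-text node tags, not through the SWC type column.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

NM_PER_UM = 1000.0

RECOGNIZED_TAGS = frozenset(
    {
        "soma",
        "microtubules end",
        "ends",
        "not a branch",
        "uncertain end",
        "uncertain continuation",
        "mitochondrion",
        "TODO",
    }
)


class SkeletonError(ValueError):
    """Raised for malformed skeletons, connectors or sidecar documents."""


@dataclass(frozen=True)
class SkeletonNode:
    """A single sample point of a neuronal arbor.

    ``parent_id is None`` marks the root.  ``confidence`` expresses the
    annotator's certainty in the edge toward the parent (5 = default and
    highest).  ``radius`` is in nm, or None when unmeasured.
    """

    node_id: int
    parent_id: int | None
    position: tuple[float, float, float]
    radius: float | None = None
    confidence: int = 5
    swc_type: int = 0
    author: str | None = None
    created_at: float | None = None
    reviewed_at: float | None = None

    def __post_init__(self) -> None:
        if self.node_id <= 0:
            raise SkeletonError(f"node_id must be positive, got {self.node_id}")
        if self.confidence not in (1, 2, 3, 4, 5):
            raise SkeletonError(
                f"confidence must be in 1..5, got {self.confidence}"
            )


@dataclass(frozen=True)
class PartnerRelation:
    """One side of a synapse: a (skeleton, node) pair with confidence."""

    skeleton_id: str
    node_id: int
    confidence: int = 5


@dataclass(frozen=True)
class Connector:
    """Polyadic synapse: one presynaptic relation, >= 0 postsynaptic ones."""

    connector_id: str
    position: tuple[float, float, float]
    presynaptic: PartnerRelation
    postsynaptic: tuple[PartnerRelation, ...] = ()


class Skeleton:
    """Rooted tree of :class:`SkeletonNode` with cached geometry.

    Construction validates the tree invariants: unique node ids, exactly
    one root, all parent references resolvable, and no cycles.
    """

    def __init__(self, skeleton_id: str, nodes: Iterable[SkeletonNode]):
        self.skeleton_id = str(skeleton_id)
        self._nodes: dict[int, SkeletonNode] = {}
        roots = []
        for node in nodes:
            if node.node_id in self._nodes:
                raise SkeletonError(f"duplicate node id {node.node_id}")
            self._nodes[node.node_id] = node
            if node.parent_id is None:
                roots.append(node.node_id)
        if len(roots) != 1:
            raise SkeletonError(
                f"skeleton {skeleton_id!r} has {len(roots)} roots, expected 1"
            )
        self.root: int = roots[0]
        self._children: dict[int, list[int]] = {nid: [] for nid in self._nodes}
        for node in self._nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self._nodes:
                    raise SkeletonError(
                        f"node {node.node_id} references missing parent "
                        f"{node.parent_id}"
                    )
                self._children[node.parent_id].append(node.node_id)
        for kids in self._children.values():
            kids.sort()
        self._check_acyclic_connected()
        self._depth_nm: dict[int, float] | None = None
        self._level: dict[int, int] | None = None

    # -- basic container protocol ------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._nodes

    def __iter__(self) -> Iterator[int]:
        return iter(self._nodes)

    def node(self, node_id: int) -> SkeletonNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise SkeletonError(
                f"node {node_id} not in skeleton {self.skeleton_id!r}"
            ) from None

    @property
    def node_ids(self) -> list[int]:
        return list(self._nodes)

    def parent(self, node_id: int) -> int | None:
        return self.node(node_id).parent_id

    def children(self, node_id: int) -> list[int]:
        self.node(node_id)
        return list(self._children[node_id])

    def neighbors(self, node_id: int) -> list[int]:
        out = self.children(node_id)
        p = self.parent(node_id)
        if p is not None:
            out.append(p)
        return out

    def leaves(self) -> list[int]:
        return [nid for nid in self._nodes if not self._children[nid]]

    def branch_points(self) -> list[int]:
        return [nid for nid in self._nodes if len(self._children[nid]) > 1]

    def position(self, node_id: int) -> np.ndarray:
        return np.asarray(self.node(node_id).position, dtype=float)

    def positions(self, node_ids: Sequence[int] | None = None) -> np.ndarray:
        ids = self.node_ids if node_ids is None else list(node_ids)
        return np.array([self.node(n).position for n in ids], dtype=float)

    # -- topology ----------------------------------------------------------

    def _check_acyclic_connected(self) -> None:
        seen = {self.root}
        stack = [self.root]
        while stack:
            nid = stack.pop()
            for child in self._children[nid]:
                if child in seen:
                    raise SkeletonError(f"cycle detected at node {child}")
                seen.add(child)
                stack.append(child)
        if len(seen) != len(self._nodes):
            raise SkeletonError(
                f"skeleton {self.skeleton_id!r} is disconnected: reached "
                f"{len(seen)} of {len(self._nodes)} nodes from the root"
            )

    def topo_order(self) -> list[int]:
        """Node ids in root-first (pre-)order; parents precede children."""
        order = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self._children[nid]))
        return order

    def edge_length_nm(self, node_id: int) -> float:
        """Length of the edge from ``node_id`` to its parent (root -> 0)."""
        node = self.node(node_id)
        if node.parent_id is None:
            return 0.0
        return float(
            np.linalg.norm(self.position(node_id) - self.position(node.parent_id))
        )

    def _ensure_depths(self) -> None:
        if self._depth_nm is not None:
            return
        depth_nm: dict[int, float] = {self.root: 0.0}
        level: dict[int, int] = {self.root: 0}
        for nid in self.topo_order():
            if nid == self.root:
                continue
            p = self._nodes[nid].parent_id
            depth_nm[nid] = depth_nm[p] + self.edge_length_nm(nid)
            level[nid] = level[p] + 1
        self._depth_nm = depth_nm
        self._level = level

    def depth_nm(self, node_id: int) -> float:
        """Cable distance from the root, nm."""
        self.node(node_id)
        self._ensure_depths()
        return self._depth_nm[node_id]

    def path_to_root(self, node_id: int) -> list[int]:
        path = [node_id]
        nid = node_id
        while (p := self.node(nid).parent_id) is not None:
            path.append(p)
            nid = p
        return path

    def lowest_common_ancestor(self, a: int, b: int) -> int:
        self._ensure_depths()
        la, lb = self._level[a], self._level[b]
        while la > lb:
            a = self._nodes[a].parent_id
            la -= 1
        while lb > la:
            b = self._nodes[b].parent_id
            lb -= 1
        while a != b:
            a = self._nodes[a].parent_id
            b = self._nodes[b].parent_id
        return a

    def path_between(self, a: int, b: int) -> list[int]:
        """The unique tree path from a to b, inclusive."""
        lca = self.lowest_common_ancestor(a, b)
        up = []
        nid = a
        while nid != lca:
            up.append(nid)
            nid = self._nodes[nid].parent_id
        down = []
        nid = b
        while nid != lca:
            down.append(nid)
            nid = self._nodes[nid].parent_id
        return up + [lca] + list(reversed(down))

    def reroot(self, new_root: int) -> "Skeleton":
        """Return a copy of the skeleton re-rooted at ``new_root``.

        Parent pointers along the old root path are reversed; geometry is
        unchanged.
        """
        self.node(new_root)
        if new_root == self.root:
            return self
        flip_path = self.path_to_root(new_root)  # new_root ... old_root
        flipped = set()
        new_nodes = []
        for i, nid in enumerate(flip_path):
            new_parent = flip_path[i - 1] if i > 0 else None
            new_nodes.append(replace(self._nodes[nid], parent_id=new_parent))
            flipped.add(nid)
        for nid, node in self._nodes.items():
            if nid not in flipped:
                new_nodes.append(node)
        return Skeleton(self.skeleton_id, new_nodes)


class TagSet:
    """Mapping node_id -> set of text labels for one skeleton."""

    def __init__(self, tags: Mapping[int, Iterable[str]] | None = None):
        self._tags: dict[int, set[str]] = {}
        if tags:
            for nid, labels in tags.items():
                self._tags[int(nid)] = set(labels)

    def add(self, node_id: int, label: str) -> None:
        self._tags.setdefault(int(node_id), set()).add(label)

    def labels(self, node_id: int) -> set[str]:
        return set(self._tags.get(node_id, ()))

    def nodes_with(self, label: str) -> list[int]:
        return sorted(n for n, ls in self._tags.items() if label in ls)

    def items(self):
        return self._tags.items()

    def __len__(self) -> int:
        return len(self._tags)

    def __bool__(self) -> bool:
        return bool(self._tags)

    def validate_against(self, skeleton: Skeleton) -> None:
        for nid in self._tags:
            if nid not in skeleton:
                raise SkeletonError(
                    f"tag on node {nid} absent from skeleton "
                    f"{skeleton.skeleton_id!r}"
                )


@dataclass
class Reconstruction:
    """A set of skeletons with their connectors and per-skeleton tags."""

    skeletons: dict[str, Skeleton] = field(default_factory=dict)
    connectors: list[Connector] = field(default_factory=list)
    tags: dict[str, TagSet] = field(default_factory=dict)

    def skeleton(self, skeleton_id: str) -> Skeleton:
        try:
            return self.skeletons[skeleton_id]
        except KeyError:
            raise SkeletonError(f"unknown skeleton {skeleton_id!r}") from None

    def tagset(self, skeleton_id: str) -> TagSet:
        return self.tags.setdefault(skeleton_id, TagSet())

    def validate(self) -> None:
        for sid, ts in self.tags.items():
            ts.validate_against(self.skeleton(sid))
        for conn in self.connectors:
            for rel in (conn.presynaptic, *conn.postsynaptic):
                skel = self.skeleton(rel.skeleton_id)
                if rel.node_id not in skel:
                    raise SkeletonError(
                        f"connector {conn.connector_id!r} references missing "
                        f"node {rel.node_id} of skeleton {rel.skeleton_id!r}"
                    )

    def connectors_on(self, skeleton_id: str) -> list[Connector]:
        out = []
        for conn in self.connectors:
            if conn.presynaptic.skeleton_id == skeleton_id or any(
                r.skeleton_id == skeleton_id for r in conn.postsynaptic
            ):
                out.append(conn)
        return out


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------


def read_swc(
    document: str, skeleton_id: str = "skeleton", unit_scale_nm: float = 1.0
) -> Skeleton:
    """Parse 7-column SWC text into a :class:`Skeleton`.

    Columns: id, type, x, y, z, radius, parent (-1 = root).  Coordinates
    are multiplied by ``unit_scale_nm`` (default: 1 SWC unit = 1 nm).
    A radius of -1 maps to None.  Lines starting with '#' are comments.
    """
    nodes = []
    for lineno, raw in enumerate(document.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SkeletonError(
                f"SWC line {lineno}: expected 7 columns, got {len(parts)}"
            )
        nid, ntype = int(parts[0]), int(parts[1])
        x, y, z, radius = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        nodes.append(
            SkeletonNode(
                node_id=nid,
                parent_id=None if parent == -1 else parent,
                position=(
                    x * unit_scale_nm,
                    y * unit_scale_nm,
                    z * unit_scale_nm,
                ),
                radius=None if radius < 0 else radius * unit_scale_nm,
                swc_type=ntype,
            )
        )
    if not nodes:
        raise SkeletonError("empty SWC document")
    return Skeleton(skeleton_id, nodes)


def write_swc(skeleton: Skeleton, unit_scale_nm: float = 1.0) -> str:
    """Serialize a skeleton to SWC text (inverse of :func:`read_swc`)."""
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for nid in skeleton.topo_order():
        node = skeleton.node(nid)
        x, y, z = (c / unit_scale_nm for c in node.position)
        radius = -1.0 if node.radius is None else node.radius / unit_scale_nm
        parent = -1 if node.parent_id is None else node.parent_id
        buf.write(
            f"{node.node_id} {node.swc_type} {x:.10g} {y:.10g} {z:.10g} "
            f"{radius:.10g} {parent}\n"
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Sidecar JSON I/O
# ---------------------------------------------------------------------------


def read_sidecar(
    document: str, skeletons: Mapping[str, Skeleton]
) -> tuple[list[Connector], dict[str, TagSet], list[dict]]:
    """Parse a sidecar JSON document of connectors, tags and edit events.

    Relations are resolved against the supplied skeletons; a relation to
    an unknown skeleton or node, or a connector without exactly one
    presynaptic relation, is an error.  Returns (connectors, tags-by-
    skeleton, raw event records).
    """
    doc = json.loads(document)

    def _resolve(rel: dict, what: str) -> PartnerRelation:
        sid = str(rel["skeleton"])
        nid = int(rel["node"])
        if sid not in skeletons:
            raise SkeletonError(f"{what} relation to unknown skeleton {sid!r}")
        if nid not in skeletons[sid]:
            raise SkeletonError(
                f"{what} relation to unknown node {nid} of skeleton {sid!r}"
            )
        return PartnerRelation(sid, nid, int(rel.get("confidence", 5)))

    connectors = []
    for rec in doc.get("connectors", []):
        pre = rec.get("pre")
        if pre is None or isinstance(pre, list):
            n = 0 if pre is None else len(pre)
            raise SkeletonError(
                f"connector {rec.get('id')!r} has {n} presynaptic relations, "
                "expected exactly 1"
            )
        connectors.append(
            Connector(
                connector_id=str(rec["id"]),
                position=(float(rec["x"]), float(rec["y"]), float(rec["z"])),
                presynaptic=_resolve(pre, "presynaptic"),
                postsynaptic=tuple(
                    _resolve(p, "postsynaptic") for p in rec.get("post", [])
                ),
            )
        )
    tags: dict[str, TagSet] = {}
    for rec in doc.get("tags", []):
        sid = str(rec["skeleton"])
        nid = int(rec["node"])
        if sid not in skeletons:
            raise SkeletonError(f"tag on unknown skeleton {sid!r}")
        if nid not in skeletons[sid]:
            raise SkeletonError(f"tag on unknown node {nid} of {sid!r}")
        tags.setdefault(sid, TagSet()).add(nid, str(rec["label"]))
    events = list(doc.get("events", []))
    return connectors, tags, events


def write_sidecar(
    recon: Reconstruction, events: list[dict] | None = None
) -> str:
    """Serialize connectors, tags and events to the sidecar JSON schema."""

    def _rel(rel: PartnerRelation) -> dict:
        return {
            "skeleton": rel.skeleton_id,
            "node": rel.node_id,
            "confidence": rel.confidence,
        }

    doc = {
        "skeletons": [
            {"id": sid, "swc_file": f"{sid}.swc"} for sid in recon.skeletons
        ],
        "connectors": [
            {
                "id": c.connector_id,
                "x": c.position[0],
                "y": c.position[1],
                "z": c.position[2],
                "pre": _rel(c.presynaptic),
                "post": [_rel(r) for r in c.postsynaptic],
            }
            for c in recon.connectors
        ],
        "tags": [
            {"skeleton": sid, "node": nid, "label": label}
            for sid, ts in recon.tags.items()
            for nid, labels in sorted(ts.items())
            for label in sorted(labels)
        ],
        "events": list(events or []),
    }
    return json.dumps(doc, indent=1)


def load_reconstruction(
    sidecar_path: str, swc_dir: str | None = None
) -> Reconstruction:
    """Load a full reconstruction from a sidecar file plus its SWC files."""
    import os

    with open(sidecar_path) as fh:
        doc_text = fh.read()
    doc = json.loads(doc_text)
    base = swc_dir or os.path.dirname(os.path.abspath(sidecar_path))
    skeletons = {}
    for rec in doc.get("skeletons", []):
        sid = str(rec["id"])
        with open(os.path.join(base, rec["swc_file"])) as fh:
            skeletons[sid] = read_swc(fh.read(), skeleton_id=sid)
    connectors, tags, _events = read_sidecar(doc_text, skeletons)
    recon = Reconstruction(skeletons=skeletons, connectors=connectors, tags=tags)
    recon.validate()
    return recon


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def geodesic_distance(skeleton: Skeleton, a: int, b: int) -> float:
    """Cable distance (µm) along the unique tree path between two nodes."""
    skeleton.node(a)
    skeleton.node(b)
    if a == b:
        return 0.0
    lca = skeleton.lowest_common_ancestor(a, b)
    d = (
        skeleton.depth_nm(a)
        + skeleton.depth_nm(b)
        - 2.0 * skeleton.depth_nm(lca)
    )
    return d / NM_PER_UM


def geodesic_matrix(
    skeleton: Skeleton,
    sources: Sequence[int],
    targets: Sequence[int] | None = None,
) -> np.ndarray:
    """Matrix of geodesic distances (µm), sources x targets.

    Each source is expanded by a single tree traversal, so the cost is
    O(|sources| * |nodes|) rather than all-pairs.
    """
    tgt = skeleton.node_ids if targets is None else list(targets)
    out = np.empty((len(sources), len(tgt)), dtype=float)
    for si, src in enumerate(sources):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            nid = stack.pop()
            for nb in skeleton.neighbors(nid):
                if nb not in dist:
                    # edge length between nid and nb
                    child = nb if skeleton.parent(nb) == nid else nid
                    dist[nb] = dist[nid] + skeleton.edge_length_nm(child)
                    stack.append(nb)
        row = out[si]
        for i, nid in enumerate(tgt):
            row[i] = dist[nid] / NM_PER_UM
    return out


def cable_length(
    skeleton: Skeleton, subset: Iterable[int] | None = None
) -> float:
    """Total cable (µm) of edges whose child node is in ``subset``.

    With ``subset=None`` this is the skeleton's total cable.  The root
    contributes no edge, so a single-node skeleton has zero cable.
    """
    ids = skeleton.node_ids if subset is None else subset
    total = 0.0
    for nid in ids:
        total += skeleton.edge_length_nm(nid)
    return total / NM_PER_UM


def subtree_nodes(skeleton: Skeleton, v: int) -> set[int]:
    """``v`` plus all of its descendants under the rooted orientation."""
    skeleton.node(v)
    out = {v}
    stack = [v]
    while stack:
        nid = stack.pop()
        for child in skeleton.children(nid):
            out.add(child)
            stack.append(child)
    return out


def resample(skeleton: Skeleton, max_spacing_nm: float) -> Skeleton:
    """Subdivide every edge into equal collinear pieces <= ``max_spacing_nm``.

    An edge of length L becomes ceil(L / max_spacing) sub-edges; branch
    points, leaves and the root are untouched, so topology and total
    cable are preserved exactly.
    """
    if max_spacing_nm <= 0:
        raise ValueError("max_spacing must be positive")
    new_nodes: list[SkeletonNode] = []
    next_id = max(skeleton.node_ids) + 1
    for nid in skeleton.topo_order():
        node = skeleton.node(nid)
        if node.parent_id is None:
            new_nodes.append(node)
            continue
        p0 = skeleton.position(node.parent_id)
        p1 = skeleton.position(nid)
        length = float(np.linalg.norm(p1 - p0))
        pieces = max(1, math.ceil(length / max_spacing_nm - 1e-12))
        prev = node.parent_id
        for k in range(1, pieces):
            pos = p0 + (p1 - p0) * (k / pieces)
            new_nodes.append(
                SkeletonNode(
                    node_id=next_id,
                    parent_id=prev,
                    position=tuple(pos),
                    confidence=node.confidence,
                    swc_type=node.swc_type,
                )
            )
            prev = next_id
            next_id += 1
        new_nodes.append(replace(node, parent_id=prev))
    return Skeleton(skeleton.skeleton_id, new_nodes)


def root_at_soma(skeleton: Skeleton, tags: TagSet) -> Skeleton:
    """Re-root at the node tagged 'soma' if one exists, else return as-is."""
    soma_nodes = tags.nodes_with("soma")
    if not soma_nodes:
        return skeleton
    return skeleton.reroot(soma_nodes[0])


# ---------------------------------------------------------------------------
# Review ordering and time accounting
# ---------------------------------------------------------------------------


def review_sequences(skeleton: Skeleton) -> list[list[int]]:
    """Partition the arbor into the fewest, longest review paths.

    Leaves are sorted by node-count path length to the root, descending
    (ties by smallest leaf id).  The deepest leaf contributes the full
    leaf-to-root path; every further leaf contributes its path up to and
    including the first node already assigned, which serves as a terminal
    anchor.  Sequences are returned longest first; excluding terminal
    anchors, every node appears exactly once.
    """
    skeleton._ensure_depths()
    leaves = skeleton.leaves()
    leaves.sort(key=lambda n: (-skeleton._level[n], n))
    assigned: set[int] = set()
    sequences: list[list[int]] = []
    for leaf in leaves:
        seq = []
        nid: int | None = leaf
        while nid is not None:
            seq.append(nid)
            if nid in assigned:
                break  # terminal anchor: included, but owned elsewhere
            assigned.add(nid)
            nid = skeleton.parent(nid)
        sequences.append(seq)
    sequences.sort(key=lambda s: (-len(s), s[0]))
    return sequences


def estimate_edit_time(
    timestamps: Sequence[float], bin_seconds: float = 20.0
) -> float:
    """Active-time estimate (minutes) from event timestamps.

    Counts distinct occupied half-open bins [k*bin, (k+1)*bin) and
    multiplies by the bin width: reconstruction uses 20 s bins over node
    and connector creation events; review uses 60 s bins per contributor,
    summed by the caller.
    """
    if bin_seconds <= 0:
        raise ValueError("bin_seconds must be positive")
    if len(timestamps) == 0:
        return 0.0
    bins = {math.floor(t / bin_seconds) for t in timestamps}
    return len(bins) * bin_seconds / 60.0
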