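"""Grotthuss proton-wire graphs and three-state segment classification.

A candidate proton-transfer ("Grotthuss-competent") connection is a chain of
water oxygens and protonatable sidechain atoms in which consecutive heavy
atoms lie within a distance cutoff (4.0 A by default).  Named pathway
segments between anchor residues are classified as

* ``connected``      - an anchor-to-anchor chain exists within the cutoff;
* ``open_gap``       - no chain, but every gap along the best bridging route
                       is sterically passable by a water-sized probe;
* ``obstructed_gap`` - at least one gap on that route is blocked by protein
                       heavy atoms.

The obstruction criterion is an explicit geometric surrogate: a 1.4 A probe
sphere must be placeable near every point of the straight gap line without
overlapping the van-der-Waals sphere of any non-water heavy atom outside the
two gap-flanking residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, QwireError
from .structure import (
    AtomRecord,
    MacromolecularModel,
    ResidueRef,
    WATER_CODES,
)

#: Protonatable sidechain atoms forming wire nodes, per residue type.
WIRE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

DEFAULT_CUTOFF = 4.0  # angstrom, inclusive

SegmentState = Literal["connected", "open_gap", "obstructed_gap", "error"]

#: Anchor sentinel: matches every node flagged "surface" in the pathway
#: (bulk-solvent terminus for matrix/IMS-facing segments).
SURFACE = "surface"


def load_vdw_radii() -> tuple[dict[str, float], float]:
    with resources.files("qwire.data").joinpath("vdw_radii.json").open() as fh:
        data = json.load(fh)
    return {k.upper(): float(v) for k, v in data["radii"].items()}, float(data["default"])


@dataclass(frozen=True)
class WireNode:
    """A water oxygen or protonatable sidechain heavy atom."""

    kind: Literal["water", "sidechain", "ligand"]
    atom_index: int
    name: str
    resname: str
    residue_key: tuple[str, int, str]
    subunit: str
    resnum: int
    position: np.ndarray
    surface: bool = False

    def matches(self, ref: ResidueRef) -> bool:
        if self.kind != "sidechain":
            return False
        if self.subunit != ref.subunit or self.resnum != ref.resnum:
            return False
        if self.resname != ref.resname:
            return False
        return ref.atoms is None or self.name in ref.atoms


class WireGraph:
    """Undirected contact graph over wire nodes with stored edge distances."""

    def __init__(self, nodes: Sequence[WireNode], cutoff: float):
        self.nodes = list(nodes)
        self.cutoff = float(cutoff)
        self.graph = nx.Graph()
        self.graph.add_nodes_from(range(len(self.nodes)))

    @property
    def positions(self) -> np.ndarray:
        if not self.nodes:
            return np.empty((0, 3))
        return np.vstack([n.position for n in self.nodes])

    def add_edge(self, i: int, j: int, distance: float) -> None:
        if i == j:
            raise ValueError("self-edges are not allowed")
        if distance > self.cutoff:
            raise ValueError(f"edge distance {distance} exceeds cutoff {self.cutoff}")
        self.graph.add_edge(i, j, distance=distance)

    def edges(self) -> list[tuple[int, int, float]]:
        return [(u, v, d["distance"]) for u, v, d in self.graph.edges(data=True)]


@dataclass(frozen=True)
class SegmentSpec:
    """One Table-style segment: anchor set A to anchor set B.

    Anchors are :class:`ResidueRef` objects or the sentinel ``"surface"``
    (every node flagged surface in the pathway, standing in for bulk
    solvent).  A and B must be non-empty and disjoint.
    """

    code: str
    A: tuple
    B: tuple

    def __post_init__(self) -> None:
        if not self.A or not self.B:
            raise ConfigurationError(f"segment {self.code}: anchor sets must be non-empty")
        if set(self.A) & set(self.B):
            raise ConfigurationError(f"segment {self.code}: anchor sets overlap")


@dataclass
class GapRecord:
    """A break along the best bridging route of a disconnected segment."""

    u: WireNode
    v: WireNode
    distance: float
    verdict: Literal["open", "obstructed"] | None = None
    blockers: list[AtomRecord] = field(default_factory=list)


@dataclass
class SegmentResult:
    spec: SegmentSpec
    state: SegmentState
    witness: list[WireNode] = field(default_factory=list)
    gaps: list[GapRecord] = field(default_factory=list)
    error: str | None = None


@dataclass
class PathwayDefinition:
    """An ordered set of segments constituting one connectivity-table row."""

    name: str
    segments: list[SegmentSpec]
    surface_waters: list[tuple[str, int]] = field(default_factory=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayDefinition":
        with open(path) as fh:
            data = json.load(fh)
        segments = []
        for seg in data["segments"]:
            def anchors(entries):
                out = []
                for e in entries:
                    if e == SURFACE or (isinstance(e, Mapping) and e.get("surface")):
                        out.append(SURFACE)
                    else:
                        out.append(ResidueRef.from_dict(e))
                return tuple(out)

            segments.append(SegmentSpec(code=seg["code"], A=anchors(seg["A"]), B=anchors(seg["B"])))
        surface = [(w["chain"], int(w["resnum"])) for w in data.get("surface_waters", [])]
        return cls(name=data.get("name", Path(path).stem), segments=segments, surface_waters=surface)


# -- node collection and graph build ---------------------------------------


def collect_wire_nodes(
    model: MacromolecularModel,
    include_ligand_polar: bool = False,
    surface_waters: Iterable[tuple[str, int]] = (),
) -> list[WireNode]:
    """Water oxygens plus the protonatable sidechain atoms of
    Asp/Glu/His/Lys/Ser/Thr/Tyr (and ligand O/N if requested)."""
    surface = {(c, n) for c, n in surface_waters}
    nodes: list[WireNode] = []
    for i, a in enumerate(model.atoms):
        kind = None
        if a.residue_name in WATER_CODES:
            if a.element == "O":
                kind = "water"
        elif a.residue_name in WIRE_ATOMS:
            if a.name in WIRE_ATOMS[a.residue_name]:
                kind = "sidechain"
        elif include_ligand_polar and a.is_hetero and a.element in ("O", "N"):
            kind = "ligand"
        if kind is None:
            continue
        nodes.append(
            WireNode(
                kind=kind,
                atom_index=i,
                name=a.name,
                resname=a.residue_name,
                residue_key=a.residue_key,
                subunit=a.subunit,
                resnum=a.residue_number,
                position=a.position,
                surface=(a.chain_id, a.residue_number) in surface,
            )
        )
    return nodes


def build_wire_graph(nodes: Sequence[WireNode], r_c: float = DEFAULT_CUTOFF) -> WireGraph:
    """Edge (u,v) iff their heavy-atom distance is <= r_c (boundary inclusive)."""
    if r_c <= 0:
        raise ValueError("cutoff must be positive")
    g = WireGraph(nodes, r_c)
    if len(nodes) < 2:
        return g
    tree = cKDTree(g.positions)
    for i, j in tree.query_pairs(r_c):
        d = float(np.linalg.norm(nodes[i].position - nodes[j].position))
        if d <= r_c:
            g.add_edge(i, j, d)
    return g


# -- anchors ---------------------------------------------------------------


def _anchor_indices(graph: WireGraph, anchors: Iterable) -> list[int]:
    out: list[int] = []
    for ref in anchors:
        if ref == SURFACE:
            hits = [i for i, n in enumerate(graph.nodes) if n.surface]
            if not hits:
                raise ConfigurationError("anchor 'surface' matches no surface-flagged node")
        else:
            hits = [i for i, n in enumerate(graph.nodes) if n.matches(ref)]
            if not hits:
                raise ConfigurationError(f"anchor {ref} contributes no wire node")
        out.extend(hits)
    # deterministic, deduplicated
    return sorted(set(out))


# -- connectivity and gap routes -------------------------------------------


def segment_connectivity(graph: WireGraph, spec: SegmentSpec) -> tuple[bool, list[WireNode]]:
    """Breadth-first reachability from anchor set A to anchor set B.

    Returns (connected, witness) where witness is a shortest hop-count path
    (node sequence, anchors included) when connected.
    """
    a_idx = _anchor_indices(graph, spec.A)
    b_idx = set(_anchor_indices(graph, spec.B))
    g = graph.graph
    # multi-source BFS with parent tracking
    parent: dict[int, int | None] = {i: None for i in a_idx}
    frontier = list(a_idx)
    hit = next((i for i in a_idx if i in b_idx), None)
    while frontier and hit is None:
        nxt: list[int] = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in parent:
                    parent[v] = u
                    if v in b_idx:
                        hit = v
                        break
                    nxt.append(v)
            if hit is not None:
                break
        frontier = nxt
    if hit is None:
        return False, []
    path_idx = [hit]
    while parent[path_idx[-1]] is not None:
        path_idx.append(parent[path_idx[-1]])
    path_idx.reverse()
    return True, [graph.nodes[i] for i in path_idx]


def bridge_path_gaps(
    graph: WireGraph, spec: SegmentSpec, max_gap_seed: float = 12.0
) -> list[GapRecord]:
    """Gaps along the minimum-total-gap-length route between anchor components.

    The graph's connected components are condensed into supernodes; links
    between components are weighted by the minimal node-pair distance; the
    route is found by Dijkstra on that condensation.  Gap records are
    returned in route order, endpoints being the closest node pair of each
    crossed gap.
    """
    a_idx = _anchor_indices(graph, spec.A)
    b_idx = _anchor_indices(graph, spec.B)
    comp_of: dict[int, int] = {}
    for ci, comp in enumerate(nx.connected_components(graph.graph)):
        for n in comp:
            comp_of[n] = ci
    a_comps = {comp_of[i] for i in a_idx}
    b_comps = {comp_of[i] for i in b_idx}
    if a_comps & b_comps:
        return []  # actually connected; no gaps

    pos = graph.positions
    n = len(graph.nodes)
    extent = float(np.linalg.norm(pos.max(0) - pos.min(0))) if n else 0.0
    max_gap = max_gap_seed
    while True:
        tree = cKDTree(pos)
        cond = nx.Graph()
        cond.add_nodes_from(set(comp_of.values()))
        best_pair: dict[tuple[int, int], tuple[float, int, int]] = {}
        for i, j in tree.query_pairs(max_gap):
            ci, cj = comp_of[i], comp_of[j]
            if ci == cj:
                continue
            key = (min(ci, cj), max(ci, cj))
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if key not in best_pair or d < best_pair[key][0]:
                best_pair[key] = (d, i, j)
        for (ci, cj), (d, i, j) in best_pair.items():
            cond.add_edge(ci, cj, weight=d, endpoints=(i, j))
        # virtual source/target across all anchor components
        cond.add_node("A")
        cond.add_node("B")
        for c in a_comps:
            cond.add_edge("A", c, weight=0.0, endpoints=None)
        for c in b_comps:
            cond.add_edge("B", c, weight=0.0, endpoints=None)
        try:
            route = nx.dijkstra_path(cond, "A", "B")
        except nx.NetworkXNoPath:
            if max_gap > extent:
                raise ConfigurationError(
                    f"segment {spec.code}: no finite bridging route between anchors"
                )
            max_gap *= 2
            continue
        break

    gaps: list[GapRecord] = []
    for u_c, v_c in zip(route, route[1:]):
        data = cond.get_edge_data(u_c, v_c)
        if data["endpoints"] is None:
            continue
        i, j = data["endpoints"]
        # orient the gap along the route direction (component u_c -> v_c)
        if comp_of[i] != u_c:
            i, j = j, i
        gaps.append(GapRecord(u=graph.nodes[i], v=graph.nodes[j], distance=data["weight"]))
    return gaps


# -- steric probe test ------------------------------------------------------


def _offset_grid(radius: float, spacing: float) -> np.ndarray:
    ax = np.arange(-radius, radius + spacing / 2, spacing)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def classify_gap(
    model: MacromolecularModel,
    u: WireNode,
    v: WireNode,
    probe_radius: float = 1.4,
    lateral_search: float = 2.0,
    step: float = 0.5,
    grid_spacing: float = 0.1,
    vdw: Mapping[str, float] | None = None,
) -> GapRecord:
    """Probe-placement test along the straight u-v gap line.

    A sample point on the line is passable if a probe sphere of
    ``probe_radius`` can be centred within ``lateral_search`` of it without
    overlapping the van-der-Waals sphere of any non-water heavy atom outside
    the two flanking residues.  The gap is open iff every sample point is
    passable; otherwise the atoms excluding every candidate centre at the
    first impassable point are reported as blockers.
    """
    radii, default_r = load_vdw_radii()
    if vdw:
        radii = {**radii, **{k.upper(): float(val) for k, val in vdw.items()}}
    p0, p1 = u.position, v.position
    length = float(np.linalg.norm(p1 - p0))
    n_samples = max(2, int(np.ceil(length / step)) + 1)
    ts = np.linspace(0.0, 1.0, n_samples)
    samples = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]

    excluded_keys = {u.residue_key, v.residue_key}
    obstacle_idx = [
        i
        for i, a in enumerate(model.atoms)
        if a.residue_name not in WATER_CODES and a.residue_key not in excluded_keys
    ]
    record = GapRecord(u=u, v=v, distance=length)
    if not obstacle_idx:
        record.verdict = "open"
        return record
    obs_pos = np.vstack([model.atoms[i].position for i in obstacle_idx])
    obs_rad = np.array([radii.get(model.atoms[i].element, default_r) for i in obstacle_idx])
    tree = cKDTree(obs_pos)
    offsets = _offset_grid(lateral_search, grid_spacing)
    reach = lateral_search + probe_radius + float(obs_rad.max())

    for point in samples:
        near = tree.query_ball_point(point, reach)
        if not near:
            continue  # passable: nothing anywhere close
        centres = point[None, :] + offsets
        npos = obs_pos[near]
        nrad = obs_rad[near]
        d = np.linalg.norm(centres[:, None, :] - npos[None, :, :], axis=2)
        overlap = d < (nrad[None, :] + probe_radius)
        if not overlap.any(axis=1).all():
            continue  # some candidate centre is clash-free
        blocking = np.nonzero(overlap.any(axis=0))[0]
        record.verdict = "obstructed"
        record.blockers = [model.atoms[obstacle_idx[near[k]]] for k in blocking]
        return record
    record.verdict = "open"
    return record


def classify_segment(
    model: MacromolecularModel,
    graph: WireGraph,
    spec: SegmentSpec,
    **probe_kwargs,
) -> SegmentResult:
    """Three-state classification of one pathway segment."""
    connected, witness = segment_connectivity(graph, spec)
    if connected:
        return SegmentResult(spec=spec, state="connected", witness=witness)
    gaps = bridge_path_gaps(graph, spec)
    classified = [
        classify_gap(model, g.u, g.v, **probe_kwargs) for g in gaps
    ]
    state: SegmentState = (
        "obstructed_gap" if any(g.verdict == "obstructed" for g in classified) else "open_gap"
    )
    return SegmentResult(spec=spec, state=state, gaps=classified)


def analyse_pathway(
    model: MacromolecularModel,
    pathway: PathwayDefinition,
    r_c: float = DEFAULT_CUTOFF,
    include_ligand_polar: bool = False,
    **probe_kwargs,
) -> list[SegmentResult]:
    """Classify every segment of a pathway; per-segment errors are collected
    into the corresponding result instead of aborting the whole row."""
    nodes = collect_wire_nodes(
        model, include_ligand_polar=include_ligand_polar, surface_waters=pathway.surface_waters
    )
    graph = build_wire_graph(nodes, r_c)
    results: list[SegmentResult] = []
    for spec in pathway.segments:
        try:
            results.append(classify_segment(model, graph, spec, **probe_kwargs))
        except QwireError as exc:
            results.append(SegmentResult(spec=spec, state="error", error=str(exc)))
    return results


# -- hydration and hydrogen bonds ------------------------------------------


def hydration_number(
    model: MacromolecularModel,
    ref: ResidueRef,
    atoms: Sequence[str] | None = None,
    cutoff: float = 3.4,
) -> int:
    """Distinct waters with an oxygen within *cutoff* of any listed atom."""
    from .structure import select_atoms

    sel = select_atoms(model, ref, atoms)
    waters: set[tuple[str, int, str]] = set()
    for wi in model.waters:
        w = model.atoms[wi]
        if w.element != "O":
            continue
        for a in sel:
            if np.linalg.norm(w.position - a.position) <= cutoff:
                waters.add(w.residue_key)
                break
    return len(waters)


#: Covalent antecedent of common polar hydrogens' heavy atoms: used for the
#: donor-angle check.  Resolved geometrically (nearest same-residue heavy
#: atom within bonding distance) so ligands work too.
_BOND_MAX = 1.8


def _antecedent(model: MacromolecularModel, atom: AtomRecord) -> AtomRecord | None:
    best, best_d = None, _BOND_MAX
    for i in model.atom_indices_of_residue(atom.residue_key):
        other = model.atoms[i]
        if other is atom or other.name == atom.name:
            continue
        d = float(np.linalg.norm(other.position - atom.position))
        if d < best_d:
            best, best_d = other, d
    return best


def detect_hbonds(
    model: MacromolecularModel,
    selection: Sequence[AtomRecord],
    d_min: float = 2.4,
    d_max: float = 3.4,
    min_angle_deg: float = 90.0,
) -> list[tuple[AtomRecord, AtomRecord, float]]:
    """Polar heavy-atom (N,O) pairs within [d_min, d_max], angle-filtered.

    When a putative donor's covalent antecedent is known, the
    antecedent-donor-acceptor angle must be >= min_angle_deg for at least
    one of the two donor assignments.  Pairs are reported once, sorted by
    distance.
    """
    if not selection:
        raise ValueError("selection must be non-empty")
    polar = [a for a in selection if a.element in ("N", "O")]
    out: list[tuple[AtomRecord, AtomRecord, float]] = []
    for i in range(len(polar)):
        for j in range(i + 1, len(polar)):
            a, b = polar[i], polar[j]
            if a.residue_key == b.residue_key and a.residue_name not in WATER_CODES:
                continue  # intra-residue contacts are covalent geometry, not H-bonds
            d = float(np.linalg.norm(a.position - b.position))
            if not (d_min <= d <= d_max):
                continue
            ok = False
            for donor, acceptor in ((a, b), (b, a)):
                ante = _antecedent(model, donor)
                if ante is None:
                    ok = True
                    break
                v1 = ante.position - donor.position
                v2 = acceptor.position - donor.position
                cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= min_angle_deg:
                    ok = True
                    break
            if ok:
                out.append((a, b, d))
    out.sort(key=lambda t: t[2])
    return out
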