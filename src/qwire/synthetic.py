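"""Synthetic coordinate fixtures with generator-verified ground truth.

Everything downstream (wire graphs, segment classification, path CVs, flip
states, metadynamics landscapes) is testable without downloading deposited
structures: this module builds minimal pseudo-residue models whose declared
truth is re-checked against the independent brute-force oracles before they
are returned, so a mislabelled fixture fails loudly at generation time.

Pseudo-residues carry only the atoms the analyses touch (a TYR is just its
hydroxyl oxygen, a water just its oxygen): rotamer realism is irrelevant to
the geometric contracts under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import GenerationError, UsageError
from .structure import AtomRecord, MacromolecularModel, ResidueRef
from .pose import MilestoneSet, distance_vector
from .wires import (
    PathwayDefinition,
    SegmentSpec,
    analyse_pathway,
    build_wire_graph,
    collect_wire_nodes,
)
from . import oracles

SegmentState = Literal["connected", "open_gap", "obstructed_gap"]

#: Element used for steric blockers: selenium (vdW 1.90 A in the shipped table).
BLOCKER_ELEMENT = "SE"


# -- low-level builders -----------------------------------------------------


def _atom(
    serial: int,
    name: str,
    element: str,
    resname: str,
    chain: str,
    resnum: int,
    pos,
    hetero: bool = False,
    subunit: str = "unmapped",
) -> AtomRecord:
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        alt_loc="",
        residue_name=resname,
        chain_id=chain,
        residue_number=resnum,
        insertion_code="",
        position=np.asarray(pos, dtype=float),
        occupancy=1.0,
        b_factor=20.0,
        is_hetero=hetero,
        subunit=subunit,
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# -- PDB writing ------------------------------------------------------------


def write_pdb(model: MacromolecularModel, path: str | Path) -> None:
    """Write standard fixed-column ATOM/HETATM records (+ END)."""
    if len(model) >= 100_000:
        raise UsageError("fixture writer supports < 100,000 atoms")
    lines = []
    for a in model.atoms:
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.position
        lines.append(
            f"{rec}{a.serial:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id[:1]:1s}{a.residue_number:4d}{a.insertion_code[:1]:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"{'':10s}{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# -- wire fixtures ----------------------------------------------------------


@dataclass
class WireFixtureSpec:
    """Declared truth and geometry knobs for a proton-wire fixture."""

    states: tuple[SegmentState, ...] = ("connected",)
    water_spacing: float = 2.8  # A, inside the 4 A cutoff and H-bond window
    gap_length: float = 5.5  # A, outside the cutoff
    n_chain_waters: int = 4
    clearance_margin: float = 0.3
    jitter: float = 0.05  # A per coordinate, keeps clearances intact
    rigid_motion: bool = False
    seed: int = 0
    cutoff: float = 4.0
    segment_separation: float = 40.0

    def __post_init__(self) -> None:
        if self.water_spacing + 2 * self.jitter > self.cutoff - self.clearance_margin:
            raise GenerationError("water spacing too close to the cutoff for the margin")
        if self.gap_length - 2 * self.jitter < self.cutoff + self.clearance_margin:
            raise GenerationError("gap length too close to the cutoff for the margin")


def make_wire_fixture(
    spec: WireFixtureSpec,
) -> tuple[MacromolecularModel, PathwayDefinition, list[SegmentState]]:
    """Build a model realising the declared per-segment states.

    Each segment runs along its own axis (segments widely separated): a TYR
    hydroxyl anchor, a chain of waters at ``water_spacing``, and a GLU
    carboxylate anchor.  Gap segments interrupt the chain by ``gap_length``;
    obstructed segments additionally centre a blocker pseudo-atom on the gap
    line.  The returned states are re-verified against
    :func:`qwire.oracles.probe_verdict_grid` and a brute-force edge scan.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    segments: list[SegmentSpec] = []
    serial = 0

    for k, state in enumerate(spec.states):
        subunit = f"SEG{k + 1}"
        chain = chr(ord("A") + k)
        y0 = spec.segment_separation * k

        # node x-positions along the chain: anchor, waters..., anchor
        xs = [0.0]
        n_before = spec.n_chain_waters // 2
        n_after = spec.n_chain_waters - n_before
        for _ in range(n_before):
            xs.append(xs[-1] + spec.water_spacing)
        if state == "connected":
            for _ in range(n_after):
                xs.append(xs[-1] + spec.water_spacing)
        else:
            xs.append(xs[-1] + spec.gap_length)
            for _ in range(n_after - 1):
                xs.append(xs[-1] + spec.water_spacing)
        xs.append(xs[-1] + spec.water_spacing)

        positions = [np.array([x, y0, 0.0]) for x in xs]
        jit = rng.uniform(-spec.jitter, spec.jitter, size=(len(positions), 3))
        positions = [p + j for p, j in zip(positions, jit)]

        serial += 1
        atoms.append(_atom(serial, "OH", "O", "TYR", chain, 1, positions[0], subunit=subunit))
        for wi, p in enumerate(positions[1:-1]):
            serial += 1
            atoms.append(
                _atom(serial, "O", "O", "HOH", chain, 100 + wi, p, hetero=True, subunit=subunit)
            )
        serial += 1
        atoms.append(
            _atom(serial, "OE1", "O", "GLU", chain, 2, positions[-1], subunit=subunit)
        )

        if state == "obstructed_gap":
            # gap runs between water n_before-1 (index n_before in positions)
            # and the next node; blocker on the midpoint of the gap line
            gap_u = positions[n_before]
            gap_v = positions[n_before + 1]
            mid = 0.5 * (gap_u + gap_v)
            serial += 1
            atoms.append(
                _atom(serial, "SE", BLOCKER_ELEMENT, "BLK", chain, 900, mid, hetero=True,
                      subunit=subunit)
            )

        segments.append(
            SegmentSpec(
                code=f"S{k + 1}",
                A=(ResidueRef(subunit=subunit, resnum=1, resname="TYR"),),
                B=(ResidueRef(subunit=subunit, resnum=2, resname="GLU"),),
            )
        )

    model = MacromolecularModel(atoms, name=f"wire-fixture-{spec.seed}")
    if spec.rigid_motion:
        R = random_rotation(rng)
        t = rng.uniform(-50, 50, 3)
        model = MacromolecularModel(
            [a for a in model.transformed(R, t).atoms], name=model.name
        )

    pathway = PathwayDefinition(name=model.name, segments=segments)
    _verify_wire_fixture(model, pathway, list(spec.states), spec.cutoff)
    return model, pathway, list(spec.states)


def _verify_wire_fixture(
    model: MacromolecularModel,
    pathway: PathwayDefinition,
    states: list[SegmentState],
    cutoff: float,
) -> None:
    # production-path check
    results = analyse_pathway(model, pathway, r_c=cutoff)
    got = [r.state for r in results]
    if got != states:
        raise GenerationError(f"fixture self-check failed: declared {states}, analysed {got}")
    # independent oracle check: edges and probe verdicts
    nodes = collect_wire_nodes(model)
    graph = build_wire_graph(nodes, cutoff)
    edges = {(min(u, v), max(u, v)) for u, v, _ in graph.edges()}
    if edges != oracles.brute_force_edges(nodes, cutoff):
        raise GenerationError("fixture self-check failed: edge set mismatch vs brute force")
    for result, state in zip(results, states):
        for gap in result.gaps:
            verdict = oracles.probe_verdict_grid(model, gap.u, gap.v)
            if verdict != gap.verdict:
                raise GenerationError(
                    f"fixture self-check failed: probe oracle says {verdict}, "
                    f"classifier says {gap.verdict}"
                )


# -- channel / milestone fixtures ------------------------------------------


@dataclass
class ChannelFixtureSpec:
    """A straight toy binding channel with milestone waypoints."""

    n_milestones: int = 4
    channel_length: float = 15.0  # A
    n_qhead_atoms: int = 3
    n_ca_anchors: int = 6
    pose_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_milestones < 2:
            raise GenerationError("need at least two milestones")
        if tuple(sorted(self.pose_fractions)) != tuple(self.pose_fractions):
            raise GenerationError("pose fractions must be ordered")


def _channel_model(
    spec: ChannelFixtureSpec, fraction: float, ca_positions: np.ndarray, head_offsets: np.ndarray
) -> MacromolecularModel:
    atoms: list[AtomRecord] = []
    serial = 0
    for i, p in enumerate(ca_positions):
        serial += 1
        atoms.append(_atom(serial, "CA", "C", "GLY", "C", i + 1, p, subunit="CHAN"))
    centre = np.array([fraction * spec.channel_length, 0.0, 0.0])
    for i, off in enumerate(head_offsets):
        serial += 1
        atoms.append(
            _atom(serial, f"Q{i + 1}", "C", "U10", "Q", 1, centre + off, hetero=True,
                  subunit="unmapped")
        )
    return MacromolecularModel(atoms, name=f"pose-f{fraction:.3f}")


def make_channel_milestones(
    spec: ChannelFixtureSpec,
) -> tuple[MilestoneSet, list[tuple[float, MacromolecularModel]]]:
    """Toy channel: C-alpha anchors flanking a line, headgroup waypoints.

    Milestone vectors are computed from the waypoint geometries themselves,
    lambda follows the default consecutive-distance rule, and pose models
    are emitted at the declared fractions (strictly increasing channel
    positions, so s_raw must increase with them).
    """
    rng = np.random.default_rng(spec.seed)
    xs = np.linspace(0.0, spec.channel_length, spec.n_ca_anchors)
    side = np.array([4.0 if i % 2 == 0 else -4.0 for i in range(spec.n_ca_anchors)])
    z = rng.uniform(-1.0, 1.0, spec.n_ca_anchors)
    ca_positions = np.column_stack([xs, side, z])
    head_offsets = rng.uniform(-0.8, 0.8, size=(spec.n_qhead_atoms, 3))

    qhead_atoms = tuple(f"Q{i + 1}" for i in range(spec.n_qhead_atoms))
    ca_refs = tuple(
        ResidueRef(subunit="CHAN", resnum=i + 1, resname="GLY", atoms=("CA",))
        for i in range(spec.n_ca_anchors)
    )

    waypoints = np.linspace(0.0, 1.0, spec.n_milestones)
    vectors = []
    for f in waypoints:
        m = _channel_model(spec, f, ca_positions, head_offsets)
        vectors.append(distance_vector(m, qhead_atoms, ca_refs, ligand_code="U10"))
    mset = MilestoneSet(
        milestones=np.vstack(vectors),
        qhead_atoms=qhead_atoms,
        ca_refs=ca_refs,
        lam=None,
        ligand_code="U10",
    )
    poses = [
        (float(f), _channel_model(spec, float(f), ca_positions, head_offsets))
        for f in spec.pose_fractions
    ]
    return mset, poses


# -- quinol headgroup poses -------------------------------------------------


def make_quinol_pose(
    flip: Literal["on", "off", "undefined"],
    tyr_position: Sequence[float] = (8.0, 0.0, 0.0),
    bend: float = 1.0,
) -> MacromolecularModel:
    """A hexagonal quinol headgroup plus a TYR hydroxyl realising *flip*.

    Ring carbons C1..C6 on a 1.39 A hexagon in the xy plane; substituents
    (O1, O4, methoxy O2/O3, 5-methyl C5M) placed radially outward.  For
    ``on`` the 5-methyl edge faces the Tyr hydroxyl; for ``off`` the
    methoxy edge does; ``undefined`` bends the methyl *bend* angstrom out
    of plane (default exceeds the 0.4 A planarity threshold).
    """
    if flip not in ("on", "off", "undefined"):
        raise UsageError(f"unknown flip request {flip!r}")
    tyr = np.asarray(tyr_position, dtype=float)
    towards = tyr / np.linalg.norm(tyr)

    # ring with C5 at angle 0; substituent map: O1@C1, O2@C2, O3@C3, O4@C4, C5M@C5
    ring_r, sub_r = 1.39, 2.45
    # methoxy midpoint sits between C2 and C3, i.e. around angle 210 deg
    # relative to C5 at 0 deg (ring order C5, C6, C1, C2, C3, C4)
    order = ["C5", "C6", "C1", "C2", "C3", "C4"]
    angles = {name: np.deg2rad(60.0 * i) for i, name in enumerate(order)}
    face = 1.0 if flip != "off" else -1.0
    # rotate so that the C5 direction points towards (on) or away from (off) Tyr
    xdir = towards * face
    zdir = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(xdir, zdir)) > 0.9:
        zdir = np.array([0.0, 1.0, 0.0])
    ydir = np.cross(zdir, xdir)
    ydir /= np.linalg.norm(ydir)
    zdir = np.cross(xdir, ydir)

    def place(angle: float, radius: float, dz: float = 0.0) -> np.ndarray:
        return radius * (np.cos(angle) * xdir + np.sin(angle) * ydir) + dz * zdir

    atoms: list[AtomRecord] = []
    serial = 0
    for name in order:
        serial += 1
        atoms.append(_atom(serial, name, "C", "U10", "Q", 1, place(angles[name], ring_r),
                           hetero=True))
    substituents = [
        ("O1", "O", angles["C1"], 0.0),
        ("O2", "O", angles["C2"], 0.0),
        ("O3", "O", angles["C3"], 0.0),
        ("O4", "O", angles["C4"], 0.0),
        ("C5M", "C", angles["C5"], bend if flip == "undefined" else 0.0),
    ]
    for name, element, angle, dz in substituents:
        serial += 1
        atoms.append(_atom(serial, name, element, "U10", "Q", 1, place(angle, sub_r, dz),
                           hetero=True))
    serial += 1
    atoms.append(_atom(serial, "OH", "O", "TYR", "A", 108, tyr, subunit="NDUFS2"))
    serial += 1
    # antecedent for hydrogen-bond geometry: CZ 1.4 A behind the hydroxyl
    atoms.append(_atom(serial, "CZ", "C", "TYR", "A", 108, tyr + 1.4 * towards,
                       subunit="NDUFS2"))
    return MacromolecularModel(atoms, name=f"quinol-{flip}")


# -- analytic landscapes ----------------------------------------------------


class _Potential:
    name = "potential"

    def value(self, x) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, x) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Harmonic(_Potential):
    name = "harmonic"

    def __init__(self, centre=23.5, kappa=10.0):
        self.centre = np.atleast_1d(np.asarray(centre, float))
        self.kappa = float(kappa)

    def value(self, x) -> float:
        d = np.atleast_1d(np.asarray(x, float)) - self.centre
        return float(0.5 * self.kappa * np.sum(d * d))

    def gradient(self, x) -> np.ndarray:
        return self.kappa * (np.atleast_1d(np.asarray(x, float)) - self.centre)


class DoubleWell(_Potential):
    """U(s) = barrier * (((s - centre)/half_sep)^2 - 1)^2 on the first CV.

    Minima at centre +/- half_sep, barrier height ``barrier`` at the centre.
    Extra dimensions are confined harmonically (kappa_transverse).
    """

    name = "double_well"

    def __init__(self, centre=23.5, half_sep=1.0, barrier=10.0, kappa_transverse=20.0,
                 transverse_centre=0.0):
        self.centre = float(centre)
        self.half_sep = float(half_sep)
        self.barrier = float(barrier)
        self.kappa_t = float(kappa_transverse)
        self.t_centre = float(transverse_centre)

    def value(self, x) -> float:
        x = np.atleast_1d(np.asarray(x, float))
        u = (x[0] - self.centre) / self.half_sep
        val = self.barrier * (u * u - 1.0) ** 2
        if len(x) > 1:
            val += 0.5 * self.kappa_t * np.sum((x[1:] - self.t_centre) ** 2)
        return float(val)

    def gradient(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        g = np.zeros_like(x)
        u = (x[0] - self.centre) / self.half_sep
        g[0] = self.barrier * 4.0 * u * (u * u - 1.0) / self.half_sep
        if len(x) > 1:
            g[1:] = self.kappa_t * (x[1:] - self.t_centre)
        return g


class Flat(_Potential):
    name = "flat"

    def value(self, x) -> float:
        return 0.0

    def gradient(self, x) -> np.ndarray:
        return np.zeros_like(np.atleast_1d(np.asarray(x, float)))


def toy_potential(name: str, **params) -> _Potential:
    """Analytic test landscape with exact gradient."""
    table = {"harmonic": Harmonic, "double_well": DoubleWell, "flat": Flat}
    if name not in table:
        raise UsageError(f"unknown potential {name!r}; choose from {sorted(table)}")
    return table[name](**params)
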