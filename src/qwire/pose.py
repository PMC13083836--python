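"""Quinone binding-pose metrics: path collective variables, ring-flip state,
subunit-restricted C-alpha RMSD, headgroup displacement and mode labels.

The position of the quinone headgroup in its binding channel is summarised
by a path collective variable built on a vector of headgroup-to-C-alpha
distances, referenced to N milestone geometries representing progressive
binding (the study used N = 4):

    d_i^2   = mean squared deviation of the pose vector from milestone i (nm^2)
    s_raw   = sum_i i exp(-lambda d_i^2) / sum_i exp(-lambda d_i^2)   in [1, N]
    Path.S  = a + b * s_raw          (affine map onto the reported scale)
    Path.Z  = -(1/lambda) ln sum_i exp(-lambda d_i^2)                 in nm^2

Poses are classified into binding modes I / J.1 / J.2 / K.1 / K.2 from
(Path.S, ring-flip): "on"-flipped headgroups (5-methyl towards the reactive
Tyr, reactive Tyr-Q hydrogen bond possible) are mode I; "off"-flipped ones
are split along the channel coordinate into J.1 / J.2 / K.2; non-planar
("undefined") headgroups are K.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DimensionError, SelectionError
from .structure import (
    AtomRecord,
    MacromolecularModel,
    ResidueRef,
    select_atoms,
)

ANGSTROM_PER_NM = 10.0

#: Default headgroup atom names (ubiquinone/ubiquinol CCD-style naming):
#: six ring carbons, ring-1/ring-4 oxygens, 2-/3-methoxy oxygens, 5-methyl C.
DEFAULT_HEADGROUP = {
    "ring": ("C1", "C2", "C3", "C4", "C5", "C6"),
    "o1": "O1",
    "o4": "O4",
    "methoxy_o": ("O2", "O3"),
    "methyl": "C5M",
}

DEFAULT_RMSD_SUBUNITS = ("NDUFS2", "NDUFS7", "ND1")

#: Mode thresholds on Path.S for off-flipped poses (cluster midpoints of the
#: printed values); config-overridable.
DEFAULT_MODE_THRESHOLDS = (23.40, 23.85)


# -- milestone sets ---------------------------------------------------------


@dataclass
class MilestoneSet:
    """Reference distance vectors along the binding channel.

    ``milestones`` has shape (N, L): N >= 2 milestone configurations, each a
    vector of L headgroup-atom <-> channel-C-alpha distances in nm.  ``lam``
    (nm^-2) sets the metric sharpness; if None it defaults to
    2.3 / <d^2_{i,i+1}> over consecutive milestones.  ``affine`` = (a, b)
    maps index-space s in [1, N] onto the reported Path.S scale.
    """

    milestones: np.ndarray
    qhead_atoms: tuple[str, ...]
    ca_refs: tuple[ResidueRef, ...]
    lam: float | None = None
    affine: tuple[float, float] = (21.0, 1.25)
    metric: Literal["mean", "sum"] = "mean"
    ligand_code: str = "U10"

    def __post_init__(self) -> None:
        self.milestones = np.asarray(self.milestones, dtype=float)
        if self.milestones.ndim != 2 or self.milestones.shape[0] < 2:
            raise ConfigurationError("milestones must be an (N>=2, L) array")
        a, b = self.affine
        if b == 0:
            raise ConfigurationError("affine slope b must be nonzero")
        if self.lam is not None and self.lam <= 0:
            raise ConfigurationError("lambda must be positive")

    @property
    def n(self) -> int:
        return self.milestones.shape[0]

    def metric_d2(self, v: np.ndarray, m: np.ndarray) -> float:
        diff2 = np.square(np.asarray(v, float) - np.asarray(m, float))
        return float(diff2.mean() if self.metric == "mean" else diff2.sum())

    @property
    def effective_lambda(self) -> float:
        if self.lam is not None:
            return self.lam
        consec = [
            self.metric_d2(self.milestones[i], self.milestones[i + 1])
            for i in range(self.n - 1)
        ]
        return 2.3 / float(np.mean(consec))

    @classmethod
    def from_json(cls, path: str | Path) -> "MilestoneSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            milestones=np.array(data["milestones"], dtype=float),
            qhead_atoms=tuple(data["qhead_atoms"]),
            ca_refs=tuple(ResidueRef.from_dict(d) for d in data["ca_refs"]),
            lam=data.get("lambda"),
            affine=tuple(data.get("affine", (21.0, 1.25))),
            metric=data.get("metric", "mean"),
            ligand_code=data.get("ligand_code", "U10"),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "milestones": self.milestones.tolist(),
                    "qhead_atoms": list(self.qhead_atoms),
                    "ca_refs": [
                        {"subunit": r.subunit, "resnum": r.resnum, "resname": r.resname,
                         "atoms": list(r.atoms) if r.atoms else ["CA"]}
                        for r in self.ca_refs
                    ],
                    "lambda": self.lam,
                    "affine": list(self.affine),
                    "metric": self.metric,
                    "ligand_code": self.ligand_code,
                },
                fh,
                indent=1,
            )


@dataclass(frozen=True)
class PoseCV:
    path_s: float
    path_z: float
    d2: np.ndarray  # per-milestone squared metric distances, nm^2
    s_raw: float


@dataclass(frozen=True)
class FlipState:
    value: Literal["on", "off", "undefined"]
    planarity_dev: float  # max ring-substituent out-of-plane deviation, angstrom


@dataclass(frozen=True)
class BindingMode:
    label: Literal["I", "J.1", "J.2", "K.1", "K.2"]
    thresholds: tuple[float, float] = DEFAULT_MODE_THRESHOLDS


@dataclass
class PoseDescriptor:
    structure_id: str
    q_species: str
    path_s: float
    path_z: float
    flip: FlipState
    rmsd: float
    mode: BindingMode


# -- distance vector and path CV -------------------------------------------


def distance_vector(
    model: MacromolecularModel,
    qhead_atoms: Sequence[str],
    ca_refs: Sequence[ResidueRef],
    ligand_code: str = "U10",
) -> np.ndarray:
    """All (headgroup atom, C-alpha) distances in nm, in declared order.

    Ordering is headgroup-major: for each headgroup atom, all C-alphas.
    """
    head = select_atoms(model, ligand_code, list(qhead_atoms))
    cas: list[AtomRecord] = []
    for ref in ca_refs:
        sel = select_atoms(model, ref, list(ref.atoms) if ref.atoms else ["CA"])
        cas.extend(sel)
    hp = np.vstack([a.position for a in head])
    cp = np.vstack([a.position for a in cas])
    d = np.linalg.norm(hp[:, None, :] - cp[None, :, :], axis=2)
    return (d / ANGSTROM_PER_NM).ravel()


def path_cv(v: np.ndarray, M: MilestoneSet) -> PoseCV:
    """Evaluate (Path.S, Path.Z) for a pose distance vector."""
    v = np.asarray(v, dtype=float)
    if v.shape != (M.milestones.shape[1],):
        raise DimensionError(
            f"vector length {v.shape} does not match milestones {M.milestones.shape}"
        )
    lam = M.effective_lambda
    d2 = np.array([M.metric_d2(v, m) for m in M.milestones])
    # overflow-safe softmin weights
    d2min = d2.min()
    w = np.exp(-lam * (d2 - d2min))
    s_raw = float(np.sum(np.arange(1, M.n + 1) * w) / w.sum())
    z = float(d2min - np.log(w.sum()) / lam)
    a, b = M.affine
    return PoseCV(path_s=a + b * s_raw, path_z=z, d2=d2, s_raw=s_raw)


# -- ring flip --------------------------------------------------------------


def _plane_deviations(points: np.ndarray, probe: np.ndarray) -> np.ndarray:
    """Signed distances of probe points from the LSQ plane of *points*."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    normal = vt[2]
    return (probe - centroid) @ normal


def flip_state(
    model: MacromolecularModel,
    tyr_ref: ResidueRef,
    ligand_code: str = "U10",
    headgroup: Mapping | None = None,
    planarity_threshold: float = 0.4,
) -> FlipState:
    """Ring-flip of the quinone headgroup relative to the reactive Tyr.

    The six ring carbons define a least-squares plane; if any named ring
    substituent deviates from it by more than ``planarity_threshold`` the
    flip is undefined (bent headgroup).  Otherwise the state is "on" iff the
    5-methyl carbon is closer to the Tyr hydroxyl oxygen than the midpoint
    of the two methoxy oxygens.
    """
    names = dict(DEFAULT_HEADGROUP)
    if headgroup:
        names.update(headgroup)
    ring = select_atoms(model, ligand_code, list(names["ring"]))
    subst_names = [names["o1"], names["o4"], *names["methoxy_o"], names["methyl"]]
    subst = select_atoms(model, ligand_code, subst_names)
    tyr_oh = select_atoms(model, tyr_ref, ["OH"])[0]

    ring_pos = np.vstack([a.position for a in ring])
    subst_pos = np.vstack([a.position for a in subst])
    dev = float(np.abs(_plane_deviations(ring_pos, subst_pos)).max())
    if dev > planarity_threshold:
        return FlipState(value="undefined", planarity_dev=dev)
    methyl = subst[-1].position
    methoxy = np.vstack([a.position for a in select_atoms(model, ligand_code, list(names["methoxy_o"]))])
    mid = methoxy.mean(axis=0)
    on = np.linalg.norm(methyl - tyr_oh.position) < np.linalg.norm(mid - tyr_oh.position)
    return FlipState(value="on" if on else "off", planarity_dev=dev)


# -- superposition ----------------------------------------------------------


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) minimising |R Q + t - P|.

    Proper rotation (det +1) enforced by sign-correcting the smallest
    singular direction.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    return R, t


def _ca_map(model: MacromolecularModel, subunits: Sequence[str]) -> dict[tuple[str, int], np.ndarray]:
    out: dict[tuple[str, int], np.ndarray] = {}
    for a in model.atoms:
        if a.name == "CA" and a.subunit in subunits:
            out.setdefault((a.subunit, a.residue_number), a.position)
    return out


def superpose_and_rmsd(
    model_a: MacromolecularModel,
    model_b: MacromolecularModel,
    subunits: Sequence[str] = DEFAULT_RMSD_SUBUNITS,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Kabsch superposition of b onto a over common subunit C-alphas.

    Atom pairing is by (subunit, residue number); residues missing from
    either model are dropped.  Returns (rmsd in angstrom, R, t).
    """
    ca_a = _ca_map(model_a, subunits)
    ca_b = _ca_map(model_b, subunits)
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise SelectionError(
            f"only {len(common)} common C-alpha positions over {subunits}; need >= 3"
        )
    P = np.vstack([ca_a[k] for k in common])
    Q = np.vstack([ca_b[k] for k in common])
    R, t = kabsch(P, Q)
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return rmsd, R, t


def headgroup_displacement(
    model_a: MacromolecularModel,
    model_b: MacromolecularModel,
    align_on: str | Sequence[str] = "NDUFS2",
    ligand_code: str = "U10",
    ring_atoms: Sequence[str] = DEFAULT_HEADGROUP["ring"],
) -> float:
    """Distance (angstrom) between headgroup ring centroids after aligning
    model_b onto model_a on the C-alphas of *align_on*."""
    subunits = [align_on] if isinstance(align_on, str) else list(align_on)
    _, R, t = superpose_and_rmsd(model_a, model_b, subunits)

    def centroid(model: MacromolecularModel) -> np.ndarray:
        ring = select_atoms(model, ligand_code, list(ring_atoms))
        return np.vstack([a.position for a in ring]).mean(axis=0)

    ca = centroid(model_a)
    cb = R @ centroid(model_b) + t
    return float(np.linalg.norm(ca - cb))


# -- mode classification ----------------------------------------------------


def classify_mode(
    path_s: float,
    flip: FlipState | str,
    thresholds: tuple[float, float] = DEFAULT_MODE_THRESHOLDS,
) -> BindingMode:
    """Binding-mode label from the channel coordinate and flip state.

    on -> I; off -> J.1 / J.2 / K.2 split at the two Path.S thresholds;
    undefined (non-planar headgroup) -> K.1.
    """
    value = flip.value if isinstance(flip, FlipState) else flip
    if not np.isfinite(path_s):
        raise ValueError("path_s must be finite")
    t1, t2 = thresholds
    if value == "on":
        label = "I"
    elif value == "off":
        label = "J.1" if path_s <= t1 else ("J.2" if path_s <= t2 else "K.2")
    elif value == "undefined":
        label = "K.1"
    else:
        raise ValueError(f"unknown flip state {value!r}")
    return BindingMode(label=label, thresholds=thresholds)


def describe_pose(
    model: MacromolecularModel,
    reference_model: MacromolecularModel,
    M: MilestoneSet,
    tyr_ref: ResidueRef,
    q_species: str = "UQ_10",
    rmsd_subunits: Sequence[str] = DEFAULT_RMSD_SUBUNITS,
    headgroup: Mapping | None = None,
    mode_thresholds: tuple[float, float] = DEFAULT_MODE_THRESHOLDS,
) -> PoseDescriptor:
    """Full pose record: path CV, flip, reference RMSD and mode label."""
    v = distance_vector(model, M.qhead_atoms, M.ca_refs, ligand_code=M.ligand_code)
    cv = path_cv(v, M)
    flip = flip_state(model, tyr_ref, ligand_code=M.ligand_code, headgroup=headgroup)
    if model is reference_model:
        rmsd = 0.0
    else:
        rmsd, _, _ = superpose_and_rmsd(reference_model, model, rmsd_subunits)
    mode = classify_mode(cv.path_s, flip, mode_thresholds)
    return PoseDescriptor(
        structure_id=model.name,
        q_species=q_species,
        path_s=cv.path_s,
        path_z=cv.path_z,
        flip=flip,
        rmsd=rmsd,
        mode=mode,
    )
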