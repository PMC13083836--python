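"""Coordinate-model I/O and basic geometry for complex I structures.

Reads PDB / mmCIF files (via gemmi), resolves alternate locations to the
highest-occupancy conformer, maps author chain ids to complex I subunit names
(ND1..ND6, ND4L, NDUFS2, NDUFS7, ...) and provides deterministic atom
selection and distance measurement.  Hydrogens are dropped on input: every
cutoff used downstream (wire graph, probe test, hydrogen-bond window) is
heavy-atom based, as are the deposited models themselves.

Coordinates are in angstroms throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    ConfigurationError,
    IdentityError,
    MissingAtomError,
    ParseError,
    SelectionError,
    UsageError,
)

#: Component codes treated as water.
WATER_CODES = frozenset({"HOH", "WAT", "DOD"})

#: Ligand component codes the study's depositions contain (quinone/quinol,
#: detergents, nucleotides, lipids); anything hetero and non-water is kept
#: as a ligand regardless, this set only aids documentation and lookups.
KNOWN_LIGANDS = frozenset(
    {"U10", "UQ1", "DQN", "LMT", "NAI", "CHD", "3PE", "PC1", "CDL", "DGT", "WYK"}
)

UNMAPPED = "unmapped"


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a macromolecular model."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray  # shape (3,), angstrom
    occupancy: float
    b_factor: float
    is_hetero: bool
    subunit: str = UNMAPPED

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite or malformed position for atom {self.name}")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.name} has an empty element symbol")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class ResidueRef:
    """A residue addressed by subunit name + author residue number.

    ``resname`` is checked on resolution; a mismatch is an :class:`IdentityError`
    rather than a silent wrong selection.
    """

    subunit: str
    resnum: int
    resname: str
    atoms: tuple[str, ...] | None = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "ResidueRef":
        atoms = d.get("atoms")
        return cls(
            subunit=d["subunit"],
            resnum=int(d["resnum"]),
            resname=d["resname"].upper(),
            atoms=tuple(atoms) if atoms else None,
        )

    def __str__(self) -> str:
        return f"{self.resname}{self.resnum}^{self.subunit}"


class SubunitMap:
    """Injective mapping chain_id -> subunit name."""

    def __init__(self, chains: Mapping[str, str]):
        seen: dict[str, str] = {}
        for chain, subunit in chains.items():
            if subunit in seen.values():
                dup = [c for c, s in seen.items() if s == subunit]
                raise ConfigurationError(
                    f"subunit {subunit!r} mapped from both chain {dup[0]!r} and {chain!r}"
                )
            seen[chain] = subunit
        self.chains: dict[str, str] = dict(seen)

    def __getitem__(self, chain_id: str) -> str:
        return self.chains.get(chain_id, UNMAPPED)

    def __len__(self) -> int:
        return len(self.chains)

    def chain_for(self, subunit: str) -> str | None:
        for c, s in self.chains.items():
            if s == subunit:
                return c
        return None

    @classmethod
    def from_json(cls, path: str | Path) -> "SubunitMap":
        with open(path) as fh:
            data = json.load(fh)
        return cls(data["chains"])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"chains": self.chains}, fh, indent=1, sort_keys=True)


class MacromolecularModel:
    """Ordered heavy-atom records plus water / ligand partitions and an index."""

    def __init__(self, atoms: Sequence[AtomRecord], name: str = ""):
        self.name = name
        self.atoms: list[AtomRecord] = list(atoms)
        self._coords: np.ndarray | None = None
        self._rebuild_index()

    # -- construction -----------------------------------------------------

    def _rebuild_index(self) -> None:
        self._index: dict[tuple[str, int, str, str], int] = {}
        self._residues: dict[tuple[str, int, str], list[int]] = {}
        self.waters: list[int] = []
        self.ligands: dict[str, list[tuple[str, int, str]]] = {}
        seen_lig: set[tuple[str, int, str]] = set()
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_number, a.insertion_code, a.name)
            # alt-locs resolved at parse time: at most one atom per key
            self._index.setdefault(key, i)
            self._residues.setdefault(a.residue_key, []).append(i)
            if a.residue_name in WATER_CODES:
                self.waters.append(i)
            elif a.is_hetero:
                if a.residue_key not in seen_lig:
                    seen_lig.add(a.residue_key)
                    self.ligands.setdefault(a.residue_name, []).append(a.residue_key)
        self._coords = None

    # -- bulk geometry -----------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            if self.atoms:
                self._coords = np.vstack([a.position for a in self.atoms])
            else:
                self._coords = np.empty((0, 3))
        return self._coords

    def __len__(self) -> int:
        return len(self.atoms)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MacromolecularModel":
        """Return a rigidly moved copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        moved = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return MacromolecularModel(moved, name=self.name)

    # -- labelling ---------------------------------------------------------

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues_of_chain(self, chain_id: str) -> list[tuple[str, int, str]]:
        return [k for k in self._residues if k[0] == chain_id]

    def atom_indices_of_residue(self, key: tuple[str, int, str]) -> list[int]:
        return self._residues.get(key, [])

    def subunit_chain(self, subunit: str) -> str | None:
        for a in self.atoms:
            if a.subunit == subunit:
                return a.chain_id
        return None


def _gemmi_structure(path: str | Path, format: str | None) -> gemmi.Structure:
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"pdb": "pdb", ".pdb": "pdb", ".ent": "pdb", ".cif": "mmcif", ".mmcif": "mmcif"}.get(
            suffix, None
        )
        if format is None:
            raise UsageError(f"cannot infer format from suffix {suffix!r}; pass format=")
    if format not in ("pdb", "mmcif"):
        raise UsageError(f"unknown format {format!r}: expected 'pdb' or 'mmcif'")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse {path} as {format}: {exc}") from exc
    return st


def read_structure(
    path: str | Path,
    format: str | None = None,
    *,
    keep_hydrogens: bool = False,
) -> MacromolecularModel:
    """Load a coordinate file into a :class:`MacromolecularModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken alphabetically by alt-loc id).  Only the first model block
    of a multi-model file is read.  Hydrogens are dropped unless
    ``keep_hydrogens``.
    """
    st = _gemmi_structure(path, format)
    if len(st) == 0:
        raise ParseError(f"{path}: no model block found")
    if len(st) > 1:
        import warnings

        warnings.warn(f"{path}: {len(st)} model blocks; reading only the first")
    model = st[0]

    records: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            # group atoms by name to resolve alt-locs
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                if not keep_hydrogens and atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            for name, alts in by_name.items():
                best = max(alts, key=lambda a: (a.occ, -ord(a.altloc or "A")))
                if len(alts) > 1:
                    # highest occupancy wins; ties alphabetical
                    top = max(a.occ for a in alts)
                    tied = sorted(a.altloc or "" for a in alts if a.occ == top)
                    best = next(a for a in alts if a.occ == top and (a.altloc or "") == tied[0])
                serial += 1
                records.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=best.element.name.upper(),
                        alt_loc=best.altloc or "",
                        residue_name=residue.name.upper(),
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                        occupancy=min(max(best.occ, 0.0), 1.0),
                        b_factor=best.b_iso,
                        is_hetero=het,
                    )
                )
    return MacromolecularModel(records, name=Path(path).stem)


# -- subunit labelling ----------------------------------------------------

#: Keyword patterns in mmCIF/PDB entity descriptions -> core subunit names.
#: Matching is case-insensitive and the most specific pattern wins.
_ENTITY_PATTERNS: list[tuple[str, str]] = [
    ("chain 1", "ND1"), ("chain 2", "ND2"), ("chain 3", "ND3"),
    ("chain 4l", "ND4L"), ("chain 4", "ND4"), ("chain 5", "ND5"),
    ("chain 6", "ND6"),
    ("subunit 1", "ND1"), ("subunit 2", "ND2"), ("subunit 3", "ND3"),
    ("subunit 4l", "ND4L"), ("subunit 4", "ND4"), ("subunit 5", "ND5"),
    ("subunit 6", "ND6"),
    ("iron-sulfur protein 1", "NDUFS1"), ("iron-sulfur protein 2", "NDUFS2"),
    ("iron-sulfur protein 3", "NDUFS3"), ("iron-sulfur protein 7", "NDUFS7"),
    ("iron-sulfur protein 8", "NDUFS8"),
    ("flavoprotein 1", "NDUFV1"), ("flavoprotein 2", "NDUFV2"),
    ("75 kda", "NDUFS1"), ("49 kda", "NDUFS2"), ("30 kda", "NDUFS3"),
    ("20 kda", "NDUFS7"), ("psst", "NDUFS7"), ("tyky", "NDUFS8"),
    ("51 kda", "NDUFV1"), ("24 kda", "NDUFV2"),
]


def _match_entity(desc: str) -> str | None:
    desc = desc.lower()
    for pattern, subunit in _ENTITY_PATTERNS:
        if pattern in desc:
            return subunit
    return None


def _entity_chains_mmcif(path: Path) -> dict[str, str]:
    """chain_id -> description, from _entity / _entity_poly loops."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    desc_by_id: dict[str, str] = {}
    for row in block.find("_entity.", ["id", "pdbx_description"]):
        desc_by_id[row.str(0)] = row.str(1)
    out: dict[str, str] = {}
    for row in block.find("_entity_poly.", ["entity_id", "pdbx_strand_id"]):
        desc = desc_by_id.get(row.str(0), "")
        for chain in row.str(1).replace(" ", "").split(","):
            if chain:
                out.setdefault(chain, desc)
    return out


def _entity_chains_pdb(path: Path) -> dict[str, str]:
    """chain_id -> description, from COMPND MOL_ID/MOLECULE/CHAIN records."""
    mols: list[dict[str, str]] = []
    text = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("COMPND"):
                text += line[10:].rstrip("\n").rstrip()
    for part in text.split("MOL_ID:"):
        if not part.strip():
            continue
        fields: dict[str, str] = {}
        for item in part.split(";"):
            if ":" in item:
                k, v = item.split(":", 1)
                fields[k.strip().upper()] = v.strip()
        mols.append(fields)
    out: dict[str, str] = {}
    for m in mols:
        desc = m.get("MOLECULE", "")
        for chain in m.get("CHAIN", "").replace(" ", "").split(","):
            if chain:
                out.setdefault(chain, desc)
    return out


def guess_subunit_map(path: str | Path, format: str | None = None) -> SubunitMap:
    """Build a chain -> subunit map from the file's entity descriptions.

    Deposited complex I entries carry entity names such as "NADH-ubiquinone
    oxidoreductase chain 1" (ND1) or "NADH dehydrogenase [ubiquinone]
    iron-sulfur protein 2" (NDUFS2); the chain correspondence is not printed
    anywhere else, so it is recovered from the header.  Chains whose entity
    description matches no pattern are left out of the map (their atoms stay
    "unmapped").
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "mmcif"
    if format == "mmcif":
        chain_desc = _entity_chains_mmcif(path)
    elif format == "pdb":
        chain_desc = _entity_chains_pdb(path)
    else:
        raise UsageError(f"unknown format {format!r}")
    chains: dict[str, str] = {}
    assigned: set[str] = set()
    for chain, desc in chain_desc.items():
        hit = _match_entity(desc)
        if hit and hit not in assigned:
            assigned.add(hit)
            chains[chain] = hit
    return SubunitMap(chains)


def apply_subunit_map(model: MacromolecularModel, smap: SubunitMap) -> MacromolecularModel:
    """Return a copy of *model* in which every atom carries a subunit label.

    Chains absent from the map are labelled "unmapped"; chains named in the
    map but absent from the model raise a :class:`ConfigurationError`.
    """
    present = set(model.chain_ids())
    missing = sorted(set(smap.chains) - present)
    if missing:
        raise ConfigurationError(f"mapped chains absent from model: {missing}")
    labelled = [replace(a, subunit=smap[a.chain_id]) for a in model.atoms]
    out = MacromolecularModel(labelled, name=model.name)
    return out


# -- selection and geometry -----------------------------------------------


def _resolve_residue(
    model: MacromolecularModel, ref: ResidueRef
) -> list[int]:
    cands = [
        i
        for i, a in enumerate(model.atoms)
        if a.subunit == ref.subunit and a.residue_number == ref.resnum
    ]
    if not cands:
        raise SelectionError(f"residue {ref} not found (is the subunit map applied?)")
    resnames = {model.atoms[i].residue_name for i in cands}
    if ref.resname not in resnames:
        raise IdentityError(
            f"residue {ref.subunit}/{ref.resnum} is {sorted(resnames)}, expected {ref.resname}"
        )
    return [i for i in cands if model.atoms[i].residue_name == ref.resname]


def select_atoms(
    model: MacromolecularModel,
    ref: ResidueRef | str,
    atom_names: Sequence[str] | None = None,
) -> list[AtomRecord]:
    """Select atoms by residue reference or ligand component code.

    Returns the atoms in model order; an empty selection raises rather than
    silently succeeding.
    """
    if isinstance(ref, ResidueRef):
        idx = _resolve_residue(model, ref)
        names = atom_names if atom_names is not None else ref.atoms
    else:
        code = ref.upper()
        keys = model.ligands.get(code)
        if not keys:
            raise SelectionError(f"no ligand with component code {code!r} in model")
        idx = [i for key in keys for i in model.atom_indices_of_residue(key)]
        names = atom_names
    if names is not None:
        found = {model.atoms[i].name: i for i in idx}
        missing = [n for n in names if n not in found]
        if missing:
            raise MissingAtomError(
                f"atoms {missing} absent from selection {ref} (have {sorted(found)})"
            )
        idx = [found[n] for n in names]
    if not idx:
        raise SelectionError(f"selection {ref} resolved to no atoms")
    return [model.atoms[i] for i in idx]


def measure_distance(
    model: MacromolecularModel,
    a: ResidueRef | str | AtomRecord,
    b: ResidueRef | str | AtomRecord,
    atom_a: str | None = None,
    atom_b: str | None = None,
) -> float:
    """Euclidean distance in angstrom between two single-atom specs."""

    def one(spec, atom_name) -> AtomRecord:
        if isinstance(spec, AtomRecord):
            return spec
        sel = select_atoms(model, spec, [atom_name] if atom_name else None)
        if len(sel) != 1:
            raise SelectionError(f"spec {spec} resolves to {len(sel)} atoms; expected 1")
        return sel[0]

    pa = one(a, atom_a).position
    pb = one(b, atom_b).position
    return float(np.linalg.norm(pa - pb))
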