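"""Rendering of connectivity matrices and pose tables.

The connectivity table uses the field's glyph convention: a filled circle
for a connected segment, an open circle for a disconnected segment whose
gaps are all sterically passable, and an X for a segment with at least one
obstructed gap (ASCII fallback: C / O / X).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import QwireError
from .pose import PoseDescriptor
from .wires import SegmentResult

GLYPHS = {"connected": "●", "open_gap": "○", "obstructed_gap": "X", "error": "?"}
ASCII_GLYPHS = {"connected": "C", "open_gap": "O", "obstructed_gap": "X", "error": "?"}

TABLE2_COLUMNS = [
    "Model", "PDB", "Q", "NADH", "Preparation",
    "RMSD", "Path.S", "Path.Z", "Ring-flip", "Mode",
]


@dataclass
class RunConfig:
    """Validated CLI/run configuration."""

    structures: list[Path] = field(default_factory=list)
    subunit_map: Path | None = None
    pathway: Path | None = None
    milestones: Path | None = None
    out_dir: Path = Path(".")
    r_c: float = 4.0
    probe_radius: float = 1.4
    lateral_search: float = 2.0
    hbond_window: tuple[float, float] = (2.4, 3.4)
    mode_thresholds: tuple[float, float] = (23.40, 23.85)
    seed: int = 0
    verbosity: int = 0

    def validate(self) -> None:
        for p in [*self.structures, self.subunit_map, self.pathway, self.milestones]:
            if p is not None and not Path(p).exists():
                raise QwireError(f"configured file does not exist: {p}")
        if self.r_c <= 0 or self.probe_radius <= 0 or self.lateral_search <= 0:
            raise QwireError("thresholds must be positive")


def _result_to_dict(r: SegmentResult) -> dict:
    return {
        "state": r.state,
        "error": r.error,
        "witness": [f"{n.resname}{n.resnum}:{n.name}" for n in r.witness],
        "gaps": [
            {
                "u": f"{g.u.resname}{g.u.resnum}:{g.u.name}",
                "v": f"{g.v.resname}{g.v.resnum}:{g.v.name}",
                "distance": round(g.distance, 2),
                "verdict": g.verdict,
                "blockers": [f"{b.residue_name}{b.residue_number}:{b.name}" for b in g.blockers],
            }
            for g in r.gaps
        ],
    }


def render_table1(
    results: Mapping[str, Sequence[SegmentResult]],
    ascii_glyphs: bool = False,
) -> tuple[str, dict]:
    """Glyph matrix (rows = structures, columns = segment codes) + JSON dict."""
    glyphs = ASCII_GLYPHS if ascii_glyphs else GLYPHS
    names = list(results)
    if not names:
        return "", {}
    columns = [r.spec.code for r in results[names[0]]]
    for name in names[1:]:
        cols = [r.spec.code for r in results[name]]
        if cols != columns:
            raise QwireError(
                f"inconsistent segment columns: {name} has {cols}, expected {columns}"
            )
    width = max([len(c) for c in columns], default=1)
    name_w = max((len(n) for n in names), default=1)
    lines = [" " * name_w + "  " + " ".join(c.rjust(width) for c in columns)]
    payload: dict = {}
    for name in names:
        row = results[name]
        lines.append(
            name.ljust(name_w)
            + "  "
            + " ".join(glyphs[r.state].rjust(width) for r in row)
        )
        payload[name] = {r.spec.code: _result_to_dict(r) for r in row}
    return "\n".join(lines), payload


def table1_json(results: Mapping[str, Sequence[SegmentResult]]) -> str:
    _, payload = render_table1(results)
    return json.dumps(payload, indent=1, sort_keys=True)


def render_table2(
    descriptors: Sequence[PoseDescriptor],
    metadata: Mapping[str, Mapping] | None = None,
) -> str:
    """CSV with fixed columns; RMSD to 2 dp, Path.S to 1 dp, Path.Z to 2 dp."""
    flips = {"on": "On", "off": "Off", "undefined": "-"}
    rows = []
    for i, d in enumerate(descriptors, start=1):
        meta = (metadata or {}).get(d.structure_id, {})
        rows.append(
            {
                "Model": meta.get("model", i),
                "PDB": meta.get("pdb", d.structure_id),
                "Q": d.q_species,
                "NADH": meta.get("nadh", ""),
                "Preparation": meta.get("preparation", ""),
                "RMSD": f"{d.rmsd:.2f}",
                "Path.S": f"{d.path_s:.1f}",
                "Path.Z": f"{d.path_z:.2f}",
                "Ring-flip": flips[d.flip.value],
                "Mode": d.mode.label,
            }
        )
    df = pd.DataFrame(rows, columns=TABLE2_COLUMNS)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()
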