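"""Brute-force reference computations.

These deliberately naive routines (all-pairs distance filters, adjacency
matrix powers, dense probe-placement grids, exhaustive route enumeration)
are independent of the production code paths in :mod:`qwire.wires`.  The
fixture generator re-verifies its declared ground truth against them before
returning, and the test suite uses them as oracles.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

from .structure import MacromolecularModel
from .wires import WATER_CODES, WireNode, load_vdw_radii


def brute_force_edges(nodes: Sequence[WireNode], r_c: float) -> set[tuple[int, int]]:
    """All node pairs within r_c, by O(n^2) scan."""
    out: set[tuple[int, int]] = set()
    for i, j in combinations(range(len(nodes)), 2):
        if np.linalg.norm(nodes[i].position - nodes[j].position) <= r_c:
            out.add((i, j))
    return out


def reachable_bruteforce(adjacency: np.ndarray, sources: Sequence[int], targets: Sequence[int]) -> bool:
    """Reachability via boolean matrix powers (transitive closure)."""
    A = adjacency.astype(bool) | np.eye(len(adjacency), dtype=bool)
    R = A.copy()
    for _ in range(len(A)):
        nxt = R @ A
        if (nxt == R).all():
            break
        R = nxt
    return bool(R[np.ix_(sources, targets)].any())


def probe_verdict_grid(
    model: MacromolecularModel,
    u: WireNode,
    v: WireNode,
    probe_radius: float = 1.4,
    lateral_search: float = 2.0,
    step: float = 0.5,
    grid: float = 0.1,
    vdw: dict | None = None,
) -> str:
    """Dense-grid probe placement test ('open' / 'obstructed')."""
    radii, default_r = load_vdw_radii()
    if vdw:
        radii = {**radii, **{k.upper(): float(val) for k, val in vdw.items()}}
    p0, p1 = u.position, v.position
    length = float(np.linalg.norm(p1 - p0))
    n_samples = max(2, int(np.ceil(length / step)) + 1)
    ts = np.linspace(0.0, 1.0, n_samples)
    excluded = {u.residue_key, v.residue_key}
    obstacles = [
        a
        for a in model.atoms
        if a.residue_name not in WATER_CODES and a.residue_key not in excluded
    ]
    if not obstacles:
        return "open"
    opos = np.vstack([a.position for a in obstacles])
    orad = np.array([radii.get(a.element, default_r) for a in obstacles])

    ax = np.arange(-lateral_search, lateral_search + grid / 2, grid)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    offsets = offsets[np.linalg.norm(offsets, axis=1) <= lateral_search]

    for t in ts:
        point = p0 + t * (p1 - p0)
        centres = point[None, :] + offsets
        ok = np.ones(len(centres), dtype=bool)
        for k in range(len(obstacles)):
            d = np.linalg.norm(centres - opos[k], axis=1)
            ok &= d >= orad[k] + probe_radius
            if not ok.any():
                break
        if not ok.any():
            return "obstructed"
    return "open"


def min_total_gap_routes(
    positions: np.ndarray,
    component_of: Sequence[int],
    a_comps: set[int],
    b_comps: set[int],
) -> tuple[float, list[tuple[int, int]]]:
    """Exhaustively enumerate simple routes through the component condensation
    and return (minimal total gap length, its gap endpoint node pairs).

    Only feasible for small node counts; used as the oracle for the Dijkstra
    route in production code.
    """
    comps = sorted(set(component_of))
    best: dict[tuple[int, int], tuple[float, int, int]] = {}
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            ci, cj = component_of[i], component_of[j]
            if ci == cj:
                continue
            key = (min(ci, cj), max(ci, cj))
            d = float(np.linalg.norm(positions[i] - positions[j]))
            if key not in best or d < best[key][0]:
                best[key] = (d, i, j)

    best_total = np.inf
    best_gaps: list[tuple[int, int]] = []

    def walk(current: int, visited: set[int], total: float, gaps: list[tuple[int, int]]):
        nonlocal best_total, best_gaps
        if total >= best_total:
            return
        if current in b_comps:
            best_total = total
            best_gaps = list(gaps)
            return
        for nxt in comps:
            if nxt in visited:
                continue
            key = (min(current, nxt), max(current, nxt))
            if key not in best:
                continue
            d, i, j = best[key]
            if component_of[i] != current:
                i, j = j, i
            walk(nxt, visited | {nxt}, total + d, gaps + [(i, j)])

    for start in a_comps:
        if start in b_comps:
            return 0.0, []
        walk(start, {start}, 0.0, [])
    return best_total, best_gaps


def path_cv_reference(v: np.ndarray, milestones: np.ndarray, lam: float, metric: str = "mean"):
    """Direct long-double evaluation of the path-CV formulas."""
    v = np.asarray(v, dtype=np.longdouble)
    ms = np.asarray(milestones, dtype=np.longdouble)
    diffs2 = np.square(v[None, :] - ms)
    d2 = diffs2.mean(axis=1) if metric == "mean" else diffs2.sum(axis=1)
    w = np.exp(-np.longdouble(lam) * d2)
    idx = np.arange(1, len(ms) + 1, dtype=np.longdouble)
    s = float((idx * w).sum() / w.sum())
    z = float(-np.log(w.sum()) / np.longdouble(lam))
    return s, z
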