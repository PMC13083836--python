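"""Desk-scale well-tempered metadynamics over a low-dimensional CV space.

The biasing protocol mirrors the enhanced-sampling setup used for the
quinol/channel free-energy calculations: Gaussian kernels deposited every
``pace`` integrator steps (500 x 2 fs = 1 ps), initial height 0.6 kJ/mol,
per-dimension widths (0.4 CV units, 0.02 rad for a dihedral), bias factor
gamma = 15 at T = 310 K, and half-harmonic walls (k = 10,000 kJ/mol/nm)
restricting the channel coordinate to 21.0 < s < 26.0 (and, when a second
dimension is used, -0.245 < z < -0.220 nm^2).

Well-tempered deposition scales each new kernel by

    h = h0 * exp(-V_bias(cv) / (k_B * dT)),        dT = (gamma - 1) T,

and the free-energy estimate is the standard well-tempered relation

    F(cv) = -(T + dT)/dT * V_bias(cv),   shifted so min F = 0.

The underlying dynamics are a surrogate: overdamped Langevin moves directly
in CV space on U + V_bias + walls (the real system's all-atom dynamics are
out of scope here); only the biasing protocol itself is reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DimensionError, StabilityError, StateError

KB = 0.008314462618  # kJ mol^-1 K^-1


@dataclass
class WTMetaParams:
    """Protocol parameters of the well-tempered metadynamics runs."""

    height0: float = 0.6  # kJ/mol
    pace: int = 500  # steps between depositions (1 ps at dt = 2 fs)
    widths: tuple[float, ...] = (0.4,)  # per-dimension Gaussian sigma
    bias_factor: float = 15.0  # gamma
    temperature: float = 310.0  # K
    walls: tuple[tuple[float, float] | None, ...] = ((21.0, 26.0),)
    wall_k: float = 10000.0  # kJ/mol per (CV unit)^2, half-harmonic
    dt: float = 0.002  # ps ("2 fs-equivalent")
    friction: float = 25.0  # kJ/mol ps / (CV unit)^2

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if self.height0 < 0 or any(w <= 0 for w in self.widths) or self.wall_k <= 0:
            raise ValueError("height0, widths and wall force constant must be positive")
        if len(self.walls) != len(self.widths):
            raise DimensionError("walls and widths must have the same dimensionality")

    @property
    def ndim(self) -> int:
        return len(self.widths)

    @property
    def delta_t(self) -> float:
        return (self.bias_factor - 1.0) * self.temperature

    @property
    def kbt(self) -> float:
        return KB * self.temperature


@dataclass(frozen=True)
class GaussianKernel:
    centre: np.ndarray
    widths: np.ndarray
    height: float  # kJ/mol, deposited (well-tempered) height
    time: float  # ps


class BiasPotential:
    """Sum of deposited Gaussian kernels plus the wall terms."""

    def __init__(self, params: WTMetaParams, capacity: int = 0):
        self.params = params
        d = params.ndim
        cap = max(capacity, 16)
        self._centres = np.empty((cap, d))
        self._heights = np.empty(cap)
        self._times = np.empty(cap)
        self.n_kernels = 0

    def _grow(self) -> None:
        self._centres = np.vstack([self._centres, np.empty_like(self._centres)])
        self._heights = np.concatenate([self._heights, np.empty_like(self._heights)])
        self._times = np.concatenate([self._times, np.empty_like(self._times)])

    def deposit(self, centre: np.ndarray, height: float, time: float) -> GaussianKernel:
        if self.n_kernels == len(self._heights):
            self._grow()
        i = self.n_kernels
        self._centres[i] = centre
        self._heights[i] = height
        self._times[i] = time
        self.n_kernels += 1
        return GaussianKernel(
            centre=np.array(centre), widths=np.array(self.params.widths), height=height, time=time
        )

    @property
    def kernels(self) -> list[GaussianKernel]:
        w = np.asarray(self.params.widths)
        return [
            GaussianKernel(self._centres[i].copy(), w.copy(), float(self._heights[i]), float(self._times[i]))
            for i in range(self.n_kernels)
        ]

    # -- evaluation (kernel part only; walls are separate) -----------------

    def value(self, x: np.ndarray, n_kernels: int | None = None) -> float:
        n = self.n_kernels if n_kernels is None else n_kernels
        if n == 0:
            return 0.0
        w = np.asarray(self.params.widths)
        z = (np.asarray(x, float)[None, :] - self._centres[:n]) / w[None, :]
        return float(np.sum(self._heights[:n] * np.exp(-0.5 * np.sum(z * z, axis=1))))

    def value_many(self, points: np.ndarray, n_kernels: int | None = None) -> np.ndarray:
        n = self.n_kernels if n_kernels is None else n_kernels
        points = np.atleast_2d(np.asarray(points, float))
        if n == 0:
            return np.zeros(len(points))
        w = np.asarray(self.params.widths)
        out = np.zeros(len(points))
        # chunked over kernels to bound memory
        step = max(1, int(2e7 // max(len(points), 1)))
        for s in range(0, n, step):
            e = min(n, s + step)
            z = (points[:, None, :] - self._centres[None, s:e, :]) / w[None, None, :]
            out += np.exp(-0.5 * np.sum(z * z, axis=2)) @ self._heights[s:e]
        return out

    def gradient(self, x: np.ndarray) -> np.ndarray:
        n = self.n_kernels
        x = np.asarray(x, float)
        if n == 0:
            return np.zeros_like(x)
        w = np.asarray(self.params.widths)
        diff = x[None, :] - self._centres[:n]
        z = diff / w[None, :]
        g = self._heights[:n] * np.exp(-0.5 * np.sum(z * z, axis=1))
        return -np.sum(g[:, None] * diff / (w * w)[None, :], axis=0)


# -- walls ------------------------------------------------------------------


def wall_energy(cv: np.ndarray, params: WTMetaParams) -> float:
    """Half-harmonic restraint: (1/2) k (excess)^2 beyond each bound."""
    cv = np.atleast_1d(np.asarray(cv, float))
    e = 0.0
    for xi, wall in zip(cv, params.walls):
        if wall is None:
            continue
        lo, hi = wall
        if xi < lo:
            e += 0.5 * params.wall_k * (lo - xi) ** 2
        elif xi > hi:
            e += 0.5 * params.wall_k * (xi - hi) ** 2
    return e


def wall_gradient(cv: np.ndarray, params: WTMetaParams) -> np.ndarray:
    cv = np.atleast_1d(np.asarray(cv, float))
    g = np.zeros_like(cv)
    for i, (xi, wall) in enumerate(zip(cv, params.walls)):
        if wall is None:
            continue
        lo, hi = wall
        if xi < lo:
            g[i] = -params.wall_k * (lo - xi)
        elif xi > hi:
            g[i] = params.wall_k * (xi - hi)
    return g


# -- the engine -------------------------------------------------------------


@dataclass
class Trajectory:
    """CV trajectory with deposition bookkeeping."""

    positions: np.ndarray  # (n_steps + 1, ndim)
    times: np.ndarray  # ps
    heights: np.ndarray  # deposited kernel heights, in order
    seed: int


def run_wt_metadynamics(
    potential,
    params: WTMetaParams,
    n_steps: int,
    seed: int,
    x0: Sequence[float] | None = None,
) -> tuple[Trajectory, BiasPotential]:
    """Overdamped Langevin on U + V_bias + walls with WT deposition.

    ``potential`` must expose ``value(x) -> float`` and
    ``gradient(x) -> ndarray``.  With ``height0 = 0`` this is plain Langevin
    sampling of the Boltzmann distribution of U inside the walls.
    Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    d = params.ndim
    if x0 is None:
        x0 = [0.5 * (w[0] + w[1]) if w else 0.0 for w in params.walls]
    x = np.array(x0, dtype=float)
    if x.shape != (d,):
        raise DimensionError(f"x0 has shape {x.shape}, expected ({d},)")

    bias = BiasPotential(params, capacity=max(n_steps // max(params.pace, 1) + 1, 16))
    traj = np.empty((n_steps + 1, d))
    traj[0] = x
    heights: list[float] = []

    mob = params.dt / params.friction
    noise_sigma = np.sqrt(2.0 * params.kbt * params.dt / params.friction)
    # divergence guard: a step larger than the walled-domain width (or 1e3)
    widths = [
        (w[1] - w[0]) if w else np.inf for w in params.walls
    ]
    max_step = max(1e3 if not np.isfinite(min(widths)) else max(widths), 1e-6)

    kbdt = KB * params.delta_t
    noise = rng.standard_normal((n_steps, d)) * noise_sigma
    for step in range(n_steps):
        if params.height0 > 0 and step % params.pace == 0:
            h = params.height0 * np.exp(-bias.value(x) / kbdt)
            bias.deposit(x.copy(), float(h), step * params.dt)
            heights.append(float(h))
        g = potential.gradient(x) + bias.gradient(x) + wall_gradient(x, params)
        dx = -mob * g + noise[step]
        if np.any(np.abs(dx) > max_step):
            raise StabilityError(
                f"step {step}: |dx| = {np.abs(dx).max():.3g} exceeds the domain width; "
                "reduce dt or increase friction"
            )
        x = x + dx
        traj[step + 1] = x

    trajectory = Trajectory(
        positions=traj,
        times=np.arange(n_steps + 1) * params.dt,
        heights=np.array(heights),
        seed=seed,
    )
    return trajectory, bias


# -- FES estimation, reweighting, convergence -------------------------------


@dataclass
class FESEstimate:
    grid: np.ndarray  # (n_points, ndim) or (n_points,) for 1-D
    values: np.ndarray  # kJ/mol, min = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free energy estimate contains non-finite values")


def estimate_fes(
    bias: BiasPotential,
    params: WTMetaParams,
    grid: np.ndarray,
    n_kernels: int | None = None,
) -> FESEstimate:
    """F(cv) = -(T + dT)/dT * V_bias(cv), shifted to min 0 on the grid."""
    if bias.n_kernels == 0:
        raise StateError("no kernels deposited; cannot estimate a free energy")
    pts = np.asarray(grid, float)
    flat = pts[:, None] if pts.ndim == 1 else pts
    factor = (params.temperature + params.delta_t) / params.delta_t
    f = -factor * bias.value_many(flat, n_kernels=n_kernels)
    f -= f.min()
    return FESEstimate(grid=pts, values=f)


def fes_from_histogram(
    trajectory: Trajectory,
    bias: BiasPotential,
    params: WTMetaParams,
    edges: np.ndarray,
    dim: int = 0,
    burn_in: float = 0.5,
    stride: int = 100,
) -> FESEstimate:
    """Free-energy profile from the reweighted visit histogram.

    Frames after ``burn_in`` (fraction of the run) are weighted by
    exp(+V_bias/k_B T) under the final bias and binned along CV dimension
    ``dim``; F = -k_B T ln(weighted histogram), shifted to min 0.  Unlike
    the running bias-potential estimate this is free of kernel-width
    smoothing, so it resolves features sharper than the deposition width;
    empty bins are dropped from the returned grid.
    """
    pos = trajectory.positions[int(burn_in * len(trajectory.positions)) :: stride]
    if len(pos) == 0:
        raise StateError("no frames left after burn-in")
    logw = bias.value_many(pos) / params.kbt
    logw -= logw.max()
    hist, _ = np.histogram(pos[:, dim], bins=np.asarray(edges, float), weights=np.exp(logw))
    centres = 0.5 * (edges[:-1] + edges[1:])
    mask = hist > 0
    f = -params.kbt * np.log(hist[mask])
    f -= f.min()
    return FESEstimate(grid=centres[mask], values=f)


def recover_fes_multirun(
    potential,
    params: WTMetaParams,
    n_steps: int,
    n_runs: int,
    seed: int,
    edges: np.ndarray,
    dim: int = 0,
    burn_in: float = 0.5,
    stride: int = 20,
) -> FESEstimate:
    """Pooled free-energy profile from independent metadynamics runs.

    Runs ``n_runs`` independent walkers (seeds derived deterministically
    from ``seed``), reweights each run's post-burn-in frames under its own
    final bias, normalises each run's weights to unit mass so every walker
    contributes equally, and sums the weighted histograms before taking
    F = -k_B T ln(rho).  Averaging over walkers suppresses the ripple a
    single history-dependent bias leaves in the profile.
    """
    edges = np.asarray(edges, float)
    pooled = np.zeros(len(edges) - 1)
    children = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    for child in children:
        traj, bias = run_wt_metadynamics(potential, params, n_steps=n_steps, seed=int(child))
        pos = traj.positions[int(burn_in * len(traj.positions)) :: stride]
        logw = bias.value_many(pos) / params.kbt
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        hist, _ = np.histogram(pos[:, dim], bins=edges, weights=w)
        pooled += hist
    centres = 0.5 * (edges[:-1] + edges[1:])
    mask = pooled > 0
    f = -params.kbt * np.log(pooled[mask])
    f -= f.min()
    return FESEstimate(grid=centres[mask], values=f)


def reweight_observable(
    trajectory: Trajectory,
    bias: BiasPotential,
    observable: Callable[[np.ndarray], float],
    params: WTMetaParams,
    n_bootstrap: int = 200,
    burn_in: float = 0.0,
    stride: int = 1,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Unbias an observable with final-bias weights w ~ exp(+V_bias/kBT).

    Returns (expectation, bootstrap confidence interval).  ``stride``
    subsamples the trajectory so the bootstrap resamples approximately
    decorrelated frames; with stride 1 on a strongly autocorrelated
    trajectory the interval is too narrow.
    """
    pos = trajectory.positions
    start = int(burn_in * len(pos))
    pos = pos[start::stride]
    obs = np.array([observable(x) for x in pos])
    if bias.n_kernels == 0:
        logw = np.zeros(len(pos))
    else:
        logw = bias.value_many(pos) / params.kbt
    logw -= logw.max()
    w = np.exp(logw)
    if w.sum() == 0 or not np.all(np.isfinite(w)):
        raise StateError("reweighting weights underflowed to zero")
    w /= w.sum()
    mean = float(np.sum(w * obs))
    if np.allclose(obs, obs[0]):
        return mean, (mean, mean)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    n = len(obs)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        wb = w[idx]
        boots[b] = np.sum(wb * obs[idx]) / wb.sum()
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return mean, (float(lo), float(hi))


def convergence_check(
    fes_snapshots: Sequence[FESEstimate], ref_index: int = 0
) -> np.ndarray:
    """Max |change of F(cv) - F(cv_ref)| between consecutive snapshots.

    Offset-invariant: snapshots differing by a constant report zero.
    """
    if len(fes_snapshots) < 2:
        raise StateError("need at least two snapshots")
    grids = [np.asarray(s.grid) for s in fes_snapshots]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise DimensionError("snapshots evaluated on different grids")
    out = []
    for a, b in zip(fes_snapshots, fes_snapshots[1:]):
        da = a.values - a.values[ref_index]
        db = b.values - b.values[ref_index]
        out.append(float(np.abs(db - da).max()))
    return np.array(out)
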