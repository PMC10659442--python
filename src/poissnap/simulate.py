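"""Snapshot generators for the birth-death-diffusion process.

Two routes to the same observation model:

* :func:`simulate_snapshot_trajectories` integrates actual particle paths
  (Euler-Maruyama with Brownian-bridge absorption) and observes survivors at
  the snapshot instant.  This is the mechanistic oracle: its output should be
  statistically indistinguishable from a Poisson point process with the
  closed-form intensity.
* :func:`sample_snapshot_direct` draws from that Poisson point process
  directly (Poisson count, then iid positions by inverse CDF), which is what
  inference experiments use.

Births form a stationary Poisson process on the time axis before the
snapshot.  The infinite past is truncated at a horizon T0 chosen so that a
particle born earlier survives to the snapshot with probability below
``burn_in_tol``: the slowest decay mode of survival is ``mu + pi^2/L^2``
(death rate plus the leading Dirichlet eigenvalue of the Laplacian), so
``T0 = -log(burn_in_tol) / (mu + pi^2/L^2)``.

Only particles whose exponential lifetime exceeds their age at the snapshot
can be observed, so the generator thins births by survival probability first
and integrates paths only for the survivors-by-lifetime; this is exact
(Poisson thinning) and much cheaper than simulating doomed particles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .model import CellGeometry, NondimParams, expected_count, intensity_shape

__all__ = [
    "SimOptions",
    "Snapshot",
    "SnapshotSet",
    "simulate_snapshot_trajectories",
    "sample_snapshot_direct",
    "simulate_snapshot_set",
]


@dataclass(frozen=True)
class SimOptions:
    """Trajectory-simulation controls.

    dt : Euler-Maruyama time step (nondimensional time).
    burn_in_tol : survival probability below which pre-horizon births are
        neglected; sets the history horizon T0.
    bridge_correction : apply the within-step Brownian-bridge absorption
        probability (removes the O(sqrt(dt)) discrete-crossing bias).
    seed : RNG seed.
    """

    dt: float = 1e-4
    burn_in_tol: float = 1e-7
    bridge_correction: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not 0 < self.burn_in_tol < 1:
            raise ValueError("burn_in_tol must be in (0, 1)")


@dataclass(frozen=True)
class Snapshot:
    """Observed particle positions in one cell at the snapshot instant."""

    cell_id: str
    geom: CellGeometry
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1:
            raise ValueError("positions must be a 1D array")
        if pos.size and (pos.min() <= 0 or pos.max() >= self.geom.L):
            raise ValueError("positions must be strictly interior to (0, L)")
        object.__setattr__(self, "positions", pos)

    @property
    def count(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class SnapshotSet:
    """A study of M cells: one snapshot per cell, unique cell ids."""

    snapshots: tuple[Snapshot, ...]

    def __post_init__(self) -> None:
        snaps = tuple(self.snapshots)
        ids = [s.cell_id for s in snaps]
        if len(set(ids)) != len(ids):
            raise ValueError("cell ids must be unique")
        object.__setattr__(self, "snapshots", snaps)

    @property
    def M(self) -> int:
        return len(self.snapshots)

    @property
    def total_count(self) -> int:
        return sum(s.count for s in self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __len__(self) -> int:
        return self.M


def history_horizon(mu: float, L: float, burn_in_tol: float) -> float:
    """Truncation time T0 of the stationary birth process before the snapshot."""
    return -np.log(burn_in_tol) / (mu + np.pi**2 / L**2)


def _check_theta(theta: NondimParams) -> None:
    if not (np.isfinite(theta.lam) and np.isfinite(theta.mu)):
        raise ValueError("non-finite parameters")


def simulate_snapshot_trajectories(
    theta: NondimParams,
    geom: CellGeometry,
    opts: SimOptions | None = None,
    rng: np.random.Generator | None = None,
    cell_id: str = "cell0",
) -> Snapshot:
    """Trajectory-level snapshot: integrate paths, observe survivors at t = 0.

    Each retained birth (age ``a``, kept with the exact thinning probability
    ``exp(-mu a)``) starts at the source ``z`` and takes Brownian steps of
    variance ``2 dt``; it is removed on stepping outside ``(0, L)`` or, with
    the bridge correction on, with within-step wall-crossing probability
    ``exp(-d1 d2 / dt)`` per wall (bridge crossing for increment variance
    ``2 dt``).
    """
    opts = opts or SimOptions()
    _check_theta(theta)
    if rng is None:
        rng = np.random.default_rng(opts.seed)
    lam, mu = theta.lam, theta.mu
    L, z = geom.L, geom.z
    dt = opts.dt
    if mu > 0 and dt >= 1.0 / mu or dt >= (L / 10.0) ** 2:
        warnings.warn("coarse time step: dt close to lifetime or domain scale", stacklevel=2)

    if lam == 0:
        return Snapshot(cell_id=cell_id, geom=geom, positions=np.empty(0))

    T0 = history_horizon(mu, L, opts.burn_in_tol)
    # Thinned births: only particles whose lifetime exceeds their age can be
    # observed; their ages follow density ~ exp(-mu a) on [0, T0].
    if mu > 0:
        mean_kept = lam * (1.0 - np.exp(-mu * T0)) / mu
    else:
        mean_kept = lam * T0
    n_kept = rng.poisson(mean_kept)
    if n_kept == 0:
        return Snapshot(cell_id=cell_id, geom=geom, positions=np.empty(0))
    u01 = rng.random(n_kept)
    if mu > 0:
        ages = -np.log1p(-u01 * (1.0 - np.exp(-mu * T0))) / mu
    else:
        ages = u01 * T0

    survivors: list[float] = []
    sqrt2dt = np.sqrt(2.0 * dt)
    for a in ages:
        n_steps = int(a / dt)
        rem = a - n_steps * dt
        incr = rng.standard_normal(n_steps + 1)
        incr[:n_steps] *= sqrt2dt
        incr[n_steps] *= np.sqrt(2.0 * max(rem, 0.0))
        path = z + np.cumsum(incr)
        out = (path <= 0.0) | (path >= L)
        first_out = int(np.argmax(out)) if out.any() else n_steps + 1
        if opts.bridge_correction:
            # bridge absorption on steps strictly before any hard exit
            x0 = np.concatenate(([z], path[:-1]))
            x1 = path
            dts = np.full(n_steps + 1, dt)
            dts[n_steps] = max(rem, 1e-300)
            with np.errstate(over="ignore"):
                p_abs = np.exp(-x0 * x1 / dts) + np.exp(-(L - x0) * (L - x1) / dts)
            crossed = rng.random(n_steps + 1) < np.minimum(p_abs, 1.0)
            crossed[first_out:] = False
            if crossed.any():
                first_out = min(first_out, int(np.argmax(crossed)))
        if first_out > n_steps:
            survivors.append(path[-1])
    pos = np.asarray(survivors, dtype=float)
    # guard against a survivor landing exactly on a wall at the final step
    pos = pos[(pos > 0.0) & (pos < L)]
    return Snapshot(cell_id=cell_id, geom=geom, positions=pos)


def sample_snapshot_direct(
    theta: NondimParams,
    geom: CellGeometry,
    seed: int | np.random.Generator | None = None,
    cell_id: str = "cell0",
    n_grid: int = 4096,
) -> Snapshot:
    """Snapshot drawn directly from the Poisson point process with intensity u.

    ``N ~ Poisson(E[N])``, then N iid positions by numerical inverse CDF of
    ``u / int u`` on an ``n_grid``-point grid.
    """
    _check_theta(theta)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if theta.lam == 0:
        return Snapshot(cell_id=cell_id, geom=geom, positions=np.empty(0))
    n = rng.poisson(expected_count(theta, geom))
    if n == 0:
        return Snapshot(cell_id=cell_id, geom=geom, positions=np.empty(0))
    grid = np.linspace(0.0, geom.L, n_grid)
    v = intensity_shape(grid, theta.mu, geom)
    cdf = np.concatenate(([0.0], np.cumsum((v[1:] + v[:-1]) * np.diff(grid) / 2.0)))
    cdf /= cdf[-1]
    pos = np.interp(rng.random(n), cdf, grid)
    eps = geom.L * 1e-12
    pos = np.clip(pos, eps, geom.L - eps)
    return Snapshot(cell_id=cell_id, geom=geom, positions=pos)


def simulate_snapshot_set(
    theta: NondimParams,
    geoms: Sequence[CellGeometry],
    mode: Literal["trajectories", "direct"] = "direct",
    opts: SimOptions | None = None,
    seed: int | None = None,
    cell_ids: Iterable[str] | None = None,
) -> SnapshotSet:
    """Independent per-cell snapshots with per-cell RNG substreams.

    The master seed is split with :class:`numpy.random.SeedSequence` so the
    output is reproducible and each cell's stream is independent.
    """
    geoms = list(geoms)
    if not geoms:
        raise ValueError("geoms must be nonempty")
    opts = opts or SimOptions(seed=seed)
    if seed is None:
        seed = opts.seed
    ids = list(cell_ids) if cell_ids is not None else [f"cell{i}" for i in range(len(geoms))]
    if len(ids) != len(geoms):
        raise ValueError("cell_ids length must match geoms")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell ids")
    streams = np.random.SeedSequence(seed).spawn(len(geoms))
    snaps = []
    for cid, g, ss in zip(ids, geoms, streams):
        rng = np.random.default_rng(ss)
        if mode == "trajectories":
            snaps.append(simulate_snapshot_trajectories(theta, g, opts, rng=rng, cell_id=cid))
        elif mode == "direct":
            snaps.append(sample_snapshot_direct(theta, g, seed=rng, cell_id=cid))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return SnapshotSet(snapshots=tuple(snaps))
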