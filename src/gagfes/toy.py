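"""Synthetic ground truth: analytic periodic landscapes with designed
basins and barriers, sampled by overdamped Langevin dynamics of a torsion
pair harmonically coupled to extended coordinates.

This module is the desk-scale stand-in for cluster-scale all-atom MD: it
produces torsion/extended-coordinate trajectories with a known stationary
density, so every downstream stage (bias accumulation, CZAR, Poisson
integration, landscape analysis) can be validated against the analytic
surface.  For a single overdamped particle the free-energy surface of the
physical coordinate equals the potential up to an additive constant.

Potentials are periodic sums of von-Mises-type wells::

    U(x, y) = offset - sum_j depth_j * exp(kappa_j * (cos(x-x_j) + cos(y-y_j) - 2))

smooth and 360-periodic in both torsions.  Dynamics use the Euler-Maruyama
scheme ``x += (F/gamma) dt + sqrt(2 kT dt / gamma) * N(0,1)`` in degrees,
with kT = 0.5922 kcal/mol at the default 298 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .fes import BOLTZMANN_KCAL, EABFState, FreeEnergySurface, PeriodicGrid2D
from .landscape import BasinDecomposition, minimax_saddle
from .pucker import (IDOA_REFERENCE_GEOMETRIES, PuckerState, RingConformer,
                     canonical_state, inverse_cremer_pople)

__all__ = [
    "ToyPotential",
    "SamplerConfig",
    "TorsionTrajectory",
    "potential_value_grad",
    "potential_grid",
    "design_two_basin",
    "run_langevin",
    "count_basin_transitions",
    "make_ring_ensemble",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class ToyPotential:
    """Periodic 2-D landscape built from wells (center degrees, depth
    kcal/mol, concentration kappa)."""

    wells: tuple  # of (center_x, center_y, depth, kappa)
    offset: float = 0.0

    def __post_init__(self):
        wells = tuple((float(cx), float(cy), float(d), float(k))
                      for cx, cy, d, k in self.wells)
        if len(wells) == 0:
            raise ValueError("a toy potential requires at least one well")
        if any(d <= 0 or k <= 0 for _, _, d, k in wells):
            raise ValueError("well depths and concentrations must be positive")
        object.__setattr__(self, "wells", wells)


def potential_value_grad(p: ToyPotential, x: float, y: float) -> tuple:
    """(U, dU/dx, dU/dy) at one point; U in kcal/mol, gradient in
    kcal/mol/degree.  Analytic and periodic."""
    u = p.offset
    gx = gy = 0.0
    for cx, cy, depth, kappa in p.wells:
        ax = (x - cx) * _DEG
        ay = (y - cy) * _DEG
        e = depth * math.exp(kappa * (math.cos(ax) + math.cos(ay) - 2.0))
        u -= e
        gx += e * kappa * math.sin(ax) * _DEG
        gy += e * kappa * math.sin(ay) * _DEG
    return u, gx, gy


def potential_grid(p: ToyPotential, nbins: int = 144) -> FreeEnergySurface:
    """The exact potential evaluated on the standard analysis grid,
    normalized to min-zero (the ground-truth surface)."""
    g = PeriodicGrid2D.zeros(nbins)
    xs = g.centers(0)[:, None] * _DEG
    ys = g.centers(1)[None, :] * _DEG
    u = np.full((nbins, nbins), p.offset)
    for cx, cy, depth, kappa in p.wells:
        u -= depth * np.exp(kappa * (np.cos(xs - cx * _DEG)
                                     + np.cos(ys - cy * _DEG) - 2.0))
    from .fes import normalize_min_zero
    return normalize_min_zero(FreeEnergySurface(grid=PeriodicGrid2D(values=u)))


def design_two_basin(
    global_depth: float,
    secondary_depth: float,
    barrier_target: float,
    centers: tuple = ((-77.5, 132.5), (-97.5, -80.0)),
    kappa_bounds: tuple = (0.2, 60.0),
    nbins: int = 144,
    tol: float = 0.02,
) -> ToyPotential:
    """Design a two-basin landscape whose escape barrier from the secondary
    basin to the global basin hits ``barrier_target`` (kcal/mol).

    Both wells share one concentration kappa, found by bisection; the
    barrier is measured as the exact minimax saddle of the densely gridded
    potential minus the secondary minimum.  Narrower wells push the saddle
    toward the flat background, so the barrier grows monotonically with
    kappa up to the secondary well depth: targets at or above
    ``secondary_depth`` are unsatisfiable and raise ``ValueError``.
    """
    if barrier_target >= secondary_depth:
        raise ValueError(
            f"barrier target {barrier_target} not reachable: escape barrier "
            f"is bounded by the secondary well depth {secondary_depth}")
    if secondary_depth > global_depth:
        raise ValueError("secondary well must not be deeper than the global")
    (gx, gy), (sx, sy) = centers

    def barrier(kappa: float) -> float:
        p = ToyPotential(wells=((gx, gy, global_depth, kappa),
                                (sx, sy, secondary_depth, kappa)))
        fes = potential_grid(p, nbins=nbins)
        ia, ja = fes.grid.index(sx, sy)
        ib, jb = fes.grid.index(gx, gy)
        saddle = minimax_saddle(fes, (ia, ja), (ib, jb))
        return saddle - fes.grid.values[ia, ja]

    lo, hi = kappa_bounds
    b_lo, b_hi = barrier(lo), barrier(hi)
    if not (b_lo <= barrier_target <= b_hi):
        raise ValueError(
            f"barrier target {barrier_target} outside achievable range "
            f"[{b_lo:.2f}, {b_hi:.2f}] for kappa in {kappa_bounds}")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        b = barrier(mid)
        if abs(b - barrier_target) <= tol:
            break
        if b < barrier_target:
            lo = mid
        else:
            hi = mid
    return ToyPotential(wells=((gx, gy, global_depth, mid),
                               (sx, sy, secondary_depth, mid)))


@dataclass(frozen=True)
class SamplerConfig:
    """Overdamped Langevin sampler settings.

    ``friction`` is the drag coefficient gamma (kcal/mol * step / deg^2);
    the mobility is 1/gamma and the diffusion constant kT/gamma.  ``k_ext``
    couples each torsion to its extended coordinate (kcal/mol/deg^2); the
    default 0.01 gives a spring fluctuation sqrt(kT/k_ext) of about 7.7
    degrees at 298 K, under two grid bins.
    """

    n_steps: int = 200_000
    dt: float = 1.0
    friction: float = 1.0
    temperature: float = 298.0
    k_ext: float = 0.01
    seed: int = 0
    bias: str = "none"  # "none" | "eabf"
    start: Optional[tuple] = None
    record_stride: int = 10
    nbins: int = 144
    n_full: int = 200

    def __post_init__(self):
        if min(self.dt, self.friction, self.k_ext) <= 0 or self.temperature < 0:
            raise ValueError("dt, friction, k_ext must be > 0 and T >= 0")
        if self.bias not in ("none", "eabf"):
            raise ValueError(f"unknown bias mode {self.bias!r}")
        if self.n_steps < 1 or self.record_stride < 1:
            raise ValueError("n_steps and record_stride must be >= 1")


@dataclass
class TorsionTrajectory:
    """Recorded time series of the torsion pair z = (phi, psi), the
    extended coordinates lambda, and the spring force on z (kcal/mol/deg)."""

    steps: np.ndarray
    z: np.ndarray
    lam: np.ndarray
    f_spring: np.ndarray

    def __post_init__(self):
        n = len(self.steps)
        if not (self.z.shape == self.lam.shape == self.f_spring.shape == (n, 2)):
            raise ValueError("trajectory column lengths disagree")

    HEADER = "# step phi psi lambda_phi lambda_psi f_lambda_phi f_lambda_psi"

    def write(self, path) -> None:
        data = np.column_stack([self.steps, self.z, self.lam, self.f_spring])
        np.savetxt(path, data, header=self.HEADER[2:], comments="# ",
                   fmt=["%d"] + ["%.10g"] * 6)

    @classmethod
    def read(cls, path) -> "TorsionTrajectory":
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] != 7:
            raise ValueError(f"{path}: expected 7 columns, got {data.shape[1]}")
        return cls(steps=data[:, 0].astype(int), z=data[:, 1:3],
                   lam=data[:, 3:5], f_spring=data[:, 5:7])


def _wrap(a: float) -> float:
    """Fast scalar wrap to [-180, 180)."""
    return (a + 180.0) % 360.0 - 180.0


def run_langevin(p: ToyPotential, cfg: SamplerConfig,
                 bias_state: Optional[EABFState] = None) -> TorsionTrajectory:
    """Sample the toy potential by overdamped Langevin dynamics with
    harmonic extended-coordinate coupling.

    The physical pair z feels the potential gradient plus the spring to
    lambda; lambda feels the spring back-force plus, in eABF mode, the
    ramped running-mean bias from ``bias_state``.  Statistics are
    accumulated into ``bias_state`` every step (a state is created when
    eABF is requested without one); the returned trajectory is recorded
    every ``record_stride`` steps.  A fixed seed gives bit-identical runs.
    """
    if cfg.bias == "eabf" and bias_state is None:
        bias_state = EABFState(nbins=cfg.nbins, k_ext=cfg.k_ext,
                               temperature=cfg.temperature, n_full=cfg.n_full)
    if bias_state is not None and bias_state.k_ext != cfg.k_ext:
        raise ValueError("bias_state k_ext differs from sampler k_ext")

    kT = BOLTZMANN_KCAL * cfg.temperature
    mob = cfg.dt / cfg.friction
    sigma = math.sqrt(2.0 * kT * mob)
    k_ext = cfg.k_ext
    use_bias = cfg.bias == "eabf"

    if cfg.start is not None:
        x, y = float(cfg.start[0]), float(cfg.start[1])
    else:  # start at the deepest well center
        deepest = max(p.wells, key=lambda w: w[2])
        x, y = deepest[0], deepest[1]
    lx, ly = x, y

    nbins = bias_state.nbins if bias_state is not None else cfg.nbins
    binw = 360.0 / nbins
    inv_binw = 1.0 / binw
    if bias_state is not None:
        counts_l = bias_state.counts_lambda
        fsum = bias_state.force_sum
        counts_z = bias_state.counts_z
        ldev = bias_state.lambda_dev_sum
        n_full = bias_state.n_full

    n_rec = (cfg.n_steps + cfg.record_stride - 1) // cfg.record_stride
    rec_steps = np.empty(n_rec, dtype=int)
    rec = np.empty((n_rec, 6))
    rng = np.random.default_rng(cfg.seed)

    block = 16384
    noise = rng.standard_normal((block, 4)) if cfg.temperature > 0 else \
        np.zeros((block, 4))
    nb = 0
    i_rec = 0
    wells = p.wells

    for step in range(cfg.n_steps):
        if nb == block:
            noise = rng.standard_normal((block, 4)) if cfg.temperature > 0 \
                else noise
            nb = 0
        # potential gradient (inlined for speed)
        gx = gy = 0.0
        for cx, cy, depth, kappa in wells:
            ax = (x - cx) * _DEG
            ay = (y - cy) * _DEG
            e = depth * math.exp(kappa * (math.cos(ax) + math.cos(ay) - 2.0))
            gx += e * kappa * math.sin(ax) * _DEG
            gy += e * kappa * math.sin(ay) * _DEG
        # spring force on z (minimal-image difference)
        dx = (lx - x + 180.0) % 360.0 - 180.0
        dy = (ly - y + 180.0) % 360.0 - 180.0
        fsx = k_ext * dx
        fsy = k_ext * dy

        # force on lambda: spring back-force plus adaptive bias
        flx, fly = -fsx, -fsy
        if bias_state is not None:
            li = int((lx + 180.0) * inv_binw + 0.5) % nbins
            lj = int((ly + 180.0) * inv_binw + 0.5) % nbins
            counts_l[li, lj] += 1
            fsum[li, lj, 0] += fsx
            fsum[li, lj, 1] += fsy
            if use_bias:
                n = counts_l[li, lj]
                ramp = 1.0 if n >= n_full else n / n_full
                flx += ramp * fsum[li, lj, 0] / n
                fly += ramp * fsum[li, lj, 1] / n
            zi = int((x + 180.0) * inv_binw + 0.5) % nbins
            zj = int((y + 180.0) * inv_binw + 0.5) % nbins
            counts_z[zi, zj] += 1
            czx = -180.0 + zi * binw
            czy = -180.0 + zj * binw
            ldev[zi, zj, 0] += (lx - czx + 180.0) % 360.0 - 180.0
            ldev[zi, zj, 1] += (ly - czy + 180.0) % 360.0 - 180.0

        # record the pre-move sample so a stride-1 trajectory reproduces
        # the accumulated statistics exactly
        if step % cfg.record_stride == 0:
            if not (math.isfinite(x) and math.isfinite(y)
                    and math.isfinite(lx) and math.isfinite(ly)):
                raise FloatingPointError(
                    f"non-finite coordinates at step {step}: "
                    f"z=({x}, {y}) lambda=({lx}, {ly}); reduce dt")
            rec_steps[i_rec] = step
            rec[i_rec] = (x, y, lx, ly, fsx, fsy)
            i_rec += 1

        row = noise[nb]
        nb += 1
        x = _wrap(x + mob * (-gx + fsx) + sigma * row[0])
        y = _wrap(y + mob * (-gy + fsy) + sigma * row[1])
        lx = _wrap(lx + mob * flx + sigma * row[2])
        ly = _wrap(ly + mob * fly + sigma * row[3])

    return TorsionTrajectory(steps=rec_steps, z=rec[:, 0:2],
                             lam=rec[:, 2:4], f_spring=rec[:, 4:6])


def count_basin_transitions(traj: TorsionTrajectory,
                            basins: BasinDecomposition,
                            dwell: int = 10) -> dict:
    """Count basin transitions of the physical-coordinate series.

    A transition from basin a to basin b registers only after the series
    stays in b for ``dwell`` consecutive frames (suppressing barrier
    recrossings); ``dwell=1`` counts every label change.  Frames in
    unlabelled bins (above the segmentation ceiling) are transparent.
    Returns ``{(a, b): count}``.
    """
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    counts: dict = {}
    current = None
    pending = None
    run = 0
    for x, y in traj.z:
        lab = basins.label_at(float(x), float(y))
        if lab < 0:
            continue
        if current is None:
            current = lab
            continue
        if lab == current:
            pending, run = None, 0
            continue
        if lab == pending:
            run += 1
        else:
            pending, run = lab, 1
        if run >= dwell:
            counts[(current, pending)] = counts.get((current, pending), 0) + 1
            current, pending, run = pending, None, 0
    return counts


def make_ring_ensemble(target: "PuckerState | str", n: int = 100,
                       jitter_deg: float = 3.0, jitter_q: float = 0.02,
                       Q: float = 0.6, seed: int = 0) -> List[RingConformer]:
    """Seeded ensemble of rings jittered around an ideal pucker state.

    Gaussian jitter is applied to (theta, phi, Q); theta reflects at the
    poles and for chair targets the azimuth is drawn uniformly (it is
    undefined at the pole itself).
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if isinstance(target, str):
        try:
            target = IDOA_REFERENCE_GEOMETRIES[target]
        except KeyError:
            target = canonical_state(target)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        theta = target.theta_ideal + jitter_deg * rng.standard_normal()
        theta = abs(theta)
        if theta > 180.0:
            theta = 360.0 - theta
        if target.phi_ideal is None:
            phi = rng.uniform(0.0, 360.0)
        else:
            phi = (target.phi_ideal + jitter_deg * rng.standard_normal()) % 360.0
        q = max(0.05, Q + jitter_q * rng.standard_normal())
        out.append(inverse_cremer_pople(q, theta, phi,
                                        source_tag=f"{target.name}:{i}"))
    return out
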