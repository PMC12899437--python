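"""Free-energy surfaces on periodic (phi, psi) grids: eABF bias statistics,
CZAR gradient estimation, and Poisson integration.

The extended-system adaptive biasing force (eABF) method couples each
torsion ``z`` harmonically to a fictitious coordinate ``lambda`` with
spring constant ``k_ext`` and applies, to lambda, an adaptive bias equal to
the running mean of the spring force accumulated in lambda-space bins,
ramped in by ``min(1, N/N_full)``.  Once the running mean converges, lambda
diffuses freely and drags z across barriers.

The unbiased free-energy gradient is recovered with the CZAR estimator::

    grad A(z) = -kT * grad ln rho~(z) + k_ext * (<lambda>_z - z)

where ``rho~`` is the biased histogram of the physical coordinate z and
``<lambda>_z`` the mean fictitious coordinate conditioned on the z bin.
The gradient field is then integrated by solving the periodic Poisson
problem ``lap A = div G`` spectrally, with divergence and Laplacian built
from the same central-difference operator so that a gradient produced by
central differences is inverted exactly (up to the additive constant and
the Nyquist mode, which central differencing cannot see).

Units: degrees, kcal/mol, K throughout.  Grid convention: bin centers at
``origin + j*width`` (default 144 bins of 2.5 deg from -180), so reporting
lattices like (-77.5, 132.5) fall on bin centers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .torsions import periodic_diff, wrap_angle

__all__ = [
    "PeriodicGrid2D",
    "EABFState",
    "FreeEnergySurface",
    "BOLTZMANN_KCAL",
    "abf_bias_force",
    "czar_gradient",
    "poisson_integrate",
    "normalize_min_zero",
    "value_at",
    "write_grid",
    "read_grid",
    "state_from_trajectory",
]

#: Boltzmann constant in kcal/mol/K.
BOLTZMANN_KCAL = 0.0019872041


@dataclass
class PeriodicGrid2D:
    """Scalar or vector values on a regular periodic grid over
    [-180, 180)^2.

    ``values`` has shape (nx, ny) for scalars or (nx, ny, ncomp) for
    vectors; bin (i, j) is centered at ``(-180 + i*wx, -180 + j*wy)`` and
    both axes wrap.
    """

    values: np.ndarray
    origin: tuple = (-180.0, -180.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("grid values must be 2-D (scalar) or 3-D (vector)")

    @classmethod
    def zeros(cls, nbins: int = 144, ncomp: Optional[int] = None,
              nbins_y: Optional[int] = None) -> "PeriodicGrid2D":
        ny = nbins_y if nbins_y is not None else nbins
        shape = (nbins, ny) if ncomp is None else (nbins, ny, ncomp)
        return cls(values=np.zeros(shape))

    @property
    def nbins(self) -> tuple:
        return self.values.shape[:2]

    @property
    def widths(self) -> tuple:
        nx, ny = self.nbins
        return 360.0 / nx, 360.0 / ny

    def centers(self, axis: int) -> np.ndarray:
        n = self.nbins[axis]
        return self.origin[axis] + (360.0 / n) * np.arange(n)

    def index(self, phi: float, psi: float) -> tuple:
        """Nearest-bin index of an angle pair, with periodic wrap."""
        nx, ny = self.nbins
        wx, wy = self.widths
        i = int(np.floor((wrap_angle(phi) - self.origin[0]) / wx + 0.5)) % nx
        j = int(np.floor((wrap_angle(psi) - self.origin[1]) / wy + 0.5)) % ny
        return i, j

    def center_of(self, i: int, j: int) -> tuple:
        wx, wy = self.widths
        return (self.origin[0] + i * wx, self.origin[1] + j * wy)

    def copy(self) -> "PeriodicGrid2D":
        return PeriodicGrid2D(values=self.values.copy(), origin=self.origin)

    def same_geometry(self, other: "PeriodicGrid2D") -> bool:
        return self.nbins == other.nbins and self.origin == other.origin


@dataclass
class FreeEnergySurface:
    """A scalar DeltaG(phi, psi) grid in kcal/mol, optionally normalized so
    the global minimum is exactly zero."""

    grid: PeriodicGrid2D
    normalized: bool = False
    argmin: Optional[tuple] = None  # (phi, psi) of the minimum bin

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


class EABFState:
    """Accumulated eABF statistics sufficient for bias evaluation and CZAR.

    Per lambda-space bin: sample count and the summed spring force exerted
    on the physical coordinates, ``k_ext * pdiff(lambda, z)``.  Per
    physical-coordinate (z) bin: sample count and the summed deviation of
    lambda from the bin center (accumulating deviations rather than raw
    angles keeps the conditional mean wrap-safe).
    """

    def __init__(self, nbins: int = 144, k_ext: float = 0.01,
                 temperature: float = 298.0, n_full: int = 200):
        if k_ext <= 0 or temperature <= 0 or n_full <= 0:
            raise ValueError("k_ext, temperature, and n_full must be positive")
        self.nbins = nbins
        self.k_ext = float(k_ext)
        self.temperature = float(temperature)
        self.n_full = int(n_full)
        self.counts_lambda = np.zeros((nbins, nbins), dtype=np.int64)
        self.force_sum = np.zeros((nbins, nbins, 2))
        self.counts_z = np.zeros((nbins, nbins), dtype=np.int64)
        self.lambda_dev_sum = np.zeros((nbins, nbins, 2))
        self._grid = PeriodicGrid2D.zeros(nbins)

    @property
    def kT(self) -> float:
        return BOLTZMANN_KCAL * self.temperature

    @property
    def total_samples(self) -> int:
        return int(self.counts_z.sum())

    def bin_index(self, x: float, y: float) -> tuple:
        return self._grid.index(x, y)

    def update(self, z: Sequence[float], lam: Sequence[float]) -> None:
        """Accumulate one sample (z, lambda), both in degrees."""
        fx = self.k_ext * periodic_diff(lam[0], z[0])
        fy = self.k_ext * periodic_diff(lam[1], z[1])
        li, lj = self._grid.index(lam[0], lam[1])
        self.counts_lambda[li, lj] += 1
        self.force_sum[li, lj, 0] += fx
        self.force_sum[li, lj, 1] += fy
        zi, zj = self._grid.index(z[0], z[1])
        cx, cy = self._grid.center_of(zi, zj)
        self.counts_z[zi, zj] += 1
        self.lambda_dev_sum[zi, zj, 0] += periodic_diff(lam[0], cx)
        self.lambda_dev_sum[zi, zj, 1] += periodic_diff(lam[1], cy)

    def merge(self, other: "EABFState") -> "EABFState":
        """Pool statistics from another state (same geometry/parameters)."""
        if (other.nbins != self.nbins or other.k_ext != self.k_ext
                or other.temperature != self.temperature):
            raise ValueError("cannot merge eABF states with different "
                             "geometry or parameters")
        out = EABFState(self.nbins, self.k_ext, self.temperature, self.n_full)
        out.counts_lambda = self.counts_lambda + other.counts_lambda
        out.force_sum = self.force_sum + other.force_sum
        out.counts_z = self.counts_z + other.counts_z
        out.lambda_dev_sum = self.lambda_dev_sum + other.lambda_dev_sum
        return out


def abf_bias_force(state: EABFState, lambda_bin: tuple) -> np.ndarray:
    """Adaptive bias force (kcal/mol/deg) applied to lambda in a bin:
    ``min(1, N/N_full)`` times the bin's running mean spring force; zero for
    an empty bin."""
    i, j = lambda_bin
    n = state.counts_lambda[i, j]
    if n == 0:
        return np.zeros(2)
    ramp = min(1.0, n / state.n_full)
    return ramp * state.force_sum[i, j] / n


def czar_gradient(state: EABFState,
                  fill_missing: bool = True) -> tuple:
    """CZAR estimate of the free-energy gradient on the z grid.

    Returns ``(gradient_grid, missing_mask)`` where the gradient grid has
    shape (n, n, 2) in kcal/mol/deg and the mask flags bins with no
    samples.  With ``fill_missing`` the log-histogram is extended into
    unsampled bins by iterative neighbor averaging before differencing
    (gradients there are interpolations, still flagged in the mask).
    """
    counts = state.counts_z
    if counts.sum() == 0:
        raise ValueError("empty eABF state: no samples accumulated")
    missing = counts == 0

    ln_rho = np.full(counts.shape, np.nan)
    nz = ~missing
    ln_rho[nz] = np.log(counts[nz] / counts.sum())
    if fill_missing and missing.any():
        ln_rho = _fill_by_neighbor_averaging(ln_rho)
    elif missing.any():
        ln_rho[missing] = ln_rho[nz].min()

    n = state.nbins
    w = 360.0 / n
    # central differences on the periodic grid
    dldx = (np.roll(ln_rho, -1, axis=0) - np.roll(ln_rho, 1, axis=0)) / (2 * w)
    dldy = (np.roll(ln_rho, -1, axis=1) - np.roll(ln_rho, 1, axis=1)) / (2 * w)

    mean_dev = np.zeros_like(state.lambda_dev_sum)
    mean_dev[nz] = state.lambda_dev_sum[nz] / counts[nz, None]

    grad = np.empty((n, n, 2))
    grad[..., 0] = -state.kT * dldx + state.k_ext * mean_dev[..., 0]
    grad[..., 1] = -state.kT * dldy + state.k_ext * mean_dev[..., 1]
    return PeriodicGrid2D(values=grad), missing


def _fill_by_neighbor_averaging(a: np.ndarray, max_iter: int = 10000) -> np.ndarray:
    """Fill NaN bins by repeatedly averaging defined 4-neighbors (periodic)."""
    a = a.copy()
    for _ in range(max_iter):
        nanmask = np.isnan(a)
        if not nanmask.any():
            return a
        neigh = np.stack([np.roll(a, s, axis=ax)
                          for ax in (0, 1) for s in (1, -1)])
        cnt = np.sum(~np.isnan(neigh), axis=0)
        s = np.nansum(neigh, axis=0)
        fillable = nanmask & (cnt > 0)
        if not fillable.any():  # pragma: no cover - disconnected empty grid
            break
        a[fillable] = s[fillable] / cnt[fillable]
    return a


def poisson_integrate(grad: PeriodicGrid2D) -> FreeEnergySurface:
    """Integrate a periodic gradient field into a free-energy surface.

    Solves ``lap A = div G`` spectrally with divergence and Laplacian both
    built from the central-difference operator, pins the zero mode (and the
    Nyquist modes, which are in the operator's null space) to zero, and
    normalizes the result to min-zero.  For a curl-free G produced by
    central differences of a Nyquist-free surface the recovery is exact to
    floating point; for noisy G the result is the least-squares potential.
    """
    v = grad.values
    if v.ndim != 3 or v.shape[2] != 2:
        raise ValueError("poisson_integrate expects an (n, m, 2) gradient grid")
    nx, ny = v.shape[:2]
    wx, wy = 360.0 / nx, 360.0 / ny

    gx_hat = np.fft.fft2(v[..., 0])
    gy_hat = np.fft.fft2(v[..., 1])
    kx = np.fft.fftfreq(nx) * 2.0 * np.pi  # radians per bin step
    ky = np.fft.fftfreq(ny) * 2.0 * np.pi
    lam_x = 1j * np.sin(kx)[:, None] / wx  # central-difference symbol
    lam_y = 1j * np.sin(ky)[None, :] / wy
    denom = lam_x * np.conj(lam_x) + lam_y * np.conj(lam_y)  # |.|^2, real >= 0

    num = np.conj(lam_x) * gx_hat + np.conj(lam_y) * gy_hat
    a_hat = np.zeros_like(num)
    ok = denom.real > 1e-14
    a_hat[ok] = num[ok] / denom[ok]
    a = np.real(np.fft.ifft2(a_hat))
    fes = FreeEnergySurface(grid=PeriodicGrid2D(values=a, origin=grad.origin))
    return normalize_min_zero(fes)


def normalize_min_zero(fes: FreeEnergySurface) -> FreeEnergySurface:
    """Shift the surface so its minimum bin is exactly zero; records the
    (phi, psi) of the minimum bin."""
    v = fes.grid.values
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot normalize a surface with non-finite values")
    i, j = np.unravel_index(np.argmin(v), v.shape)
    out = fes.grid.copy()
    out.values -= v[i, j]
    return FreeEnergySurface(grid=out, normalized=True,
                             argmin=fes.grid.center_of(int(i), int(j)))


def value_at(fes: FreeEnergySurface, phi: float, psi: float) -> float:
    """Nearest-bin surface value (no interpolation, matching the 2.5-degree
    reporting lattice)."""
    i, j = fes.grid.index(phi, psi)
    return float(fes.grid.values[i, j])


# ---------------------------------------------------------------------------
# Colvars-style multicolumn text grids
# ---------------------------------------------------------------------------

def write_grid(grid: PeriodicGrid2D, path) -> None:
    """Write a grid in Colvars-style multicolumn text.

    Header: ``# 2`` then one ``# origin width nbins periodic`` line per
    axis; body rows are ``x_center y_center value...`` with a blank line
    between x-blocks.  Values use full precision so a write/read round trip
    is bit-exact.
    """
    v = grid.values
    nx, ny = v.shape[:2]
    ncomp = 1 if v.ndim == 2 else v.shape[2]
    wx, wy = grid.widths
    buf = io.StringIO()
    buf.write("# 2\n")
    buf.write(f"# {grid.origin[0]:.17g} {wx:.17g} {nx} 1\n")
    buf.write(f"# {grid.origin[1]:.17g} {wy:.17g} {ny} 1\n")
    xs, ys = grid.centers(0), grid.centers(1)
    for i in range(nx):
        for j in range(ny):
            vals = v[i, j] if ncomp > 1 else [v[i, j]]
            row = " ".join(f"{x:.17g}" for x in np.atleast_1d(vals))
            buf.write(f"{xs[i]:.17g} {ys[j]:.17g} {row}\n")
        buf.write("\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_grid(path) -> PeriodicGrid2D:
    """Read a Colvars-style multicolumn text grid written by
    :func:`write_grid` (or by Colvars, for periodic 2-D grids)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: not a multicolumn grid file")
    ndim = int(lines[0].lstrip("# ").split()[0])
    if ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grid, got {ndim}-D")
    axes = []
    for k in (1, 2):
        parts = lines[k].lstrip("# ").split()
        origin, width, nbins, per = (float(parts[0]), float(parts[1]),
                                     int(parts[2]), int(parts[3]))
        if not per:
            raise ValueError(f"{path}: non-periodic axis in a periodic grid")
        axes.append((origin, width, nbins))
    (ox, wx, nx), (oy, wy, ny) = axes
    data_rows = [ln.split() for ln in lines[3:]]
    ncomp = len(data_rows[0]) - 2
    shape = (nx, ny) if ncomp == 1 else (nx, ny, ncomp)
    values = np.zeros(shape)
    tmp = PeriodicGrid2D(values=np.zeros((nx, ny)), origin=(ox, oy))
    for row in data_rows:
        x, y = float(row[0]), float(row[1])
        i, j = tmp.index(x, y)
        vals = [float(t) for t in row[2:]]
        values[i, j] = vals[0] if ncomp == 1 else vals
    return PeriodicGrid2D(values=values, origin=(ox, oy))


def state_from_trajectory(steps, z, lam, nbins: int = 144,
                          k_ext: float = 0.01, temperature: float = 298.0,
                          n_full: int = 200) -> EABFState:
    """Rebuild an :class:`EABFState` from recorded (z, lambda) samples."""
    state = EABFState(nbins=nbins, k_ext=k_ext, temperature=temperature,
                      n_full=n_full)
    z = np.asarray(z, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if z.shape != lam.shape or z.ndim != 2 or z.shape[1] != 2:
        raise ValueError("z and lambda series must both have shape (n, 2)")
    for zi, li in zip(z, lam):
        state.update(zi, li)
    return state
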