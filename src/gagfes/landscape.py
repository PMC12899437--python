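"""Analysis of DeltaG(phi, psi) landscapes: local minima, basin
segmentation, minimax saddle barriers, quadrants, basin extents, replicate
convergence, and pucker-dependent minimum shifts.

All operations treat the grid as a torus (both axes periodic) with
8-connectivity.  Barriers between basins are minimax crossing heights: the
lowest, over all 8-connected periodic paths between two minima, of the
highest bin on the path; escape barriers are measured from the starting
minimum and are therefore directional.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fes import FreeEnergySurface, PeriodicGrid2D
from .torsions import periodic_diff

__all__ = [
    "Minimum",
    "BasinDecomposition",
    "find_local_minima",
    "segment_basins",
    "barrier_height",
    "minimax_saddle",
    "quadrant",
    "basin_extent",
    "compare_replicates",
    "min_shift",
    "crop_phi_report",
    "analysis_report",
]

_NEIGH8 = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
           if (di, dj) != (0, 0)]


@dataclass(frozen=True)
class Minimum:
    i: int
    j: int
    phi: float
    psi: float
    value: float


@dataclass
class BasinDecomposition:
    """Per-bin basin labels (-1 above the segmentation ceiling), the list
    of minima (one per basin, label k belongs to ``minima[k]``), and the
    grid geometry they refer to."""

    labels: np.ndarray
    minima: List[Minimum]
    grid: PeriodicGrid2D
    ceiling: float

    def label_at(self, phi: float, psi: float) -> int:
        i, j = self.grid.index(phi, psi)
        return int(self.labels[i, j])

    def saddle_matrix(self, fes: FreeEnergySurface) -> np.ndarray:
        """Pairwise minimax crossing heights (absolute, kcal/mol)."""
        k = len(self.minima)
        out = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                s = minimax_saddle(fes, (self.minima[a].i, self.minima[a].j),
                                   (self.minima[b].i, self.minima[b].j))
                out[a, b] = out[b, a] = s
        return out


def _neighbor_values(v: np.ndarray) -> np.ndarray:
    """Stack of the 8 periodically shifted neighbor grids."""
    return np.stack([np.roll(np.roll(v, -di, axis=0), -dj, axis=1)
                     for di, dj in _NEIGH8])


def find_local_minima(fes: FreeEnergySurface,
                      ceiling: float = 15.0) -> List[Minimum]:
    """Bins strictly below all 8 periodic neighbors and below the ceiling,
    sorted by value; flat plateaus that are local minima collapse to their
    lexicographically smallest bin."""
    v = fes.grid.values
    neigh = _neighbor_values(v)
    nmin = neigh.min(axis=0)
    strict = (v < nmin) & (v < ceiling)
    minima = [(int(i), int(j)) for i, j in zip(*np.nonzero(strict))]

    # plateau candidates: <= all neighbors, equal to at least one
    flat = (v <= nmin) & ~strict & (v < ceiling)
    visited = np.zeros(v.shape, dtype=bool)
    nx, ny = v.shape
    for i0, j0 in zip(*np.nonzero(flat)):
        if visited[i0, j0]:
            continue
        # flood-fill the equal-value component
        comp, stack = [], [(int(i0), int(j0))]
        visited[i0, j0] = True
        val = v[i0, j0]
        is_min = True
        while stack:
            i, j = stack.pop()
            comp.append((i, j))
            for di, dj in _NEIGH8:
                ni, nj = (i + di) % nx, (j + dj) % ny
                if v[ni, nj] == val:
                    if not visited[ni, nj]:
                        visited[ni, nj] = True
                        stack.append((ni, nj))
                elif v[ni, nj] < val:
                    is_min = False
        if is_min and len(comp) < v.size:  # a constant surface has no minima
            minima.append(min(comp))

    out = []
    for i, j in minima:
        phi, psi = fes.grid.center_of(i, j)
        out.append(Minimum(i=i, j=j, phi=phi, psi=psi, value=float(v[i, j])))
    out.sort(key=lambda m: (m.value, m.i, m.j))
    return out


def segment_basins(fes: FreeEnergySurface, minima: Sequence[Minimum],
                   ceiling: float = 15.0) -> BasinDecomposition:
    """Steepest-descent basin assignment.

    Bins are processed in increasing (value, index) order; each bin below
    the ceiling inherits the label of its lowest already-labelled neighbor
    (ties by bin index), which realizes descent-to-minimum on the periodic
    grid.  Bins at or above the ceiling stay unlabelled (-1).
    """
    if len(minima) == 0:
        raise ValueError("cannot segment without minima")
    v = fes.grid.values
    nx, ny = v.shape
    labels = np.full((nx, ny), -1, dtype=int)
    for k, m in enumerate(minima):
        labels[m.i, m.j] = k

    order = sorted(((v[i, j], i, j) for i in range(nx) for j in range(ny)
                    if v[i, j] < ceiling))
    for val, i, j in order:
        if labels[i, j] >= 0:
            continue
        best = None
        for di, dj in _NEIGH8:
            ni, nj = (i + di) % nx, (j + dj) % ny
            if labels[ni, nj] >= 0 and v[ni, nj] <= val:
                key = (v[ni, nj], ni, nj)
                if best is None or key < best[0]:
                    best = (key, labels[ni, nj])
        if best is not None:
            labels[i, j] = best[1]
    return BasinDecomposition(labels=labels, minima=list(minima),
                              grid=fes.grid, ceiling=ceiling)


def minimax_saddle(fes: FreeEnergySurface, start: Tuple[int, int],
                   end: Tuple[int, int],
                   mask: Optional[np.ndarray] = None) -> float:
    """Lowest crossing height between two bins: the minimum over
    8-connected periodic paths of the maximum bin value along the path
    (endpoints included).  ``mask`` marks forbidden bins.

    Implemented as a widest-path (bottleneck) Dijkstra.
    """
    v = fes.grid.values
    nx, ny = v.shape
    if mask is not None and (mask[start] or mask[end]):
        raise ValueError("start or end bin is masked")
    best = np.full((nx, ny), np.inf)
    si, sj = start
    best[si, sj] = v[si, sj]
    heap = [(v[si, sj], si, sj)]
    while heap:
        h, i, j = heapq.heappop(heap)
        if (i, j) == tuple(end):
            return float(h)
        if h > best[i, j]:
            continue
        for di, dj in _NEIGH8:
            ni, nj = (i + di) % nx, (j + dj) % ny
            if mask is not None and mask[ni, nj]:
                continue
            nh = max(h, v[ni, nj])
            if nh < best[ni, nj]:
                best[ni, nj] = nh
                heapq.heappush(heap, (nh, ni, nj))
    raise ValueError("end bin unreachable from start (masked region)")


def barrier_height(decomp: BasinDecomposition, fes: FreeEnergySurface,
                   basin_a: int, basin_b: int,
                   mask: Optional[np.ndarray] = None) -> float:
    """Escape barrier from basin_a to basin_b: minimax crossing height
    minus the starting minimum's value (directional; 0 within one basin)."""
    if basin_a == basin_b:
        return 0.0
    ma, mb = decomp.minima[basin_a], decomp.minima[basin_b]
    saddle = minimax_saddle(fes, (ma.i, ma.j), (mb.i, mb.j), mask=mask)
    return float(saddle - ma.value)


def quadrant(phi: float, psi: float) -> tuple:
    """Sign quadrant of a wrapped (phi, psi) pair; zero counts as '+'."""
    phi, psi = periodic_diff(phi, 0.0), periodic_diff(psi, 0.0)
    return ("+" if phi >= 0 else "-", "+" if psi >= 0 else "-")


def _tightest_interval(centers: np.ndarray, width: float) -> tuple:
    """Tightest periodic interval covering a set of bin centers; returned
    as (lo, hi) traversed in the +direction, so lo > hi means the interval
    crosses the +/-180 seam."""
    c = np.sort(np.unique(centers))
    if len(c) == 0:
        return (np.nan, np.nan)
    if len(c) * width >= 360.0 - 1e-9:
        return (-180.0, 180.0)
    gaps = np.diff(np.concatenate([c, [c[0] + 360.0]]))
    k = int(np.argmax(gaps))
    lo = c[(k + 1) % len(c)]
    hi = c[k]
    return (float(periodic_diff(lo, 0.0)), float(periodic_diff(hi, 0.0)))


def basin_extent(decomp: BasinDecomposition, fes: FreeEnergySurface,
                 basin: int, level: float) -> tuple:
    """Tightest periodic (phi, psi) intervals covering the basin's bins
    with DeltaG <= level; empty (NaN) intervals if the level lies below the
    basin minimum."""
    sel = (decomp.labels == basin) & (fes.grid.values <= level)
    if not sel.any():
        return ((np.nan, np.nan), (np.nan, np.nan))
    ii, jj = np.nonzero(sel)
    wx, wy = fes.grid.widths
    phis = fes.grid.centers(0)[np.unique(ii)]
    psis = fes.grid.centers(1)[np.unique(jj)]
    return (_tightest_interval(phis, wx), _tightest_interval(psis, wy))


def min_shift(fes_a: FreeEnergySurface, fes_b: FreeEnergySurface) -> tuple:
    """Periodic shift (dphi, dpsi) of the global-minimum location, b - a."""
    for f in (fes_a, fes_b):
        if f.argmin is None:
            raise ValueError("surfaces must be normalized (argmin recorded)")
    return (float(periodic_diff(fes_b.argmin[0], fes_a.argmin[0])),
            float(periodic_diff(fes_b.argmin[1], fes_a.argmin[1])))


def compare_replicates(surfaces: Sequence[FreeEnergySurface],
                       low_region: float = 5.0,
                       argmin_tol: float = 15.0,
                       ceiling: float = 15.0) -> dict:
    """Convergence report across replicate surfaces.

    RMS deviation is computed bin-wise against the replicate mean over the
    region where every surface is at or below ``low_region`` kcal/mol.  The
    verdict is "consistent" iff all global-minimum locations agree within
    ``argmin_tol`` degrees (periodic Euclidean) or fall inside one shared
    basin of the first surface.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least two surfaces to compare")
    g0 = surfaces[0].grid
    if not all(s.grid.same_geometry(g0) for s in surfaces):
        raise ValueError("replicate surfaces are on different grids")
    if any(s.argmin is None for s in surfaces):
        raise ValueError("surfaces must be normalized (argmin recorded)")

    stack = np.stack([s.grid.values for s in surfaces])
    region = np.all(stack <= low_region, axis=0)
    if region.any():
        mean = stack[:, region].mean(axis=0)
        rms = float(np.sqrt(np.mean((stack[:, region] - mean) ** 2)))
    else:
        rms = float("nan")

    argmins = [s.argmin for s in surfaces]
    dists = []
    for a in range(len(argmins)):
        for b in range(a + 1, len(argmins)):
            d = np.hypot(periodic_diff(argmins[a][0], argmins[b][0]),
                         periodic_diff(argmins[a][1], argmins[b][1]))
            dists.append(float(d))
    within_tol = all(d <= argmin_tol for d in dists)

    shared_basin = False
    if not within_tol:
        minima = find_local_minima(surfaces[0], ceiling=ceiling)
        if minima:
            decomp = segment_basins(surfaces[0], minima, ceiling=ceiling)
            labels = {decomp.label_at(*am) for am in argmins}
            shared_basin = len(labels) == 1 and -1 not in labels

    return {
        "rms_low_region": rms,
        "argmins": argmins,
        "pairwise_argmin_distances": dists,
        "consistent": bool(within_tol or shared_basin),
    }


def crop_phi_report(fes: FreeEnergySurface, phi_range: tuple) -> dict:
    """Reporting view of the surface restricted to a phi range (useful when
    one half of phi is uniformly high, as across the anomeric torsion).

    Returns a dict with the selected phi centers, all psi centers, and the
    value block; analysis functions always operate on the full torus.
    """
    lo, hi = phi_range
    phis = fes.grid.centers(0)
    if lo <= hi:
        sel = (phis >= lo) & (phis <= hi)
    else:  # wrap-straddling range
        sel = (phis >= lo) | (phis <= hi)
    return {
        "phi": phis[sel],
        "psi": fes.grid.centers(1),
        "values": fes.grid.values[sel, :],
    }


def analysis_report(surfaces: Sequence[FreeEnergySurface],
                    ceiling: float = 15.0,
                    minima_ceiling: float = 3.0,
                    extent_level: float = 1.0) -> dict:
    """Structured landscape report for one or more replicate surfaces.

    Uses the first surface for minima/basins/barriers; adds replicate
    convergence when more than one surface is given.  JSON-serializable.
    """
    fes = surfaces[0]
    all_minima = find_local_minima(fes, ceiling=ceiling)
    # barriers/extents are reported for the low-lying minima only (sorted,
    # capped): spurious shallow minima in noisy surfaces are not basins
    low = [m for m in all_minima if m.value <= minima_ceiling][:20]
    report: dict = {
        "minima": [{"phi": m.phi, "psi": m.psi, "dG": m.value,
                    "quadrant": "".join(quadrant(m.phi, m.psi))}
                   for m in low],
        "n_minima_below_ceiling": len(all_minima),
    }
    if low:
        decomp = segment_basins(fes, low, ceiling=ceiling)
        saddles = decomp.saddle_matrix(fes)
        report["saddle_matrix"] = saddles.tolist()
        report["escape_barriers"] = [
            [float(saddles[a, b] - decomp.minima[a].value) if a != b else 0.0
             for b in range(len(low))] for a in range(len(low))]
        report["basin_extents"] = [
            {"basin": k,
             "phi_interval": list(basin_extent(decomp, fes, k, extent_level)[0]),
             "psi_interval": list(basin_extent(decomp, fes, k, extent_level)[1])}
            for k in range(len(low))]
    if len(surfaces) > 1:
        conv = compare_replicates(surfaces)
        report["convergence"] = {
            "rms_low_region": conv["rms_low_region"],
            "consistent": conv["consistent"],
            "argmins": [list(a) for a in conv["argmins"]],
        }
        report["min_shifts_vs_first"] = [
            list(min_shift(surfaces[0], s)) for s in surfaces[1:]]
    return report
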