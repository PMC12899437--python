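import numpy as np
import pytest

from gagfes.fes import FreeEnergySurface, PeriodicGrid2D, normalize_min_zero
from gagfes.toy import ToyPotential, design_two_basin, potential_grid


def surface(values) -> FreeEnergySurface:
    """Normalized surface from a raw value array (test helper)."""
    return normalize_min_zero(FreeEnergySurface(
        grid=PeriodicGrid2D(values=np.asarray(values, float))))


_NEIGH8 = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
           if (di, dj) != (0, 0)]


def brute_force_minimax(values: np.ndarray, start, end) -> float:
    """Exhaustive threshold scan: the minimax crossing height is the
    smallest bin value t such that start and end are connected within the
    8-connected periodic subgraph of bins <= t.  Every distinct level is
    tried in ascending order with a plain flood fill, so the oracle shares
    no machinery with the widest-path search it checks."""
    nx, ny = values.shape
    floor = max(values[tuple(start)], values[tuple(end)])
    for t in sorted(np.unique(values)):
        if t < floor:
            continue
        allowed = values <= t
        stack, seen = [tuple(start)], {tuple(start)}
        while stack:
            i, j = stack.pop()
            if (i, j) == tuple(end):
                return float(t)
            for di, dj in _NEIGH8:
                ni, nj = (i + di) % nx, (j + dj) % ny
                if allowed[ni, nj] and (ni, nj) not in seen:
                    seen.add((ni, nj))
                    stack.append((ni, nj))
    raise AssertionError("endpoints not connected at any level")


def enumerate_paths_minimax(values: np.ndarray, start, end) -> float:
    """Literal enumeration of all simple 8-connected periodic paths
    (feasible only for tiny grids); the strongest form of the oracle."""
    nx, ny = values.shape
    best = [np.inf]

    def dfs(i, j, cur_max, visited):
        cur_max = max(cur_max, values[i, j])
        if cur_max >= best[0]:
            return
        if (i, j) == tuple(end):
            best[0] = cur_max
            return
        for di, dj in _NEIGH8:
            ni, nj = (i + di) % nx, (j + dj) % ny
            if (ni, nj) not in visited:
                visited.add((ni, nj))
                dfs(ni, nj, cur_max, visited)
                visited.remove((ni, nj))

    dfs(start[0], start[1], -np.inf, {tuple(start)})
    return best[0]


@pytest.fixture(scope="session")
def two_basin():
    """Designed two-basin landscape with a 4 kcal/mol escape barrier from
    the secondary basin, centers on the reporting lattice."""
    return design_two_basin(6.0, 4.5, 4.0,
                            centers=((-77.5, 132.5), (-97.5, -80.0)))


@pytest.fixture(scope="session")
def two_basin_truth(two_basin):
    return potential_grid(two_basin)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
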