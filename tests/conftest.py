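"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by brute force (flood
fill, per-threshold component labelling, explicit normal equations,
exhaustive permutation enumeration) so the package's optimized paths are
checked against independent code rather than against themselves.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _scipy_cc

from sbbrep.surface import SurfaceMesh, build_test_mesh
from sbbrep.synthetic import default_study_panel


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def grid2() -> SurfaceMesh:
    return build_test_mesh("grid", 2)


@pytest.fixture(scope="session")
def grid3() -> SurfaceMesh:
    return build_test_mesh("grid", 3)


@pytest.fixture(scope="session")
def ico0() -> SurfaceMesh:
    return build_test_mesh("icosphere", 0)


@pytest.fixture(scope="session")
def ico1() -> SurfaceMesh:
    return build_test_mesh("icosphere", 1)


@pytest.fixture(scope="session")
def study_panel():
    """Full-size default panel (420 subjects, two icosphere hemispheres)."""
    return default_study_panel(seed=11)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def reachability_components(mesh: SurfaceMesh, mask) -> list[set[int]]:
    """Brute-force flood fill over masked vertices (independent of the
    package's component code)."""
    mask = np.asarray(mask, dtype=bool)
    adj = {v: set() for v in range(mesh.n_vertices)}
    for u, w in mesh.edges:
        adj[int(u)].add(int(w))
        adj[int(w)].add(int(u))
    seen: set[int] = set()
    comps = []
    for start in range(mesh.n_vertices):
        if not mask[start] or start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if mask[u] and u not in seen:
                    seen.add(u)
                    comp.add(u)
                    stack.append(u)
        comps.append(comp)
    comps.sort(key=min)
    return comps


def tfce_oracle(values, mesh: SurfaceMesh, E, H, dh, n_steps) -> np.ndarray:
    """Brute-force TFCE: loop the threshold ladder, label suprathreshold
    components with scipy, and sum extent**E * h**H * dh per vertex."""
    vals = np.asarray(values, dtype=float)
    out = np.zeros(vals.size)
    e = mesh.edges
    for k in range(1, n_steps + 1):
        h = k * dh
        m = vals >= h - 1e-12
        if not m.any():
            continue
        keep = m[e[:, 0]] & m[e[:, 1]]
        sub = sp.csr_matrix(
            (np.ones(int(keep.sum())), (e[keep, 0], e[keep, 1])),
            shape=(vals.size, vals.size),
        )
        _, lab = _scipy_cc(sub + sub.T, directed=False)
        sizes = np.bincount(lab[m], minlength=lab.max() + 1)
        out[m] += sizes[lab[m]] ** E * h**H * dh
    return out


def ols_t_oracle(y: np.ndarray, x_full: np.ndarray, coef_index: int) -> np.ndarray:
    """Per-column OLS t-statistics via explicit normal equations."""
    xtx_inv = np.linalg.inv(x_full.T @ x_full)
    beta = xtx_inv @ x_full.T @ y
    resid = y - x_full @ beta
    df = x_full.shape[0] - x_full.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[coef_index, coef_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        return beta[coef_index] / se


def rank_partial_oracle(x, y, z) -> tuple[float, float]:
    """Explicit rank -> residualize -> Pearson pipeline, coded separately."""
    from scipy import stats

    rx, ry = stats.rankdata(x), stats.rankdata(y)
    n = len(rx)
    zz = np.column_stack([np.ones(n), np.asarray(z, dtype=float).reshape(n, -1)])
    proj = zz @ np.linalg.pinv(zz)
    ex = rx - proj @ rx
    ey = ry - proj @ ry
    rho = float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))
    k = zz.shape[1] - 1
    df = n - 2 - k
    t = rho * np.sqrt(df / (1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), df))
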