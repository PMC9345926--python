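"""Vertex-wise GLM association mapping with permutation-based FWE inference.

The exploratory stage fits, at every mesh vertex, an ordinary least squares
model of cortical thickness on a score of interest plus confounders
(age, gender, education), enhances the resulting t-map with threshold-free
cluster enhancement (TFCE), and calibrates family-wise-error-corrected
p-values with a Freedman-Lane permutation scheme using the maximum TFCE
statistic jointly over both tails and both hemispheres.  Significant
vertices are grouped into signed clusters.

TFCE integrates cluster extent^E x height^H over a ladder of thresholds::

    TFCE(v) = sum_h  e_h(v)**E * h**H * dh

where ``e_h(v)`` is the size of the suprathreshold connected component
containing ``v`` at height ``h``.  The implementation walks the threshold
ladder top-down with a weighted union-find over the mesh graph, which makes
it cheap enough to run inside the permutation loop; a numba-compiled kernel
is used when available, with a pure NumPy fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np

from .surface import SurfaceMesh, connected_components, _values

try:  # optional acceleration; the fallback is exact but slower
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


class DesignError(ValueError):
    """Raised for rank-deficient or misaligned design matrices."""


@dataclass
class DesignMatrix:
    """Design for one association test: score of interest plus confounders.

    Rows must be aligned to the subject order of the thickness matrices.
    The fitted model is ``thickness ~ 1 + score + confounders``; the
    t-statistic reported per vertex is the one for the score coefficient.
    """

    score: np.ndarray
    confounders: np.ndarray | None = None
    score_name: str = "score"

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float).ravel()
        n = self.score.size
        if self.confounders is None:
            self.confounders = np.empty((n, 0))
        z = np.asarray(self.confounders, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise DesignError("confounder rows do not match score length")
        self.confounders = z
        x = self.matrix()
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise DesignError("design matrix is rank deficient")

    def matrix(self) -> np.ndarray:
        n = self.score.size
        return np.column_stack([np.ones(n), self.score, self.confounders])

    @property
    def n_subjects(self) -> int:
        return self.score.size

    @property
    def n_columns(self) -> int:
        return 2 + self.confounders.shape[1]


@dataclass
class TFCEParams:
    """TFCE exponents and threshold ladder.

    ``E`` weights cluster extent, ``H`` weights height; the defaults
    (E=1, H=2) are the standard surface-data choice.  The ladder step is
    ``dh`` if given, otherwise the rectified maximum divided by ``n_steps``
    (adaptive per map).
    """

    E: float = 1.0
    H: float = 2.0
    dh: float | None = None
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("TFCE exponents must be non-negative")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class StatMap:
    """Result of one exploratory run over one or two hemispheres.

    All per-vertex arrays are dicts keyed by hemisphere label.  ``p_fwe``
    is corrected jointly over both tails, both hemispheres and all
    vertices via the permutation max-TFCE distribution and lies in
    ``[1/(n_perm+1), 1]``.
    """

    t_values: dict[str, np.ndarray]
    tfce_pos: dict[str, np.ndarray]
    tfce_neg: dict[str, np.ndarray]
    p_fwe: dict[str, np.ndarray]
    n_permutations: int
    seed: int | None
    null_max: np.ndarray = field(default=None, repr=False)

    @property
    def hemispheres(self) -> list[str]:
        return list(self.t_values)


@dataclass
class Cluster:
    hemisphere: str
    vertices: np.ndarray
    sign: int
    peak_t: float
    min_p: float

    @property
    def size(self) -> int:
        return int(len(self.vertices))


@dataclass
class ClusterSet:
    """Significant signed clusters from one exploratory run.

    Extent is counted in vertices (``size_measure`` is a hook for a future
    area-weighted variant).
    """

    clusters: list[Cluster]
    score_name: str = ""
    split_id: int | None = None
    alpha: float = 0.05
    size_measure: str = "vertex_count"

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def count_by_sign(self) -> dict[int, int]:
        out = {1: 0, -1: 0}
        for c in self.clusters:
            out[c.sign] += 1
        return out


# ---------------------------------------------------------------------------
# GLM t-maps
# ---------------------------------------------------------------------------


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of columns of y on [1 | z] via least squares."""
    n = y.shape[0]
    zz = np.column_stack([np.ones(n), z])
    coef, *_ = np.linalg.lstsq(zz, y, rcond=None)
    return y - zz @ coef


def fit_glm_tmap(thickness: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Per-vertex OLS t-statistic for the score coefficient.

    ``thickness`` is subjects x vertices.  Residual df is
    ``n - (2 + n_confounders)``.  Zero-variance vertices get t = 0 (with a
    warning); perfect fits with a nonzero coefficient get ``+/-inf``.
    """
    y = np.asarray(thickness, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = design.n_subjects
    if y.shape[0] != n:
        raise DesignError("thickness rows do not match design rows")
    p = design.n_columns
    if n <= p + 1:
        raise DesignError("too few subjects for the design")
    x_res = _residualize(design.score[:, None], design.confounders).ravel()
    xtx = float(x_res @ x_res)
    if xtx <= 0:
        raise DesignError("score is collinear with confounders")
    y_res = _residualize(y, design.confounders)
    beta = (x_res @ y_res) / xtx
    resid = y_res - np.outer(x_res, beta)
    df = n - p
    sse = np.einsum("ij,ij->j", resid, resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / xtx)
        t = beta / se
    flat = np.ptp(y, axis=0) == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance vertices; t set to 0", RuntimeWarning
        )
        t[flat] = 0.0
    exact = (~flat) & (sse <= 1e-12 * np.maximum(np.abs(beta) * xtx, 1.0))
    t[exact] = np.sign(beta[exact]) * np.inf
    t[np.isnan(t)] = 0.0
    return t


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True)
    def _tfce_kernel(values, indptr, indices, order, n_steps, dh, E, H):  # pragma: no cover - numba
        n = values.shape[0]
        parent = np.full(n, -1, dtype=np.int64)
        delta = np.zeros(n)
        acc = np.zeros(n)
        size = np.zeros(n, dtype=np.int64)
        out = np.zeros(n)
        pos = 0  # next vertex in descending-value order to activate
        for k in range(n_steps, 0, -1):
            h = k * dh
            thr = h - 1e-12
            # activate vertices with value >= h and union with active peers
            while pos < n and values[order[pos]] >= thr:
                v = order[pos]
                pos += 1
                parent[v] = v
                size[v] = 1
                for j in range(indptr[v], indptr[v + 1]):
                    u = indices[j]
                    if parent[u] == -1:
                        continue
                    # find roots with path compression, tracking offsets
                    ru = u
                    du = 0.0
                    while parent[ru] != ru:
                        du += delta[ru]
                        ru = parent[ru]
                    node = u
                    dsum = du
                    while parent[node] != node:
                        nxt = parent[node]
                        d = delta[node]
                        parent[node] = ru
                        delta[node] = dsum
                        dsum -= d
                        node = nxt
                    rv = v
                    while parent[rv] != rv:
                        rv = parent[rv]
                    if ru == rv:
                        continue
                    if size[ru] < size[rv]:
                        ru, rv = rv, ru
                    # merge rv under ru, preserving accumulated values
                    parent[rv] = ru
                    delta[rv] = acc[rv] - acc[ru]
                    size[ru] += size[rv]
            # add this threshold's contribution to every live component
            inc_h = h ** H * dh
            for r in range(n):
                if parent[r] == r:
                    acc[r] += size[r] ** E * inc_h
        for v in range(n):
            if parent[v] == -1:
                continue
            node = v
            dsum = 0.0
            while parent[node] != node:
                dsum += delta[node]
                node = parent[node]
            out[v] = dsum + acc[node]
        return out


def _tfce_python(values, indptr, indices, order, n_steps, dh, E, H):
    """Pure-Python union-find TFCE; same algorithm as the numba kernel."""
    n = values.shape[0]
    parent = np.full(n, -1, dtype=np.int64)
    delta = np.zeros(n)
    acc = np.zeros(n)
    size = np.zeros(n, dtype=np.int64)
    out = np.zeros(n)
    pos = 0

    def find(u):
        ru = u
        du = 0.0
        while parent[ru] != ru:
            du += delta[ru]
            ru = parent[ru]
        node, dsum = u, du
        while parent[node] != node:
            nxt = parent[node]
            d = delta[node]
            parent[node] = ru
            delta[node] = dsum
            dsum -= d
            node = nxt
        return ru

    vertex_range = np.arange(n)
    for k in range(n_steps, 0, -1):
        h = k * dh
        thr = h - 1e-12
        while pos < n and values[order[pos]] >= thr:
            v = order[pos]
            pos += 1
            parent[v] = v
            size[v] = 1
            for u in indices[indptr[v] : indptr[v + 1]]:
                if parent[u] == -1:
                    continue
                ru, rv = find(u), find(v)
                if ru == rv:
                    continue
                if size[ru] < size[rv]:
                    ru, rv = rv, ru
                parent[rv] = ru
                delta[rv] = acc[rv] - acc[ru]
                size[ru] += size[rv]
        roots = parent == vertex_range
        acc[roots] += size[roots] ** E * (h ** H * dh)
    for v in range(n):
        if parent[v] == -1:
            continue
        node, dsum = v, 0.0
        while parent[node] != node:
            dsum += delta[node]
            node = parent[node]
        out[v] = dsum + acc[node]
    return out


def tfce_transform(
    t_map,
    mesh: SurfaceMesh,
    params: TFCEParams | None = None,
    tail: str = "+",
    dh: float | None = None,
) -> np.ndarray:
    """TFCE of the tail-rectified statistic map.

    ``tail`` is ``"+"`` (enhance positive values) or ``"-"`` (enhance the
    negated map).  ``dh`` overrides the ladder step; by default it is the
    rectified maximum over ``params.n_steps`` (so the ladder tops out at the
    map maximum).  Output is non-negative and zero wherever the rectified
    map is zero.
    """
    params = params or TFCEParams()
    x = _values(mesh, t_map)
    if tail == "+":
        v = np.maximum(x, 0.0)
    elif tail == "-":
        v = np.maximum(-x, 0.0)
    else:
        raise ValueError("tail must be '+' or '-'")
    finite_max = np.max(v[np.isfinite(v)], initial=0.0)
    v = np.minimum(v, np.finfo(float).max)  # inf sentinels saturate
    vmax = finite_max if np.isfinite(v).all() else np.max(v)
    if vmax <= 0:
        return np.zeros(mesh.n_vertices)
    step = dh if dh is not None else params.dh
    if step is None:
        step = vmax / params.n_steps
        n_steps = params.n_steps
    else:
        n_steps = int(math.floor(vmax / step + 1e-9))
        if n_steps < 1:
            return np.zeros(mesh.n_vertices)
    adj = mesh.adjacency
    order = np.argsort(-v, kind="stable").astype(np.int64)
    kernel = _tfce_kernel if _HAVE_NUMBA else _tfce_python
    return kernel(
        v.astype(float),
        adj.indptr.astype(np.int64),
        adj.indices.astype(np.int64),
        order,
        n_steps,
        float(step),
        float(params.E),
        float(params.H),
    )


# ---------------------------------------------------------------------------
# Permutation FWE
# ---------------------------------------------------------------------------


def _tmap_from_parts(x_res, xtx, w, z, df):
    """t-stats of the score coefficient for permuted residual data ``w``.

    Freedman-Lane: the permuted outcome is ``Z g + P e``; refitting the full
    model makes the fitted-confounder part drop out of both the numerator
    (``x_res`` is Z-orthogonal) and the residual sum of squares.
    """
    w_res = _residualize(w, z)
    beta = (x_res @ w_res) / xtx
    sse = np.einsum("ij,ij->j", w_res, w_res) - beta**2 * xtx
    sse = np.maximum(sse, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sse / df / xtx)
    t[~np.isfinite(t)] = np.sign(beta[~np.isfinite(t)]) * np.inf
    t[np.isnan(t)] = 0.0
    return t


def permutation_fwe(
    thickness: dict[str, np.ndarray] | np.ndarray,
    design: DesignMatrix,
    meshes: dict[str, SurfaceMesh] | SurfaceMesh,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> StatMap:
    """Permutation FWE-corrected TFCE inference over one or two hemispheres.

    The null distribution is the per-permutation maximum TFCE over both
    tails, all hemispheres and all vertices, giving joint two-sided,
    cross-hemisphere family-wise error control.  Permutation follows the
    Freedman-Lane scheme: thickness is residualized on the confounders
    (plus intercept), residual rows are permuted (the same subject
    permutation in both hemispheres), and the full model is refit.

    ``p_fwe(v) = (1 + #{null max >= TFCE_obs(v)}) / (n_perm + 1)`` with the
    observed vertex statistic ``max(TFCE+, TFCE-)(v)``.  When ``n_perm``
    is at least ``n!`` the group is enumerated exhaustively instead and
    ``p = #{perm max >= obs} / n!`` over all ``n!`` permutations
    (identity included).
    """
    params = params or TFCEParams()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(meshes, SurfaceMesh):
        meshes = {meshes.hemisphere: meshes}
        if not isinstance(thickness, dict):
            thickness = {next(iter(meshes)): thickness}
    hemis = list(meshes)
    n = design.n_subjects
    y = {h: np.asarray(thickness[h], dtype=float) for h in hemis}
    for h in hemis:
        if y[h].shape != (n, meshes[h].n_vertices):
            raise ValueError(f"thickness for {h} is not subjects x vertices")

    z = design.confounders
    x_res = _residualize(design.score[:, None], z).ravel()
    xtx = float(x_res @ x_res)
    df = n - design.n_columns
    y_res = {h: _residualize(y[h], z) for h in hemis}

    def stat_maps(resid_by_hemi):
        """(t, tfce+, tfce-) per hemisphere with a shared adaptive dh."""
        t = {h: _tmap_from_parts(x_res, xtx, resid_by_hemi[h], z, df) for h in hemis}
        gmax = max(
            (np.max(np.abs(tv[np.isfinite(tv)]), initial=0.0) for tv in t.values()),
            default=0.0,
        )
        dh = gmax / params.n_steps if params.dh is None else params.dh
        if dh <= 0:
            zeros = {h: np.zeros(meshes[h].n_vertices) for h in hemis}
            return t, zeros, dict(zeros)
        pos = {h: tfce_transform(t[h], meshes[h], params, "+", dh=dh) for h in hemis}
        neg = {h: tfce_transform(t[h], meshes[h], params, "-", dh=dh) for h in hemis}
        return t, pos, neg

    t_obs, tfce_pos, tfce_neg = stat_maps(y_res)
    obs_stat = {h: np.maximum(tfce_pos[h], tfce_neg[h]) for h in hemis}

    exhaustive = n <= 20 and n_perm >= math.factorial(n)
    if exhaustive:
        warnings.warn(
            f"n_perm={n_perm} >= {n}! = {math.factorial(n)}; "
            "enumerating all permutations exhaustively",
            RuntimeWarning,
        )
        perms = [np.array(p) for p in _iter_permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]

    null_max = np.empty(len(perms))
    for i, perm in enumerate(perms):
        _, p_pos, p_neg = stat_maps({h: y_res[h][perm] for h in hemis})
        null_max[i] = max(
            max(np.max(p_pos[h], initial=0.0), np.max(p_neg[h], initial=0.0))
            for h in hemis
        )

    p_fwe = {}
    for h in hemis:
        exceed = (null_max[:, None] >= obs_stat[h][None, :] - 1e-12).sum(axis=0)
        if exhaustive:
            p_fwe[h] = exceed / len(perms)
        else:
            p_fwe[h] = (1.0 + exceed) / (n_perm + 1.0)
    return StatMap(
        t_values=t_obs,
        tfce_pos=tfce_pos,
        tfce_neg=tfce_neg,
        p_fwe=p_fwe,
        n_permutations=len(perms),
        seed=seed,
        null_max=null_max,
    )


# ---------------------------------------------------------------------------
# Cluster extraction
# ---------------------------------------------------------------------------


def extract_clusters(
    stat: StatMap,
    meshes: dict[str, SurfaceMesh] | SurfaceMesh,
    alpha: float = 0.05,
    score_name: str = "",
    split_id: int | None = None,
) -> ClusterSet:
    """Signed connected components of the significant-vertex mask.

    For each hemisphere the mask ``p_fwe < alpha`` is split by t-sign and
    each sign mask is decomposed into connected components.  Clusters are
    sorted by size descending (ties: hemisphere label, then smallest
    vertex index).
    """
    if isinstance(meshes, SurfaceMesh):
        meshes = {meshes.hemisphere: meshes}
    clusters: list[Cluster] = []
    for h, mesh in meshes.items():
        p = stat.p_fwe[h]
        t = stat.t_values[h]
        for sign in (1, -1):
            mask = (p < alpha) & ((t > 0) if sign > 0 else (t < 0))
            for comp in connected_components(mesh, mask):
                clusters.append(
                    Cluster(
                        hemisphere=h,
                        vertices=comp,
                        sign=sign,
                        peak_t=float(np.max(np.abs(t[comp]))),
                        min_p=float(np.min(p[comp])),
                    )
                )
    clusters.sort(key=lambda c: (-c.size, c.hemisphere, int(c.vertices[0])))
    return ClusterSet(
        clusters=clusters, score_name=score_name, split_id=split_id, alpha=alpha
    )
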