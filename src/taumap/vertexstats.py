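"""Pointwise GLM on the template skeleton with permutation cluster FWE.

The analysis fits, at every skeleton vertex, an ordinary least-squares
model with thickness as the dependent variable and a pathology measure of
interest (plus optional nuisance covariates) as regressors. Missing
thickness observations are handled by dropping rows per vertex, so the
degrees of freedom vary across vertices; vertices with fewer than a
configurable fraction of valid observations are excluded.

Before fitting, thickness is smoothed along the mesh with an explicit
heat-equation iteration modified for missing data (normalized convolution:
the value-times-validity and validity fields are diffused separately and
their ratio taken), which preserves constants and never propagates missing
values into observed ones.

Cluster-level family-wise error correction follows the Freedman-Lane
scheme: the nuisance-only model is fitted, its residuals permuted by a
global specimen permutation and added back to the nuisance fit, the full
model and cluster extraction recomputed per permutation, and each observed
suprathreshold cluster compared against the permutation distribution of
the maximum cluster statistic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph

from .thickness import SkeletonField

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "VertexStatMap",
    "ClusterResult",
    "mesh_adjacency",
    "diffuse_smooth",
    "vertex_glm",
    "cluster_extract",
    "freedman_lane_fwe",
]

_DIFFUSION_STEP = 0.25
_VALIDITY_FLOOR = 1e-6


@dataclass
class DesignMatrix:
    """Specimen-level design: intercept, variable of interest, nuisances.

    ``contrast`` selects the variable of interest; its zero entries define
    the reduced (nuisance-only) model used by Freedman-Lane permutation.
    ``sidedness`` is one of ``negative`` (pathology thins cortex, the
    default direction), ``positive`` or ``two_sided``.
    """

    X: np.ndarray
    contrast: np.ndarray
    sidedness: str = "negative"
    columns: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (specimens x columns)")
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length must equal the column count")
        if self.sidedness not in ("negative", "positive", "two_sided"):
            raise ValueError("sidedness must be negative/positive/two_sided")
        if not self.columns:
            self.columns = tuple(f"x{i}" for i in range(self.X.shape[1]))

    @property
    def n_specimens(self) -> int:
        return self.X.shape[0]

    @property
    def nuisance_idx(self) -> np.ndarray:
        return np.where(self.contrast == 0)[0]

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        variable: str,
        covariates: Sequence[str] = (),
        sidedness: str = "negative",
    ) -> "DesignMatrix":
        """Build intercept + variable + covariates from a specimen table.

        A ``sex`` column with M/F values is coded 1/0.
        """
        cols = ["intercept", variable, *covariates]
        n = len(table)
        X = np.ones((n, len(cols)))
        for j, c in enumerate(cols[1:], start=1):
            col = table[c]
            if col.dtype == object:
                X[:, j] = (col == "M").astype(float)
            else:
                X[:, j] = col.to_numpy(dtype=float)
        contrast = np.zeros(len(cols))
        contrast[1] = 1.0
        return cls(X=X, contrast=contrast, sidedness=sidedness, columns=tuple(cols))


@dataclass
class VertexStatMap:
    """Per-vertex t statistic, degrees of freedom and analyzed flag."""

    t: np.ndarray
    df: np.ndarray
    analyzed: np.ndarray


@dataclass
class ClusterResult:
    """A maximal connected suprathreshold component of the skeleton mesh."""

    cluster_id: int
    vertices: np.ndarray
    extent: int
    mass: float
    corrected_p: Optional[float] = None


def mesh_adjacency(faces: np.ndarray, n_vertices: int) -> sparse.csr_matrix:
    """Symmetric vertex adjacency (edge graph) of a triangle mesh."""
    faces = np.asarray(faces, dtype=np.int64)
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    data = np.ones(i.shape[0], dtype=np.int8)
    A = sparse.coo_matrix((data, (i, j)), shape=(n_vertices, n_vertices))
    A = A + A.T
    A.data[:] = 1
    return A.tocsr()


def diffuse_smooth(
    fld: SkeletonField,
    adjacency: sparse.spmatrix,
    T: float,
    step: float = _DIFFUSION_STEP,
    validity_floor: float = _VALIDITY_FLOOR,
) -> SkeletonField:
    """Heat-equation smoothing of a skeleton field, missing-data aware.

    Runs ``ceil(T / step)`` explicit uniform-weight graph-Laplacian steps
    on the value-times-validity field and the validity field separately and
    returns their ratio (normalized convolution). Vertices whose diffused
    validity stays below ``validity_floor`` remain missing; ``T = 0``
    returns the input unchanged. Disconnected mesh components are smoothed
    independently (an intrinsic property of the graph iteration).
    """
    if T < 0:
        raise ValueError("diffusion time T must be >= 0")
    n_steps = int(np.ceil(T / step))
    if n_steps == 0:
        return SkeletonField(thickness=fld.thickness.copy(), valid=fld.valid.copy())
    A = adjacency.tocsr().astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    n_comp, _ = csgraph.connected_components(A, directed=False)
    if n_comp > 1:
        logger.info("mesh has %d components; smoothing each independently", n_comp)
    safe_deg = np.maximum(deg, 1.0)

    w = fld.valid.astype(float)
    f = np.where(fld.valid, fld.thickness, 0.0)
    for _ in range(n_steps):
        f = f + step * (A @ f / safe_deg - f * (deg > 0))
        w = w + step * (A @ w / safe_deg - w * (deg > 0))
    valid = w > validity_floor
    out = np.full(fld.thickness.shape, np.nan)
    out[valid] = f[valid] / w[valid]
    return SkeletonField(thickness=out, valid=valid)


def _group_by_pattern(valid: np.ndarray) -> Dict[bytes, np.ndarray]:
    """Group vertex columns by identical specimen-validity pattern."""
    keys = np.ascontiguousarray(valid.T).view(
        np.dtype((np.void, valid.shape[0] * valid.dtype.itemsize))
    ).ravel()
    order = np.argsort(keys, kind="stable")
    groups: Dict[bytes, np.ndarray] = {}
    start = 0
    sorted_keys = keys[order]
    for end in range(1, len(order) + 1):
        if end == len(order) or sorted_keys[end] != sorted_keys[start]:
            groups[sorted_keys[start].tobytes()] = order[start:end]
            start = end
    return groups


def _glm_tstats(
    Y: np.ndarray,
    valid: np.ndarray,
    X: np.ndarray,
    contrast: np.ndarray,
    min_valid: int,
) -> VertexStatMap:
    """Vectorized per-vertex OLS t statistics with row-wise missing data.

    Vertices are grouped by identical validity patterns so each distinct
    pattern costs one least-squares factorization.
    """
    n, V = Y.shape
    p = X.shape[1]
    t = np.zeros(V)
    df = np.zeros(V, dtype=int)
    analyzed = np.zeros(V, dtype=bool)
    for key, cols in _group_by_pattern(valid).items():
        m = valid[:, cols[0]]
        nv = int(m.sum())
        if nv < max(min_valid, p + 1):
            continue
        Xm = X[m]
        rank = np.linalg.matrix_rank(Xm)
        if rank < p:
            continue
        pinv = np.linalg.pinv(Xm)
        xtx_inv = pinv @ pinv.T
        cvar = float(contrast @ xtx_inv @ contrast)
        Ym = Y[np.ix_(m, cols)]
        B = pinv @ Ym
        resid = Ym - Xm @ B
        dof = nv - p
        sigma2 = (resid * resid).sum(axis=0) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = (contrast @ B) / np.sqrt(sigma2 * cvar)
        tt = np.where(np.isnan(tt), 0.0, tt)
        t[cols] = tt
        df[cols] = dof
        analyzed[cols] = True
    return VertexStatMap(t=t, df=df, analyzed=analyzed)


def vertex_glm(
    thickness: np.ndarray,
    valid: np.ndarray,
    design: DesignMatrix,
    min_valid_fraction: float = 0.25,
) -> VertexStatMap:
    """Per-vertex OLS of thickness on the design, on valid rows only.

    ``thickness`` is (specimens x vertices); entries where ``valid`` is
    False are ignored. A vertex is analyzed when at least
    ``min_valid_fraction`` of specimens are valid, the design has full
    column rank on the valid subset (a constant variable of interest fails
    this), and at least one residual degree of freedom remains.
    """
    thickness = np.asarray(thickness, dtype=float)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(thickness)
    n = thickness.shape[0]
    if design.n_specimens != n:
        raise ValueError("design rows must match the specimen count")
    min_valid = int(np.ceil(min_valid_fraction * n))
    Y = np.where(valid, thickness, 0.0)
    return _glm_tstats(Y, valid, design.X, design.contrast, min_valid)


def _vertex_pvalues(statmap: VertexStatMap, sidedness: str) -> np.ndarray:
    p = np.ones(statmap.t.shape)
    a = statmap.analyzed
    df = np.maximum(statmap.df, 1)
    if sidedness == "negative":
        p[a] = stats.t.cdf(statmap.t[a], df[a])
    elif sidedness == "positive":
        p[a] = stats.t.sf(statmap.t[a], df[a])
    else:
        p[a] = 2.0 * stats.t.sf(np.abs(statmap.t[a]), df[a])
    return p


def cluster_extract(
    statmap: VertexStatMap,
    adjacency: sparse.spmatrix,
    cluster_p: float = 0.01,
    sidedness: str = "negative",
) -> List[ClusterResult]:
    """Maximal connected suprathreshold components of the t map.

    A vertex is suprathreshold when its one-sided (or two-sided) p-value
    from the t distribution with that vertex's degrees of freedom falls
    below ``cluster_p``. Components are connected over mesh edges; the
    cluster statistic is the vertex extent (count), with the summed |t|
    mass also reported.
    """
    if not 0.0 < cluster_p < 1.0:
        raise ValueError("cluster_p must lie in (0, 1)")
    pv = _vertex_pvalues(statmap, sidedness)
    supra = statmap.analyzed & (pv < cluster_p)
    idx = np.where(supra)[0]
    if idx.size == 0:
        return []
    sub = adjacency[np.ix_(idx, idx)]
    n_comp, labels = csgraph.connected_components(sub, directed=False)
    out: List[ClusterResult] = []
    for k in range(n_comp):
        verts = idx[labels == k]
        out.append(
            ClusterResult(
                cluster_id=k,
                vertices=verts,
                extent=int(verts.size),
                mass=float(np.abs(statmap.t[verts]).sum()),
            )
        )
    out.sort(key=lambda c: -c.extent)
    for k, c in enumerate(out):
        c.cluster_id = k
    return out


def _cluster_stat(clusters: List[ClusterResult], statistic: str) -> float:
    if not clusters:
        return 0.0
    if statistic == "extent":
        return float(max(c.extent for c in clusters))
    return float(max(c.mass for c in clusters))


def freedman_lane_fwe(
    thickness: np.ndarray,
    valid: np.ndarray,
    design: DesignMatrix,
    adjacency: sparse.spmatrix,
    cluster_p: float = 0.01,
    n_permutations: int = 1000,
    min_valid_fraction: float = 0.25,
    seed: int = 0,
    statistic: str = "extent",
    exhaustive: bool = False,
) -> Tuple[VertexStatMap, List[ClusterResult], np.ndarray]:
    """Cluster-level FWE-corrected inference via Freedman-Lane permutation.

    Fits the reduced (nuisance-only) model per vertex, permutes its
    residual rows by one global specimen permutation per iteration,
    reconstructs pseudo-data as nuisance fit + permuted residuals,
    recomputes the full GLM and cluster extraction, and records the maximum
    cluster statistic.

    Missing data: each vertex keeps exactly its observed valid rows, and
    the global permutation is compressed onto that subset (the valid rows
    are reordered by their rank in the global permutation). This preserves
    each vertex's degrees of freedom under permutation — dropping rows
    missing in the permuted position instead makes the permutation maps
    systematically noisier than the observed map and the correction
    severely conservative — while vertices sharing a validity pattern still
    share one coherent permutation.

    With ``exhaustive=True`` all n! permutations are enumerated (n <= 8)
    and the corrected p of each observed cluster is the exact fraction of
    permutations (including identity) whose maximum statistic reaches the
    observed one. Monte-Carlo mode draws ``n_permutations`` random
    permutations and uses (1 + exceedances) / (1 + n_permutations).

    Returns the observed stat map, the observed clusters with corrected
    p-values, and the permutation max-statistic distribution.
    """
    thickness = np.asarray(thickness, dtype=float)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(thickness)
    n, V = thickness.shape
    Z_idx = design.nuisance_idx
    if Z_idx.size == 0:
        raise ValueError("design needs at least an intercept nuisance column")
    min_valid = int(np.ceil(min_valid_fraction * n))

    obs = _glm_tstats(
        np.where(valid, thickness, 0.0), valid, design.X, design.contrast, min_valid
    )
    if not obs.analyzed.any():
        raise ValueError("no analyzed vertices: validity too sparse")
    obs_clusters = cluster_extract(obs, adjacency, cluster_p, design.sidedness)

    # reduced-model fit and residuals per validity-pattern group, held in
    # full specimen-by-vertex arrays (zero at invalid entries)
    Z = design.X[:, Z_idx]
    pz = Z.shape[1]
    fit = np.zeros((n, V))
    resid = np.zeros((n, V))
    reduced_ok = np.zeros(V, dtype=bool)
    groups: List[Tuple[np.ndarray, np.ndarray]] = []  # (valid rows, vertices)
    Y0 = np.where(valid, thickness, 0.0)
    for key, cols in _group_by_pattern(valid).items():
        m = valid[:, cols[0]]
        nv = int(m.sum())
        if nv <= pz:
            continue
        Zm = Z[m]
        if np.linalg.matrix_rank(Zm) < pz:
            raise ValueError("nuisance-only model is rank-deficient")
        G = np.linalg.pinv(Zm) @ Y0[np.ix_(m, cols)]
        Fm = Zm @ G
        fit[np.ix_(m, cols)] = Fm
        resid[np.ix_(m, cols)] = Y0[np.ix_(m, cols)] - Fm
        reduced_ok[cols] = True
        groups.append((np.where(m)[0], cols))

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8 specimens")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(int(n_permutations))]

    vp = valid & reduced_ok[None, :]
    maxima = np.empty(len(perms))
    rank = np.empty(n, dtype=int)
    for k, perm in enumerate(perms):
        rank[perm] = np.arange(n)
        Yp = np.zeros((n, V))
        for rows, cols in groups:
            # global permutation compressed onto this validity subset
            source = rows[np.argsort(rank[rows], kind="stable")]
            Yp[np.ix_(rows, cols)] = (
                fit[np.ix_(rows, cols)] + resid[np.ix_(source, cols)]
            )
        sm = _glm_tstats(Yp, vp, design.X, design.contrast, min_valid)
        cl = cluster_extract(sm, adjacency, cluster_p, design.sidedness)
        maxima[k] = _cluster_stat(cl, statistic)

    for c in obs_clusters:
        stat = float(c.extent if statistic == "extent" else c.mass)
        exceed = int((maxima >= stat).sum())
        if exhaustive:
            c.corrected_p = exceed / len(perms)
        else:
            c.corrected_p = (1 + exceed) / (1 + len(perms))
    return obs, obs_clusters, maxima
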