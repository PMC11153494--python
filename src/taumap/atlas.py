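"""Synthetic template atlas: a curved cortical ribbon with known thickness.

The template stands in for a groupwise ex-vivo atlas of the medial temporal
lobe: a raster label volume of MTL subregions, and a triangulated skeleton
(mid-surface) mesh with per-vertex subregion labels. The geometry is a
parametric ribbon rather than a brain-shaped mesh so that the thickness
field is known analytically — every voxel of the ribbon lies within a
half-thickness h(u, v) of the mid-surface, hence the true thickness at a
mid-surface point is exactly 2 h(u, v). That analytic ground truth is what
the skeletonization and resampling stages are validated against.

The chart (u, v) over the mid-surface runs anterior (u=0) to posterior
(u=1) and medial (v=0) to lateral (v=1). Subregion bands are laid out
medial to lateral in the order of the standard MTL subregion maps
(pre/parasubiculum through Area TE), with the parahippocampal areas TF/TH
replacing the entorhinal/perirhinal bands in the posterior third, and the
entorhinal band subdivided into its eight cytoarchitectonic subfields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TemplateAtlas",
    "make_template",
    "LABEL_TABLE",
    "ERC_SUBFIELD_CODES",
]

# Subregion label codes. 10-17 are the entorhinal subfields; the remaining
# codes are the combined-analysis subregions.
LABEL_TABLE: Dict[int, str] = {
    1: "PrS-PaS",
    2: "S",
    3: "CA1",
    4: "CA2",
    5: "CA3",
    6: "DG",
    7: "SRLM",
    8: "PP",
    10: "Eo",
    11: "ER",
    12: "EMI",
    13: "EI",
    14: "ELr",
    15: "ELc",
    16: "EC",
    17: "ECL",
    20: "BA35",
    21: "BA36",
    22: "TE",
    23: "TF",
    24: "TH",
}

ERC_SUBFIELD_CODES: Tuple[int, ...] = (10, 11, 12, 13, 14, 15, 16, 17)

# Medial-to-lateral band layout of the anterior two thirds: (name, weight).
# The ERC band is wide because it hosts the eight subfields.
_BANDS = [
    ("PrS-PaS", 1.0),
    ("S", 1.0),
    ("CA1", 1.5),
    ("CA2", 0.75),
    ("CA3", 0.75),
    ("DG", 1.0),
    ("SRLM", 0.8),
    ("PP", 0.8),
    ("ERC", 3.0),
    ("BA35", 1.3),
    ("BA36", 1.3),
    ("TE", 1.5),
]
_NAME_TO_CODE = {v: k for k, v in LABEL_TABLE.items()}

# ERC subfield grid within the ERC band: rows are anterior->posterior
# quarters of u in [0, 2/3); columns are the medial/lateral halves of the
# band. Eo/ER sit most anteriorly, EC/ECL most caudally.
_ERC_GRID = [("Eo", "ER"), ("EMI", "EI"), ("ELr", "ELc"), ("EC", "ECL")]


@dataclass
class TemplateAtlas:
    """Shared raster grid, subregion label volume and skeleton surface.

    ``skeleton_vertices`` are mm coordinates of the mid-surface mesh;
    ``vertex_thickness`` is the analytic ground-truth thickness (2 x the
    local half-thickness) at each vertex. ``vertex_u``/``vertex_v`` are the
    chart coordinates, with u the anterior-posterior fraction.
    """

    grid_shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    label_volume: np.ndarray
    skeleton_vertices: np.ndarray
    skeleton_faces: np.ndarray
    vertex_labels: np.ndarray
    vertex_thickness: np.ndarray
    vertex_u: np.ndarray
    vertex_v: np.ndarray
    label_table: Dict[int, str] = field(default_factory=lambda: dict(LABEL_TABLE))
    params: Dict[str, float] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return int(self.skeleton_vertices.shape[0])

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """mm coordinates of voxel centers for an (N, 3) index array."""
        return np.asarray(indices, dtype=float) * np.asarray(self.spacing)

    def code_of(self, name: str) -> int:
        for code, nm in self.label_table.items():
            if nm == name:
                return code
        raise KeyError(f"unknown subregion name: {name!r}")

    def half_thickness(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Analytic half-thickness h(u, v) of the ribbon, in mm."""
        p = self.params
        return p["h0"] + p["h_amp"] * np.sin(np.pi * u + p["phi_h1"]) * np.cos(
            np.pi * v + p["phi_h2"]
        )

    def ap_fraction(self, x_mm: np.ndarray) -> np.ndarray:
        """Anterior-posterior chart fraction u for mm x-coordinates."""
        p = self.params
        return np.clip((np.asarray(x_mm) - p["x0"]) / (p["x1"] - p["x0"]), 0.0, 1.0)

    def foreground_mask(self) -> np.ndarray:
        return self.label_volume > 0


def _chart_labels(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Map chart coordinates to subregion codes (vectorized)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    weights = np.array([w for _, w in _BANDS])
    edges = np.concatenate([[0.0], np.cumsum(weights) / weights.sum()])
    edges[-1] = 1.0 + 1e-9
    band_idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(_BANDS) - 1)
    out = np.zeros(u.shape, dtype=np.int16)
    posterior = u >= 2.0 / 3.0
    for i, (name, _) in enumerate(_BANDS):
        sel = band_idx == i
        if not np.any(sel):
            continue
        if name == "ERC":
            lo, hi = edges[i], edges[i + 1]
            vloc = (v[sel] - lo) / (hi - lo)
            uq = np.clip((u[sel] / (2.0 / 3.0) * 4).astype(int), 0, 3)
            lateral = vloc >= 0.5
            codes = np.empty(sel.sum(), dtype=np.int16)
            for q in range(4):
                med_name, lat_name = _ERC_GRID[q]
                qi = uq == q
                codes[qi & ~lateral] = _NAME_TO_CODE[med_name]
                codes[qi & lateral] = _NAME_TO_CODE[lat_name]
            # posterior third of the ERC/BA35/BA36 territory becomes TH
            codes[posterior[sel]] = _NAME_TO_CODE["TH"]
            out[sel] = codes
        elif name in ("BA35", "BA36"):
            code = np.full(sel.sum(), _NAME_TO_CODE[name], dtype=np.int16)
            code[posterior[sel]] = _NAME_TO_CODE["TF"]
            out[sel] = code
        else:
            out[sel] = _NAME_TO_CODE[name]
    return out


def make_template(
    grid_shape: Tuple[int, int, int] = (72, 56, 40),
    spacing: Tuple[float, float, float] = (0.4, 0.4, 0.4),
    seed: int = 0,
    skeleton_shape: Tuple[int, int] | None = None,
) -> TemplateAtlas:
    """Build the synthetic ribbon template.

    Parameters
    ----------
    grid_shape:
        Raster dimensions (x = anterior-posterior, y = medial-lateral,
        z = depth); must be at least (32, 24, 24) so that every subregion
        receives at least one voxel.
    spacing:
        Voxel spacing in mm per axis.
    seed:
        Randomizes the gentle phase offsets of the mid-surface curvature and
        thickness field; identical seeds give identical templates.
    skeleton_shape:
        (nu, nv) resolution of the skeleton mesh; defaults to roughly one
        vertex per voxel column of the mid-surface.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or any(
        g < m for g, m in zip(grid_shape, (32, 24, 24))
    ):
        raise ValueError(
            f"grid_shape {grid_shape} too small to hold all subregion labels; "
            "need at least (32, 24, 24)"
        )
    spacing = tuple(float(s) for s in spacing)
    nx, ny, nz = grid_shape
    sx, sy, sz = spacing
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-0.25, 0.25, size=4)

    # Thickness field: h in [h0-h_amp, h0+h_amp], kept >= ~2 voxels so the
    # ribbon is never thinner than ~4 voxels.
    h0 = max(1.0, 2.6 * sz)
    h_amp = 0.4 * h0
    margin_vox = 3.0
    x0, x1 = margin_vox * sx, (nx - 1 - margin_vox) * sx
    y0, y1 = margin_vox * sy, (ny - 1 - margin_vox) * sy
    zc = 0.5 * (nz - 1) * sz
    half_depth = zc
    z_amp = 0.5 * max(0.0, half_depth - (h0 + h_amp) - 2.0 * sz)

    params = dict(
        h0=h0,
        h_amp=h_amp,
        z_amp=z_amp,
        zc=zc,
        x0=x0,
        x1=x1,
        y0=y0,
        y1=y1,
        phi_h1=float(phi[0]),
        phi_h2=float(phi[1]),
        phi_z1=float(phi[2]),
        phi_z2=float(phi[3]),
        seed=float(seed),
    )

    def mid_z(u, v):
        return zc + z_amp * np.sin(np.pi * u + params["phi_z1"]) * np.cos(
            np.pi * v + params["phi_z2"]
        )

    def half_t(u, v):
        return h0 + h_amp * np.sin(np.pi * u + params["phi_h1"]) * np.cos(
            np.pi * v + params["phi_h2"]
        )

    # Dense mid-surface sampling at ~half-voxel pitch for voxelization.
    nu_d = max(64, int(np.ceil((x1 - x0) / (0.5 * sx))) + 1)
    nv_d = max(48, int(np.ceil((y1 - y0) / (0.5 * sy))) + 1)
    ud = np.linspace(0.0, 1.0, nu_d)
    vd = np.linspace(0.0, 1.0, nv_d)
    UU, VV = np.meshgrid(ud, vd, indexing="ij")
    px = x0 + UU * (x1 - x0)
    py = y0 + VV * (y1 - y0)
    pz = mid_z(UU, VV)
    dense_pts = np.column_stack([px.ravel(), py.ravel(), pz.ravel()])
    dense_h = half_t(UU, VV).ravel()
    dense_lab = _chart_labels(UU.ravel(), VV.ravel())

    tree = cKDTree(dense_pts)
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    centers = np.column_stack(
        [ix.ravel() * sx, iy.ravel() * sy, iz.ravel() * sz]
    )
    dist, nearest = tree.query(centers, workers=-1)
    # half-voxel interface convention: the implied raster surface lies at
    # the fg/bg voxel interface, i.e. at the analytic offset distance h
    inside = dist <= dense_h[nearest] + 0.5 * float(np.mean(spacing))
    labels = np.zeros(nx * ny * nz, dtype=np.int16)
    labels[inside] = dense_lab[nearest[inside]]
    label_volume = labels.reshape(grid_shape)

    missing = [
        nm
        for code, nm in LABEL_TABLE.items()
        if not np.any(label_volume == code)
    ]
    if missing:
        raise ValueError(
            f"grid_shape {grid_shape} too small: subregions {missing} received "
            "no voxels; enlarge the grid"
        )

    # Skeleton mesh on a coarser (nu, nv) grid of the same chart.
    if skeleton_shape is None:
        skeleton_shape = (
            max(16, int(round((x1 - x0) / sx / 1.5))),
            max(12, int(round((y1 - y0) / sy / 1.5))),
        )
    nu_s, nv_s = skeleton_shape
    us = np.linspace(0.0, 1.0, nu_s)
    vs = np.linspace(0.0, 1.0, nv_s)
    US, VS = np.meshgrid(us, vs, indexing="ij")
    verts = np.column_stack(
        [
            (x0 + US * (x1 - x0)).ravel(),
            (y0 + VS * (y1 - y0)).ravel(),
            mid_z(US, VS).ravel(),
        ]
    )
    vert_u = US.ravel()
    vert_v = VS.ravel()
    vert_lab = _chart_labels(vert_u, vert_v)
    vert_thick = 2.0 * half_t(US, VS).ravel()

    faces = []
    for i in range(nu_s - 1):
        for j in range(nv_s - 1):
            a = i * nv_s + j
            b = a + 1
            c = a + nv_s
            d = c + 1
            faces.append((a, b, c))
            faces.append((b, d, c))
    faces = np.asarray(faces, dtype=np.int64)

    return TemplateAtlas(
        grid_shape=grid_shape,
        spacing=spacing,
        label_volume=label_volume,
        skeleton_vertices=verts,
        skeleton_faces=faces,
        vertex_labels=vert_lab,
        vertex_thickness=vert_thick,
        vertex_u=vert_u,
        vertex_v=vert_v,
        label_table=dict(LABEL_TABLE),
        params=params,
    )
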