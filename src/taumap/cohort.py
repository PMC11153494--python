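"""Synthetic specimen cohorts with known ground truth.

The generator emulates the statistical structure of an ex-vivo MTL cohort
with histology-derived tau (NFT) burden maps:

* an anterior-to-posterior exponential decline in burden,
* subregion-specific susceptibility (CA1 and entorhinal cortex highest;
  dentate gyrus, pre/parasubiculum and Area TE lowest; the SRLM and
  perforant pathway accumulate no tangles themselves),
* severity increasing with Braak B-score and age,
* burden-dependent cortical thinning realized as a deformed binary
  segmentation around the template mid-surface,
* slab-wise missingness of the burden validity mask, emulating excluded
  histology sections, and
* semi-quantitative site ratings obtained by discretizing ipsilateral ROI
  burden at fixed cut points and averaging over three sampling sites.

All randomness flows from one integer seed through spawned per-specimen
generator streams, so cohorts are reproducible bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .atlas import ERC_SUBFIELD_CODES, TemplateAtlas
from .thickness import SkeletonField

__all__ = [
    "SpecimenRecord",
    "BurdenVolume",
    "GroundTruth",
    "Specimen",
    "Cohort",
    "default_truth",
    "simulate_cohort",
    "simulate_label_votes",
    "RATING_CUTS",
    "RATING_LEVELS",
]

# Fixed cut points mapping continuous burden to the ordinal rating scale.
# The cuts reuse the canonical burden levels (rare/mild/moderate/severe).
RATING_CUTS = (0.1, 0.25, 0.5, 1.0)
RATING_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)

# Site categorical distributions for co-pathologies not modeled as burden
# volumes; chosen to match typical AD-continuum cohort prevalence (amyloid
# common, TDP-43 and alpha-synuclein mostly absent).
_COPATH_SITE_PROBS = {
    "abeta": (0.35, 0.10, 0.15, 0.20, 0.20),
    "tdp43": (0.85, 0.06, 0.05, 0.03, 0.01),
    "asyn": (0.82, 0.06, 0.05, 0.04, 0.03),
}

_RATING_SITES = ("ERC", "DG", "CA1")  # contralateral sampling sites


@dataclass
class SpecimenRecord:
    """Demographics, Braak grouping and semi-quantitative ratings."""

    specimen_id: str
    age: float
    sex: str  # "M" or "F"
    b_score: int  # 0-3
    ratings: Dict[str, float] = field(default_factory=dict)

    @property
    def braak_group(self) -> str:
        """"low" for B0/B1 (Braak 0-II), "high" for B2/B3 (Braak III-VI)."""
        return "low" if self.b_score <= 1 else "high"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if not 0 <= int(self.b_score) <= 3:
            raise ValueError("b_score must be an integer in 0..3")
        for k, v in self.ratings.items():
            if not 0.0 <= v <= 3.0:
                raise ValueError(f"rating {k}={v} outside [0, 3]")


@dataclass
class BurdenVolume:
    """Nonnegative NFT-burden raster plus validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("burden values must be finite")
        if (self.values < 0).any():
            raise ValueError("burden values must be nonnegative")


def _default_susceptibility() -> Dict[str, float]:
    # Ranking mirrors the relative-to-BA35 ordering of regional burden:
    # CA1 ~ ERC > BA35 > S > BA36 > TF/TH > PrS-PaS ~ TE ~ DG. Within the
    # entorhinal subfields the anterior-lateral subfields are the most
    # vulnerable and the caudal subfields (EC, ECL) the least.
    susc = {
        "PrS-PaS": 0.25,
        "S": 0.60,
        "CA1": 1.00,
        "CA2": 0.50,
        "CA3": 0.45,
        "DG": 0.25,
        "SRLM": 0.0,
        "PP": 0.0,
        "Eo": 0.95,
        "ER": 0.95,
        "EMI": 1.05,
        "EI": 1.00,
        "ELr": 1.05,
        "ELc": 1.00,
        "EC": 0.70,
        "ECL": 0.70,
        "BA35": 0.80,
        "BA36": 0.50,
        "TE": 0.25,
        "TF": 0.40,
        "TH": 0.40,
    }
    return susc


@dataclass
class GroundTruth:
    """Generative parameters, recorded verbatim alongside each cohort.

    ``thinning_beta`` is the fractional thickness lost per unit burden
    (thickness = template * (1 - beta * burden)); ``age_slope`` is in mm
    per year of age beyond 75. ``severities`` is filled in by
    :func:`simulate_cohort` with the realized per-specimen severity scalars.
    """

    severity_scale: float = 0.35
    b_coef: float = 0.50  # log-severity increment per B-score unit
    age_coef: float = 0.03  # log-severity increment per year beyond 75
    susceptibility: Dict[str, float] = field(default_factory=_default_susceptibility)
    gradient_slope: float = 1.2  # exponential AP decay rate
    thinning_beta: float = 0.15
    age_slope: float = -0.01
    burden_noise_sigma: float = 0.30  # lognormal sigma, voxelwise
    thickness_noise_sigma: float = 0.25  # mm, per vertex
    rating_noise_sigma: float = 0.15  # on burden before discretization
    slab_drop_prob: float = 0.15  # per coronal slab
    seed: int = 0
    severities: Optional[List[float]] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


def default_truth() -> GroundTruth:
    return GroundTruth()


@dataclass
class Specimen:
    record: SpecimenRecord
    burden: Optional[BurdenVolume]
    segmentation: Optional[np.ndarray]
    field: SkeletonField  # generated per-vertex thickness (with noise)
    true_thickness: np.ndarray  # noise-free per-vertex thickness
    vertex_burden: np.ndarray  # noise-free per-vertex burden driving thinning


@dataclass
class Cohort:
    template: TemplateAtlas
    specimens: List[Specimen]
    truth: GroundTruth
    affected_vertices: np.ndarray  # bool: ground-truth thinning region

    @property
    def n_specimens(self) -> int:
        return len(self.specimens)

    @property
    def records(self) -> List[SpecimenRecord]:
        return [s.record for s in self.specimens]


def _thinning_susceptibility(
    template: TemplateAtlas, truth: GroundTruth
) -> np.ndarray:
    """Effective thinning susceptibility per skeleton vertex.

    The SRLM and perforant pathway do not accumulate tangles themselves but
    thin with the burden of their paired source region (CA1 and ERC
    respectively).
    """
    erc_mean = float(
        np.mean([truth.susceptibility[template.label_table[c]] for c in ERC_SUBFIELD_CODES])
    )
    per_vertex = np.zeros(template.n_vertices)
    for i, code in enumerate(template.vertex_labels):
        name = template.label_table[int(code)]
        if name == "SRLM":
            per_vertex[i] = truth.susceptibility["CA1"]
        elif name == "PP":
            per_vertex[i] = erc_mean
        else:
            per_vertex[i] = truth.susceptibility[name]
    return per_vertex


def _severity(truth: GroundTruth, b_score: int, age: float) -> float:
    return truth.severity_scale * float(
        np.exp(truth.b_coef * b_score + truth.age_coef * (age - 75.0))
    )


def _draw_demographics(rng: np.random.Generator, n: int):
    ages = np.clip(rng.normal(79.0, 10.0, size=n), 57.0, 99.0)
    sexes = np.where(rng.random(n) < 0.62, "M", "F")
    b_scores = rng.choice(4, size=n, p=np.array([4, 17, 15, 11]) / 47.0)
    return ages, sexes, b_scores


def _discretize_rating(x: float) -> float:
    idx = int(np.searchsorted(RATING_CUTS, x, side="right"))
    return RATING_LEVELS[idx]


def simulate_cohort(
    template: TemplateAtlas,
    n_specimens: int,
    truth: Optional[GroundTruth] = None,
    seed: int = 0,
    realize_volumes: bool = True,
) -> Cohort:
    """Generate a cohort of synthetic specimens on the template.

    Each specimen comprises a demographics/ratings record, a voxelwise NFT
    burden volume with a slab-wise validity mask, a binary segmentation
    realizing the burden-thinned cortical ribbon, and the per-vertex
    thickness field it encodes. With ``realize_volumes=False`` only the
    per-vertex fields and records are generated (the generative model is
    identical; the raster realization is skipped), which is the fast path
    for statistical calibration experiments.
    """
    if n_specimens < 4:
        raise ValueError("n_specimens must be >= 4")
    truth = truth if truth is not None else default_truth()
    master = np.random.default_rng(seed)
    ages, sexes, b_scores = _draw_demographics(master, n_specimens)
    streams = master.spawn(n_specimens)

    V = template.n_vertices
    susc_thin = _thinning_susceptibility(template, truth)
    grad_v = np.exp(-truth.gradient_slope * template.vertex_u)
    severities = np.array(
        [_severity(truth, int(b), float(a)) for b, a in zip(b_scores, ages)]
    )

    # reject thinning so strong that the deterministic thickness goes <= 0
    max_vb = severities.max() * (susc_thin * grad_v)
    worst = template.vertex_thickness * (1.0 - truth.thinning_beta * max_vb)
    worst = worst + truth.age_slope * (ages.max() - 75.0 if truth.age_slope < 0
                                       else ages.min() - 75.0)
    if np.any(worst <= 0):
        raise ValueError(
            "thinning_beta too large: deterministic thickness would be "
            "non-positive at some vertices"
        )

    # precompute raster helpers once
    if realize_volumes:
        fg = template.foreground_mask()
        labels = template.label_volume
        nx, ny, nz = template.grid_shape
        sx = template.spacing[0]
        u_vox = template.ap_fraction(np.arange(nx) * sx)[:, None, None]
        susc_vox = np.zeros(nx * ny * nz)
        flat_lab = labels.ravel()
        code_susc = {
            c: truth.susceptibility[template.label_table[c]]
            for c in template.label_table
        }
        for c, s in code_susc.items():
            susc_vox[flat_lab == c] = s
        susc_vox = susc_vox.reshape(template.grid_shape)
        base_vox = susc_vox * np.broadcast_to(
            np.exp(-truth.gradient_slope * u_vox), template.grid_shape
        )
        # nearest skeleton vertex of every voxel, for the deformed
        # segmentation realization
        tree = cKDTree(template.skeleton_vertices)
        centers = np.column_stack(
            [
                g.ravel() * s
                for g, s in zip(
                    np.meshgrid(
                        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
                    ),
                    template.spacing,
                )
            ]
        )
        vox_dist, vox_near = tree.query(centers, workers=-1)
        vox_dist = vox_dist.reshape(template.grid_shape)
        vox_near = vox_near.reshape(template.grid_shape)
        # ROI voxel masks of the rating sites
        site_masks = {}
        site_masks["ERC"] = np.isin(labels, ERC_SUBFIELD_CODES)
        site_masks["DG"] = labels == template.code_of("DG")
        site_masks["CA1"] = labels == template.code_of("CA1")

    specimens: List[Specimen] = []
    for i in range(n_specimens):
        rng = streams[i]
        rec_age, rec_sex, rec_b = float(ages[i]), str(sexes[i]), int(b_scores[i])
        sev = severities[i]

        # per-vertex burden driving thinning (noise-free) and thickness
        vb = sev * susc_thin * grad_v
        t_true = template.vertex_thickness * (1.0 - truth.thinning_beta * vb)
        t_true = t_true + truth.age_slope * (rec_age - 75.0)
        noise = (
            rng.normal(0.0, truth.thickness_noise_sigma, size=V)
            if truth.thickness_noise_sigma > 0
            else np.zeros(V)
        )
        t_noisy = np.maximum(t_true + noise, 0.3 * min(template.spacing))

        # slab-wise dropout shared by the burden validity mask and the
        # thickness field (excluded histology sections)
        nx_ = template.grid_shape[0]
        dropped = rng.random(nx_) < truth.slab_drop_prob
        vert_slab = np.clip(
            np.round(template.skeleton_vertices[:, 0] / template.spacing[0]),
            0,
            nx_ - 1,
        ).astype(int)
        vert_valid = ~dropped[vert_slab]
        fld = SkeletonField(thickness=t_noisy.copy(), valid=vert_valid)

        burden_vol = None
        seg = None
        if realize_volumes:
            base = sev * base_vox
            if truth.burden_noise_sigma > 0:
                z = rng.normal(0.0, 1.0, size=template.grid_shape)
                ln = np.exp(
                    truth.burden_noise_sigma * z - 0.5 * truth.burden_noise_sigma**2
                )
            else:
                ln = 1.0
            values = np.where(fg, base * ln, 0.0)
            valid = fg & ~dropped[:, None, None]
            burden_vol = BurdenVolume(values=values, valid_mask=valid)
            # half-voxel interface convention (see atlas voxelization)
            seg = (
                vox_dist
                <= 0.5 * t_noisy[vox_near] + 0.5 * float(np.mean(template.spacing))
            ).astype(np.uint8)

        # semi-quantitative ratings: tau from ipsilateral site burden,
        # co-pathologies from site-level categorical draws
        ratings: Dict[str, float] = {}
        tau_sites = []
        for site in _RATING_SITES:
            if realize_volumes:
                m = site_masks[site] & burden_vol.valid_mask
                site_burden = (
                    float(burden_vol.values[m].mean()) if m.any() else 0.0
                )
            else:
                if site == "ERC":
                    vm = np.isin(template.vertex_labels, ERC_SUBFIELD_CODES)
                else:
                    vm = template.vertex_labels == template.code_of(site)
                site_burden = (
                    float((sev * grad_v[vm] * susc_thin[vm]).mean())
                    if vm.any()
                    else 0.0
                )
            noisy = site_burden + (
                rng.normal(0.0, truth.rating_noise_sigma)
                if truth.rating_noise_sigma > 0
                else 0.0
            )
            tau_sites.append(_discretize_rating(max(noisy, 0.0)))
        ratings["tau"] = float(np.mean(tau_sites))
        for path, probs in _COPATH_SITE_PROBS.items():
            sites = rng.choice(RATING_LEVELS, size=3, p=probs)
            ratings[path] = float(np.mean(sites))

        rec = SpecimenRecord(
            specimen_id=f"SYN{i:03d}",
            age=rec_age,
            sex=rec_sex,
            b_score=rec_b,
            ratings=ratings,
        )
        specimens.append(
            Specimen(
                record=rec,
                burden=burden_vol,
                segmentation=seg,
                field=fld,
                true_thickness=t_true,
                vertex_burden=vb,
            )
        )

    # ground-truth affected region: vertices whose cohort-mean expected
    # thinning exceeds half the maximum expected thinning
    mean_thin = (
        truth.thinning_beta
        * float(severities.mean())
        * susc_thin
        * grad_v
        * template.vertex_thickness
    )
    affected = mean_thin >= 0.5 * mean_thin.max() if mean_thin.max() > 0 else (
        np.zeros(V, dtype=bool)
    )

    truth_out = GroundTruth(**{**truth.to_dict(), "seed": seed})
    truth_out.severities = [float(s) for s in severities]
    return Cohort(
        template=template,
        specimens=specimens,
        truth=truth_out,
        affected_vertices=affected,
    )


def simulate_label_votes(
    template: TemplateAtlas,
    n_raters: int,
    flip_rate: float,
    seed: int = 0,
) -> List[np.ndarray]:
    """Simulate rater label volumes with boundary-localized corruptions.

    Each rater's volume equals the template labels except at label-boundary
    voxels (voxels with a 6-neighbor of a different label), which are
    independently flipped with probability ``flip_rate`` to a label drawn
    uniformly from the differing neighbor values.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5)")
    if n_raters < 3:
        raise ValueError("n_raters must be >= 3")
    labels = template.label_volume
    rng = np.random.default_rng(seed)

    # collect differing 6-neighbor labels per boundary voxel
    neighbor_labels = []
    for axis in range(3):
        for shift in (-1, 1):
            rolled = np.roll(labels, shift, axis=axis)
            # mark out-of-bounds wrap as self (no difference)
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = labels[tuple(sl)]
            neighbor_labels.append(rolled)
    neighbor_labels = np.stack(neighbor_labels, axis=0)
    differs = neighbor_labels != labels[None]
    boundary = differs.any(axis=0)
    bidx = np.argwhere(boundary)
    ncand = neighbor_labels[:, boundary]  # (6, Nb)
    dcand = differs[:, boundary]

    votes = []
    for _ in range(n_raters):
        vol = labels.copy()
        flips = rng.random(bidx.shape[0]) < flip_rate
        if flips.any():
            which = np.where(flips)[0]
            for j in which:
                choices = ncand[dcand[:, j], j]
                vol[tuple(bidx[j])] = rng.choice(choices)
        votes.append(vol)
    return votes
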