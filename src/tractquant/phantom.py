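"""Synthetic orientation-field phantoms with known ground truth.

Every downstream stage of the pipeline (tracking, two-ROI selection,
connectivity matrices, density maps, laterality) is validated on phantoms
built here: straight cylindrical fiber bundles, 90-degree crossing
configurations, designed streamline-yield ratios, and multi-subject cohorts
with a controlled left/right asymmetry.

A *bundle* is a cylinder around a straight centerline: voxels whose center
lies within ``radius_mm`` of the centerline segment carry a single unit
orientation parallel to the axis with QA ``qa_inside``; all other voxels
carry ``qa_outside``.  QA is piecewise constant so the QA-stopping behaviour
of the tracker is sharply testable.  End-cap label regions are placed at the
bundle termini and extend slightly beyond the cylinder ends so that tracked
endpoints -- which come to rest in the first sub-threshold voxel past the
bundle -- fall inside them.

Cohorts emulate a population with a designed hemispheric asymmetry: left and
right mirror-image bundles whose cross-sectional areas are scaled per
subject so that the expected streamline-count laterality index equals
``target_li`` plus zero-mean noise.  Mirroring is about the grid's
mid-sagittal plane (x-index reflection) and hemisphere tags follow the side
of that plane.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectivity import LabelAtlas
from .tracking import OrientationField

__all__ = [
    "BundleSpec",
    "CohortSpec",
    "MirroredTemplate",
    "make_straight_bundle",
    "make_crossing_phantom",
    "make_yield_ratio_phantom",
    "make_cohort",
    "load_scenario",
    "write_phantom",
    "read_phantom",
    "load_orientation_field",
    "load_atlas",
]

logger = logging.getLogger(__name__)

# fixed entropy for the mirror-symmetric tie-break noise used by the
# rank-based membership rule (see _rank_membership)
_TIEBREAK_SEED = 0x7A3D


@dataclass(frozen=True)
class BundleSpec:
    """Geometry and contrast of one synthetic fiber bundle.

    ``centerline`` is an ordered list of world-mm control points; bundles
    here are straight, so the first and last control points define the axis
    (intermediate points must lie on that segment).
    """

    name: str
    centerline: Tuple[Tuple[float, float, float], ...]
    radius_mm: float
    qa_inside: float
    qa_outside: float
    endpoint_region_a: str
    endpoint_region_b: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("centerline needs >= 2 world-mm control points")
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")
        if not (0 < self.qa_inside <= 1):
            raise ValueError("qa_inside must be in (0, 1]")
        if not (0 <= self.qa_outside < 1):
            raise ValueError("qa_outside must be in [0, 1)")
        if not self.qa_inside > self.qa_outside:
            raise ValueError("qa_inside must exceed qa_outside")
        p0, p1 = pts[0], pts[-1]
        axis = p1 - p0
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("centerline endpoints coincide")
        for p in pts[1:-1]:
            lateral = np.linalg.norm(np.cross(p - p0, axis / norm))
            if lateral > 1e-6:
                raise ValueError("centerline control points must be collinear")

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.centerline, dtype=np.float64)

    @property
    def axis(self) -> np.ndarray:
        pts = self.points
        v = pts[-1] - pts[0]
        return v / np.linalg.norm(v)

    @property
    def length_mm(self) -> float:
        pts = self.points
        return float(np.linalg.norm(pts[-1] - pts[0]))


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic multi-subject cohort.

    ``target_li`` is the designed expected streamline-count laterality index
    (L - R) / (L + R); per-subject zero-mean Gaussian noise with standard
    deviation ``yield_noise_sd`` is added on the LI scale.  Per-subject RNG
    streams are derived deterministically from ``base_seed``.
    """

    n_subjects: int
    target_li: float
    yield_noise_sd: float
    base_seed: int

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not abs(self.target_li) < 1:
            raise ValueError(
                "|target_li| must be < 1: an LI of +/-1 implies a "
                "non-positive bundle area on one side"
            )
        if self.yield_noise_sd < 0:
            raise ValueError("yield_noise_sd must be non-negative")


@dataclass(frozen=True)
class MirroredTemplate:
    """Template for cohort generation: a left-hemisphere bundle whose
    right-hemisphere counterpart is its exact mirror image about the grid's
    mid-sagittal plane (x-index reflection)."""

    grid_shape: Tuple[int, int, int]
    voxel_size_mm: float
    bundle: BundleSpec
    cap_thickness_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        mid_x = (self.grid_shape[0] - 1) / 2.0 * self.voxel_size_mm
        pts = self.bundle.points
        if not np.all(pts[:, 0] + self.bundle.radius_mm < mid_x):
            raise ValueError(
                "template bundle (incl. radius) must lie strictly in the "
                "left half of the grid"
            )
        if abs(abs(self.bundle.axis[2]) - 1.0) > 1e-9:
            raise ValueError(
                "cohort template bundles must run along the grid z-axis "
                "(column-based area scaling)"
            )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grid_affine(voxel_size_mm: float) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = float(voxel_size_mm)
    return a


def _voxel_centers(grid_shape, voxel_size_mm: float) -> np.ndarray:
    """World-mm coordinates of all voxel centers, shape (X*Y*Z, 3)."""
    idx = np.indices(grid_shape).reshape(3, -1).T.astype(np.float64)
    return idx * float(voxel_size_mm)


def _segment_geometry(
    centers: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point distance to the segment [p0, p1], raw axial coordinate t
    (mm along the axis, unclipped), and lateral distance to the infinite
    axis line."""
    axis = p1 - p0
    length = np.linalg.norm(axis)
    u = axis / length
    rel = centers - p0
    t = rel @ u
    lateral = np.linalg.norm(rel - np.outer(t, u), axis=1)
    t_clip = np.clip(t, 0.0, length)
    closest = p0 + np.outer(t_clip, u)
    dist = np.linalg.norm(centers - closest, axis=1)
    return dist, t, lateral


def _check_margin(member_flat: np.ndarray, grid_shape, what: str) -> None:
    """Reject bundles that do not keep a 2-voxel margin to the grid faces."""
    member = member_flat.reshape(grid_shape)
    if not member.any():
        raise ValueError(f"{what} lies entirely outside the grid")
    idx = np.argwhere(member)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    if (lo < 2).any() or (hi > np.asarray(grid_shape) - 3).any():
        raise ValueError(
            f"{what} does not fit in the grid with a 2-voxel margin; "
            "enlarge the grid or shrink the bundle"
        )


def _cap_masks(
    dist: np.ndarray,
    t: np.ndarray,
    lateral: np.ndarray,
    length: float,
    radius: float,
    voxel_size: float,
    cap_thickness_mm: Optional[float],
) -> Tuple[np.ndarray, np.ndarray]:
    """End-cap label masks at the two termini of a bundle.

    Caps extend ``cap_thickness_mm`` (default 2 voxels) into the bundle and
    ``radius + 2 voxels`` beyond each end, with a lateral bound of
    ``radius + 1.5 voxels``: tracked endpoints come to rest at most one step
    plus one voxel past the cylinder (including its spherical end), so this
    envelope always contains them.
    """
    cap_in = 2.0 * voxel_size if cap_thickness_mm is None else cap_thickness_mm
    cap_out = radius + 2.0 * voxel_size
    lat_ok = lateral <= radius + 1.5 * voxel_size
    cap_a = lat_ok & (t >= -cap_out) & (t <= cap_in)
    cap_b = lat_ok & (t >= length - cap_in) & (t <= length + cap_out)
    if (cap_a & cap_b).any():
        raise ValueError("bundle too short: its two end caps overlap")
    return cap_a, cap_b


def _jitter_directions(
    directions: np.ndarray, sd_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Approximate angular jitter: add isotropic Gaussian noise of scale
    tan(sd) to each unit vector and renormalise."""
    noise = math.tan(math.radians(sd_deg)) * rng.standard_normal(directions.shape)
    v = directions + noise
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# single bundles and crossings
# ---------------------------------------------------------------------------

def make_straight_bundle(
    grid_shape: Tuple[int, int, int],
    voxel_size_mm: float,
    spec: BundleSpec,
    rng_seed: int = 0,
    *,
    cap_thickness_mm: Optional[float] = None,
    hemispheres: Tuple[str, str] = ("none", "none"),
    jitter_sd_deg: float = 0.0,
) -> Tuple[OrientationField, LabelAtlas]:
    """Build a straight cylindrical bundle phantom.

    In-bundle voxels (center within ``radius_mm`` of the centerline segment)
    carry one unit orientation parallel to the axis with ``qa_inside``; all
    other voxels carry the same axis direction with ``qa_outside``.  The
    atlas labels two end-cap regions (1 = ``endpoint_region_a``,
    2 = ``endpoint_region_b``) at the termini.

    ``jitter_sd_deg`` optionally perturbs in-bundle orientations (seeded by
    ``rng_seed``); the default phantom is exactly noiseless.
    """
    affine = _grid_affine(voxel_size_mm)
    centers = _voxel_centers(grid_shape, voxel_size_mm)
    pts = spec.points
    p0, p1 = pts[0], pts[-1]
    dist, t, lateral = _segment_geometry(centers, p0, p1)
    member = dist <= spec.radius_mm + 1e-9
    _check_margin(member, grid_shape, f"bundle '{spec.name}'")

    n_vox = centers.shape[0]
    directions = np.tile(spec.axis, (n_vox, 1)).reshape(*grid_shape, 1, 3)
    if jitter_sd_deg > 0:
        rng = np.random.default_rng(rng_seed)
        flat = directions.reshape(-1, 3)
        flat[member] = _jitter_directions(flat[member], jitter_sd_deg, rng)
    qa = np.where(member, spec.qa_inside, spec.qa_outside).reshape(*grid_shape, 1)
    field = OrientationField(directions=directions, qa=qa, affine=affine)

    cap_a, cap_b = _cap_masks(
        dist, t, lateral, spec.length_mm, spec.radius_mm, voxel_size_mm,
        cap_thickness_mm,
    )
    labels = np.zeros(n_vox, dtype=np.int32)
    labels[cap_a] = 1
    labels[cap_b] = 2
    regions = pd.DataFrame(
        {
            "label": [1, 2],
            "name": [spec.endpoint_region_a, spec.endpoint_region_b],
            "hemisphere": list(hemispheres),
        }
    )
    atlas = LabelAtlas(labels.reshape(grid_shape), affine=affine, regions=regions)
    return field, atlas


def make_crossing_phantom(
    grid_shape: Tuple[int, int, int],
    voxel_size_mm: float,
    spec_a: BundleSpec,
    spec_b: BundleSpec,
    crossing_angle_deg: float,
    rng_seed: int = 0,
    *,
    cap_thickness_mm: Optional[float] = None,
) -> Tuple[OrientationField, LabelAtlas]:
    """Two straight bundles crossing at ``crossing_angle_deg``.

    Voxels inside both bundles carry both unit orientations (K = 2), each
    with its own bundle's QA; slot 0 is bundle A, slot 1 is bundle B.
    Background voxels carry bundle A's axis with ``spec_a.qa_outside``.
    The stated crossing angle is validated against the axial angle between
    the two centerlines (within 1 degree).  Four end-cap regions are
    labelled 1..4 in the order (A_a, A_b, B_a, B_b).
    """
    if not (0 < crossing_angle_deg <= 90):
        raise ValueError("crossing_angle_deg must be in (0, 90]")
    cosang = abs(float(spec_a.axis @ spec_b.axis))
    actual = math.degrees(math.acos(min(1.0, cosang)))
    if abs(actual - crossing_angle_deg) > 1.0:
        raise ValueError(
            f"centerlines cross at {actual:.1f} deg, not the stated "
            f"{crossing_angle_deg:.1f} deg"
        )

    affine = _grid_affine(voxel_size_mm)
    centers = _voxel_centers(grid_shape, voxel_size_mm)
    n_vox = centers.shape[0]

    geom = {}
    for tag, spec in (("a", spec_a), ("b", spec_b)):
        pts = spec.points
        dist, t, lateral = _segment_geometry(centers, pts[0], pts[-1])
        member = dist <= spec.radius_mm + 1e-9
        _check_margin(member, grid_shape, f"bundle '{spec.name}'")
        geom[tag] = (member, dist, t, lateral)

    member_a = geom["a"][0]
    member_b = geom["b"][0]
    if not (member_a & member_b).any():
        logger.warning(
            "crossing phantom: bundles '%s' and '%s' do not overlap",
            spec_a.name, spec_b.name,
        )

    directions = np.zeros((n_vox, 2, 3), dtype=np.float64)
    qa = np.zeros((n_vox, 2), dtype=np.float64)
    directions[:, 0] = spec_a.axis
    qa[:, 0] = np.where(member_a, spec_a.qa_inside, spec_a.qa_outside)
    directions[member_b, 1] = spec_b.axis
    qa[member_b, 1] = spec_b.qa_inside
    field = OrientationField(
        directions=directions.reshape(*grid_shape, 2, 3),
        qa=qa.reshape(*grid_shape, 2),
        affine=affine,
    )

    labels = np.zeros(n_vox, dtype=np.int32)
    names = []
    next_label = 1
    for tag, spec in (("a", spec_a), ("b", spec_b)):
        _, dist, t, lateral = geom[tag]
        cap_a, cap_b = _cap_masks(
            dist, t, lateral, spec.length_mm, spec.radius_mm, voxel_size_mm,
            cap_thickness_mm,
        )
        for cap, name in ((cap_a, spec.endpoint_region_a),
                          (cap_b, spec.endpoint_region_b)):
            if (labels[cap] != 0).any():
                raise ValueError(
                    "end-cap regions of the two bundles overlap; separate "
                    "the bundle termini"
                )
            labels[cap] = next_label
            names.append(name)
            next_label += 1

    regions = pd.DataFrame(
        {
            "label": list(range(1, next_label)),
            "name": names,
            "hemisphere": ["none"] * len(names),
        }
    )
    atlas = LabelAtlas(labels.reshape(grid_shape), affine=affine, regions=regions)
    return field, atlas


# ---------------------------------------------------------------------------
# column-based membership (yield-calibrated bundles)
# ---------------------------------------------------------------------------
#
# Yield-calibrated bundles run along the grid z-axis and are built from
# whole *columns* (one (x, y) cross-section cell over the full axial
# extent).  Under uniform in-mask seeding every column of a bundle yields
# the same expected number of retained streamlines, so the expected yield
# ratio of two bundles equals their column-count ratio exactly -- and full
# columns leave no sub-threshold gaps for the tracker to stop in, which
# per-voxel membership truncation would create.

def _column_eps(nx: int, ny: int) -> np.ndarray:
    """Mirror-symmetric (x-reflection) tie-break noise for column ranking.

    Column lateral distances on a regular grid are heavily tied (symmetric
    offsets); a tiny deterministic epsilon breaks the ties so membership
    can be targeted to an exact column count, while the x-symmetry makes
    mirrored bundles select mirrored columns.
    """
    rng = np.random.default_rng(_TIEBREAK_SEED)
    eps = rng.uniform(0.0, 1.0, size=(nx, ny))
    return 0.5 * (eps + eps[::-1])


def _select_columns(
    grid_shape,
    voxel_size_mm: float,
    center_xy: Tuple[float, float],
    n_columns: int,
) -> Tuple[np.ndarray, float]:
    """The ``n_columns`` (x, y) columns closest to a bundle axis.

    Returns (2D boolean mask over (nx, ny), effective radius in mm).
    """
    nx, ny = grid_shape[0], grid_shape[1]
    xs = np.arange(nx) * voxel_size_mm
    ys = np.arange(ny) * voxel_size_mm
    dist = np.hypot(xs[:, None] - center_xy[0], ys[None, :] - center_xy[1])
    key = (dist + 1e-6 * voxel_size_mm * _column_eps(nx, ny)).reshape(-1)
    order = np.argsort(key, kind="stable")[:n_columns]
    mask = np.zeros(nx * ny, dtype=bool)
    mask[order] = True
    r_eff = float(dist.reshape(-1)[order].max())
    return mask.reshape(nx, ny), r_eff


def _column_count(radius_mm: float, voxel_size_mm: float,
                  grid_shape, center_xy) -> int:
    nx, ny = grid_shape[0], grid_shape[1]
    xs = np.arange(nx) * voxel_size_mm
    ys = np.arange(ny) * voxel_size_mm
    dist = np.hypot(xs[:, None] - center_xy[0], ys[None, :] - center_xy[1])
    return int((dist <= radius_mm + 1e-9).sum())


def _column_bundle_member(
    grid_shape,
    voxel_size_mm: float,
    col_mask: np.ndarray,
    z0_mm: float,
    z1_mm: float,
) -> np.ndarray:
    """3D membership of a column bundle with flat axial ends, flattened."""
    nz = grid_shape[2]
    zc = np.arange(nz) * voxel_size_mm
    z_ok = (zc >= z0_mm - 1e-9) & (zc <= z1_mm + 1e-9)
    member = col_mask[:, :, None] & z_ok[None, None, :]
    return member.reshape(-1)


def make_yield_ratio_phantom(
    grid_shape: Tuple[int, int, int],
    voxel_size_mm: float,
    yield_ratio: float,
    *,
    radius_mm: float = 3.0,
    length_mm: float = 36.0,
    qa_inside: float = 0.6,
    qa_outside: float = 0.0,
    hub_name: str = "HUB",
    strong_name: str = "STRONG_END",
    weak_name: str = "WEAK_END",
) -> Tuple[OrientationField, LabelAtlas]:
    """Two parallel bundles sharing a hub region, with a designed
    streamline-yield ratio.

    Both bundles run along z; their *upper* end caps are merged into one
    hub region (label 1) so the phantom exposes two region pairs,
    (hub, strong) and (hub, weak).  Bundle cross-sections are whole-column
    selections calibrated so the column counts -- hence the expected
    streamline yields under uniform in-mask seeding -- are in the exact
    ratio ``yield_ratio`` : 1 (the strong count is re-rounded to make the
    ratio of the two integers as close to exact as the weak count allows).
    """
    if yield_ratio <= 0:
        raise ValueError("yield_ratio must be positive")
    affine = _grid_affine(voxel_size_mm)
    centers = _voxel_centers(grid_shape, voxel_size_mm)
    vs = float(voxel_size_mm)

    nx = grid_shape[0]
    x_strong = (nx - 1) * vs * 0.27
    x_weak = (nx - 1) * vs * 0.73
    y_c = (grid_shape[1] - 1) * vs / 2.0
    z0 = (grid_shape[2] - 1) * vs / 2.0 - length_mm / 2.0
    z1 = z0 + length_mm

    c_base = _column_count(radius_mm, vs, grid_shape, (x_strong, y_c))
    n_cols_w = max(1, int(round(c_base / yield_ratio)))
    n_cols_s = max(1, int(round(n_cols_w * yield_ratio)))
    cols_s, r_s = _select_columns(grid_shape, vs, (x_strong, y_c), n_cols_s)
    cols_w, r_w = _select_columns(grid_shape, vs, (x_weak, y_c), n_cols_w)
    mask_s = _column_bundle_member(grid_shape, vs, cols_s, z0, z1)
    mask_w = _column_bundle_member(grid_shape, vs, cols_w, z0, z1)
    _check_margin(mask_s, grid_shape, "strong bundle")
    _check_margin(mask_w, grid_shape, "weak bundle")
    if (mask_s & mask_w).any():
        raise ValueError("bundles overlap; enlarge the grid")

    p0_s = np.array([x_strong, y_c, z0]); p1_s = np.array([x_strong, y_c, z1])
    p0_w = np.array([x_weak, y_c, z0]); p1_w = np.array([x_weak, y_c, z1])
    dist_s, t_s, lat_s = _segment_geometry(centers, p0_s, p1_s)
    dist_w, t_w, lat_w = _segment_geometry(centers, p0_w, p1_w)

    n_vox = centers.shape[0]
    directions = np.tile(np.array([0.0, 0.0, 1.0]), (n_vox, 1))
    qa = np.where(mask_s | mask_w, qa_inside, qa_outside)
    field = OrientationField(
        directions=directions.reshape(*grid_shape, 1, 3),
        qa=qa.reshape(*grid_shape, 1),
        affine=affine,
    )

    labels = np.zeros(n_vox, dtype=np.int32)
    cap_hub_s, cap_strong = _cap_masks(
        dist_s, t_s, lat_s, length_mm, r_s, vs, None
    )
    cap_hub_w, cap_weak = _cap_masks(
        dist_w, t_w, lat_w, length_mm, r_w, vs, None
    )
    labels[cap_strong] = 2
    labels[cap_weak] = 3
    labels[cap_hub_s | cap_hub_w] = 1
    regions = pd.DataFrame(
        {
            "label": [1, 2, 3],
            "name": [hub_name, strong_name, weak_name],
            "hemisphere": ["none", "none", "none"],
        }
    )
    atlas = LabelAtlas(labels.reshape(grid_shape), affine=affine, regions=regions)
    return field, atlas


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _mirror_point(p: np.ndarray, nx: int, voxel_size_mm: float) -> np.ndarray:
    q = np.array(p, dtype=np.float64)
    q[0] = (nx - 1) * voxel_size_mm - q[0]
    return q


def make_cohort(
    template_phantom: MirroredTemplate,
    cohort: CohortSpec,
) -> List[Tuple[OrientationField, LabelAtlas]]:
    """Generate per-subject phantoms with a designed left/right asymmetry.

    For each subject the designed LI is ``target_li`` plus Gaussian noise
    (sd ``yield_noise_sd``); the left and right bundle cross-sectional
    areas are then scaled -- via column-based membership targeting the
    column counts ``c0 * (1 + li)`` and ``c0 * (1 - li)`` -- so the
    expected streamline-count LI under uniform seeding over the union mask
    equals the designed value (to within column-count rounding, well below
    one percent at the default cross-section).  Per-streamline geometry is
    identical on both sides, so the LI isolates pure count asymmetry.

    With ``target_li = 0`` and zero noise, every subject's left and right
    bundles are exact mirror images voxel-for-voxel.

    Atlas labels: 1/2 = left region a/b, 3/4 = right region a/b, with
    hemisphere tags L, L, R, R.
    """
    tpl = template_phantom
    grid_shape = tpl.grid_shape
    vs = float(tpl.voxel_size_mm)
    bundle = tpl.bundle
    affine = _grid_affine(vs)
    centers = _voxel_centers(grid_shape, vs)
    nx = grid_shape[0]

    pts = bundle.points
    p0_l, p1_l = pts[0], pts[-1]
    if p0_l[2] > p1_l[2]:
        p0_l, p1_l = p1_l, p0_l
    p0_r = _mirror_point(p0_l, nx, vs)
    p1_r = _mirror_point(p1_l, nx, vs)
    axis_l = (p1_l - p0_l) / np.linalg.norm(p1_l - p0_l)
    axis_r = (p1_r - p0_r) / np.linalg.norm(p1_r - p0_r)
    length = bundle.length_mm
    z0, z1 = p0_l[2], p1_l[2]
    center_l = (float(p0_l[0]), float(p0_l[1]))
    center_r = (float(p0_r[0]), float(p0_r[1]))

    dist_l, t_l, lat_l = _segment_geometry(centers, p0_l, p1_l)
    dist_r, t_r, lat_r = _segment_geometry(centers, p0_r, p1_r)
    c0 = _column_count(bundle.radius_mm, vs, grid_shape, center_l)
    if c0 == 0:
        raise ValueError("template bundle contains no columns")

    children = np.random.SeedSequence(cohort.base_seed).spawn(cohort.n_subjects)
    out: List[Tuple[OrientationField, LabelAtlas]] = []
    n_vox = centers.shape[0]
    for child in children:
        rng = np.random.default_rng(child)
        li = cohort.target_li
        if cohort.yield_noise_sd > 0:
            li += rng.normal(0.0, cohort.yield_noise_sd)
        li = float(np.clip(li, -0.95, 0.95))
        n_left = max(1, int(round(c0 * (1.0 + li))))
        n_right = max(1, int(round(c0 * (1.0 - li))))
        cols_l, r_l = _select_columns(grid_shape, vs, center_l, n_left)
        cols_r, r_r = _select_columns(grid_shape, vs, center_r, n_right)
        mask_l = _column_bundle_member(grid_shape, vs, cols_l, z0, z1)
        mask_r = _column_bundle_member(grid_shape, vs, cols_r, z0, z1)
        _check_margin(mask_l, grid_shape, "left bundle")
        _check_margin(mask_r, grid_shape, "right bundle")
        if (mask_l & mask_r).any():
            raise ValueError("left and right bundles overlap; widen the grid")

        directions = np.tile(axis_l, (n_vox, 1))
        directions[mask_r] = axis_r
        qa = np.where(mask_l | mask_r, bundle.qa_inside, bundle.qa_outside)
        field = OrientationField(
            directions=directions.reshape(*grid_shape, 1, 3),
            qa=qa.reshape(*grid_shape, 1),
            affine=affine,
        )

        labels = np.zeros(n_vox, dtype=np.int32)
        caps_l = _cap_masks(dist_l, t_l, lat_l, length, r_l, vs,
                            tpl.cap_thickness_mm)
        caps_r = _cap_masks(dist_r, t_r, lat_r, length, r_r, vs,
                            tpl.cap_thickness_mm)
        for lab, cap in zip((1, 2, 3, 4), (*caps_l, *caps_r)):
            if (labels[cap] != 0).any():
                raise ValueError("cohort end-cap regions overlap")
            labels[cap] = lab
        regions = pd.DataFrame(
            {
                "label": [1, 2, 3, 4],
                "name": [
                    f"{bundle.endpoint_region_a}_L",
                    f"{bundle.endpoint_region_b}_L",
                    f"{bundle.endpoint_region_a}_R",
                    f"{bundle.endpoint_region_b}_R",
                ],
                "hemisphere": ["L", "L", "R", "R"],
            }
        )
        atlas = LabelAtlas(labels.reshape(grid_shape), affine=affine,
                           regions=regions)
        out.append((field, atlas))
    return out


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------

def load_scenario(path) -> dict:
    """Build phantom specs from a YAML scenario file.

    Recognized top-level keys (all optional):

    * ``bundles`` -- list of :class:`BundleSpec` mappings,
    * ``cohort`` -- a :class:`CohortSpec` mapping,
    * ``template`` -- a :class:`MirroredTemplate` mapping whose ``bundle``
      entry is either an inline BundleSpec mapping or the name of a bundle
      from ``bundles``.

    Returns a dict with keys ``bundles`` (name -> BundleSpec), ``cohort``
    (CohortSpec or None) and ``template`` (MirroredTemplate or None).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    bundles = {}
    for entry in data.get("bundles", []):
        spec = BundleSpec(
            name=entry["name"],
            centerline=tuple(tuple(p) for p in entry["centerline"]),
            radius_mm=float(entry["radius_mm"]),
            qa_inside=float(entry["qa_inside"]),
            qa_outside=float(entry["qa_outside"]),
            endpoint_region_a=entry["endpoint_region_a"],
            endpoint_region_b=entry["endpoint_region_b"],
        )
        bundles[spec.name] = spec
    cohort = None
    if "cohort" in data:
        cohort = CohortSpec(**data["cohort"])
    template = None
    if "template" in data:
        tpl = dict(data["template"])
        bundle = tpl.pop("bundle")
        if isinstance(bundle, str):
            bundle = bundles[bundle]
        else:
            bundle = BundleSpec(
                name=bundle["name"],
                centerline=tuple(tuple(p) for p in bundle["centerline"]),
                radius_mm=float(bundle["radius_mm"]),
                qa_inside=float(bundle["qa_inside"]),
                qa_outside=float(bundle["qa_outside"]),
                endpoint_region_a=bundle["endpoint_region_a"],
                endpoint_region_b=bundle["endpoint_region_b"],
            )
        template = MirroredTemplate(
            grid_shape=tuple(tpl.pop("grid_shape")),
            voxel_size_mm=float(tpl.pop("voxel_size_mm")),
            bundle=bundle,
            **tpl,
        )
    return {"bundles": bundles, "cohort": cohort, "template": template}


# ---------------------------------------------------------------------------
# NIfTI round trips
# ---------------------------------------------------------------------------

def write_phantom(field: OrientationField, atlas: LabelAtlas, directory) -> None:
    """Write a phantom to ``directory``.

    Layout: ``directions.nii.gz`` (4D float64, x,y,z,3K -- K interleaved
    direction triplets), ``qa.nii.gz`` (4D float64, x,y,z,K),
    ``labels.nii.gz`` (3D int32) and ``regions.tsv`` (columns
    label, name, hemisphere).  Arrays round-trip bit-exactly; the affine
    round-trips within NIfTI header (float32) precision.
    """
    if field.shape != atlas.labels.shape:
        raise ValueError("orientation field and atlas grids differ")
    if not np.allclose(field.affine, atlas.affine, atol=1e-6):
        raise ValueError("orientation field and atlas affines differ")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    x, y, z, k, _ = field.directions.shape
    dirs4d = field.directions.reshape(x, y, z, 3 * k)
    nib.save(nib.Nifti1Image(dirs4d, field.affine),
             directory / "directions.nii.gz")
    nib.save(nib.Nifti1Image(field.qa, field.affine), directory / "qa.nii.gz")
    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.int32), atlas.affine),
        directory / "labels.nii.gz",
    )
    atlas.regions.to_csv(directory / "regions.tsv", sep="\t", index=False)


def load_orientation_field(directions_path, qa_path) -> OrientationField:
    """Read an orientation field from a direction-triplet NIfTI (x,y,z,3K)
    and a QA NIfTI (x,y,z,K)."""
    dimg = nib.load(str(directions_path))
    qimg = nib.load(str(qa_path))
    dirs4d = np.asarray(dimg.dataobj, dtype=np.float64)
    qa = np.asarray(qimg.dataobj, dtype=np.float64)
    if dirs4d.ndim == 3:
        dirs4d = dirs4d[..., None]
    if qa.ndim == 3:
        qa = qa[..., None]
    if dirs4d.shape[-1] % 3 != 0:
        raise ValueError("directions volume must hold 3K channels")
    k = dirs4d.shape[-1] // 3
    if qa.shape[-1] != k:
        raise ValueError("qa volume channel count must match K")
    directions = dirs4d.reshape(*dirs4d.shape[:3], k, 3)
    return OrientationField(directions=directions, qa=qa,
                            affine=np.asarray(dimg.affine, dtype=np.float64))


def load_atlas(labels_path, regions_path) -> LabelAtlas:
    """Read a label atlas from a 3D integer NIfTI and a region-table TSV."""
    limg = nib.load(str(labels_path))
    labels = np.asarray(limg.dataobj)
    labels = np.rint(labels).astype(np.int32)
    regions = pd.read_csv(regions_path, sep="\t")
    return LabelAtlas(labels, affine=np.asarray(limg.affine, dtype=np.float64),
                      regions=regions)


def read_phantom(directory) -> Tuple[OrientationField, LabelAtlas]:
    """Inverse of :func:`write_phantom`."""
    directory = Path(directory)
    field = load_orientation_field(
        directory / "directions.nii.gz", directory / "qa.nii.gz"
    )
    atlas = load_atlas(directory / "labels.nii.gz", directory / "regions.tsv")
    return field, atlas
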