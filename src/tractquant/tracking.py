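"""Deterministic streamline tractography over discrete fiber-orientation fields.

The tracker walks a regular 3D grid in which every voxel stores up to K
candidate fiber orientations (axial, sign-ambiguous unit vectors) together
with a quantitative-anisotropy (QA) scalar per orientation.  Propagation is
the classic deterministic peak-following scheme used for whole-brain
tractography of diffusion-MRI reconstructions:

1. at the current position, look up the orientations of the *nearest* voxel
   (no interpolation);
2. among orientations whose QA is at or above ``qa_threshold``, evaluate both
   sign polarities and select the one most congruent with the incoming
   direction, provided the turning angle is below ``angle_threshold_deg``;
3. smooth the moving direction as a weighted mean of the incoming direction
   (weight ``smoothing_weight``) and the selected orientation, and advance by
   ``step_size_mm``;
4. stop when QA drops below threshold, when no orientation is congruent
   enough, when the track leaves the grid, or when it reaches
   ``max_length_mm``.

Seeds are placed at random sub-voxel positions inside a seed mask and tracked
bidirectionally; assembled tracks shorter than ``min_length_mm`` are
discarded.  All randomness flows through a single integer seed, so identical
inputs give bit-identical output.

Coordinate conventions follow NIfTI: voxel indices are 0-based, a voxel's
*center* maps through the 4x4 voxel-to-world affine, and world coordinates
are in millimetres (RAS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml
from nibabel.streamlines import Tractogram
from nibabel.streamlines.header import Field
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

__all__ = [
    "TerminationReason",
    "TrackingParams",
    "OrientationField",
    "Streamline",
    "StreamlineSet",
    "select_orientation",
    "propagate_step",
    "track_from_seed",
    "whole_brain_track",
]

_UNIT_TOL = 1e-6
# Seeds are propagated in chunks so memory stays bounded at
# chunk * max_steps * 3 * 8 bytes per half-track buffer.
_SEED_CHUNK = 2048


class TerminationReason(str, Enum):
    """Why propagation stopped at one end of a streamline."""

    QA_BELOW_THRESHOLD = "qa_below_threshold"
    NO_CONGRUENT_ORIENTATION = "no_congruent_orientation"
    LEFT_FIELD = "left_field"
    MAX_LENGTH = "max_length"


# integer codes used internally by the vectorised stepper
_CODE_OK = 0
_CODE_QA = 1
_CODE_ANGLE = 2
_CODE_LEFT = 3
_CODE_MAXLEN = 4

_CODE_TO_REASON = {
    _CODE_QA: TerminationReason.QA_BELOW_THRESHOLD,
    _CODE_ANGLE: TerminationReason.NO_CONGRUENT_ORIENTATION,
    _CODE_LEFT: TerminationReason.LEFT_FIELD,
    _CODE_MAXLEN: TerminationReason.MAX_LENGTH,
}


@dataclass(frozen=True)
class TrackingParams:
    """Propagation and stopping constants for deterministic fiber tracking.

    Defaults are the standard deterministic-tracking settings for
    high-resolution diffusion data: 0.8 mm steps, 20-800 mm length window,
    75 degree turning-angle threshold, QA stopping threshold 0.06, and a
    50/50 smoothing of the moving direction with the previous incoming
    direction.  ``max_seeds`` caps the seed budget of a whole-brain run
    (10,000,000 by default).
    """

    step_size_mm: float = 0.8
    min_length_mm: float = 20.0
    max_length_mm: float = 800.0
    angle_threshold_deg: float = 75.0
    qa_threshold: float = 0.06
    smoothing_weight: float = 0.5
    max_seeds: int = 10_000_000

    def __post_init__(self) -> None:
        if not self.step_size_mm > 0:
            raise ValueError("step_size_mm must be positive")
        if not (0 < self.min_length_mm < self.max_length_mm):
            raise ValueError("need 0 < min_length_mm < max_length_mm")
        if not (0 < self.angle_threshold_deg < 180):
            raise ValueError("angle_threshold_deg must be in (0, 180)")
        if not (0 <= self.smoothing_weight <= 1):
            raise ValueError("smoothing_weight must be in [0, 1]")
        if self.qa_threshold < 0:
            raise ValueError("qa_threshold must be non-negative")
        if self.max_seeds < 0:
            raise ValueError("max_seeds must be non-negative")

    @property
    def cos_angle_threshold(self) -> float:
        return math.cos(math.radians(self.angle_threshold_deg))

    @property
    def max_steps(self) -> int:
        """Maximum number of steps an assembled track may contain."""
        return int(math.floor(self.max_length_mm / self.step_size_mm + 1e-9))

    @classmethod
    def from_yaml(cls, path) -> "TrackingParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "step_size_mm": self.step_size_mm,
            "min_length_mm": self.min_length_mm,
            "max_length_mm": self.max_length_mm,
            "angle_threshold_deg": self.angle_threshold_deg,
            "qa_threshold": self.qa_threshold,
            "smoothing_weight": self.smoothing_weight,
            "max_seeds": self.max_seeds,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class OrientationField:
    """Per-voxel candidate fiber directions with QA values.

    Parameters
    ----------
    directions : ndarray, shape (X, Y, Z, K, 3)
        Up to K axial unit vectors per voxel.  A slot is *empty* when its
        vector is all-zero; occupied slots must be unit-norm within 1e-6.
    qa : ndarray, shape (X, Y, Z, K)
        Non-negative QA value per orientation slot (0 for empty slots is
        conventional but not required; empty slots are never selectable).
    affine : ndarray, shape (4, 4)
        Voxel-to-world (mm) transform; voxel centers map through it.
    """

    def __init__(self, directions: np.ndarray, qa: np.ndarray, affine: np.ndarray):
        directions = np.asarray(directions, dtype=np.float64)
        qa = np.asarray(qa, dtype=np.float64)
        affine = np.asarray(affine, dtype=np.float64)
        if directions.ndim != 5 or directions.shape[-1] != 3:
            raise ValueError("directions must have shape (X, Y, Z, K, 3)")
        if qa.shape != directions.shape[:-1]:
            raise ValueError("qa must have shape (X, Y, Z, K) matching directions")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        norms2 = np.einsum("...d,...d->...", directions, directions)
        occupied = norms2 > 0.25
        if occupied.any():
            err = np.abs(np.sqrt(norms2[occupied]) - 1.0)
            if err.max() > _UNIT_TOL:
                raise ValueError(
                    f"occupied orientation slots must be unit-norm within {_UNIT_TOL}"
                )
        if (qa < 0).any():
            raise ValueError("qa values must be non-negative")
        self.directions = directions
        self.qa = qa
        self.affine = affine
        self._inv_affine = np.linalg.inv(affine)
        self._occupied = occupied

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.directions.shape[:3]

    @property
    def n_peaks(self) -> int:
        return self.directions.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to (fractional) voxel coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return points @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        voxels = np.atleast_2d(np.asarray(voxels, dtype=np.float64))
        return voxels @ self.affine[:3, :3].T + self.affine[:3, 3]

    def nearest_voxel(self, points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Nearest voxel index for each world point, plus an in-bounds mask."""
        vox = np.rint(self.world_to_voxel(points)).astype(np.int64)
        shape = np.asarray(self.shape)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        return vox, inside

    def peaks_at(self, voxel: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
        """Occupied orientations and their QA values at an integer voxel."""
        i, j, k = (int(v) for v in voxel)
        occ = self._occupied[i, j, k]
        return self.directions[i, j, k][occ], self.qa[i, j, k][occ]


@dataclass
class Streamline:
    """A tracked polyline in world-mm coordinates with its provenance."""

    points: np.ndarray
    seed_point: Optional[np.ndarray] = None
    termination_reasons: Optional[Tuple[TerminationReason, TerminationReason]] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a streamline needs >= 2 points of shape (n, 3)")

    @property
    def length_mm(self) -> float:
        segs = np.diff(self.points, axis=0)
        return float(np.linalg.norm(segs, axis=1).sum())

    @property
    def endpoints(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class StreamlineSet:
    """A collection of streamlines sharing one grid / world frame."""

    streamlines: List[Streamline]
    affine: np.ndarray
    shape: Tuple[int, int, int]
    provenance: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    def __getitem__(self, i: int) -> Streamline:
        return self.streamlines[i]

    def endpoints(self) -> np.ndarray:
        """Array of shape (n, 2, 3): first and last point of each streamline."""
        if not self.streamlines:
            return np.empty((0, 2, 3))
        return np.stack([np.stack(s.endpoints) for s in self.streamlines])

    # -- TRK / TCK round trips -------------------------------------------

    def _tractogram(self) -> Tractogram:
        return Tractogram(
            [s.points for s in self.streamlines], affine_to_rasmm=np.eye(4)
        )

    def save_trk(self, path) -> None:
        header = {
            Field.VOXEL_TO_RASMM: np.asarray(self.affine, dtype=np.float32),
            Field.VOXEL_SIZES: np.linalg.norm(self.affine[:3, :3], axis=0).astype(
                np.float32
            ),
            Field.DIMENSIONS: np.asarray(self.shape, dtype=np.int16),
            Field.VOXEL_ORDER: b"RAS",
        }
        TrkFile(self._tractogram(), header=header).save(path)

    def save_tck(self, path) -> None:
        TckFile(self._tractogram()).save(path)

    @classmethod
    def load_trk(cls, path) -> "StreamlineSet":
        trk = TrkFile.load(path, lazy_load=False)
        affine = np.asarray(trk.header[Field.VOXEL_TO_RASMM], dtype=np.float64)
        shape = tuple(int(d) for d in trk.header[Field.DIMENSIONS])
        lines = [
            Streamline(np.asarray(s, dtype=np.float64))
            for s in trk.tractogram.streamlines
        ]
        return cls(lines, affine=affine, shape=shape, provenance={"source": str(path)})

    @classmethod
    def load_tck(cls, path, affine: Optional[np.ndarray] = None,
                 shape: Tuple[int, int, int] = (0, 0, 0)) -> "StreamlineSet":
        tck = TckFile.load(path, lazy_load=False)
        lines = [
            Streamline(np.asarray(s, dtype=np.float64))
            for s in tck.tractogram.streamlines
        ]
        aff = np.eye(4) if affine is None else np.asarray(affine, dtype=np.float64)
        return cls(lines, affine=aff, shape=shape, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# Orientation selection
# ---------------------------------------------------------------------------

def _select_batch(
    incoming: np.ndarray,
    dirs: np.ndarray,
    qa: np.ndarray,
    params: TrackingParams,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised congruent-orientation selection.

    Parameters: ``incoming`` (N, 3) unit vectors, ``dirs`` (N, K, 3) axial
    candidates (zero vector = empty slot), ``qa`` (N, K).

    Returns ``(chosen, ok, codes)`` where ``chosen`` (N, 3) is the
    polarity-resolved orientation (undefined where not ok), ``ok`` (N,) bool
    and ``codes`` (N,) the failure code for tracks that stop here.

    Selection rule: among occupied slots with qa >= qa_threshold, pick the
    slot with the largest |dot| to the incoming direction (smallest axial
    angle); ties go to the higher QA, then the lowest slot index.  The
    winner is accepted only if its turning angle is strictly below the
    angle threshold.
    """
    occupied = np.einsum("nkd,nkd->nk", dirs, dirs) > 0.25
    eligible = occupied & (qa >= params.qa_threshold)
    has_eligible = eligible.any(axis=1)

    dots = np.einsum("nkd,nd->nk", dirs, incoming)
    adots = np.where(eligible, np.abs(dots), -1.0)
    best = adots.max(axis=1)
    # tie-break: exact-equal angles resolved by higher QA, then lowest index
    tied = adots == best[:, None]
    qa_tied = np.where(tied, qa, -1.0)
    k_sel = qa_tied.argmax(axis=1)

    n_idx = np.arange(len(incoming))
    sel_dots = dots[n_idx, k_sel]
    sign = np.where(sel_dots >= 0, 1.0, -1.0)
    chosen = dirs[n_idx, k_sel] * sign[:, None]

    congruent = best > params.cos_angle_threshold  # angle strictly < threshold
    ok = has_eligible & congruent

    codes = np.full(len(incoming), _CODE_OK, dtype=np.int8)
    codes[~has_eligible] = _CODE_QA
    codes[has_eligible & ~congruent] = _CODE_ANGLE
    return chosen, ok, codes


def select_orientation(
    incoming_dir: np.ndarray,
    directions: np.ndarray,
    qa: np.ndarray,
    params: TrackingParams,
) -> Optional[np.ndarray]:
    """Pick the candidate orientation most congruent with ``incoming_dir``.

    Candidates are axial (both sign polarities are considered).  Returns the
    polarity-resolved unit vector, or ``None`` when no candidate has
    qa >= qa_threshold and turning angle below the angle threshold.
    """
    incoming = np.asarray(incoming_dir, dtype=np.float64)
    incoming = incoming / np.linalg.norm(incoming)
    directions = np.asarray(directions, dtype=np.float64).reshape(1, -1, 3)
    qa = np.asarray(qa, dtype=np.float64).reshape(1, -1)
    if directions.shape[1] == 0:
        return None
    chosen, ok, _ = _select_batch(incoming[None, :], directions, qa, params)
    return chosen[0] if ok[0] else None


def _smooth(incoming: np.ndarray, chosen: np.ndarray, w: float) -> np.ndarray:
    v = w * incoming + (1.0 - w) * chosen
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    # the angle test guarantees chosen . incoming > cos(threshold) > -1,
    # so the mixture can only vanish for w in {0,1} degenerate cases
    n = np.where(n == 0, 1.0, n)
    return v / n


def propagate_step(
    position: np.ndarray,
    incoming_dir: np.ndarray,
    field: OrientationField,
    params: TrackingParams,
) -> Union[Tuple[np.ndarray, np.ndarray], TerminationReason]:
    """Advance one step from ``position`` along the field.

    Looks up the nearest voxel, selects the congruent orientation, smooths
    the moving direction (``smoothing_weight`` on the incoming direction)
    and advances ``step_size_mm``.  Returns ``(new_position, new_dir)`` or
    the :class:`TerminationReason` that stops the track here.
    """
    position = np.asarray(position, dtype=np.float64)
    incoming = np.asarray(incoming_dir, dtype=np.float64)
    incoming = incoming / np.linalg.norm(incoming)

    vox, inside = field.nearest_voxel(position[None, :])
    if not inside[0]:
        return TerminationReason.LEFT_FIELD
    i, j, k = vox[0]
    dirs = field.directions[i, j, k][None, :, :]
    qa = field.qa[i, j, k][None, :]
    chosen, ok, codes = _select_batch(incoming[None, :], dirs, qa, params)
    if not ok[0]:
        return _CODE_TO_REASON[int(codes[0])]
    new_dir = _smooth(incoming, chosen[0], params.smoothing_weight)
    new_pos = position + params.step_size_mm * new_dir
    return new_pos, new_dir


# ---------------------------------------------------------------------------
# Bidirectional tracking
# ---------------------------------------------------------------------------

def _initial_directions(
    field: OrientationField, vox: np.ndarray, params: TrackingParams
) -> Tuple[np.ndarray, np.ndarray]:
    """Highest-QA selectable orientation at each seed voxel.

    Returns (dirs (N, 3), ok (N,)); ``ok`` is False where no occupied slot
    reaches the QA threshold.
    """
    dirs = field.directions[vox[:, 0], vox[:, 1], vox[:, 2]]
    qa = field.qa[vox[:, 0], vox[:, 1], vox[:, 2]]
    occupied = np.einsum("nkd,nkd->nk", dirs, dirs) > 0.25
    eligible = occupied & (qa >= params.qa_threshold)
    ok = eligible.any(axis=1)
    qa_masked = np.where(eligible, qa, -1.0)
    k_sel = qa_masked.argmax(axis=1)  # ties -> lowest slot index
    d0 = dirs[np.arange(len(vox)), k_sel]
    return d0, ok


def _propagate_half(
    field: OrientationField,
    pos0: np.ndarray,
    dir0: np.ndarray,
    max_steps: int,
    params: TrackingParams,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Propagate N tracks until termination or ``max_steps``.

    Returns (points (N, max_steps + 1, 3), n_points (N,), codes (N,)).
    """
    n = len(pos0)
    pts = np.empty((n, max_steps + 1, 3), dtype=np.float64)
    pts[:, 0] = pos0
    n_pts = np.ones(n, dtype=np.int64)
    codes = np.full(n, _CODE_MAXLEN, dtype=np.int8)
    active = np.ones(n, dtype=bool)

    pos = np.array(pos0, dtype=np.float64)
    dirn = np.array(dir0, dtype=np.float64)
    shape = np.asarray(field.shape)

    for _ in range(max_steps):
        act = np.flatnonzero(active)
        if act.size == 0:
            break
        vox, inside = field.nearest_voxel(pos[act])
        out = act[~inside]
        codes[out] = _CODE_LEFT
        active[out] = False

        sub = act[inside]
        if sub.size == 0:
            continue
        v = vox[inside]
        dirs_v = field.directions[v[:, 0], v[:, 1], v[:, 2]]
        qa_v = field.qa[v[:, 0], v[:, 1], v[:, 2]]
        chosen, ok, sel_codes = _select_batch(dirn[sub], dirs_v, qa_v, params)

        failed = sub[~ok]
        codes[failed] = sel_codes[~ok]
        active[failed] = False

        good = sub[ok]
        if good.size == 0:
            continue
        new_dir = _smooth(dirn[good], chosen[ok], params.smoothing_weight)
        pos[good] += params.step_size_mm * new_dir
        dirn[good] = new_dir
        pts[good, n_pts[good]] = pos[good]
        n_pts[good] += 1

    return pts, n_pts, codes


def _assemble(
    back_pts: np.ndarray,
    n_back: np.ndarray,
    back_codes: np.ndarray,
    fwd_pts: np.ndarray,
    n_fwd: np.ndarray,
    fwd_codes: np.ndarray,
    seeds_world: np.ndarray,
    params: TrackingParams,
) -> List[Streamline]:
    """Join backward/forward half-tracks, apply the length window."""
    max_steps = params.max_steps
    step = params.step_size_mm
    out: List[Streamline] = []
    for i in range(len(seeds_world)):
        nb, nf = int(n_back[i]), int(n_fwd[i])
        bcode, fcode = int(back_codes[i]), int(fwd_codes[i])
        total_steps = (nb - 1) + (nf - 1)
        if total_steps > max_steps:
            # trim from the forward end; the track hit the length cap
            nf -= total_steps - max_steps
            fcode = _CODE_MAXLEN
            total_steps = max_steps
        length = total_steps * step
        if length < params.min_length_mm - 1e-9:
            continue
        points = np.concatenate([back_pts[i, nb - 1:0:-1], fwd_pts[i, :nf]])
        out.append(
            Streamline(
                points=np.ascontiguousarray(points),
                seed_point=seeds_world[i].copy(),
                termination_reasons=(
                    _CODE_TO_REASON[bcode],
                    _CODE_TO_REASON[fcode],
                ),
            )
        )
    return out


def track_from_seed(
    seed: np.ndarray,
    field: OrientationField,
    params: TrackingParams,
) -> Optional[Streamline]:
    """Track bidirectionally from one world-mm seed point.

    The initial direction is the highest-QA orientation of the seed voxel;
    the two half-tracks (propagated along +/- that axis) are concatenated.
    Returns ``None`` when the seed voxel offers no orientation at or above
    the QA threshold, or when the assembled track is shorter than
    ``min_length_mm``.  Raises ``ValueError`` for a seed outside the grid.
    """
    seed = np.asarray(seed, dtype=np.float64)
    vox, inside = field.nearest_voxel(seed[None, :])
    if not inside[0]:
        raise ValueError("seed point lies outside the orientation field")
    d0, ok = _initial_directions(field, vox, params)
    if not ok[0]:
        return None
    seeds = seed[None, :]
    max_steps = params.max_steps
    fwd = _propagate_half(field, seeds, d0, max_steps, params)
    bwd = _propagate_half(field, seeds, -d0, max_steps, params)
    lines = _assemble(*bwd, *fwd, seeds, params)
    return lines[0] if lines else None


def whole_brain_track(
    field: OrientationField,
    seed_mask: np.ndarray,
    n_seeds: int,
    params: TrackingParams,
    rng_seed: int,
) -> StreamlineSet:
    """Seed ``n_seeds`` random sub-voxel positions in ``seed_mask`` and track.

    Voxel selection is uniform over mask voxels and the in-voxel offset is
    uniform over the voxel cube, so the expected number of seeds landing in
    any voxel subset is proportional to its voxel count.  Identical
    ``(field, seed_mask, n_seeds, rng_seed)`` give bit-identical output.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != field.shape:
        raise ValueError("seed_mask shape must match the field grid")
    mask_voxels = np.argwhere(seed_mask)
    if len(mask_voxels) == 0:
        raise ValueError("seed_mask is empty")
    if n_seeds > params.max_seeds:
        raise ValueError(f"n_seeds exceeds the seed budget ({params.max_seeds})")

    rng = np.random.default_rng(rng_seed)
    lines: List[Streamline] = []
    max_steps = params.max_steps

    remaining = int(n_seeds)
    while remaining > 0:
        chunk = min(remaining, _SEED_CHUNK)
        remaining -= chunk
        picks = rng.integers(0, len(mask_voxels), size=chunk)
        offsets = rng.uniform(-0.5, 0.5, size=(chunk, 3))
        vox_coords = mask_voxels[picks] + offsets
        seeds = field.voxel_to_world(vox_coords)

        vox, _ = field.nearest_voxel(seeds)
        d0, ok = _initial_directions(field, vox, params)
        seeds_ok = seeds[ok]
        if len(seeds_ok) == 0:
            continue
        fwd = _propagate_half(field, seeds_ok, d0[ok], max_steps, params)
        bwd = _propagate_half(field, seeds_ok, -d0[ok], max_steps, params)
        lines.extend(_assemble(*bwd, *fwd, seeds_ok, params))

    return StreamlineSet(
        streamlines=lines,
        affine=np.array(field.affine),
        shape=field.shape,
        provenance={
            "rng_seed": int(rng_seed),
            "n_seeds": int(n_seeds),
            "params": params,
        },
    )
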