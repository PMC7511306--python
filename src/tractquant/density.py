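"""Streamline density maps and group-level map integration.

A per-subject density map counts, at each voxel of a reference grid, the
number of *distinct* streamlines visiting it (a streamline increments a
voxel at most once, so the map reads as streamline count per voxel).
Group-level integration binarizes each subject's map at >= 1 and sums the
binary maps, giving a voxelwise count of subjects whose tract passes
through the voxel.  All maps must share one grid and affine; spatial
normalization to a template is outside this pipeline's scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import nibabel as nib
import numpy as np

from .connectivity import _grid_of
from .tracking import Streamline, StreamlineSet

__all__ = ["DensityMap", "GroupMap", "density_map", "binarize_and_stack"]


@dataclass
class DensityMap:
    """Per-voxel distinct-streamline visitation counts."""

    values: np.ndarray
    affine: np.ndarray
    n_streamlines: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D volume")
        if (self.values < 0).any():
            raise ValueError("density values must be non-negative")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.int32), self.affine),
                 str(path))

    @classmethod
    def load(cls, path) -> "DensityMap":
        img = nib.load(str(path))
        values = np.rint(np.asarray(img.dataobj)).astype(np.int32)
        return cls(values=values, affine=np.asarray(img.affine),
                   n_streamlines=-1)


@dataclass
class GroupMap:
    """Voxelwise count of subjects with any streamline in the voxel."""

    values: np.ndarray
    affine: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if ((self.values < 0) | (self.values > self.n_subjects)).any():
            raise ValueError("group map values must lie in [0, n_subjects]")

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.int32), self.affine),
                 str(path))


def density_map(
    streamlines: Union[StreamlineSet, Sequence[Streamline]],
    reference_grid,
) -> DensityMap:
    """Count distinct streamlines visiting each voxel of the reference grid.

    Rasterization is by point membership of the polyline samples; with the
    default 0.8 mm step below typical voxel sizes this leaves no gaps along
    a track.  Points outside the grid are ignored.
    """
    shape, affine = _grid_of(reference_grid)
    inv = np.linalg.inv(affine)
    values = np.zeros(shape, dtype=np.int32)
    lines = list(streamlines)
    sh = np.asarray(shape)
    for s in lines:
        vox = np.rint(
            s.points @ inv[:3, :3].T + inv[:3, 3]
        ).astype(np.int64)
        inside = np.all((vox >= 0) & (vox < sh), axis=1)
        v = vox[inside]
        if len(v) == 0:
            continue
        flat = np.unique(np.ravel_multi_index((v[:, 0], v[:, 1], v[:, 2]), shape))
        values.reshape(-1)[flat] += 1
    return DensityMap(values=values, affine=affine, n_streamlines=len(lines))


def binarize_and_stack(per_subject_maps: Sequence[DensityMap]) -> GroupMap:
    """Threshold each subject's map at >= 1 and sum across subjects.

    All maps must share the grid shape and affine (registration to a
    common space is a precondition, not performed here).
    """
    maps = list(per_subject_maps)
    if not maps:
        raise ValueError("need at least one density map")
    ref = maps[0]
    for m in maps[1:]:
        if m.values.shape != ref.values.shape:
            raise ValueError("density maps must share one grid shape")
        if not np.allclose(m.affine, ref.affine, atol=1e-6):
            raise ValueError("density maps must share one affine")
    stacked = np.zeros(ref.values.shape, dtype=np.int32)
    for m in maps:
        stacked += (m.values >= 1).astype(np.int32)
    return GroupMap(values=stacked, affine=np.array(ref.affine),
                    n_subjects=len(maps))
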