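"""Two-ROI endpoint selection, connectivity matrices and connection indices.

From a whole-brain tractogram, streamlines whose two endpoints fall in two
specified region groups are selected (the two-ROI approach); region-pair
matrices then tally, per subject, the number of streamlines ending in each
pair of atlas regions and the number of distinct voxels those streamlines
occupy.  Per-subject matrices are converted to a connection index (CI):
each entry divided by the subject's total selected-streamline count (or
total voxel volume), averaged across subjects, and rescaled so the
strongest inter-region connection is exactly 100.

Endpoint-region assignment is the label of the voxel containing the
terminal point; no dilation or radius search is applied.  Streamlines with
a background (label 0) endpoint are excluded from the matrices but counted
in an auditable drop tally.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .tracking import Streamline, StreamlineSet

__all__ = [
    "LabelAtlas",
    "ConnectivityResult",
    "ConnectionIndexMatrix",
    "two_roi_select",
    "connectivity_matrix",
    "streamline_voxel_volume",
    "connection_index",
    "load_roi_groups",
]


def load_roi_groups(path) -> Dict[str, List[str]]:
    """Read named ROI groups from YAML: a mapping of group name to a list
    of region-name patterns (e.g. the IPS and fusiform area lists)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    out = {}
    for name, patterns in data.items():
        if isinstance(patterns, str):
            patterns = [patterns]
        out[str(name)] = [str(p) for p in patterns]
    return out

_HEMISPHERES = {"L", "R", "none"}


@dataclass
class LabelAtlas:
    """Integer parcellation volume plus a region table.

    ``regions`` has columns ``label`` (positive int), ``name`` and
    ``hemisphere`` (one of L, R, none).  Every non-zero label occurring in
    the volume must appear in the table exactly once; label 0 is background.
    """

    labels: np.ndarray
    affine: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D integer volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        self.regions = pd.DataFrame(self.regions).reset_index(drop=True)
        required = {"label", "name", "hemisphere"}
        if not required.issubset(self.regions.columns):
            raise ValueError(f"region table needs columns {sorted(required)}")
        table_labels = self.regions["label"].to_numpy()
        if len(set(table_labels)) != len(table_labels):
            raise ValueError("region table labels must be unique")
        bad_hemi = set(self.regions["hemisphere"].astype(str)) - _HEMISPHERES
        if bad_hemi:
            raise ValueError(f"unknown hemisphere tags: {sorted(bad_hemi)}")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(int(v) for v in table_labels)
        if missing:
            raise ValueError(
                f"labels {sorted(missing)} occur in the volume but not in "
                "the region table"
            )
        self._inv_affine = np.linalg.inv(self.affine)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def region_names(self) -> List[str]:
        return [str(n) for n in self.regions["name"]]

    @property
    def region_labels(self) -> List[int]:
        return [int(v) for v in self.regions["label"]]

    def labels_at(self, points: np.ndarray) -> np.ndarray:
        """Label of the voxel containing each world-mm point (0 outside)."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        vox = np.rint(
            points @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]
        ).astype(np.int64)
        shape = np.asarray(self.shape)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        out = np.zeros(len(points), dtype=np.int64)
        v = vox[inside]
        out[inside] = self.labels[v[:, 0], v[:, 1], v[:, 2]]
        return out

    def labels_for_names(self, patterns: Union[str, Iterable[str]]) -> Set[int]:
        """Region labels whose names match any fnmatch-style pattern."""
        if isinstance(patterns, str):
            patterns = [patterns]
        names = self.regions["name"].astype(str)
        mask = np.zeros(len(names), dtype=bool)
        for pat in patterns:
            mask |= np.array([fnmatch.fnmatch(n, pat) for n in names])
        return {int(v) for v in self.regions.loc[mask, "label"]}


@dataclass
class ConnectivityResult:
    """Region-pair streamline counts and voxel volumes for one tractogram."""

    count_matrix: pd.DataFrame
    volume_matrix: pd.DataFrame
    total_count: int
    n_dropped_background: int
    regions: pd.DataFrame
    per_subject: bool = True


@dataclass
class ConnectionIndexMatrix:
    """Connection index (CI) on [0, 100]; the strongest inter-region
    connection is exactly 100 whenever any connection exists."""

    ci: pd.DataFrame
    basis: str
    n_subjects: int

    def __post_init__(self) -> None:
        vals = self.ci.to_numpy(dtype=float)
        if vals.size and ((vals < -1e-9).any() or (vals > 100 + 1e-9).any()):
            raise ValueError("CI entries must lie in [0, 100]")
        if self.basis not in ("count", "volume"):
            raise ValueError("basis must be 'count' or 'volume'")

    def to_tsv(self, path) -> None:
        self.ci.to_csv(path, sep="\t", index_label="region",
                       float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, basis: str = "count",
                 n_subjects: int = 1) -> "ConnectionIndexMatrix":
        ci = pd.read_csv(path, sep="\t", index_col="region")
        return cls(ci=ci, basis=basis, n_subjects=n_subjects)


def _as_streamline_list(
    streamlines: Union[StreamlineSet, Sequence[Streamline]],
) -> List[Streamline]:
    return list(streamlines)


def _grid_of(grid) -> Tuple[Tuple[int, int, int], np.ndarray]:
    """Accept an OrientationField / LabelAtlas / (shape, affine) pair."""
    if hasattr(grid, "shape") and hasattr(grid, "affine"):
        return tuple(grid.shape), np.asarray(grid.affine, dtype=np.float64)
    shape, affine = grid
    return tuple(shape), np.asarray(affine, dtype=np.float64)


def _voxel_ids(points: np.ndarray, shape, inv_affine: np.ndarray) -> np.ndarray:
    """Distinct flat voxel ids visited by the points (in-grid only)."""
    vox = np.rint(
        points @ inv_affine[:3, :3].T + inv_affine[:3, 3]
    ).astype(np.int64)
    sh = np.asarray(shape)
    inside = np.all((vox >= 0) & (vox < sh), axis=1)
    v = vox[inside]
    flat = np.ravel_multi_index((v[:, 0], v[:, 1], v[:, 2]), shape)
    return np.unique(flat)


def two_roi_select(
    streamlines: Union[StreamlineSet, Sequence[Streamline]],
    atlas: LabelAtlas,
    roi_a_labels: Iterable[int],
    roi_b_labels: Iterable[int],
) -> StreamlineSet:
    """Keep streamlines with one endpoint in ROI group A and the other in
    ROI group B (order-agnostic).  The label groups must be disjoint and
    non-empty."""
    set_a = {int(v) for v in roi_a_labels}
    set_b = {int(v) for v in roi_b_labels}
    if not set_a or not set_b:
        raise ValueError("ROI label groups must be non-empty")
    if set_a & set_b:
        raise ValueError("ROI label groups must be disjoint")

    lines = _as_streamline_list(streamlines)
    if lines:
        first = atlas.labels_at(np.stack([s.points[0] for s in lines]))
        last = atlas.labels_at(np.stack([s.points[-1] for s in lines]))
        in_a_first = np.isin(first, sorted(set_a))
        in_b_first = np.isin(first, sorted(set_b))
        in_a_last = np.isin(last, sorted(set_a))
        in_b_last = np.isin(last, sorted(set_b))
        keep = (in_a_first & in_b_last) | (in_b_first & in_a_last)
        selected = [s for s, k in zip(lines, keep) if k]
    else:
        selected = []

    if isinstance(streamlines, StreamlineSet):
        affine, shape = streamlines.affine, streamlines.shape
        provenance = dict(streamlines.provenance)
    else:
        affine, shape = atlas.affine, atlas.shape
        provenance = {}
    provenance.update(
        {"roi_a_labels": sorted(set_a), "roi_b_labels": sorted(set_b)}
    )
    return StreamlineSet(selected, affine=np.array(affine), shape=tuple(shape),
                         provenance=provenance)


def streamline_voxel_volume(
    streamlines: Union[StreamlineSet, Sequence[Streamline], Streamline],
    grid,
) -> int:
    """Number of distinct grid voxels containing at least one streamline
    point (point-membership rasterization; the union over streamlines)."""
    shape, affine = _grid_of(grid)
    if not all(s > 0 for s in shape):
        raise ValueError("grid shape must be positive")
    if isinstance(streamlines, Streamline):
        streamlines = [streamlines]
    lines = _as_streamline_list(streamlines)
    if not lines:
        return 0
    inv = np.linalg.inv(affine)
    pts = np.concatenate([s.points for s in lines])
    return int(len(_voxel_ids(pts, shape, inv)))


def connectivity_matrix(
    selected_streamlines: Union[StreamlineSet, Sequence[Streamline]],
    atlas: LabelAtlas,
) -> ConnectivityResult:
    """Tally, per region pair, the streamlines ending in the two regions and
    the distinct voxels their union occupies.

    ``count_matrix[i, j]`` is the number of streamlines with one endpoint in
    region i and the other in region j; ``volume_matrix[i, j]`` is the
    number of distinct voxels visited by those streamlines.  Both matrices
    are symmetric.  Streamlines with a background endpoint are skipped and
    reported in ``n_dropped_background``.
    """
    lines = _as_streamline_list(selected_streamlines)
    region_labels = atlas.region_labels
    names = atlas.region_names
    n = len(region_labels)
    label_to_idx = {lab: i for i, lab in enumerate(region_labels)}

    counts = np.zeros((n, n), dtype=np.int64)
    pair_members: Dict[Tuple[int, int], List[int]] = {}
    dropped = 0
    if lines:
        first = atlas.labels_at(np.stack([s.points[0] for s in lines]))
        last = atlas.labels_at(np.stack([s.points[-1] for s in lines]))
        for si, (la, lb) in enumerate(zip(first, last)):
            if la == 0 or lb == 0:
                dropped += 1
                continue
            i, j = label_to_idx[int(la)], label_to_idx[int(lb)]
            if i == j:
                counts[i, i] += 1
            else:
                counts[i, j] += 1
                counts[j, i] += 1
            pair_members.setdefault((min(i, j), max(i, j)), []).append(si)

    volumes = np.zeros((n, n), dtype=np.int64)
    inv = np.linalg.inv(atlas.affine)
    for (i, j), members in pair_members.items():
        pts = np.concatenate([lines[si].points for si in members])
        vol = len(_voxel_ids(pts, atlas.shape, inv))
        volumes[i, j] = vol
        volumes[j, i] = vol

    total = int(np.triu(counts).sum())
    return ConnectivityResult(
        count_matrix=pd.DataFrame(counts, index=names, columns=names),
        volume_matrix=pd.DataFrame(volumes, index=names, columns=names),
        total_count=total,
        n_dropped_background=dropped,
        regions=atlas.regions.copy(),
    )


def connection_index(
    per_subject_results: Sequence[ConnectivityResult],
    basis: str = "count",
) -> ConnectionIndexMatrix:
    """Average per-subject connection fractions and rescale to [0, 100].

    Per subject, each matrix entry is divided by that subject's total (the
    upper-triangle sum of the same basis; zero totals give a zero matrix).
    The across-subject mean is then scaled so its maximum *inter-region*
    entry is exactly 100; within-region (diagonal) entries are tallied in
    the matrices but excluded from CI scaling.  An all-zero mean stays
    all-zero.
    """
    if basis not in ("count", "volume"):
        raise ValueError("basis must be 'count' or 'volume'")
    if len(per_subject_results) == 0:
        raise ValueError("need at least one subject")
    ref = per_subject_results[0]
    ref_key = list(zip(ref.regions["label"], ref.regions["name"]))
    for res in per_subject_results[1:]:
        if list(zip(res.regions["label"], res.regions["name"])) != ref_key:
            raise ValueError("subjects have mismatching region tables")

    fracs = []
    for res in per_subject_results:
        mat = (res.count_matrix if basis == "count"
               else res.volume_matrix).to_numpy(dtype=float)
        total = float(np.triu(mat).sum())
        fracs.append(mat / total if total > 0 else np.zeros_like(mat))
    mean = np.mean(fracs, axis=0)
    np.fill_diagonal(mean, 0.0)
    peak = mean.max() if mean.size else 0.0
    ci = mean / peak * 100.0 if peak > 0 else np.zeros_like(mean)
    names = ref.count_matrix.index
    return ConnectionIndexMatrix(
        ci=pd.DataFrame(ci, index=names, columns=names),
        basis=basis,
        n_subjects=len(per_subject_results),
    )
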