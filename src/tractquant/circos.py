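"""Connectogram table export (CIRCOS tableviewer conventions).

The quantitative output feeding a connectogram is a symmetric matrix of
connection-index weights between cortical regions; the circular rendering
itself is delegated to external CIRCOS tooling.  This module emits the
tab-delimited table the mkweb tableviewer ingests: a header row of region
labels followed by one row per region, with regions ordered left-hemisphere
group first, then right, then unlateralized, each group in region-table
order.  Output is byte-stable for identical input.
"""

from __future__ import annotations

from io import StringIO
from typing import Optional

import numpy as np
import pandas as pd

from .connectivity import ConnectionIndexMatrix

__all__ = ["to_circos_table", "parse_circos_table", "circos_region_order"]


def circos_region_order(regions: pd.DataFrame) -> list:
    """Deterministic region ordering: hemisphere L, then R, then none,
    preserving region-table order within each group."""
    names = regions["name"].astype(str).tolist()
    hemis = regions["hemisphere"].astype(str).tolist()
    ordered = []
    for group in ("L", "R", "none"):
        ordered.extend(n for n, h in zip(names, hemis) if h == group)
    return ordered


def to_circos_table(
    ci: ConnectionIndexMatrix,
    regions: pd.DataFrame,
    *,
    precision: int = 2,
    floor: float = 0.0,
) -> str:
    """Render a CI matrix as tab-delimited tableviewer text.

    ``regions`` is the atlas region table (columns name, hemisphere); its
    region set must match the CI matrix.  Cells are rounded to
    ``precision`` decimals; weights below ``floor`` (default 0 = off) are
    zeroed to declutter the ribbon display.  Raises on duplicate region
    names, which would make the table ambiguous.
    """
    names = regions["name"].astype(str).tolist()
    if len(set(names)) != len(names):
        raise ValueError("duplicate region names in the region table")
    if set(names) != set(ci.ci.index.astype(str)):
        raise ValueError("CI matrix regions do not match the region table")
    order = circos_region_order(regions)
    mat = ci.ci.loc[order, order].to_numpy(dtype=float)
    if floor > 0:
        mat = np.where(mat < floor, 0.0, mat)

    lines = ["labels\t" + "\t".join(order)]
    for name, row in zip(order, mat):
        cells = "\t".join(f"{v:.{precision}f}" for v in row)
        lines.append(f"{name}\t{cells}")
    return "\n".join(lines) + "\n"


def parse_circos_table(text: str) -> pd.DataFrame:
    """Parse tableviewer text back into a region-by-region weight matrix."""
    df = pd.read_csv(StringIO(text), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df.astype(float)
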