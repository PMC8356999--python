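"""Atlas comparison via the Dice similarity coefficient (DSC).

DSC between two voxel sets A and B is 2|A and B| / (|A| + |B|): twice
the intersection volume over the sum of the two volumes, ranging from 0
(disjoint) to 1 (identical).  A full matrix compares every parcel of one
atlas against every parcel of another.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .volume import LabelVolume, require_same_grid

__all__ = ["dice", "dsc_matrix"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two boolean voxel masks on one grid.

    Both-empty is defined as 0 (absence of both parcels is not evidence
    of agreement).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid/shape")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def dsc_matrix(atlas_a: LabelVolume, atlas_b: LabelVolume) -> pd.DataFrame:
    """Pairwise Dice coefficients between all nonzero parcels of two atlases.

    Rows are parcels of ``atlas_a``, columns parcels of ``atlas_b``,
    indexed by parcel name.
    """
    require_same_grid([atlas_a, atlas_b], "atlases")
    rows = atlas_a.present_labels()
    cols = atlas_b.present_labels()
    values = np.array(
        [
            [dice(atlas_a.labels == i, atlas_b.labels == j) for j in cols]
            for i in rows
        ]
    ).reshape(len(rows), len(cols))
    return pd.DataFrame(
        values,
        index=[atlas_a.label_names[i] for i in rows],
        columns=[atlas_b.label_names[j] for j in cols],
    )
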