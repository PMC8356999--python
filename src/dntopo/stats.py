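"""Group-level summaries and nonparametric tests.

Per-parcel metric means (the normative-values table), paired left/right
comparisons (Wilcoxon signed-rank), across-parcel comparisons (Friedman)
and two-group comparisons (Mann-Whitney U), all two-sided at alpha =
0.05 with no multiple-testing correction (a deliberate caveat, see the
methods note).  Exact p values are used at the small sample sizes where
they are feasible; otherwise the normal / chi-square approximation with
tie correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .volume import LabelVolume, ScalarVolume, require_same_grid

__all__ = [
    "SubjectFeatureTable",
    "parcel_metric_means",
    "wilcoxon_paired",
    "friedman_parcels",
    "mann_whitney_groups",
]

#: Sample-size limit under which exact p values are computed.
EXACT_N_MAX = 25


@dataclass
class SubjectFeatureTable:
    """Subjects x named features, with an optional grouping column.

    ``data`` holds one row per subject; ``group`` names a categorical
    column of ``data`` (e.g. sex) used for two-group comparisons.
    """

    data: pd.DataFrame
    group: str | None = None

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in self.data.columns:
            raise ValueError(f"group column {self.group!r} not in table")

    def tested_columns(self) -> list[str]:
        cols = [c for c in self.data.columns if c != self.group]
        bad = [c for c in cols if self.data[c].isna().any()]
        if bad:
            raise ValueError(f"missing cells in tested columns: {bad}")
        return cols


def parcel_metric_means(atlas: LabelVolume, metric: ScalarVolume) -> dict[int, float]:
    """Mean metric value over the voxels of each nonzero atlas label.

    Labels present in the dictionary but absent from the volume get NaN
    (empty parcel: mean undefined).
    """
    require_same_grid([atlas, metric], "atlas and metric")
    out: dict[int, float] = {}
    for k in sorted(atlas.label_names):
        sel = atlas.labels == k
        out[k] = float(metric.values[sel].mean()) if sel.any() else float("nan")
    return out


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; the p value is exact for n <= 25
    remaining differences (conditional on the observed ranks), otherwise
    a normal approximation with tie correction.  If every difference is
    zero the test is degenerate and (0, 1) is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    d = d[d != 0.0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    method = "exact" if len(d) <= EXACT_N_MAX else "approx"
    res = _sps.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def friedman_parcels(table) -> tuple[float, float]:
    """Friedman chi-square test across parcels (columns) over subjects (rows).

    Within-subject ranks use mid-ranks for ties; the chi-square statistic
    carries the standard tie correction and is referred to a chi-square
    distribution with k - 1 degrees of freedom.  If every subject's row
    is constant there is no ranking information: the statistic is 0 and
    p = 1.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be subjects x parcels")
    n, k = table.shape
    if k < 2:
        raise ValueError("need at least 2 parcels")
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if np.isnan(table).any():
        raise ValueError("table has missing cells")

    ranks = np.apply_along_axis(_sps.rankdata, 1, table)
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)

    # tie correction: 1 - sum(t^3 - t) / (n (k^3 - k)) over tie groups per row
    tie_term = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0.0:
        # every row fully tied: no ranking information at all
        return 0.0, 1.0
    stat = q / correction
    p = float(_sps.chi2.sf(stat, df=k - 1))
    return float(stat), p


def mann_whitney_groups(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two independent groups.

    Returns (U of the first group, p).  Exact p for combined n <= 25
    without ties, otherwise a normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_N_MAX and not ties) else "asymptotic"
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
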