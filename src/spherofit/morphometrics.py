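"""Conventional size-based spheroid morphometrics and group statistics.

These are the comparator measurements a drug-response assay would normally
report: the *core diameter* (equivalent-circle diameter of the bright
spheroid body at the first frame's intensity threshold) and the *invasive
diameter* (longest caliper / max-Feret dimension of the whole segmented
region of interest, capturing how far cells have invaded the gel).  Group
differences per time point are assessed with an unpaired two-sample t-test,
pooled-variance by default (Welch available behind a flag), with the usual
star convention: p < 0.05 (*), p < 0.01 (**), p < 0.001 (***).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.morphology import erosion

from .mesh import PixelGrid


def significance_stars(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class MorphometricsRecord:
    time_h: float
    core_diameter_um: float
    invasive_diameter_um: float
    system_id: str = ""
    group: str = ""


def core_diameter(normalized_image: np.ndarray, pixel_size_um: float, threshold: float = 0.5) -> float:
    """Equivalent-circle diameter 2·√(area/π) of the supra-threshold core, µm.

    The threshold (default 0.5 on the normalized 0-1 intensity scale) defines
    the dense spheroid body; an empty mask yields 0 with a warning.
    """
    img = np.asarray(normalized_image, dtype=float)
    mask = img > threshold
    if not mask.any():
        warnings.warn("no pixels above the core threshold; diameter 0", stacklevel=2)
        return 0.0
    area_um2 = mask.sum() * pixel_size_um**2
    return float(2.0 * np.sqrt(area_um2 / np.pi))


def invasive_diameter(mask: np.ndarray, pixel_size_um: float) -> float:
    """Longest dimension (max Feret diameter) of a binary ROI mask, µm.

    Measured as the maximum pairwise distance between boundary-pixel centers
    plus one pixel to account for the pixels' own extent; a single-pixel mask
    therefore reports one pixel width.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        warnings.warn("empty ROI mask; invasive diameter 0", stacklevel=2)
        return 0.0
    boundary = m & ~erosion(m)
    pts = np.argwhere(boundary).astype(float)
    if len(pts) == 1:
        return float(pixel_size_um)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear degenerate sets fall through to pdist
            pass
    return float((pdist(pts).max() + 1.0) * pixel_size_um)


def measure_frame(
    normalized_image: np.ndarray,
    roi_mask: np.ndarray,
    grid: PixelGrid,
    time_h: float,
    core_threshold: float = 0.5,
    system_id: str = "",
    group: str = "",
) -> MorphometricsRecord:
    return MorphometricsRecord(
        time_h=time_h,
        core_diameter_um=core_diameter(normalized_image, grid.pixel_size, core_threshold),
        invasive_diameter_um=invasive_diameter(roi_mask, grid.pixel_size),
        system_id=system_id,
        group=group,
    )


@dataclass(frozen=True)
class GroupComparison:
    """One comparison row: two group summaries plus the t-test verdict."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    stars: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def unpaired_ttest(
    group_a, group_b, alpha: float = 0.05, welch: bool = False
) -> GroupComparison:
    """Two-sample t-test between independent groups (pooled variance unless
    ``welch``), two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=a.size,
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=b.size,
        t_statistic=float(t), p_value=float(p), stars=significance_stars(float(p)),
        alpha=alpha,
    )


def ttest_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    alpha: float = 0.05, welch: bool = False,
) -> GroupComparison:
    """Same verdict computed from printed group summaries (mean ± SD, n)."""
    t, p = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=not welch
    )
    return GroupComparison(
        mean_a=mean_a, sd_a=sd_a, n_a=n_a, mean_b=mean_b, sd_b=sd_b, n_b=n_b,
        t_statistic=float(t), p_value=float(p), stars=significance_stars(float(p)),
        alpha=alpha,
    )


def group_table(
    values: pd.DataFrame,
    value_columns: list[str],
    group_column: str = "group",
    time_column: str = "time_h",
    groups: tuple[str, str] = ("untreated", "treated"),
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-time-point group summary table (mean ± SD per group, stars).

    One row per time point; for each value column the table reports the two
    group means, SDs and the significance stars of the unpaired t-test.
    """
    rows = []
    for t, sub in values.groupby(time_column):
        row = {time_column: t}
        for col in value_columns:
            a = sub.loc[sub[group_column] == groups[0], col].to_numpy()
            b = sub.loc[sub[group_column] == groups[1], col].to_numpy()
            cmp = unpaired_ttest(a, b, alpha=alpha, welch=welch)
            row[f"{col}_{groups[0]}_mean"] = cmp.mean_a
            row[f"{col}_{groups[0]}_sd"] = cmp.sd_a
            row[f"{col}_{groups[1]}_mean"] = cmp.mean_b
            row[f"{col}_{groups[1]}_sd"] = cmp.sd_b
            row[f"{col}_p"] = cmp.p_value
            row[f"{col}_stars"] = cmp.stars
        rows.append(row)
    return pd.DataFrame(rows).sort_values(time_column).reset_index(drop=True)
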