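"""Fluorescent cell counting inside a manually drawn gut ROI.

Mirrors the larval imaging readout: per channel (green neutrophils, red
macrophages), pixels inside the hand-drawn gut polygon are thresholded
(Otsu by default) and bright 8-connected components of at least ``min_area``
pixels are counted as cells.  Touching cells are not split — the granularity
matches a manual count.  Dose groups are then compared against the control
group with the normality-gated test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from matplotlib.path import Path
from scipy import ndimage
from skimage.filters import threshold_otsu

from .community import group_compare

logger = logging.getLogger(__name__)


def roi_mask(roi, shape) -> np.ndarray:
    """Rasterize a polygon: pixel centres inside, even-odd rule."""
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] < 3:
        raise ValueError("ROI polygon needs at least 3 vertices")
    path = Path(roi)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    return path.contains_points(pts).reshape(shape)


def count_cells_in_roi(
    image: np.ndarray, roi, min_area: int = 5, threshold="otsu"
) -> int:
    """Count bright connected components inside the ROI polygon.

    ``threshold`` is "otsu" or an absolute intensity.  Components with area
    below ``min_area`` pixels are discarded; the count is therefore
    non-increasing in ``min_area``.
    """
    image = np.asarray(image, dtype=float)
    inside = roi_mask(roi, image.shape)
    if threshold == "otsu":
        thr = float(threshold_otsu(image))
    else:
        thr = float(threshold)
    bright = (image > thr) & inside
    labeled, n = ndimage.label(bright, structure=np.ones((3, 3), int))
    if n == 0:
        return 0
    areas = np.bincount(labeled.ravel())[1:]
    return int((areas >= min_area).sum())


def dose_response_compare(
    counts: pd.DataFrame, control_label: str, channel_col: str = "channel"
) -> pd.DataFrame:
    """Compare each treatment/dose group against control, per channel.

    ``counts`` needs columns ``group`` (treatment@dose label), ``channel``
    and ``count``.  Groups of fewer than 3 fish are skipped with a warning.
    Returns one row per (channel, group) with the gate's chosen test and p.
    """
    if control_label not in set(counts["group"]):
        raise ValueError(f"control group {control_label!r} not present")
    rows = []
    for channel in pd.unique(counts[channel_col]):
        sub = counts[counts[channel_col] == channel]
        ctrl = sub.loc[sub["group"] == control_label, "count"]
        for grp in pd.unique(sub["group"]):
            if grp == control_label:
                continue
            vals = sub.loc[sub["group"] == grp, "count"]
            if len(vals) < 3 or len(ctrl) < 3:
                logger.warning("group %s (channel %s): too few fish, skipped", grp, channel)
                rows.append({"channel": channel, "group": grp, "test": "skipped",
                             "statistic": np.nan, "p": np.nan})
                continue
            res = group_compare(
                np.concatenate([ctrl.to_numpy(float), vals.to_numpy(float)]),
                ["control"] * len(ctrl) + ["dose"] * len(vals),
            )
            rows.append({"channel": channel, "group": grp, "test": res.test,
                         "statistic": res.statistic, "p": res.p_value})
    return pd.DataFrame(rows, columns=["channel", "group", "test", "statistic", "p"])
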