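"""Derived per-tree statistics.

* **Inverted relative SPAD index** — senescence progression in [0, 1]:
  the product of a tree's leaf count and average SPAD on each date,
  divided by the tree's seasonal maximum of that product, subtracted
  from one in absolute value.  The maximum is taken over the full
  measurement set before any date-window restriction.
* **DOY of 50 % senescence** — the real-valued day of year at which the
  index crosses 0.5 for the last time, by linear interpolation between
  the bracketing measurements; undefined (flagged, not an error) for a
  tree whose index never reaches 0.5.
* **Total leaf-level autumn photosynthesis** — the trapezoidal area
  under the cleaned net-photosynthesis time series.  The time base is
  days, so totals carry units of umol m-2 s-1 * day; no day-to-second
  conversion is applied (ratios and percent comparisons are unaffected
  by this convention).
* **Total relative tree-level carbon gain** — the same area after
  scaling each flux by the ratio of the closest-in-time leaf count to
  the pre-treatment leaf count, correcting for tree size and
  defoliation.
* **Relative organ counts** — each count divided by the census taken
  just before the first removal of that organ.
"""

from __future__ import annotations

import datetime
import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "inverted_spad_index",
    "restrict_to_modeling_window",
    "doy_50pct_senescence",
    "auc_trapezoid",
    "total_autumn_photosynthesis",
    "total_relative_carbon_gain",
    "relative_counts",
    "date_to_doy",
    "compute_tree_metrics",
    "MODELING_CUTOFF_DOY",
]

#: Default start of the senescence modeling window (September 30, 2020).
MODELING_CUTOFF_DOY = 274


def inverted_spad_index(leaf_counts: pd.Series, spad_values: pd.Series) -> pd.Series:
    """Inverted relative SPAD index over a tree's measurement dates.

    Parameters
    ----------
    leaf_counts, spad_values : Series
        Aligned series indexed by day of year.  At least one date must
        have a positive count-times-SPAD product.

    Returns
    -------
    Series
        ``|LC_d * Chl_d / max_i(LC_i * Chl_i) - 1|`` indexed by DOY,
        guaranteed to lie in [0, 1] with 0 attained at the
        maximum-product date.
    """
    lc, chl = leaf_counts.align(spad_values, join="inner")
    if len(lc) == 0:
        raise ValueError("leaf count and SPAD series share no dates")
    product = lc.astype(float) * chl.astype(float)
    peak = product.max()
    if not peak > 0:
        raise ValueError("all count-SPAD products are zero; index undefined")
    return (product / peak - 1.0).abs().sort_index()


def restrict_to_modeling_window(series: pd.Series, cutoff_doy: int = MODELING_CUTOFF_DOY) -> pd.Series:
    """Retain the points at or after the modeling cutoff day.

    With the default 13-interval schedule and the September 30 cutoff
    (DOY 274) this keeps the last nine measurements.  Raises if nothing
    survives.
    """
    out = series[series.index >= cutoff_doy]
    if len(out) == 0:
        raise ValueError(f"no measurements at or after DOY {cutoff_doy}")
    return out


def doy_50pct_senescence(series: pd.Series, threshold: float = 0.5) -> float | None:
    """Day of year at which the index last crosses the threshold, rising.

    Scans adjacent pairs ``(d1, v1), (d2, v2)`` for the last one with
    ``v1 <= threshold <= v2`` and ``v1 < v2`` and linearly interpolates;
    a point sitting exactly on the threshold counts as a crossing.
    Returns ``None`` when the series never reaches the threshold (the
    caller flags such trees instead of erroring).  Requires at least two
    points.
    """
    s = series.sort_index()
    if len(s) < 2:
        raise ValueError("need at least two points to interpolate a crossing")
    d = s.index.to_numpy(dtype=float)
    v = s.to_numpy(dtype=float)
    crossing = None
    for i in range(len(v) - 1):
        if v[i] <= threshold <= v[i + 1] and v[i] < v[i + 1]:
            crossing = d[i] + (threshold - v[i]) / (v[i + 1] - v[i]) * (d[i + 1] - d[i])
    return crossing


def auc_trapezoid(points: Sequence[tuple[float, float]] | pd.Series) -> float:
    """Trapezoidal area under ``(x, y)`` points with strictly increasing x.

    ``x`` is in days.  Raises for fewer than two points or non-increasing
    abscissae.
    """
    if isinstance(points, pd.Series):
        x = points.index.to_numpy(dtype=float)
        y = points.to_numpy(dtype=float)
    else:
        pts = list(points)
        x = np.array([p[0] for p in pts], dtype=float)
        y = np.array([p[1] for p in pts], dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two points for a trapezoidal area")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x values must be strictly increasing")
    return float(np.trapezoid(y, x))


def total_autumn_photosynthesis(clean_obs_for_tree: pd.DataFrame) -> float:
    """Area under a tree's cleaned net-photosynthesis series.

    Expects QC-cleaned, interval-day-assigned records with columns
    ``doy`` and ``a_net_umol_m2_s``.  A tree whose surviving values are
    all zero scores 0 regardless of how many points survived.
    """
    df = clean_obs_for_tree.sort_values("doy")
    y = df["a_net_umol_m2_s"].to_numpy(dtype=float)
    if np.allclose(y, 0.0):
        return 0.0
    series = pd.Series(y, index=df["doy"].to_numpy(dtype=float))
    return auc_trapezoid(series)


def total_relative_carbon_gain(
    clean_obs_for_tree: pd.DataFrame,
    leaf_counts: pd.Series,
    pretreatment_count: float,
) -> float:
    """Size-corrected AUC: each flux scaled by relative leaf count.

    Every net-photosynthesis value is multiplied by the ratio of the
    closest-in-time leaf count to the pre-treatment count (ties between
    equidistant counts go to the earlier census), then integrated.
    """
    if pretreatment_count <= 0:
        raise ValueError("pretreatment_count must be positive")
    if len(leaf_counts) == 0:
        raise ValueError("leaf count series is empty")
    lc = leaf_counts.sort_index()
    count_doys = lc.index.to_numpy(dtype=float)
    df = clean_obs_for_tree.sort_values("doy")
    scaled = []
    for doy, a in zip(df["doy"].to_numpy(dtype=float),
                      df["a_net_umol_m2_s"].to_numpy(dtype=float)):
        dist = np.abs(count_doys - doy)
        nearest = int(np.argmin(dist))  # argmin takes the first = earlier on ties
        scaled.append(a * float(lc.iloc[nearest]) / pretreatment_count)
    series = pd.Series(scaled, index=df["doy"].to_numpy(dtype=float))
    if np.allclose(series.to_numpy(), 0.0):
        return 0.0
    return auc_trapezoid(series)


def relative_counts(
    count_series: pd.DataFrame, organ: str, first_removal_doy: int
) -> pd.Series:
    """Counts of one tree and organ relative to the pre-removal census.

    ``count_series`` needs columns ``doy``, ``organ``, ``count`` and
    ``event_phase``; the reference is the ``pre`` census at the organ's
    first removal day (falling back to the latest count at or before
    it).  Regrowth can push ratios above 1.
    """
    sub = count_series[count_series["organ"] == organ]
    ref_rows = sub[(sub["doy"] == first_removal_doy) & (sub["event_phase"] == "pre")]
    if len(ref_rows) == 0:
        earlier = sub[sub["doy"] <= first_removal_doy].sort_values("doy")
        if len(earlier) == 0:
            raise ValueError(f"no pre-removal {organ} census at or before DOY {first_removal_doy}")
        ref = float(earlier["count"].iloc[-1])
    else:
        ref = float(ref_rows["count"].iloc[0])
    if ref == 0:
        raise ValueError("pre-removal reference count is zero")
    post = sub[(sub["event_phase"] != "pre") | (sub["doy"] != first_removal_doy)]
    out = pd.Series(post["count"].to_numpy(dtype=float) / ref,
                    index=post["doy"].to_numpy())
    ref_point = pd.Series([1.0], index=[first_removal_doy])
    return pd.concat([ref_point, out]).sort_index()


def date_to_doy(year: int, month: int, day: int) -> int:
    """1-based, leap-year-aware day of year of a Gregorian date."""
    return datetime.date(year, month, day).timetuple().tm_yday


def compute_tree_metrics(
    clean_photo: pd.DataFrame,
    counts: pd.DataFrame,
    spad: pd.DataFrame,
    first_leaf_removal_doy: int,
    cutoff_doy: int = MODELING_CUTOFF_DOY,
) -> pd.DataFrame:
    """Per-tree endpoint metrics for the whole experiment.

    Parameters
    ----------
    clean_photo : DataFrame
        QC-cleaned photosynthesis records for all trees.
    counts, spad : DataFrame
        Count and chlorophyll observation tables.
    first_leaf_removal_doy : int
        Day of the first leaf removal; its ``pre`` census is the
        pre-treatment leaf count.
    cutoff_doy : int
        Start of the senescence modeling window (kept alongside the
        metrics for the longitudinal model; the 50 % crossing is
        searched on the full index series, whose maximum is likewise
        taken over all dates).

    Returns
    -------
    DataFrame
        Columns: tree_id, total_autumn_photo, total_rel_carbon_gain,
        doy_50pct, doy_50pct_defined.
    """
    rows = []
    spad_by_tree = {t: g.set_index("doy")["avg_spad"] for t, g in spad.groupby("tree_id")}
    leaf_counts = counts[(counts["organ"] == "leaf") & (counts["event_phase"] == "none")]
    lc_by_tree = {t: g.set_index("doy")["count"] for t, g in leaf_counts.groupby("tree_id")}
    pre_rows = counts[
        (counts["organ"] == "leaf")
        & (counts["event_phase"] == "pre")
        & (counts["doy"] == first_leaf_removal_doy)
    ].set_index("tree_id")["count"]

    for tree_id, photo_g in clean_photo.groupby("tree_id"):
        lc = lc_by_tree.get(tree_id)
        sp = spad_by_tree.get(tree_id)
        if lc is None or sp is None:
            raise ValueError(f"missing count or SPAD series for tree {tree_id}")
        total_photo = total_autumn_photosynthesis(photo_g)
        pre_count = float(pre_rows.get(tree_id, lc.iloc[0]))
        total_rel = total_relative_carbon_gain(photo_g, lc, pre_count)
        index = inverted_spad_index(lc, sp)
        doy50 = doy_50pct_senescence(index)
        rows.append((tree_id, total_photo, total_rel,
                     math.nan if doy50 is None else doy50, doy50 is not None))
    return pd.DataFrame(
        rows,
        columns=["tree_id", "total_autumn_photo", "total_rel_carbon_gain",
                 "doy_50pct", "doy_50pct_defined"],
    )
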