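"""Frequency-distribution histograms, rotation-variance-aware first-order
statistics, and the S_parameter recovery indicator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mm_core import EmptyForegroundError
from .pbp import PARAM_RANGES

__all__ = [
    "FDH",
    "GroupStat",
    "compute_fdh",
    "axial_sd_deg",
    "summary_stat",
    "roi_statistics",
    "s_parameter",
]


@dataclass
class FDH:
    """Proportion-normalized frequency distribution histogram."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_pixels: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean(self) -> float:
        return float(np.sum(self.bin_centers * self.frequencies))


def _finite(values) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise EmptyForegroundError("no finite foreground values")
    return v


def compute_fdh(values, n_bins: int = 100, value_range=None, parameter: str | None = None) -> FDH:
    """Histogram with frequencies summing to one.

    ``value_range`` defaults to the parameter's natural range (when
    ``parameter`` names a known PBP) or to the data range.
    """
    v = _finite(values)
    if value_range is None and parameter is not None:
        value_range = PARAM_RANGES.get(parameter)
    if value_range is None:
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        value_range = (lo, hi)
    counts, edges = np.histogram(v, bins=n_bins, range=value_range)
    total = counts.sum()
    if total == 0:  # all values outside the requested range
        raise EmptyForegroundError("no values fall inside the histogram range")
    return FDH(bin_edges=edges, frequencies=counts / total, n_pixels=int(v.size))


def axial_sd_deg(angles_deg, period_deg: float = 180.0) -> float:
    """Circular standard deviation of axial angles by angle doubling.

    R = |mean(exp(i * (360/period) * angle))|, sd = (period/360) *
    sqrt(-2 ln R), reported in degrees. Invariant to adding a constant
    angle and to relabeling by the period.
    """
    a = _finite(angles_deg)
    scale = 360.0 / period_deg
    z = np.exp(1j * np.radians(scale * a))
    r = float(np.abs(z.mean()))
    if r >= 1.0:
        return 0.0
    if r <= 0.0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(r)) / scale))


@dataclass
class GroupStat:
    """One first-order statistic of a parameter map: mean (rotation-invariant
    parameters) or axial circular SD (rotation-variant angles)."""

    parameter: str
    kind: str  # "mean" | "axial_sd" | "sd"
    value: float
    roi_values: list[float] | None = None


def summary_stat(
    values,
    mask: np.ndarray | None = None,
    rotation_variant: bool = False,
    period_deg: float = 180.0,
    linear_sd: bool = False,
    parameter: str = "",
) -> GroupStat:
    """Mean for rotation-invariant parameters; axial circular SD (degrees,
    period 180) for rotation-variant ones. ``linear_sd`` substitutes the
    plain standard deviation for the axial estimator."""
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[mask]
    v = _finite(v)
    if not rotation_variant:
        return GroupStat(parameter, "mean", float(v.mean()))
    if linear_sd:
        return GroupStat(parameter, "sd", float(v.std()))
    return GroupStat(parameter, "axial_sd", axial_sd_deg(v, period_deg))


def roi_statistics(
    values: np.ndarray,
    rois,
    rotation_variant: bool = False,
    background: np.ndarray | None = None,
    pooled: bool = False,
    parameter: str = "",
    **kw,
) -> GroupStat:
    """Per-ROI statistics aggregated to a group statistic.

    Default: compute the statistic inside each ROI, then average over ROIs.
    ``pooled`` instead pools all ROI pixels into a single statistic.
    """
    rois = list(rois)
    if not rois:
        raise EmptyForegroundError("no ROIs given")
    fg = None if background is None else ~background
    if pooled:
        mask = np.zeros_like(rois[0], dtype=bool)
        for r in rois:
            mask |= r
        if fg is not None:
            mask &= fg
        stat = summary_stat(values, mask, rotation_variant, parameter=parameter, **kw)
        stat.roi_values = [stat.value]
        return stat
    per_roi = []
    for r in rois:
        mask = r if fg is None else (r & fg)
        per_roi.append(summary_stat(values, mask, rotation_variant, parameter=parameter, **kw))
    kind = per_roi[0].kind
    vals = [s.value for s in per_roi]
    return GroupStat(parameter, kind, float(np.mean(vals)), roi_values=vals)


def s_parameter(p: float, p_n: float) -> float:
    """Recovery indicator: statistic of the evaluated sample over the
    normal-group reference statistic."""
    if p_n == 0:
        raise ValueError("normal-group reference statistic is zero; ratio undefined")
    return float(p) / float(p_n)
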