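"""Depth profiles and group comparisons.

Per-slice metric records are aggregated into per-specimen depth profiles;
group curves (mean line + SD band per depth) and unpaired two-sample tests
over depth regions (proximal half, distal half, whole specimen) reproduce the
study design of comparing diseased and control femoral heads. The unit of
analysis for the tests is the per-specimen region mean — slices within one
specimen are not independent samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .netmetrics import MetricsRecord

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class DepthProfile:
    """Ordered per-depth metric records for one specimen."""

    specimen_id: str
    group: str  # "CTRL" | "HOA"
    depth_mm: tuple[float, ...]
    records: tuple[MetricsRecord, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_mm)
        if len(d) != len(self.records):
            raise ValueError("one record per depth required")
        if len(d) > 1 and not (np.diff(d) > 0).all():
            raise ValueError("depth_mm must be strictly increasing")

    def metric(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records], float)


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-sample test of one metric over one depth region."""

    metric_name: str
    region: str  # "first_half" | "second_half" | "whole"
    group_means: dict
    group_sds: dict
    normality_p: dict  # Shapiro-Wilk p per group (NaN when n < 3)
    t_statistic: float
    p_value: float
    significant: bool
    n_per_group: dict


def profile_stack(records: list[MetricsRecord], slice_spacing_um: float,
                  specimen_id: str = "specimen", group: str = "CTRL") -> DepthProfile:
    """Attach physical depths (mm) to a stack of per-slice records."""
    recs = sorted(records, key=lambda r: r.depth_index)
    idx = [r.depth_index for r in recs]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate depth indices")
    depths = tuple(i * slice_spacing_um / 1000.0 for i in idx)
    return DepthProfile(specimen_id, group, depths, tuple(recs))


def region_slices(n_slices: int) -> dict[str, range]:
    """Proximal/distal halves and the whole stack as index ranges."""
    if n_slices < 2:
        raise ValueError("need at least 2 slices to split into halves")
    half = n_slices // 2
    return {
        "first_half": range(0, half),
        "second_half": range(half, n_slices),
        "whole": range(0, n_slices),
    }


def smooth(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average for plotting; stored records are never smoothed."""
    if window <= 1:
        return np.asarray(values, float)
    kernel = np.ones(window) / window
    padded = np.pad(np.asarray(values, float), window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[:len(values)]


def group_band(profiles: list[DepthProfile], metric_name: str):
    """Per-group mean curve and sample-SD band on a common depth grid.

    Profiles are linearly interpolated onto the depth grid of the shortest
    profile (no-op for already-aligned grids). Returns
    ``{group: (depth_grid, mean, sd)}``; a single-specimen group gets SD 0
    with a warning.
    """
    if not profiles:
        raise ValueError("no profiles given")
    grid = np.asarray(min(profiles, key=lambda p: p.depth_mm[-1]).depth_mm, float)
    out = {}
    for group in sorted({p.group for p in profiles}):
        members = [p for p in profiles if p.group == group]
        curves = np.vstack([
            np.interp(grid, np.asarray(p.depth_mm), p.metric(metric_name))
            for p in members
        ])
        mean = curves.mean(axis=0)
        if len(members) == 1:
            logger.warning("group %s has a single specimen; SD band is 0", group)
            sd = np.zeros_like(mean)
        else:
            sd = curves.std(axis=0, ddof=1)
        out[group] = (grid, mean, sd)
    return out


def region_means(profile: DepthProfile, metric_name: str, region: str) -> float:
    """Per-specimen mean of one metric over one depth region (NaN-aware)."""
    values = profile.metric(metric_name)
    idx = region_slices(len(values))[region]
    return float(np.nanmean(values[list(idx)]))


def ttest_groups(a: np.ndarray, b: np.ndarray, welch: bool = False):
    """Unpaired two-sample t test (Student's pooled-variance by default)."""
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_groups(profiles: list[DepthProfile], metric_name: str,
                   region: str = "whole", welch: bool = False) -> GroupComparison:
    """Unpaired t test of per-specimen region means between the two groups.

    Shapiro-Wilk normality p-values are reported per group (NaN when a group
    has fewer than 3 specimens). Significance is declared at alpha = 0.05.
    """
    groups = sorted({p.group for p in profiles})
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    samples = {
        g: np.array([region_means(p, metric_name, region)
                     for p in profiles if p.group == g])
        for g in groups
    }
    for g, vals in samples.items():
        if len(vals) < 2:
            raise ValueError(f"group {g} needs >= 2 specimens, has {len(vals)}")
    normality = {}
    for g, vals in samples.items():
        if len(vals) >= 3 and np.ptp(vals) > 0:
            normality[g] = float(stats.shapiro(vals).pvalue)
        else:
            normality[g] = math.nan
    t, p = ttest_groups(samples[groups[0]], samples[groups[1]], welch=welch)
    return GroupComparison(
        metric_name=metric_name,
        region=region,
        group_means={g: float(v.mean()) for g, v in samples.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in samples.items()},
        normality_p=normality,
        t_statistic=t,
        p_value=p,
        significant=bool(p < ALPHA),
        n_per_group={g: int(len(v)) for g, v in samples.items()},
    )
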