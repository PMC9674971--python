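"""Molt timing from population feeding-fluorescence time series.

Animals stop feeding during lethargus, so ingested-bead fluorescence dips at
each molt.  Molts are called as prominent local minima of the kernel-smoothed
population median fluorescence; stage boundaries are placed at the minima.
Detection is range-relative, hence invariant to affine rescaling of the
fluorescence values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .stretcher import kernel_smooth

__all__ = [
    "FluorescenceSeries",
    "MoltAnnotation",
    "build_fluorescence_series",
    "detect_molts",
    "compare_molt_timing",
]

log = logging.getLogger(__name__)

STAGES = ("L1", "L2", "L3", "L4")


@dataclass
class FluorescenceSeries:
    """Population median normalized fluorescence per hour, one strain."""

    strain_id: str
    hours: np.ndarray
    median: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, float)
        self.median = np.asarray(self.median, float)
        self.sd = np.asarray(self.sd, float)
        if np.any(np.diff(self.hours) <= 0):
            raise ValueError("hours must be strictly increasing")
        if np.any(self.median < 0):
            raise ValueError("fluorescence must be >= 0")


@dataclass
class MoltAnnotation:
    """Detected (or configured) molt times and the stage windows they imply."""

    strain_id: str
    molt_times: tuple[float, ...]
    stage_windows: tuple[tuple[str, float, float], ...]
    source: str = "detected"


def build_fluorescence_series(summaries: pd.DataFrame) -> list[FluorescenceSeries]:
    """Per-strain population series from well summaries (median and SD over
    wells at each hour)."""
    out = []
    for strain, grp in summaries.groupby("strain", sort=True):
        agg = grp.groupby("hour", sort=True)["median_norm_fluorescence"].agg(
            ["median", "std"]
        )
        out.append(
            FluorescenceSeries(
                strain_id=strain,
                hours=agg.index.to_numpy(float),
                median=agg["median"].to_numpy(float),
                sd=np.nan_to_num(agg["std"].to_numpy(float)),
            )
        )
    return out


def detect_molts(
    series: FluorescenceSeries,
    min_prominence: float = 0.15,
    min_separation: float = 5.0,
    h_bw: float = 2.0,
    grid_step: float = 0.25,
    max_molts: int = 3,
) -> MoltAnnotation:
    """Call molts as prominent minima of the smoothed fluorescence series.

    ``min_prominence`` is a fraction of the smoothed series' dynamic range;
    minima closer than ``min_separation`` hours collapse to the more
    prominent one.  At most ``max_molts`` (the three larval transitions
    within the assay span) are reported, ordered in time.
    """
    if len(series.hours) < 10:
        raise ValueError("molt detection needs >= 10 time points")
    grid = np.arange(series.hours[0], series.hours[-1] + 1e-9, grid_step)
    smooth, _ = kernel_smooth(series.hours, series.median, grid, h_bw)
    rng_ = float(smooth.max() - smooth.min())
    if rng_ <= 0:
        warnings.warn(f"{series.strain_id}: flat fluorescence series, no molts")
        return _annotate(series, (), "detected")
    idx, props = find_peaks(
        -smooth,
        prominence=min_prominence * rng_,
        distance=max(1, int(round(min_separation / grid_step))),
    )
    if len(idx) == 0:
        warnings.warn(f"{series.strain_id}: no feeding minima found")
        return _annotate(series, (), "detected")
    if len(idx) > max_molts:
        order = np.argsort(props["prominences"])[::-1][:max_molts]
        idx = np.sort(idx[order])
    return _annotate(series, tuple(float(grid[i]) for i in idx), "detected")


def _annotate(series, molt_times, source) -> MoltAnnotation:
    edges = [float(series.hours[0]), *molt_times, float(series.hours[-1])]
    windows = tuple(
        (STAGES[i], edges[i], edges[i + 1]) for i in range(len(edges) - 1)
    )
    return MoltAnnotation(
        strain_id=series.strain_id,
        molt_times=tuple(molt_times),
        stage_windows=windows,
        source=source,
    )


def compare_molt_timing(annotations) -> pd.DataFrame:
    """Rank strains by per-stage transition hour.

    Columns: stage, strain, transition_hour, rank, tied.  Strains without a
    detection for a given transition are excluded and logged; exact ties
    share a rank, are flagged, and break by strain label order.
    """
    annotations = list(annotations)
    rows = []
    n_molts = max((len(a.molt_times) for a in annotations), default=0)
    for mi in range(n_molts):
        entries = []
        for ann in annotations:
            if mi < len(ann.molt_times):
                entries.append((ann.strain_id, ann.molt_times[mi]))
            else:
                log.info("%s: no detection for molt %d, excluded", ann.strain_id, mi + 1)
        entries.sort(key=lambda e: (e[1], e[0]))
        times = [t for _, t in entries]
        for strain, t in entries:
            rank = 1 + sorted(set(times)).index(t)
            rows.append(
                {
                    "stage": f"{STAGES[mi]}-{STAGES[mi + 1]}",
                    "strain": strain,
                    "transition_hour": t,
                    "rank": rank if len(entries) > 1 else pd.NA,
                    "tied": times.count(t) > 1,
                }
            )
    return pd.DataFrame(rows, columns=["stage", "strain", "transition_hour", "rank", "tied"])
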