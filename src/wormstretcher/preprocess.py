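"""Raw object records -> calibrated per-well median summaries.

Three steps mirror the cytometer data-processing workflow: (1) gate out
non-animal objects (bacterial clumps, shed cuticles, next-generation larvae)
with model-based clustering on (log TOF, log EXT); (2) summarize each well by
the medians of kept objects, with red fluorescence normalized per object by
the area proxy TOF*norm.EXT; (3) convert instrument units to microns with a
through-origin calibration fitted against manual image measurements (pixels,
converted to µm by the fixed magnification factor of 3.2937 pixels/µm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "CalibrationModel",
    "gate_animals",
    "summarize_wells",
    "fit_calibration",
    "convert_units",
    "PIXELS_PER_MICRON",
]

log = logging.getLogger(__name__)

#: fixed imaging magnification factor, pixels per micron.
PIXELS_PER_MICRON = 3.2937

#: below this pooled-hour object count the mixture gate falls back to
#: robust-quantile gating; a single object passes through.
MIN_CLUSTER_SIZE = 20

#: minimum Euclidean gap in (log TOF, log EXT) between a mixture component's
#: mean and the animal component's mean for that component to be discarded.
_SEPARATION = 1.0

#: after this hour, kept objects smaller than _FLOOR_FRACTION of the hour's
#: median TOF are removed (next-generation larvae hatch late in the assay).
_LATE_HOUR = 30.0
_FLOOR_FRACTION = 0.25


def _iqr_keep(x: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)


def _gate_hour_pool(X: np.ndarray) -> np.ndarray:
    """Boolean keep-mask for one pooled hour of (log tof, log ext) points."""
    n = len(X)
    if n == 1:
        return np.ones(1, bool)
    if n < MIN_CLUSTER_SIZE:
        return _iqr_keep(X[:, 0]) & _iqr_keep(X[:, 1])
    fits = []
    for k in (1, 2, 3):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=2,
            random_state=0, reg_covar=1e-6,
        ).fit(X)
        fits.append((gm.bic(X), k, gm))
    _, k, gm = min(fits, key=lambda f: (f[0], f[1]))
    if k == 1:
        return np.ones(n, bool)
    animal = int(np.argmax(gm.means_[:, 0]))
    labels = gm.predict(X)
    keep = labels == animal
    for comp in range(k):
        if comp == animal:
            continue
        gap = float(np.linalg.norm(gm.means_[comp] - gm.means_[animal]))
        if gap < _SEPARATION:
            # too close to call contaminant: treat as animal
            keep |= labels == comp
    return keep


def gate_animals(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition object records into (kept, removed).

    Clustering is pooled per hour across wells and strains; any ground-truth
    columns present are ignored by the decision rule.  Deterministic given
    the input.
    """
    if records.empty:
        warnings.warn("gate_animals: empty input", stacklevel=2)
        return records.copy(), records.copy()
    keep = np.zeros(len(records), bool)
    logtof = np.log(records["tof"].to_numpy(float))
    logext = np.log(records["ext"].to_numpy(float))
    for hour, idx in records.groupby("hour", sort=True).indices.items():
        X = np.column_stack([logtof[idx], logext[idx]])
        mask = _gate_hour_pool(X)
        if float(hour) > _LATE_HOUR and mask.any():
            tof = records["tof"].to_numpy(float)[idx]
            floor = _FLOOR_FRACTION * np.median(tof[mask])
            mask &= tof >= floor
        keep[idx] = mask
    kept = records.iloc[keep].copy()
    removed = records.iloc[~keep].copy()
    log.info("gated %d objects: kept %d, removed %d", len(records), len(kept), len(removed))
    return kept, removed


def summarize_wells(
    kept: pd.DataFrame, removed: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-(strain, well, hour) medians of kept objects.

    ``median_norm_fluorescence`` is the median of per-object red/(tof*norm_ext)
    (red fluorescence normalized by the optical area proxy).  Wells present
    only in ``removed`` are omitted (nothing to summarize) and logged.
    """
    if kept.empty:
        warnings.warn("summarize_wells: no kept records", stacklevel=2)
        return pd.DataFrame(
            columns=["strain", "well", "hour", "median_tof", "median_norm_ext",
                     "median_norm_fluorescence", "n_objects_kept", "n_objects_removed"]
        )
    k = kept.copy()
    k["_normfl"] = k["red"] / (k["tof"] * k["norm_ext"])
    out = (
        k.groupby(["strain", "well", "hour"], sort=True)
        .agg(
            median_tof=("tof", "median"),
            median_norm_ext=("norm_ext", "median"),
            median_norm_fluorescence=("_normfl", "median"),
            n_objects_kept=("tof", "size"),
        )
        .reset_index()
    )
    if removed is not None and not removed.empty:
        rem = (
            removed.groupby(["strain", "well", "hour"], sort=True)
            .size()
            .rename("n_objects_removed")
            .reset_index()
        )
        out = out.merge(rem, on=["strain", "well", "hour"], how="left")
        out["n_objects_removed"] = out["n_objects_removed"].fillna(0).astype(int)
        lost = set(map(tuple, rem[["strain", "well", "hour"]].itertuples(index=False))) - set(
            map(tuple, out[["strain", "well", "hour"]].itertuples(index=False))
        )
        if lost:
            log.info("%d wells had zero kept objects and were omitted", len(lost))
    else:
        out["n_objects_removed"] = 0
    return out


@dataclass(frozen=True)
class CalibrationModel:
    """Through-origin conversion from instrument units to microns.

    A zero-length object has zero TOF, so the regressions of µm on
    instrument units are fitted without intercepts.
    """

    tof_to_um_slope: float
    normext_to_um_slope: float
    pixels_per_micron: float = PIXELS_PER_MICRON
    length_resid_sd: float = float("nan")
    width_resid_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.tof_to_um_slope <= 0 or self.normext_to_um_slope <= 0:
            raise ValueError("calibration slopes must be positive")

    def length_um(self, tof):
        return self.tof_to_um_slope * np.asarray(tof, float)

    def width_um(self, norm_ext):
        return self.normext_to_um_slope * np.asarray(norm_ext, float)

    def invert_length(self, um):
        return np.asarray(um, float) / self.tof_to_um_slope

    def invert_width(self, um):
        return np.asarray(um, float) / self.normext_to_um_slope


def _through_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope = float(np.dot(x, y) / np.dot(x, x))
    resid = y - slope * x
    sd = float(np.std(resid, ddof=1)) if len(x) > 1 else float("nan")
    return slope, sd


def fit_calibration(
    manual: pd.DataFrame,
    summaries: pd.DataFrame,
    pixels_per_micron: float = PIXELS_PER_MICRON,
    min_pairs: int = 10,
) -> CalibrationModel:
    """Fit instrument-unit -> µm slopes from manual image measurements.

    ``manual`` has per-animal rows (hour, well, length_px, width_px); they are
    reduced to per-well medians, converted to µm by ``pixels_per_micron``, and
    matched to well summaries on (hour, well).  Requires >= ``min_pairs``
    matched wells.
    """
    man = (
        manual.groupby(["hour", "well"], sort=True)
        .agg(length_px=("length_px", "median"), width_px=("width_px", "median"))
        .reset_index()
    )
    pairs = man.merge(summaries, on=["hour", "well"], how="inner")
    if len(pairs) < min_pairs:
        raise ValueError(
            f"calibration needs >= {min_pairs} matched wells, got {len(pairs)}"
        )
    len_um = pairs["length_px"].to_numpy(float) / pixels_per_micron
    wid_um = pairs["width_px"].to_numpy(float) / pixels_per_micron
    s_len = _through_origin(pairs["median_tof"].to_numpy(float), len_um)
    s_wid = _through_origin(pairs["median_norm_ext"].to_numpy(float), wid_um)
    return CalibrationModel(
        tof_to_um_slope=s_len[0],
        normext_to_um_slope=s_wid[0],
        pixels_per_micron=pixels_per_micron,
        length_resid_sd=s_len[1],
        width_resid_sd=s_wid[1],
    )


def convert_units(summaries: pd.DataFrame, model: CalibrationModel) -> pd.DataFrame:
    """Add ``median_length_um`` / ``median_width_um``; raw columns retained."""
    if model is None:
        raise ValueError("a fitted CalibrationModel is required")
    out = summaries.copy()
    out["median_length_um"] = model.length_um(out["median_tof"].to_numpy(float))
    out["median_width_um"] = model.width_um(out["median_norm_ext"].to_numpy(float))
    return out
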