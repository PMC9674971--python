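"""Figure-style outputs and summary tables from pipeline products.

Produces the standard five-panel view of a growth assay: Tukey boxplots of
per-well normalized fluorescence, length and width by hour; the length-width
phase plane; and the slope-ratio curves with SD shading.  All tabular output
is deterministic (byte-identical on identical inputs) and every plotted
series is traceable through the emitted manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["TukeyBoxStats", "tukey_box_stats", "ReportBundle", "render_report"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class TukeyBoxStats:
    """Five-number boxplot summary with 1.5*IQR whiskers.

    Quartiles use linear interpolation between order statistics; whiskers sit
    at the most extreme observations within 1.5*IQR of the quartile box and
    points beyond are outliers.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def tukey_box_stats(values) -> TukeyBoxStats:
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("tukey_box_stats requires at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
    return TukeyBoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in outliers),
    )


@dataclass
class ReportBundle:
    """Everything the report needs: calibrated well summaries, the slope
    ratio curves and the relaxation records."""

    summaries: pd.DataFrame
    slope_ratio_curves: list = field(default_factory=list)
    relaxation_records: list = field(default_factory=list)


def _box_stats_frame(summaries: pd.DataFrame) -> pd.DataFrame:
    rows = []
    metrics = {
        "fluorescence": "median_norm_fluorescence",
        "length_um": "median_length_um",
        "width_um": "median_width_um",
    }
    for (strain, hour), grp in summaries.groupby(["strain", "hour"], sort=True):
        for name, col in metrics.items():
            if col not in grp:
                continue
            st = tukey_box_stats(grp[col].to_numpy(float))
            rows.append(
                {
                    "strain": strain, "hour": hour, "metric": name,
                    "median": st.median, "q1": st.q1, "q3": st.q3,
                    "whisker_low": st.whisker_low, "whisker_high": st.whisker_high,
                    "n_outliers": len(st.outliers), "n_wells": len(grp),
                }
            )
    return pd.DataFrame(rows)


def _slope_ratio_frame(curves, segmentations=None) -> pd.DataFrame:
    seg_by_key = {}
    for seg in segmentations or []:
        seg_by_key[(seg.strain_id, seg.stage)] = seg
    rows = []
    for c in curves:
        seg = seg_by_key.get((c.strain_id, c.stage))
        for i, t in enumerate(c.grid):
            rows.append(
                {
                    "strain": c.strain_id, "stage": c.stage, "t": float(t),
                    "r": float(c.ratio[i]) if np.isfinite(c.ratio[i]) else np.nan,
                    "sd": float(c.sd[i]) if np.isfinite(c.sd[i]) else np.nan,
                    "label": (seg.labels[i] if seg is not None else
                              ("defined" if c.mask[i] else "masked")),
                }
            )
    return pd.DataFrame(rows, columns=["strain", "stage", "t", "r", "sd", "label"])


def _relaxation_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": r.strain_id, "molt_index": r.molt_index,
                "molt_time": r.molt_time, "delta_length_um": r.delta_length_um,
                "delta_width_um": r.delta_width_um,
                "direction": r.direction or "ambiguous",
                "magnitude_um": r.magnitude_um, "flagged": r.flagged,
            }
            for r in records
        ],
        columns=["strain", "molt_index", "molt_time", "delta_length_um",
                 "delta_width_um", "direction", "magnitude_um", "flagged"],
    )


def _boxplot_figure(summaries, col, ylabel, path):
    strains = sorted(summaries["strain"].unique())
    fig, axes = plt.subplots(
        len(strains), 1, figsize=(8, 2.2 * len(strains)), sharex=True, squeeze=False
    )
    for ax, strain in zip(axes.ravel(), strains):
        grp = summaries[summaries["strain"] == strain]
        hours = sorted(grp["hour"].unique())
        data = [grp.loc[grp["hour"] == h, col].to_numpy(float) for h in hours]
        ax.boxplot(data, positions=hours, widths=0.6, whis=1.5,
                   flierprops={"markersize": 2})
        ax.set_ylabel(f"{strain}\n{ylabel}", fontsize=8)
    axes.ravel()[-1].set_xlabel("hours post-feeding")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _phase_plane_figure(summaries, path):
    fig, ax = plt.subplots(figsize=(6, 5))
    for strain, grp in summaries.groupby("strain", sort=True):
        pop = grp.groupby("hour", sort=True)[
            ["median_length_um", "median_width_um"]
        ].median()
        ax.plot(pop["median_length_um"], pop["median_width_um"],
                marker="o", ms=3, lw=1, label=strain)
    ax.set_xlabel("median length (µm)")
    ax.set_ylabel("median width (µm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _slope_ratio_figure(curves, path):
    strains = sorted({c.strain_id for c in curves})
    stages = sorted({c.stage for c in curves})
    fig, axes = plt.subplots(
        len(stages), len(strains),
        figsize=(2.5 * len(strains), 2.0 * len(stages)),
        squeeze=False, sharex=False,
    )
    index = {(c.strain_id, c.stage): c for c in curves}
    for i, stage in enumerate(stages):
        for j, strain in enumerate(strains):
            ax = axes[i][j]
            c = index.get((strain, stage))
            if c is not None:
                ax.plot(c.grid, c.ratio, lw=1.2)
                ax.fill_between(
                    c.grid,
                    np.nan_to_num(c.ratio - c.sd),
                    np.nan_to_num(c.ratio + c.sd),
                    alpha=0.3, linewidth=0,
                )
            if i == 0:
                ax.set_title(strain, fontsize=9)
            if j == 0:
                ax.set_ylabel(f"{stage}\ndW/dL", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_report(bundle: ReportBundle, outdir, segmentations=None) -> dict:
    """Write figures (SVG + PNG), CSV tables and a provenance manifest.

    Re-running on identical inputs reproduces byte-identical CSVs.  Returns
    the manifest (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"figures": [], "tables": {}}
    summaries = bundle.summaries

    tables = {
        "box_stats.csv": _box_stats_frame(summaries) if not summaries.empty
        else pd.DataFrame(),
        "slope_ratio.csv": _slope_ratio_frame(bundle.slope_ratio_curves, segmentations),
        "relaxation.csv": _relaxation_frame(bundle.relaxation_records),
    }
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        manifest["tables"][name] = {
            "rows": int(len(df)),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    if not summaries.empty:
        figures = [
            ("fluorescence_boxplots", lambda p: _boxplot_figure(
                summaries, "median_norm_fluorescence", "norm. fluorescence", p)),
            ("length_boxplots", lambda p: _boxplot_figure(
                summaries, "median_length_um", "length (µm)", p)),
            ("width_boxplots", lambda p: _boxplot_figure(
                summaries, "median_width_um", "width (µm)", p)),
            ("phase_plane", lambda p: _phase_plane_figure(summaries, p)),
            ("slope_ratio", lambda p: _slope_ratio_figure(
                bundle.slope_ratio_curves, p)),
        ]
        for name, fn in figures:
            for ext in ("svg", "png"):
                path = outdir / f"{name}.{ext}"
                fn(path)
                manifest["figures"].append(path.name)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
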