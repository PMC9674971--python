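"""Seeded synthetic large-particle flow-cytometer datasets for larval growth assays.

Emulates a COPAS BIOSORT time course of *C. elegans* larvae sampled hourly
from liquid culture: per-object time-of-flight (TOF, axial length proxy),
optical extinction (EXT; norm.EXT = EXT/TOF is the width proxy) and red
fluorescence from ingested beads (feeding proxy), plus non-animal contaminant
objects (bacterial clumps, shed-cuticle-like streaks).

Growth model
------------
Each larval stage k spans ``[s_k, e_k]`` hours post-feeding; active growth is
confined to a sub-window that excludes a lethargus plateau of
``molt_plateau`` hours flanking each molt (growth stalls while the animal
stops feeding).  During active growth, length increases linearly at
``growth_rates[k]`` µm/h.  Width follows the cuticle-stretch ("Stretcher")
phenomenology: the local slope ratio dW/dL equals the baseline aspect slope
``c_k`` in the linear regime, then ramps linearly to ``c_k * gain`` between
the nonlinear onset (a fraction of the active window) and the end of the
stage.  At each molt an instantaneous post-molt relaxation step is applied:
the named axis steps up by ``relaxation_magnitude`` µm while the other axis
decreases by ``RELAX_SECONDARY_FRACTION`` times that.  Feeding rate dips at
each molt by ``feeding_dip_depth`` with Gaussian half-width
``feeding_dip_halfwidth``.

All pieces are linear or quadratic in time, so closed-form trajectories are
available as oracles for every downstream stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StrainProfile",
    "SimulationConfig",
    "DEFAULT_PROFILES",
    "default_config",
    "simulate_trajectory",
    "simulate_dataset",
    "simulate_manual_measurements",
    "planted_molts",
    "write_dataset",
    "read_dataset",
    "RAW_COLUMNS",
    "TRUTH_COLUMNS",
    "RELAX_SECONDARY_FRACTION",
]

#: fraction of the relaxation magnitude applied (with opposite sign) to the
#: non-relaxing axis at each molt.
RELAX_SECONDARY_FRACTION = 0.5

#: SD (hours) of per-animal molt-time jitter for molts 1-3; grows with stage
#: index to emulate population desynchronization as animals age.
MOLT_JITTER_SD = (0.3, 0.6, 1.0)

RAW_COLUMNS = ["strain", "well", "hour", "tof", "ext", "norm_ext", "red"]
TRUTH_COLUMNS = RAW_COLUMNS + ["truth_class", "truth_length_um", "truth_width_um"]

#: instrument gain applied to red fluorescence (units per µm² of animal area).
FLUOR_GAIN = 0.05


@dataclass(frozen=True)
class StrainProfile:
    """Ground-truth growth parameters for one strain.

    Lengths/widths in µm, times in hours post-feeding.
    """

    strain_id: str
    stage_boundaries: tuple[float, float, float]  # molt hours L1->L2, L2->L3, L3->L4
    growth_rates: tuple[float, float, float, float]  # µm/h of length, per stage
    aspect_slopes: tuple[float, float, float, float]  # c_k = baseline dW/dL per stage
    nonlinear_onset_fraction: float = 0.7
    nonlinear_slope_gain: float = 1.5
    relaxation_direction: str = "length-relax"  # or "width-relax"
    relaxation_magnitude: float = 5.0  # µm step on the named axis at each molt
    feeding_dip_depth: float = 0.6  # fraction of baseline fluorescence
    feeding_dip_halfwidth: float = 1.0  # h (Gaussian sigma of the dip)
    length_at_start: float = 250.0  # µm at t = 0 (arrested L1)
    width_at_start: float = 12.0  # µm at t = 0
    molt_plateau: float = 2.5  # h of stalled growth before each molt (lethargus)
    post_molt_plateau: float = 3.0  # h of stalled growth after each molt (relaxation period)
    span: tuple[float, float] = (0.0, 42.0)

    def __post_init__(self) -> None:
        b = self.stage_boundaries
        lo, hi = self.span
        if not (lo <= b[0] < b[1] < b[2] <= hi):
            raise ValueError(
                f"stage_boundaries must be strictly increasing within {self.span}: {b}"
            )
        if any(c <= 0 for c in self.aspect_slopes):
            raise ValueError("aspect slopes c_k must be positive")
        if not 0.0 < self.nonlinear_onset_fraction < 1.0:
            raise ValueError("nonlinear_onset_fraction must be in (0, 1)")
        if self.nonlinear_slope_gain < 1.0:
            raise ValueError("nonlinear_slope_gain must be >= 1")
        if not 0.0 < self.feeding_dip_depth <= 1.0:
            raise ValueError("feeding_dip_depth must be in (0, 1]")
        if self.relaxation_direction not in ("length-relax", "width-relax"):
            raise ValueError(f"unknown relaxation_direction {self.relaxation_direction!r}")
        for s, e in zip((lo, *b), (*b, hi)):
            a0 = s + (self.post_molt_plateau if s != lo else 0.0)
            a1 = e - (self.molt_plateau if e != hi else 0.0)
            if a1 - a0 <= 0:
                raise ValueError("molt plateaus leave a stage with no active growth")

    def active_window(self, stage: int) -> tuple[float, float]:
        """Active-growth hours of stage 1..4 (lethargus plateaus excluded)."""
        lo, hi = self.span
        edges = (lo, *self.stage_boundaries, hi)
        s, e = edges[stage - 1], edges[stage]
        a0 = s + (self.post_molt_plateau if stage > 1 else 0.0)
        a1 = e - (self.molt_plateau if stage < 4 else 0.0)
        return a0, a1


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated assay; identical config + seed give
    bit-identical output."""

    strain_profiles: tuple[StrainProfile, ...]
    n_wells_per_hour: int = 30
    n_animals_per_well: int = 30
    hours: tuple[float, ...] = tuple(float(h) for h in range(1, 43))
    contaminant_rate: float = 0.1
    noise_sd_length: float = 15.0  # µm, per object
    noise_sd_width: float = 1.5  # µm, per object
    noise_sd_fluorescence: float = 0.15  # multiplicative fraction
    pixels_per_micron: float = 3.2937
    tof_per_pixel: float = 1.0
    ext_per_pixel: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells_per_hour < 1 or self.n_animals_per_well < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.contaminant_rate < 1.0:
            raise ValueError("contaminant_rate must be in [0, 1)")
        for name in ("noise_sd_length", "noise_sd_width", "noise_sd_fluorescence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.pixels_per_micron, self.tof_per_pixel, self.ext_per_pixel) <= 0:
            raise ValueError("instrument gains must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["strain_profiles"] = [dataclasses.asdict(p) for p in self.strain_profiles]
        Path(path).write_text(yaml.safe_dump(_tuples_to_lists(d), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        profiles = tuple(
            StrainProfile(**_lists_to_tuples(p)) for p in d.pop("strain_profiles")
        )
        return cls(strain_profiles=profiles, **_lists_to_tuples(d))


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _lists_to_tuples(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


# Default strain roster.  Boundaries and rates encode the qualitative
# contrasts of the four-strain panel: lon-3 tracks wild type, both dpy
# mutants molt late (dpy-1 latest at every transition), dpy mutants are
# shorter and wider (larger aspect slopes), dpy-1 shows a weak nonlinear
# regime, and dpy-5 relaxes in width where the others relax in length.
DEFAULT_PROFILES: tuple[StrainProfile, ...] = (
    StrainProfile(
        strain_id="N2",
        stage_boundaries=(14.0, 25.0, 33.0),
        growth_rates=(10.0, 22.0, 30.0, 40.0),
        aspect_slopes=(0.060, 0.060, 0.070, 0.080),
        relaxation_direction="length-relax",
        relaxation_magnitude=5.0,
    ),
    StrainProfile(
        strain_id="lon-3",
        stage_boundaries=(14.0, 25.5, 34.0),
        growth_rates=(10.5, 23.0, 31.0, 42.0),
        aspect_slopes=(0.055, 0.055, 0.065, 0.075),
        relaxation_direction="length-relax",
        relaxation_magnitude=5.0,
    ),
    StrainProfile(
        strain_id="dpy-5",
        stage_boundaries=(16.5, 27.0, 36.0),
        growth_rates=(8.0, 15.0, 19.0, 26.0),
        aspect_slopes=(0.110, 0.110, 0.125, 0.140),
        relaxation_direction="width-relax",
        relaxation_magnitude=6.0,
        width_at_start=13.5,
    ),
    StrainProfile(
        strain_id="dpy-1",
        stage_boundaries=(17.5, 29.0, 37.0),
        growth_rates=(7.5, 14.0, 18.0, 24.0),
        aspect_slopes=(0.120, 0.120, 0.135, 0.150),
        nonlinear_slope_gain=1.1,
        relaxation_direction="length-relax",
        relaxation_magnitude=2.0,
        width_at_start=14.0,
    ),
)


def default_config(**overrides) -> SimulationConfig:
    """The default four-strain, 42 h hourly assay configuration."""
    return SimulationConfig(strain_profiles=DEFAULT_PROFILES, **overrides)


# ---------------------------------------------------------------------------
# Trajectory (closed form)
# ---------------------------------------------------------------------------

def _piecewise_shape(profile: StrainProfile, t, boundaries):
    """Length, width and feeding rate at hours ``t`` for per-sample molt
    ``boundaries`` (shape ``(..., 3)``, broadcast against ``t``)."""
    t = np.asarray(t, float)
    b = np.asarray(boundaries, float)
    lo, hi = profile.span
    shape = np.broadcast_shapes(t.shape, b[..., 0].shape)
    L = np.empty(shape)
    W = np.empty(shape)
    Lk = np.broadcast_to(np.asarray(profile.length_at_start, float), b[..., 0].shape).copy()
    Wk = np.broadcast_to(np.asarray(profile.width_at_start, float), b[..., 0].shape).copy()
    f = profile.nonlinear_onset_fraction
    gain = profile.nonlinear_slope_gain
    mag = profile.relaxation_magnitude
    sec = RELAX_SECONDARY_FRACTION * mag
    starts = [np.full_like(b[..., 0], lo), b[..., 0], b[..., 1], b[..., 2]]
    ends = [b[..., 0], b[..., 1], b[..., 2], np.full_like(b[..., 0], hi)]
    for k in range(4):
        s, e = starts[k], ends[k]
        a0 = s + (profile.post_molt_plateau if k > 0 else 0.0)
        a1 = e - (profile.molt_plateau if k < 3 else 0.0)
        D = a1 - a0
        g = profile.growth_rates[k]
        c = profile.aspect_slopes[k]
        ton = f * D
        d = np.clip(t - a0, 0.0, D)
        Lt = Lk + g * d
        over = np.clip(d - ton, 0.0, None)
        Wt = Wk + c * g * np.minimum(d, ton)
        Wt = Wt + g * c * (over + (gain - 1.0) * over**2 / (2.0 * (D - ton)))
        in_stage = (t >= s) & ((t < e) if k < 3 else (t <= e))
        L[...] = np.where(in_stage, Lt, L)
        W[...] = np.where(in_stage, Wt, W)
        # advance cumulative state across the molt
        L_end = Lk + g * D
        W_end = Wk + c * g * ton + g * c * ((D - ton) + (gain - 1.0) * (D - ton) / 2.0)
        if k < 3:
            if profile.relaxation_direction == "length-relax":
                Lk = L_end + mag
                Wk = W_end - sec
            else:
                Wk = W_end + mag
                Lk = L_end - sec
    feeding = np.ones(shape)
    hw = profile.feeding_dip_halfwidth
    for k in range(3):
        feeding = feeding - profile.feeding_dip_depth * np.exp(
            -0.5 * ((t - b[..., k]) / hw) ** 2
        )
    feeding = np.clip(feeding, 0.0, 1.0)
    return L, W, feeding


def simulate_trajectory(profile: StrainProfile, t):
    """Noiseless (length µm, width µm, feeding rate) at hour(s) ``t``.

    Raises ``ValueError`` for ``t`` outside the profile's observation span.
    """
    t_arr = np.asarray(t, float)
    lo, hi = profile.span
    if np.any(t_arr < lo) or np.any(t_arr > hi):
        raise ValueError(f"t outside observation span {profile.span}")
    b = np.asarray(profile.stage_boundaries, float)
    if t_arr.ndim:
        b = np.broadcast_to(b, t_arr.shape + (3,))
    L, W, feed = _piecewise_shape(profile, t_arr, b)
    if t_arr.ndim == 0:
        return float(L), float(W), float(feed)
    return L, W, feed


def planted_molts(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth molt times per strain, for truth-table assertions."""
    rows = [
        {"strain": p.strain_id, "molt_index": k + 1, "hour": p.stage_boundaries[k]}
        for p in config.strain_profiles
        for k in range(3)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dataset (measurement model)
# ---------------------------------------------------------------------------

def _well_rng(seed: int, si: int, hi: int, wi: int) -> np.random.Generator:
    # counter-based stream split: changing well/hour counts never reshuffles
    # the draws of other wells
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, si, hi, wi)))


def _clamped_boundaries(profile: StrainProfile, jitter: np.ndarray) -> np.ndarray:
    b = np.asarray(profile.stage_boundaries, float) + jitter
    lo, hi = profile.span
    gap = profile.molt_plateau + profile.post_molt_plateau + 0.5
    b[:, 0] = np.clip(b[:, 0], lo + 0.5, hi - 3 * gap)
    for k in (1, 2):
        b[:, k] = np.maximum(b[:, k], b[:, k - 1] + gap)
    b[:, 2] = np.minimum(b[:, 2], hi - gap)
    b[:, 1] = np.minimum(b[:, 1], b[:, 2] - gap)
    b[:, 0] = np.minimum(b[:, 0], b[:, 1] - gap)
    return b


def simulate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Simulate per-object records for the whole assay.

    Returns a DataFrame with the raw instrument columns plus the synthetic
    ground-truth columns (``truth_class``, ``truth_length_um``,
    ``truth_width_um``).  Deterministic for a given config (incl. seed).
    """
    g_tof = config.tof_per_pixel * config.pixels_per_micron
    g_ext = config.ext_per_pixel * config.pixels_per_micron
    cols: dict[str, list] = {c: [] for c in TRUTH_COLUMNS}

    for si, prof in enumerate(config.strain_profiles):
        for hi, hour in enumerate(config.hours):
            for wi in range(config.n_wells_per_hour):
                rng = _well_rng(config.seed, si, hi, wi)
                well_id = f"{prof.strain_id}_h{hour:g}_w{wi:02d}"
                n = config.n_animals_per_well
                n_cont = int(rng.binomial(n, config.contaminant_rate))
                n_anim = n - n_cont

                if n_anim:
                    jit = rng.normal(0.0, MOLT_JITTER_SD, size=(n_anim, 3))
                    bounds = _clamped_boundaries(prof, jit)
                    L, W, feed = _piecewise_shape(prof, float(hour), bounds)
                    tof = g_tof * np.clip(
                        L + rng.normal(0, config.noise_sd_length, n_anim), 1.0, None
                    )
                    nex = g_ext * np.clip(
                        W + rng.normal(0, config.noise_sd_width, n_anim), 0.1, None
                    )
                    red = (
                        FLUOR_GAIN
                        * feed
                        * L
                        * W
                        * np.clip(
                            1 + rng.normal(0, config.noise_sd_fluorescence, n_anim),
                            0.05,
                            None,
                        )
                    )
                    _append(cols, prof.strain_id, well_id, hour, tof, nex, red,
                            "animal", L, W)

                if n_cont:
                    is_clump = rng.random(n_cont) < 0.5
                    Leq = np.where(
                        is_clump,
                        rng.lognormal(np.log(60.0), 0.35, n_cont),
                        rng.lognormal(np.log(120.0), 0.40, n_cont),
                    )
                    Weq = np.where(
                        is_clump,
                        rng.lognormal(np.log(50.0), 0.30, n_cont),
                        rng.lognormal(np.log(2.5), 0.30, n_cont),
                    )
                    tof = g_tof * np.clip(
                        Leq + rng.normal(0, config.noise_sd_length, n_cont), 1.0, None
                    )
                    nex = g_ext * np.clip(
                        Weq + rng.normal(0, config.noise_sd_width, n_cont), 0.1, None
                    )
                    bead = np.where(is_clump, 0.2, 0.05)
                    red = (
                        FLUOR_GAIN
                        * bead
                        * Leq
                        * Weq
                        * np.clip(
                            1 + rng.normal(0, config.noise_sd_fluorescence, n_cont),
                            0.05,
                            None,
                        )
                    )
                    _append(cols, prof.strain_id, well_id, hour, tof, nex, red,
                            "contaminant", Leq, Weq)

    df = pd.DataFrame(
        {
            "strain": cols["strain"],
            "well": cols["well"],
            "hour": np.asarray(cols["hour"], float),
            "tof": np.concatenate(cols["tof"]) if cols["tof"] else np.array([]),
            "norm_ext": np.concatenate(cols["norm_ext"]) if cols["norm_ext"] else np.array([]),
            "red": np.concatenate(cols["red"]) if cols["red"] else np.array([]),
            "truth_class": cols["truth_class"],
            "truth_length_um": np.concatenate(cols["truth_length_um"]) if cols["truth_length_um"] else np.array([]),
            "truth_width_um": np.concatenate(cols["truth_width_um"]) if cols["truth_width_um"] else np.array([]),
        }
    )
    df["ext"] = df["tof"] * df["norm_ext"]
    return df[TRUTH_COLUMNS]


def _append(cols, strain, well, hour, tof, nex, red, klass, L, W):
    n = len(tof)
    cols["strain"].extend([strain] * n)
    cols["well"].extend([well] * n)
    cols["hour"].extend([hour] * n)
    cols["tof"].append(tof)
    cols["norm_ext"].append(nex)
    cols["red"].append(red)
    cols["truth_class"].extend([klass] * n)
    cols["truth_length_um"].append(np.asarray(L, float))
    cols["truth_width_um"].append(np.asarray(W, float))


def simulate_manual_measurements(
    dataset: pd.DataFrame,
    pixels_per_micron: float = 3.2937,
    n_wells_per_hour: int = 30,
    n_per_well: int = 5,
    px_noise_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate manual ImageJ measurements (pixels) of animals from imaged wells.

    Samples up to ``n_per_well`` animals from up to ``n_wells_per_hour`` wells
    per hour of the truth table and converts their true sizes to pixels with
    additive measurement noise.  Columns: hour, well, length_px, width_px.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 9101)))
    animals = dataset[dataset["truth_class"] == "animal"]
    rows = []
    for hour, hgrp in animals.groupby("hour", sort=True):
        wells = sorted(hgrp["well"].unique())[:n_wells_per_hour]
        for well in wells:
            wgrp = hgrp[hgrp["well"] == well]
            take = min(n_per_well, len(wgrp))
            idx = rng.choice(len(wgrp), size=take, replace=False)
            sub = wgrp.iloc[np.sort(idx)]
            lpx = sub["truth_length_um"].to_numpy() * pixels_per_micron
            wpx = sub["truth_width_um"].to_numpy() * pixels_per_micron
            lpx = np.clip(lpx + rng.normal(0, px_noise_sd, take), 1.0, None)
            wpx = np.clip(wpx + rng.normal(0, px_noise_sd, take), 0.5, None)
            for l, w in zip(lpx, wpx):
                rows.append({"hour": hour, "well": well, "length_px": l, "width_px": w})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_dataset(df: pd.DataFrame, outdir: str | Path) -> tuple[Path, Path]:
    """Write ``raw.csv`` (instrument columns only) and ``truth.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw_path = outdir / "raw.csv"
    truth_path = outdir / "truth.csv"
    df[RAW_COLUMNS].to_csv(raw_path, index=False)
    df[TRUTH_COLUMNS].to_csv(truth_path, index=False)
    return raw_path, truth_path


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a raw or truth CSV written by :func:`write_dataset`."""
    return pd.read_csv(path)
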