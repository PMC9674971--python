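import numpy as np
import pytest

import wormstretcher as ws


@pytest.fixture(scope="session")
def identity_calibration():
    """Calibration that undoes the default instrument gain exactly."""
    return ws.CalibrationModel(
        tof_to_um_slope=1.0 / ws.PIXELS_PER_MICRON,
        normext_to_um_slope=1.0 / ws.PIXELS_PER_MICRON,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Four-strain assay at reduced sampling, with contaminants."""
    cfg = ws.default_config(
        n_wells_per_hour=8, n_animals_per_well=25, contaminant_rate=0.15, seed=11
    )
    return cfg, ws.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_summaries(identity_calibration):
    """Calibrated well summaries from a contaminant-free default assay."""
    cfg = ws.default_config(
        n_wells_per_hour=10, n_animals_per_well=25, contaminant_rate=0.0, seed=7
    )
    df = ws.simulate_dataset(cfg)
    summ = ws.summarize_wells(df)
    return cfg, ws.convert_units(summ, identity_calibration)


def wide_stage_profile(gain=1.5, c=0.2, onset=0.7):
    """Single-strain profile with a steep aspect slope, used for planted
    slope-ratio recovery; stage 2 active growth spans hours 17-22.5."""
    return ws.StrainProfile(
        strain_id="wide",
        stage_boundaries=(14.0, 25.0, 33.0),
        growth_rates=(10.0, 22.0, 30.0, 40.0),
        aspect_slopes=(c, c, c, c),
        nonlinear_onset_fraction=onset,
        nonlinear_slope_gain=gain,
        width_at_start=14.0,
    )
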