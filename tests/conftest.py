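import numpy as np
import pytest

from cvreserve.hemodynamics import build_beat_table
from cvreserve.synthetic import CohortConfig, simulate_subject


def small_config(**overrides) -> CohortConfig:
    """A desk-scale protocol: 2-min baseline, 4-5-min LBNP."""
    kw = dict(baseline_duration_s=120.0, lbnp_duration_range_s=(240.0, 300.0))
    kw.update(overrides)
    return CohortConfig(**kw)


def zero_noise(**overrides) -> CohortConfig:
    kw = dict(sap_noise_mmhg=0.0, dap_noise_mmhg=0.0, ibi_noise_s=0.0,
              fv_noise_cms=0.0, etco2_noise_mmhg=0.0, ti_noise_ohm=0.0,
              nirs_noise_umol=0.0)
    kw.update(overrides)
    return small_config(**kw)


def flat_config(**overrides) -> CohortConfig:
    """Zero noise and zero LBNP effect sizes: every beat identical."""
    kw = dict(pp_decline_frac=0.0, mcav_decline_frac=0.0,
              hr_rise_bpm_resistance=0.0, hr_rise_bpm_hrdom=0.0,
              dap_shift_mmhg_resistance=0.0, dap_shift_mmhg_hrdom=0.0,
              etco2_drop_mmhg=0.0, ti_rise_ohm=0.0, o2hb_drop_umol=0.0,
              hhb_rise_umol=0.0, collapse_fraction=0.0)
    kw.update(overrides)
    return zero_noise(**kw)


@pytest.fixture(scope="session")
def default_subject():
    return simulate_subject(small_config(), 42, subject_id="S42")


@pytest.fixture(scope="session")
def noise_free_subject():
    return simulate_subject(zero_noise(), 7, subject_id="S07")


@pytest.fixture(scope="session")
def full_beat_table(default_subject):
    """Beat table with every feature block, including TFA; needs a recording
    long enough for 3-min transfer-function windows."""
    cfg = small_config(baseline_duration_s=200.0,
                       lbnp_duration_range_s=(300.0, 300.0))
    rec = simulate_subject(cfg, 11, subject_id="S11")
    return build_beat_table(rec, sv_baseline_ml=cfg.sv_baseline_ml), rec.marks


@pytest.fixture(scope="session")
def strong_cohort_features():
    """12-subject strong-effect, low-noise cohort with volumetric (model 8)
    features — the parameter-recovery setting."""
    from cvreserve.pipeline import cohort_feature_matrices
    from cvreserve.synthetic import simulate_cohort

    cfg = CohortConfig(n_subjects=12, seed=1, baseline_duration_s=150.0,
                       lbnp_duration_range_s=(240.0, 360.0),
                       sap_noise_mmhg=0.5, dap_noise_mmhg=0.3,
                       ibi_noise_s=0.005, fv_noise_cms=0.5)
    cohort = simulate_cohort(cfg)
    return cohort_feature_matrices(cohort, 8, downsample_factor=10)
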