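import numpy as np
import pytest

from fdkin import ChipParams, NoiseModel, RateConstantSet
from fdkin.synth import ExperimentDesign, spr_design_for


@pytest.fixture
def full_rates() -> RateConstantSet:
    """A complete, cycle-consistent rate set usable by every topology."""
    return RateConstantSet.with_closed_cycle(
        k_on_TH=1e6, k_off_TH=9e-5,
        k_on_HE=1e7, k_off_HE=5e-6,
        k_on_THE_viaE=1e6, k_off_THE_toE=1e-3,
        k_on_THE_viaT=1e6,
        k_switch=1e-3, k_unswitch=1e-2, k_off_THn=2e-5,
        solve_for="k_off_THE_toT",
    )


@pytest.fixture
def chip_truth() -> ChipParams:
    """Canonical ground truth for SPR round-trips (fold acceleration 2400)."""
    return ChipParams(
        k_off_T_H=1e-5, k_off_T_HE=2.4e-2, k_on_TH_E=1e6, k_off_TH_E=1e-3,
        k_off_T_Hn=2e-5, f_responsive=0.95, a_TH=1.0, a_THE=1.15, a_THn=1.0,
    )


@pytest.fixture
def coarse_design(chip_truth) -> ExperimentDesign:
    """Default SPR design thinned to 0.1 Hz sampling to keep tests fast."""
    design = spr_design_for(chip_truth)
    design.sampling_interval_s = 10.0
    return design


@pytest.fixture
def noise_half_pct() -> NoiseModel:
    return NoiseModel(sigma_frac=0.005, seed=20240917)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
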