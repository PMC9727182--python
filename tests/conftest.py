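import numpy as np
import pytest

from pkmarker.io import PKProfile
from pkmarker.simulate import (
    DispositionModel,
    ErrorModel,
    PK_SAMPLING_TIMES,
    simulate_iv_profile,
)


@pytest.fixture
def mono_model():
    """1-compartment model with k = 0.693/h (t1/2 = 1 h), V = 0.1 L/kg."""
    return DispositionModel(clearance=0.0693, volumes=(0.1,))


@pytest.fixture
def clean_profile(mono_model):
    """Noise-free, uncensored IV-bolus profile on the study schedule."""
    return simulate_iv_profile(
        mono_model, dose=1000.0, times=PK_SAMPLING_TIMES,
        error=ErrorModel(proportional_cv=0.0, lod=0.0),
    )


def make_profile(times, concs, blq=None, subject="S1", analyte="A",
                 dose_group="high", volume_dose=4.0):
    return PKProfile(
        subject_id=subject,
        dose_group=dose_group,
        volume_dose=volume_dose,
        analyte=analyte,
        times=np.asarray(times, float),
        concentrations=np.asarray(concs, float),
        blq=None if blq is None else np.asarray(blq, bool),
    )
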