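import copy
import dataclasses
import warnings

import pytest

from cim import ModelConfig, load_parameters
from cim.parameters import AgeBandRates, AgeBandTable, ParameterBundle


@pytest.fixture(scope="session")
def params():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # packaged T2D column dips at 65-69
        return load_parameters()


@pytest.fixture()
def config():
    return ModelConfig()


def make_zero_risk_bundle(base: ParameterBundle) -> ParameterBundle:
    """Bundle with all incidence, mortality and case fatality zeroed,
    every utility 1 and no wellbeing gain: a cohort that stays Well."""
    out = copy.deepcopy(base)
    bands = [dataclasses.replace(
        b, inc_t2d=0.0, inc_cancer=0.0, inc_stroke=0.0, inc_chd=0.0,
        mort_cvd=0.0, mort_allcause=0.0, cfr_chd=0.0, cfr_stroke=0.0)
        for b in out.age_rates]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out.age_rates = AgeBandTable(bands)
    for name in ("util_cancer", "util_chd1", "util_chd1plus", "util_stroke1",
                 "util_stroke1plus", "util_t2d"):
        setattr(out.costs, name, 1.0)
    out.costs.wellbeing_gain_active = 0.0
    return out


@pytest.fixture()
def zero_risk_params(params):
    return make_zero_risk_bundle(params)
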