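import numpy as np
import pytest

import voripbpk as v

#: solver settings used throughout the suite: tight enough that AUC changes
#: by far less than any assertion tolerance, fast enough for population runs
FAST = v.ModelOptions(rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="session")
def no_var():
    return v.VariabilitySpec.none()


@pytest.fixture(scope="session")
def adult_nm(no_var):
    return v.generate_individual(30, "male", "NM", no_var, seed=1)


@pytest.fixture(scope="session")
def adult_pm(no_var):
    return v.generate_individual(30, "male", "PM", no_var, seed=1)


@pytest.fixture(scope="session")
def nm_single_iv_result(adult_nm):
    """Single 200 mg i.v. (60-min infusion) in a reference NM adult."""
    model = v.build_model(adult_nm, options=FAST)
    return model.simulate(v.DosingRegimen.single_iv(200, 60), t_end=48,
                          output_dt=0.25)


def auc(result, t0=None, t1=None):
    return v.auc_trapezoid(result.t, result.conc_mg_l, t0, t1)
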