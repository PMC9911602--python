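import numpy as np
import pytest
from hypothesis import settings

import phytossd as p

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def curculionidae_records():
    return p.load_curculionidae()


@pytest.fixture(scope="session")
def tephritidae_records():
    return p.load_tephritidae()


@pytest.fixture(scope="session")
def tephritidae_doses(tephritidae_records):
    return np.array([r.dose_gy for r in tephritidae_records])


@pytest.fixture(scope="session")
def tephritidae_gamma_fit(tephritidae_doses):
    return p.fit_mle("gamma", tephritidae_doses)


@pytest.fixture(scope="session")
def curculionidae_pipeline_report(curculionidae_records):
    """Crude Curculionidae pipeline without bootstrap CIs (fast, reused)."""
    config = p.RunConfig(
        taxon="Curculionidae",
        candidate_doses_gy=(150.0, 175.0),
        compute_ci=False,
    )
    # pipeline-internal warnings are captured into the report
    return p.run_pipeline(config, records=curculionidae_records)
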