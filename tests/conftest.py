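import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")

from beadlysis.outcomes import validate_records


def build_records(
    *,
    bead=4.55e9,
    plasmin=1.0,
    trial_id="t1",
    n_tense=0,
    n_elongated_only=0,
    n_bundled_only=0,
    n_bundled_elongated=0,
    n_ridge_recoil=0,
    n_ridge_none=0,
    n_length=0,
    frame=3,
):
    """Record frame with exact outcome counts for one condition/trial."""
    rows = []

    def add(cleaved, cframe=None, site=None, further=None, bundled=False, elongated=False):
        rows.append(
            dict(
                trial_id=trial_id,
                bead_concentration=bead,
                plasmin_concentration=plasmin,
                cleaved=cleaved,
                cleavage_frame=cframe,
                cleavage_site=site,
                further_digestion=further,
                bundled=bundled,
                elongated=elongated,
            )
        )

    for _ in range(n_tense):
        add(False)
    for _ in range(n_elongated_only):
        add(False, elongated=True)
    for _ in range(n_bundled_only):
        add(False, bundled=True)
    for _ in range(n_bundled_elongated):
        add(False, bundled=True, elongated=True)
    for _ in range(n_ridge_recoil):
        add(True, frame, "ridge", "recoil_collapse")
    for _ in range(n_ridge_none):
        add(True, frame, "ridge", "none")
    for _ in range(n_length):
        add(True, frame, "length")
    return validate_records(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20230407)
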