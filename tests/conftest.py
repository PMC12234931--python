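"""Shared fixtures: presets, phantoms and the default-cohort experiment.

Heavy objects (the reference shell cohort, the default-cohort sweep)
are session-scoped so the acceptance tests and unit tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import svdose as sv
from svdose.phantoms import reference_shell_cohort


@pytest.fixture(scope="session")
def ascc():
    return sv.protocol_preset("ASCC")


@pytest.fixture(scope="session")
def ac():
    return sv.protocol_preset("AC")


@pytest.fixture(scope="session")
def kidney_100():
    """A mid-sized uniform kidney phantom (100 mL, 18 mm rim)."""
    return sv.make_kidney_phantom(100.0, 18.0, kidney_id="fix100")


@pytest.fixture(scope="session")
def shell_cohort():
    """The fixed 36-kidney reference shell cohort (uniform, no background)."""
    return reference_shell_cohort()


@pytest.fixture(scope="session")
def shell_cohort_rc(shell_cohort, ascc, ac):
    """Noiseless RCs of the reference cohort under both presets."""
    return {
        "ASCC": [sv.simulate_rc(p.wkp_mask, ascc, p.kidney_id) for p in shell_cohort],
        "AC": [sv.simulate_rc(p.wkp_mask, ac, p.kidney_id) for p in shell_cohort],
    }


@pytest.fixture(scope="session")
def default_sweep(ascc):
    """Default synthetic cohort and its sigma in {0, 4} mm sweep (seeded)."""
    cohort = sv.make_cohort(sv.CohortSpec())  # documented defaults, seed 0
    doses, summary = sv.run_sweep(cohort, ascc, sigmas_mm=(0.0, 4.0), seed=0)
    return {"cohort": cohort, "doses": doses, "summary": summary}
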