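from datetime import date, timedelta

import pytest
from hypothesis import HealthCheck, settings

from capscore import (
    CognitiveScore,
    ImagingRatings,
    NPIQProfile,
    Subject,
    paper_fixture,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

T0 = date(2022, 1, 1)


def make_subject(
    npi_severities=None,
    rapid=False,
    fazekas=0,
    scheltens=None,
    reference="positive",
    n_visits=2,
    **overrides,
):
    """Minimal scoreable subject with the given CAPS component inputs."""
    drop = 4 if rapid else 1
    visits = [CognitiveScore("MMSE", 26, T0)]
    if n_visits >= 2:
        visits.append(CognitiveScore("MMSE", 26 - drop, T0 + timedelta(days=365)))
    fields = dict(
        id="S1",
        age=70.0,
        sex="female",
        npiq=NPIQProfile.from_partial(npi_severities or {}),
        cognitive_scores=tuple(visits),
        imaging=ImagingRatings(fazekas=fazekas, scheltens_mtla=scheltens),
        amyloid_status_reference=reference,
        reference_modality="CSF",
    )
    fields.update(overrides)
    return Subject(**fields)


@pytest.fixture(scope="session")
def fixture_cohort():
    return paper_fixture()
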