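import numpy as np
import pytest

from matchqual.cohort import CohortTable, Participant
from matchqual.varspec import EDUCATION_LEVELS, VariableSpec


def make_participant(subject_id, group, link=None, **kw):
    """A participant with sensible defaults, overridable per field."""
    defaults = dict(
        sex="male",
        race="white",
        age=64.0,
        education="post-HS",
        employment="retired",
        days_smoked_30=0,
        age_first_cig=None,
        age_last_cig=None,
        is_current_smoker=False,
        alc_freq_month=1.5,
        alc_typical=0.7,
        alc_six_freq=0.5,
        cancer_history=(group == "survivor"),
    )
    defaults.update(kw)
    return Participant(
        subject_id=subject_id,
        group=group,
        survivor_link=link or (subject_id if group == "survivor" else ""),
        **defaults,
    )


def paired_cohort(survivor_vals, peer_vals, listed_vals, variable="age"):
    """A fully explicit cohort with one varying variable; None skips a subject."""
    participants = []
    for i, sv in enumerate(survivor_vals):
        sid = f"S{i:03d}"
        participants.append(make_participant(sid, "survivor", **{variable: sv}))
        if peer_vals[i] is not None:
            participants.append(
                make_participant(f"P{i:03d}", "peer", sid, **{variable: peer_vals[i]})
            )
        if listed_vals[i] is not None:
            participants.append(
                make_participant(f"L{i:03d}", "listed", sid, **{variable: listed_vals[i]})
            )
    return CohortTable.from_participants(participants)


@pytest.fixture
def age_spec():
    return VariableSpec("age", "continuous")


@pytest.fixture
def education_spec():
    return VariableSpec("education", "ordinal", EDUCATION_LEVELS)


@pytest.fixture
def toy_pairs():
    """The cautionary fixture: equal margins, every pair differing by 9."""
    survivors = [1.0, 10.0, 1.0, 10.0]
    comparisons = [10.0, 1.0, 10.0, 1.0]
    return survivors, comparisons


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
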