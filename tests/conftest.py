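import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracle.py helper

settings.register_profile("ci", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("ci")

from recallseq import SequencePolicy, parse_letter_trial  # noqa: E402


@pytest.fixture
def first_policy():
    return SequencePolicy.first()


@pytest.fixture
def any_policy():
    return SequencePolicy.any()


#: The four worked 8-item recalls with their (start, end) lengths; the
#: third recall circulates in two variants that annotate identically.
WORKED_EXAMPLES = [
    ("ABCDEFGH", "FGHCABG", 2, 3),
    ("ABCDEFGH", "HGABCE", 3, 1),
    ("ABCDEFGH", "ABCFEGH", 3, 2),
    ("ABCDEFGH", "ABCEGH", 3, 2),
    ("ABCDEFGH", "GFAC", 1, 0),
]


@pytest.fixture
def worked_trials():
    return [
        (parse_letter_trial(pres, rec, trial_id=f"w{i}"), s, e)
        for i, (pres, rec, s, e) in enumerate(WORKED_EXAMPLES)
    ]
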