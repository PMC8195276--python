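import pytest

from fairgame.game import CHICKEN_DEFAULT, Action, JointOutcome
from fairgame.model import preset_params


@pytest.fixture
def matrix():
    """The default chicken-game reward scale."""
    return CHICKEN_DEFAULT


@pytest.fixture
def exchange_params():
    return preset_params("mutual_exchange")


@pytest.fixture
def rush_params():
    return preset_params("rush")


def outcome(code: str) -> JointOutcome:
    """Build a joint outcome from its two-letter code (self first)."""
    letter = {"A": Action.AVOID, "R": Action.RUSH}
    return JointOutcome(letter[code[0]], letter[code[1]])
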