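"""Model-chain tests: kindness, fairness update, reciprocity, utility, sigmoid."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairgame.game import Action, CHICKEN_DEFAULT, PayoffMatrix
from fairgame.model import (
    DegenerateMatrixError,
    FairnessState,
    ModelParams,
    avoid_probability,
    expected_payoffs,
    kindness_per_action,
    preset_params,
    reciprocity,
    signed_power,
    update_fairness,
    utility,
)

EXCHANGE = preset_params("mutual_exchange")


class TestKindness:
    def test_default_matrix_values(self):
        assert kindness_per_action(Action.AVOID, CHICKEN_DEFAULT) == pytest.approx(0.6)
        assert kindness_per_action(Action.RUSH, CHICKEN_DEFAULT) == pytest.approx(-0.6)

    def test_opponent_role_matches_on_symmetric_matrix(self):
        for a in Action:
            assert kindness_per_action(a, CHICKEN_DEFAULT, "opponent_to_self") == (
                kindness_per_action(a, CHICKEN_DEFAULT, "self_to_opponent")
            )

    @settings(max_examples=50, deadline=None)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        shift=st.floats(min_value=-1e4, max_value=1e4),
        action=st.sampled_from(list(Action)),
    )
    def test_invariance_to_rescaling_and_recipient_shift(self, scale, shift, action):
        """Kindness is normalized: positive rescaling of the whole matrix and
        constant shifts of the recipient's payoffs change nothing."""
        base = kindness_per_action(action, CHICKEN_DEFAULT)
        scaled = PayoffMatrix(
            **{
                k: (v[0] * scale, v[1] * scale)
                for k, v in CHICKEN_DEFAULT.to_dict().items()
            }
        )
        shifted = PayoffMatrix(
            **{k: (v[0], v[1] + shift) for k, v in CHICKEN_DEFAULT.to_dict().items()}
        )
        assert kindness_per_action(action, scaled) == pytest.approx(base, abs=1e-9)
        assert kindness_per_action(action, shifted) == pytest.approx(base, abs=1e-9)

    def test_antisymmetric_on_zero_mean_symmetric_matrix(self):
        assert kindness_per_action(Action.AVOID, CHICKEN_DEFAULT) == pytest.approx(
            -kindness_per_action(Action.RUSH, CHICKEN_DEFAULT)
        )

    def test_degenerate_matrix_rejected(self):
        flat = PayoffMatrix(aa=(0, 5), ar=(1, 5), ra=(2, 5), rr=(3, 5))
        with pytest.raises(DegenerateMatrixError):
            kindness_per_action(Action.AVOID, flat)


class TestFairnessUpdate:
    def test_one_step_from_zero_ledger(self):
        """Self avoids, opponent rushes, zero ledger: F_self 0.5, F_opp -0.431."""
        state = update_fairness(
            FairnessState(), Action.AVOID, Action.RUSH, EXCHANGE, CHICKEN_DEFAULT
        )
        assert state.f_self == pytest.approx(0.5)
        assert state.f_opp == pytest.approx(-0.431, abs=5e-4)

    def test_identity_update_when_kindness_zero(self):
        """Symmetric-constant recipient columns give zero kindness; with full
        retention and no benevolence the ledger is a fixed point."""
        m = PayoffMatrix(aa=(0, 1), ar=(2, -1), ra=(2, 1), rr=(0, -1))
        assert kindness_per_action(Action.AVOID, m) == pytest.approx(0.0)
        params = ModelParams(alpha=1.0, beta=0.0, gamma=1.0, theta=0.5)
        state = FairnessState(0.7, 0.7)
        out = update_fairness(state, Action.AVOID, Action.RUSH, params, m)
        assert out.f_self == pytest.approx(0.7)
        assert out.f_opp == pytest.approx(0.7)

    def test_boundedness_under_extreme_sequences(self):
        """With gamma < 1 fairness stays inside the geometric-series bounds
        |F_self| <= eta*K/(1-gamma), |F_opp| <= (eta*K+|beta|)/(1-gamma)
        no matter how adversarial the action history is."""
        k_max = 0.6
        for params in (preset_params("mutual_exchange"), preset_params("rush")):
            bound_self = params.eta * k_max / (1 - params.gamma)
            bound_opp = (params.eta * k_max + abs(params.beta)) / (1 - params.gamma)
            for self_a, opp_a in [
                (Action.RUSH, Action.RUSH),
                (Action.AVOID, Action.AVOID),
                (Action.AVOID, Action.RUSH),
            ]:
                state = FairnessState()
                for _ in range(10_000):
                    state = update_fairness(state, self_a, opp_a, params, CHICKEN_DEFAULT)
                assert abs(state.f_self) <= bound_self + 1e-9
                assert abs(state.f_opp) <= bound_opp + 1e-9


class TestReciprocity:
    def test_worked_ledger(self):
        assert reciprocity(FairnessState(0.5, -0.4311), 0.5) == pytest.approx(-0.9311)

    def test_zero_state(self):
        assert reciprocity(FairnessState(), 0.3) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        f_self=st.floats(-10, 10),
        f_opp=st.floats(-10, 10),
    )
    def test_unbiased_weight_is_plain_difference(self, f_self, f_opp):
        state = FairnessState(f_self, f_opp)
        assert reciprocity(state, 0.5) == pytest.approx(f_opp - f_self)

    @settings(max_examples=50, deadline=None)
    @given(f_self=st.floats(-10, 10), f_opp=st.floats(-10, 10))
    def test_mirror_ledgers_give_opposite_reciprocity(self, f_self, f_opp):
        """At theta=0.5 two players holding mirror-image ledgers see exactly
        opposite reciprocities."""
        mine = reciprocity(FairnessState(f_self, f_opp), 0.5)
        theirs = reciprocity(FairnessState(f_opp, f_self), 0.5)
        assert mine == pytest.approx(-theirs)

    def test_theta_bounds(self):
        with pytest.raises(ValueError):
            reciprocity(FairnessState(), 1.5)


class TestUtility:
    @pytest.mark.parametrize(
        "action,expected",
        [(Action.AVOID, (-150.0, 150.0)), (Action.RUSH, (-350.0, -650.0))],
    )
    def test_expected_payoffs_default(self, action, expected):
        assert expected_payoffs(action, CHICKEN_DEFAULT) == pytest.approx(expected)

    def test_expected_payoffs_identical_columns(self):
        m = PayoffMatrix(aa=(5, 2), ar=(5, 2), ra=(-1, 3), rr=(-1, 3))
        assert expected_payoffs(Action.AVOID, m) == (5.0, 2.0)

    def test_linear_self_interested_limit(self):
        """alpha=1, r=0 collapses utility to the self's expected wealth."""
        params = ModelParams(alpha=1.0, beta=0.0, gamma=0.0, theta=0.5)
        u = utility(Action.AVOID, 1000.0, 123.0, 0.0, params, CHICKEN_DEFAULT)
        assert u == pytest.approx(1000.0 - 150.0)

    def test_worked_regime_direct_arithmetic(self):
        """Independent arithmetic oracle for the uniform-expectation convention
        at cum=(1000, 1000), r=0.9311, alpha=0.986."""
        a, r = 0.986, 0.9311
        expected = ((1000 - 150) ** a + r * (1000 + 150) ** a) / a
        got = utility(Action.AVOID, 1000.0, 1000.0, r, EXCHANGE, CHICKEN_DEFAULT)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(1768.3, abs=0.1)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(0, 1e6), alpha=st.floats(0.01, 1.0))
    def test_signed_power_is_odd(self, x, alpha):
        assert signed_power(-x, alpha) == pytest.approx(-signed_power(x, alpha))


class TestAvoidProbability:
    def test_worked_utilities(self):
        assert avoid_probability(1781.7, 1778.9) == pytest.approx(0.9427, abs=5e-5)

    def test_equal_utilities(self):
        assert avoid_probability(3.0, 3.0) == 0.5

    def test_monotone_in_avoid_utility(self):
        ps = [avoid_probability(u, 0.0) for u in (-2.0, -1.0, 0.0, 1.0, 2.0)]
        assert ps == sorted(ps)

    @settings(max_examples=100, deadline=None)
    @given(a=st.floats(-1e4, 1e4), b=st.floats(-1e4, 1e4))
    def test_complement(self, a, b):
        assert avoid_probability(a, b) + avoid_probability(b, a) == pytest.approx(1.0)

    def test_saturation_stays_inside_open_interval(self):
        assert 0.0 < avoid_probability(-1e9, 1e9)
        assert avoid_probability(1e9, -1e9) < 1.0


class TestParams:
    def test_presets(self):
        ex = preset_params("mutual_exchange")
        assert (ex.alpha, ex.beta, ex.gamma, ex.theta) == (0.986, 0.069, 0.110, 0.710)
        ru = preset_params("rush")
        assert (ru.alpha, ru.beta, ru.gamma, ru.theta) == (0.863, -0.739, 0.673, 0.696)
        assert ex.eta == ru.eta == pytest.approx(5 / 6)

    def test_unknown_preset_names_alternatives(self):
        with pytest.raises(KeyError, match="mutual_exchange"):
            preset_params("typo")

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha=0.0, beta=0, gamma=0.5, theta=0.5),
            dict(alpha=1.5, beta=0, gamma=0.5, theta=0.5),
            dict(alpha=0.5, beta=0, gamma=-0.1, theta=0.5),
            dict(alpha=0.5, beta=0, gamma=1.1, theta=0.5),
            dict(alpha=0.5, beta=0, gamma=0.5, theta=2.0),
            dict(alpha=0.5, beta=0, gamma=0.5, theta=0.5, eta=0.0),
            dict(alpha=0.5, beta=math.inf, gamma=0.5, theta=0.5),
        ],
    )
    def test_bounds_enforced(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_dict_round_trip(self):
        assert ModelParams.from_dict(EXCHANGE.to_dict()) == EXCHANGE
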