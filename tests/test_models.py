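"""Learning rule, decision rule, state representations and their limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorchoice.inference import encode_trials, p_left_trials
from odorchoice.models import (
    MODELS,
    SIX_STATES,
    DecisionContext,
    ModelParams,
    ModelState,
    StateValueTable,
    choice_probability,
    decision_variables,
    hybrid_learning_update,
    init_table,
    simulate_agent,
    state_for,
    trial_step,
    update_values,
)
from odorchoice.task import SessionConfig, build_session_schedule


def _p(**kw):
    base = dict(eta=0.2, gamma=0.9, beta=2.0)
    base.update(kw)
    return ModelParams(**base)


class TestStateFor:
    @pytest.mark.parametrize(
        "odor,action,expected",
        [
            ("free", "left", "Left"),
            ("free", "right", "Right"),
            ("left_forced", "left", "Left"),
            ("right_forced", "right", "Right"),
            ("left_forced", "right", "Right-NoRwd"),
            ("right_forced", "left", "Left-NoRwd"),
        ],
    )
    def test_four_state_map(self, odor, action, expected):
        assert state_for(odor, action, "four_state") == expected

    def test_six_state_bijective(self):
        labels = {
            state_for(o, a, "six_state")
            for o in ("left_forced", "right_forced", "free")
            for a in ("left", "right")
        }
        assert labels == set(SIX_STATES)

    def test_hybrid_value_returns_both(self):
        assert state_for("free", "left", "hybrid_value") == ("Left", "free:left")


class TestUpdateValues:
    def test_hand_worked_delay_discounted_update(self):
        """V=0.5, eta=0.2, gamma=0.81, d=0.5, r=2: target 0.9*2=1.8,
        prediction error 1.3, V' = 0.5 + 0.2*1.3 = 0.76."""
        table = StateValueTable(
            "four_state",
            {"Left": 0.5, "Right": 0.1, "Left-NoRwd": 0.0, "Right-NoRwd": 0.0},
        )
        out = update_values(table, "Left", 2, 0.5, _p(eta=0.2, gamma=0.81))
        assert out.values["Left"] == pytest.approx(0.76, abs=1e-12)
        # all other states untouched
        assert out.values["Right"] == 0.1
        assert out.values["Left-NoRwd"] == 0.0

    def test_zero_learning_rate_and_zero_prediction_error(self):
        table = StateValueTable(
            "four_state",
            {"Left": 0.5, "Right": 0.0, "Left-NoRwd": 0.0, "Right-NoRwd": 0.0},
        )
        assert update_values(table, "Left", 1, 1.0, _p(eta=0.0)).values == table.values
        p = _p(eta=0.3, gamma=0.5)
        table2 = StateValueTable(
            "four_state",
            {"Left": 0.5, "Right": 0.0, "Left-NoRwd": 0.0, "Right-NoRwd": 0.0},
        )
        assert update_values(table2, "Left", 1, 1.0, p).values["Left"] == 0.5


class TestHybridLearningUpdate:
    def test_hand_worked_generalization(self):
        """Valid left-forced trial, eta=0.3, eta_g=0.03, gamma=1, r=1:
        experienced state 0.2 -> 0.44, paired free state 0.8 -> 0.806."""
        values = {s: 0.0 for s in SIX_STATES}
        values["left_forced:left"] = 0.2
        values["free:left"] = 0.8
        table = StateValueTable("six_state", values)
        p = _p(eta=0.3, gamma=1.0, eta_g=0.03)
        out = hybrid_learning_update(table, "left_forced", "left", 1, 0.5, p)
        assert out.values["left_forced:left"] == pytest.approx(0.44, abs=1e-12)
        assert out.values["free:left"] == pytest.approx(0.806, abs=1e-12)

    def test_zero_generalization_matches_plain_update(self):
        table = init_table("six_state")
        p = _p(eta=0.3, eta_g=0.0)
        a = hybrid_learning_update(table, "free", "right", 1, 0.5, p)
        b = update_values(table, "free:right", 1, 0.5, p)
        assert a.values == b.values

    def test_invalid_trial_updates_own_state_only(self):
        values = {s: 0.5 for s in SIX_STATES}
        table = StateValueTable("six_state", values)
        p = _p(eta=0.2, eta_g=0.1)
        out = hybrid_learning_update(
            table, "left_forced", "right", 0, 0.5, p, valid=False
        )
        assert out.values["left_forced:right"] == pytest.approx(0.4)
        assert all(
            out.values[s] == 0.5 for s in SIX_STATES if s != "left_forced:right"
        )


class TestDecisionRule:
    def test_hand_worked_decision_variables(self):
        """V_L=0.6, V_R=0.3, b=0.1, p=0.2, previous=left -> DV=(0.8, 0.4)."""
        values = {s: 0.0 for s in SIX_STATES}
        values["free:left"], values["free:right"] = 0.6, 0.3
        table = StateValueTable("six_state", values)
        params = _p(bias_b=0.1, persev_p=0.2)
        dv = decision_variables(
            table, DecisionContext("free", "left"), params, "six_state"
        )
        assert dv == pytest.approx((0.8, 0.4), abs=1e-12)
        # no bias terms -> raw values; no previous choice -> no perseveration
        plain = decision_variables(
            table, DecisionContext("free", None), _p(), "six_state"
        )
        assert plain == pytest.approx((0.6, 0.3), abs=1e-12)

    def test_hybrid_value_weighted_sum(self):
        t4 = StateValueTable(
            "four_state",
            {"Left": 1.0, "Right": 0.0, "Left-NoRwd": 0.0, "Right-NoRwd": 0.0},
        )
        values = {s: 0.0 for s in SIX_STATES}
        values["free:left"] = 0.5
        t6 = StateValueTable("six_state", values)
        dv = decision_variables(
            (t4, t6), DecisionContext("free", None), _p(w4=0.3), "hybrid_value"
        )
        assert dv[0] == pytest.approx(0.3 * 1.0 + 0.7 * 0.5, abs=1e-12)

    def test_choice_probability_hand_worked(self):
        """dDV=1, beta=2, lapse=0.1 -> 0.9*logistic(2) + 0.05 = 0.84272..."""
        p = choice_probability(1.0, 0.0, _p(beta=2.0, lapse=0.1))
        assert p == pytest.approx(0.9 / (1 + np.exp(-2)) + 0.05, abs=1e-12)

    @pytest.mark.parametrize("lapse", [0.0, 0.3, 1.0])
    def test_choice_probability_symmetry_and_lapse(self, lapse):
        assert choice_probability(0.4, 0.4, _p(beta=5.0, lapse=lapse)) == 0.5
        if lapse == 1.0:
            assert choice_probability(10.0, -10.0, _p(beta=5.0, lapse=1.0)) == 0.5

    @given(
        dv=st.floats(-2, 2),
        dv2=st.floats(-2, 2),
        beta=st.floats(0.1, 5),
        lapse=st.floats(0, 0.9),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_choice_probability_bounds_and_monotonicity(self, dv, dv2, beta, lapse):
        p = _p(beta=beta, lapse=lapse)
        pr = choice_probability(dv, dv2, p)
        assert lapse / 2 - 1e-12 <= pr <= 1 - lapse / 2 + 1e-12
        assert pr + choice_probability(dv2, dv, p) == pytest.approx(1.0)
        assert choice_probability(dv + 0.5, dv2, p) > pr  # strict when lapse<1


def _replay(model, params, df):
    """Per-trial P(left) through the pure-Python trial_step path."""
    from odorchoice.task import frame_to_records

    state = ModelState(model, params)
    ps, prev_sess = [], None
    for rec in frame_to_records(df):
        key = (rec.animal_id, rec.session_id)
        if key != prev_sess:
            state.reset_session()
            prev_sess = key
        ps.append(trial_step(state, rec))
    return np.array(ps)


class TestTrialStepAndLimits:
    def test_first_trial_indifference(self, schedule):
        for model in MODELS:
            params = _p(w4=0.5, eta_g=0.1)
            assert ModelState(model, params).p_left("free") == 0.5
            assert ModelState(model, params).p_left("left_forced") == 0.5

    def test_limit_equivalences_per_trial(self, mixed_log):
        """hybrid_value at w4 in {0,1} and hybrid_learning at eta_g in
        {0, eta} reproduce the pure models' probabilities exactly."""
        base = dict(eta=0.3, gamma=0.85, beta=2.5, bias_b=0.1, persev_p=0.15, lapse=0.05)
        pairs = [
            (("hybrid_value", ModelParams(w4=0.0, **base)), ("six_state", ModelParams(**base))),
            (("hybrid_value", ModelParams(w4=1.0, **base)), ("four_state", ModelParams(**base))),
            (("hybrid_learning", ModelParams(eta_g=0.0, **base)), ("six_state", ModelParams(**base))),
            (("hybrid_learning", ModelParams(eta_g=base["eta"], **base)), ("four_state", ModelParams(**base))),
        ]
        for (m1, p1), (m2, p2) in pairs:
            a = _replay(m1, p1, mixed_log)
            b = _replay(m2, p2, mixed_log)
            np.testing.assert_allclose(a, b, atol=1e-12, rtol=0)

    def test_kernel_matches_python_path(self, mixed_log):
        enc = encode_trials(mixed_log)
        for model, params in [
            ("four_state", _p()),
            ("six_state", _p(bias_b=-0.2, persev_p=0.3)),
            ("hybrid_value", _p(w4=0.4, lapse=0.1)),
            ("hybrid_learning", _p(eta_g=0.07, persev_p=-0.2)),
        ]:
            np.testing.assert_allclose(
                p_left_trials(model, params, enc),
                _replay(model, params, mixed_log),
                atol=1e-12,
                rtol=0,
            )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_values_stay_bounded(self, seed):
        """With r <= 2 and eta, gamma in [0,1], values stay in [0, 2]."""
        rng = np.random.default_rng(seed)
        params = _p(
            eta=float(rng.uniform(0, 1)),
            gamma=float(rng.uniform(0, 1)),
            w4=0.5,
        )
        state = ModelState("hybrid_value", params)
        odors = ("left_forced", "right_forced", "free")
        for _ in range(200):
            odor = odors[rng.integers(3)]
            choice = ("left", "right")[rng.integers(2)]
            valid = odor == "free" or odor == f"{choice}_forced"
            r = int(rng.integers(1, 3)) if valid else 0
            state.observe(odor, choice, valid, r, float(rng.uniform(0.5, 7)))
            for table in state.tables:
                assert all(0.0 <= v <= 2.0 for v in table.values.values())


class TestSimulateAgent:
    def test_same_seed_identical_log(self, schedule, default_params):
        import pandas as pd

        from odorchoice.task import records_to_frame

        a = simulate_agent("six_state", default_params, schedule, 3)
        b = simulate_agent("six_state", default_params, schedule, 3)
        pd.testing.assert_frame_equal(records_to_frame(a), records_to_frame(b))

    def test_pure_lapse_agent_is_indifferent(self):
        cfg = SessionConfig()
        params = ModelParams(eta=0.25, gamma=0.8, beta=3.0, lapse=1.0)
        lefts, frees = 0, 0
        for s in range(30):
            sch = build_session_schedule(cfg, 1000 + s)
            for rec in simulate_agent("six_state", params, sch, 2000 + s):
                if rec.odor == "free":
                    frees += 1
                    lefts += rec.choice == "left"
        assert abs(lefts / frees - 0.5) < 0.03

    def test_shared_representation_learns_faster_after_switch(self):
        """Four-state agents generalize forced-trial outcomes to free
        choices, so their free-choice accuracy right after a reversal beats
        matched six-state agents (simulation oracle, 500 sessions)."""
        from odorchoice.behavior import compute_learning_curves
        from odorchoice.experiments import simulate_dataset

        params = ModelParams(eta=0.25, gamma=0.8, beta=3.0, persev_p=0.2, lapse=0.02)
        acc = {}
        for model in ("four_state", "six_state"):
            df = simulate_dataset(model, {"a0": params}, 500, seed=31)
            t = compute_learning_curves(df).table
            post = t[(t.trial_type == "free") & (t.offset >= 1) & (t.offset <= 10)]
            acc[model] = post["accuracy"].mean()
        assert acc["four_state"] > acc["six_state"]
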