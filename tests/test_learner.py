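"""Rule-based training phase: weights, dynamics, transitions, learning."""

import numpy as np
import pytest

from thoughtseeds.learner import (
    ActivationState,
    distraction_growth,
    dominant_thoughtseed,
    forced_transition,
    init_weight_matrix,
    meta_awareness_update,
    modulated_target,
    natural_transition_check,
    sample_dwell,
    train,
    update_activations,
)
from thoughtseeds.analytics import episode_durations, pooled_episode_mean
from thoughtseeds.profiles import (
    DEFAULT_ATTRACTORS,
    STATES,
    THOUGHTSEEDS,
    TS_INDEX,
    AttractorSpec,
    DwellLimits,
    MeditationState,
    Thoughtseed,
    ValidationError,
    make_profile,
    reference_transition_matrix,
)

BC, MW, MA, RB = STATES
BF = TS_INDEX[Thoughtseed.BREATH_FOCUS]
EQ = TS_INDEX[Thoughtseed.EQUANIMITY]
PD = TS_INDEX[Thoughtseed.PAIN_DISCOMFORT]
PT = TS_INDEX[Thoughtseed.PENDING_TASKS]
SR = TS_INDEX[Thoughtseed.SELF_REFLECTION]


class TestWeightInit:
    def test_role_bands(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            w = init_weight_matrix(DEFAULT_ATTRACTORS, 1.0, rng)
            for state in STATES:
                for ts in THOUGHTSEEDS:
                    v = w[state, ts]
                    role = DEFAULT_ATTRACTORS.role(state, ts)
                    lo, hi = {
                        "primary": (0.9, 1.1),
                        "secondary": (0.7, 0.9),
                        "other": (0.05, 0.2),
                    }[role]
                    assert lo <= v <= hi

    def test_omega_scaling_and_degeneracy(self):
        rng = np.random.default_rng(1)
        w0 = init_weight_matrix(DEFAULT_ATTRACTORS, 0.0, rng)
        assert np.all(w0.weights == 0.0)
        w2 = init_weight_matrix(DEFAULT_ATTRACTORS, 2.0, np.random.default_rng(7))
        assert w2[BC, Thoughtseed.BREATH_FOCUS] >= 1.8

    def test_reproducible_from_seed(self):
        a = init_weight_matrix(rng=np.random.default_rng(42))
        b = init_weight_matrix(rng=np.random.default_rng(42))
        assert np.array_equal(a.weights, b.weights)

    def test_overlapping_attractors_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            AttractorSpec(
                primary={s: frozenset({Thoughtseed.BREATH_FOCUS}) for s in STATES},
                secondary={BC: frozenset({Thoughtseed.BREATH_FOCUS})},
            )


class TestDistractionGrowth:
    def test_zero_probability_gives_zero(self):
        p = make_profile("novice", {"distraction_spike_prob": 0.0})
        delta = distraction_growth(p, np.random.default_rng(0))
        assert np.all(delta == 0.0)

    def test_point_mass_spike(self):
        p = make_profile(
            "novice",
            {"distraction_spike_prob": 1.0, "distraction_spike_range": (0.3, 0.3)},
        )
        delta = distraction_growth(p, np.random.default_rng(0))
        assert delta[PD] == pytest.approx(0.3)
        assert delta[PT] == pytest.approx(0.3)
        assert delta[BF] == delta[EQ] == delta[SR] == 0.0

    def test_spike_frequency_matches_binomial(self):
        # Monte-Carlo against the binomial oracle: p_hat within 3 s.e. of 0.10
        p = make_profile("novice")
        rng = np.random.default_rng(12345)
        n = 10_000
        hits = np.zeros(2)
        for _ in range(n):
            delta = distraction_growth(p, rng)
            hits += delta[[PD, PT]] > 0
        se = np.sqrt(0.1 * 0.9 / n)
        assert np.all(np.abs(hits / n - 0.10) < 3 * se)


class TestModulatedTarget:
    @pytest.fixture
    def weights(self):
        w = init_weight_matrix(rng=np.random.default_rng(3))
        w.weights[STATES.index(MW), BF] = 0.8
        w.weights[STATES.index(MW), PT] = 0.5
        return w

    def test_low_awareness_suppression_and_enhancement(self, weights):
        p = make_profile("novice")
        t = modulated_target(MW, 0.55, weights, p)
        assert t[BF] == pytest.approx(0.8 * 0.05)
        assert t[PT] == pytest.approx(0.5 * 1.2)

    def test_high_awareness_unmodulated(self, weights):
        p = make_profile("novice")
        t = modulated_target(MW, 0.75, weights, p)
        assert t[BF] == pytest.approx(0.8)

    def test_other_states_unmodulated(self, weights):
        p = make_profile("novice")
        t = modulated_target(BC, 0.2, weights, p)
        assert np.allclose(t, np.clip(weights.row(BC), 0, 1))


class TestUpdateActivations:
    def test_direct_evaluation(self, zero_noise):
        p = make_profile("novice")
        a = update_activations(
            np.zeros(5), np.ones(5), np.zeros(5), p, zero_noise
        )
        assert np.allclose(a, 0.1)

    def test_fixed_point(self, zero_noise):
        p = make_profile("novice")
        a = update_activations(
            np.full(5, 0.5), np.full(5, 0.5), np.zeros(5), p, zero_noise
        )
        assert np.allclose(a, 0.5)

    def test_upper_clip(self, zero_noise):
        p = make_profile("novice")
        spike = np.zeros(5)
        spike[PD] = 0.3
        a = update_activations(np.ones(5), np.ones(5), spike, p, zero_noise)
        assert np.all(a == 1.0)

    def test_geometric_convergence_closed_form(self, zero_noise):
        # gap to target shrinks by exactly (1-gamma)^t without noise/spikes
        p = make_profile("expert")
        target = np.full(5, 0.8)
        alpha = np.zeros(5)
        for t in range(1, 30):
            alpha = update_activations(alpha, target, np.zeros(5), p, zero_noise)
            expected_gap = 0.8 * (1 - p.momentum_gamma) ** t
            assert np.allclose(0.8 - alpha, expected_gap, rtol=0, atol=1e-12)


class TestMetaAwareness:
    @pytest.mark.parametrize(
        "state,dominant,expected",
        [
            (MW, Thoughtseed.PENDING_TASKS, 0.55),
            (MW, Thoughtseed.PAIN_DISCOMFORT, 0.55),
            (MW, Thoughtseed.BREATH_FOCUS, 1.0),
            (RB, Thoughtseed.EQUANIMITY, 0.85),
            (BC, Thoughtseed.BREATH_FOCUS, 0.75),
            (MA, Thoughtseed.SELF_REFLECTION, 0.9),
        ],
    )
    def test_branch_values_zero_noise(self, state, dominant, expected):
        p = make_profile("expert")
        assert meta_awareness_update(state, dominant, p, eps=0.0) == expected

    def test_caps_and_floors(self):
        p = make_profile("expert")
        # cap binds against positive noise; floor binds against negative noise
        assert meta_awareness_update(BC, Thoughtseed.BREATH_FOCUS, p, eps=0.5) == 0.75
        assert (
            meta_awareness_update(MW, Thoughtseed.PENDING_TASKS, p, eps=-0.5) == 0.55
        )

    def test_floor_holds_on_traces(self, novice_models, expert_models):
        for m in novice_models + expert_models:
            assert all(rec.mu >= 0.55 for rec in m.trace)


class TestDominance:
    def test_unique_max(self):
        assert (
            dominant_thoughtseed(np.array([0.9, 0.1, 0.1, 0.1, 0.1]))
            is Thoughtseed.BREATH_FOCUS
        )

    def test_tie_breaks_to_canonical_order(self):
        assert (
            dominant_thoughtseed(np.array([0.2, 0.7, 0.7, 0.1, 0.1]))
            is Thoughtseed.EQUANIMITY
        )
        assert dominant_thoughtseed(np.ones(5)) is Thoughtseed.BREATH_FOCUS


class TestNaturalTransition:
    @pytest.fixture
    def weights(self):
        return init_weight_matrix(rng=np.random.default_rng(5))

    def test_below_dwell_requirement_blocks(self, weights):
        p = make_profile("novice")
        alpha = np.ones(5)
        assert natural_transition_check(MW, alpha, 2, 10, weights, p) is None

    def test_breath_focus_takeover_from_mind_wandering(self, weights):
        # evidence on breath_focus only: phi_bc = phi_rb = 0.5 > theta; tie
        # resolves to the earlier canonical state (breath_control)
        p = make_profile("novice")
        alpha = np.zeros(5)
        alpha[BF] = 1.0
        cand = natural_transition_check(MW, alpha, 10, 10, weights, p)
        assert cand is BC

    def test_no_crossing_from_rest(self, weights):
        p = make_profile("novice")
        assert natural_transition_check(MW, np.zeros(5), 10, 10, weights, p) is None

    def test_takeover_requires_beating_current_support(self, weights):
        # candidate evidence above theta but below the current basin's own
        # support must not fire
        p = make_profile("novice")
        alpha = np.zeros(5)
        alpha[BF] = 0.6
        alpha[EQ] = 0.6
        alpha[PD] = alpha[PT] = 0.7  # current mind_wandering support higher
        assert natural_transition_check(MW, alpha, 10, 10, weights, p) is None


class TestForcedTransition:
    def test_renormalized_sampling_matches_row(self):
        # multinomial Monte-Carlo against the renormalized off-diagonal row
        ref = reference_transition_matrix("expert")
        row = ref.row(BC)  # stay-mass 0.55
        rng = np.random.default_rng(99)
        n = 10_000
        counts = {s: 0 for s in STATES}
        for _ in range(n):
            counts[forced_transition(BC, 10, 10, row, rng)] += 1
        assert counts[BC] == 0
        expected = row / (1 - row[0])
        for j, s in enumerate(STATES[1:], start=1):
            p = expected[j]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[s] / n - p) < 3 * se

    def test_dominant_exit_probability(self):
        # expert meta_awareness row: 0.80 to redirect_breath, zero stay-mass,
        # so the renormalized exit probability is 0.80 exactly
        ref = reference_transition_matrix("expert")
        row = ref.row(MA)
        rng = np.random.default_rng(4)
        n = 10_000
        hits = sum(forced_transition(MA, 5, 5, row, rng) is RB for _ in range(n))
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(hits / n - 0.80) < 3 * se

    def test_single_target_row_deterministic(self):
        row = np.array([0.0, 1.0, 0.0, 0.0])
        rng = np.random.default_rng(0)
        assert all(forced_transition(BC, 3, 3, row, rng) is MW for _ in range(50))

    def test_early_call_is_contract_violation(self):
        ref = reference_transition_matrix("novice")
        with pytest.raises(ValidationError, match="dwell"):
            forced_transition(BC, 2, 10, ref.row(BC), np.random.default_rng(0))


class TestTrain:
    def test_bookkeeping_identities(self, novice_models):
        for m in novice_models:
            assert len(m.trace) == 200
            changes = sum(
                1
                for a, b in zip(m.trace, m.trace[1:])
                if a.state is not b.state
            )
            assert m.transition_model.total_transitions == changes
            assert (
                m.transition_model.n_natural + m.transition_model.n_forced == changes
            )

    def test_transition_rows_stochastic(self, novice_models, expert_models):
        for m in novice_models + expert_models:
            T = m.transition_model.T
            for i, state in enumerate(STATES):
                if m.transition_model.has_exits(state):
                    assert T[i].sum() == pytest.approx(1.0, abs=1e-9)
                else:
                    assert np.all(T[i] == 0.0)

    def test_mean_transition_alpha_defined_iff_counted(self, expert_models):
        m = expert_models[0]
        for src in STATES:
            for dst in STATES:
                mean = m.transition_model.mean_transition_alpha(src, dst)
                n = m.transition_model.counts[STATES.index(src), STATES.index(dst)]
                if n > 0:
                    assert mean.shape == (5,)
                    assert np.all((mean >= 0) & (mean <= 1))
                else:
                    assert mean is None

    def test_bit_identical_from_seed(self, novice_profile):
        a = train(novice_profile, n_steps=150, seed=7)
        b = train(novice_profile, n_steps=150, seed=7)
        assert np.array_equal(a.weight_matrix.weights, b.weight_matrix.weights)
        for ra, rb in zip(a.trace, b.trace):
            assert np.array_equal(ra.alpha, rb.alpha)
            assert ra.state is rb.state and ra.mu == rb.mu

    def test_rest_dynamics_never_leave_breath_control(self):
        # negligible noise, no spikes, effectively unbounded dwell: no
        # threshold crossing arises from the relaxation dynamics alone
        p = make_profile(
            "novice",
            {
                "noise_scale": 1e-12,
                "meta_noise_scale": 1e-12,
                "distraction_spike_prob": 0.0,
                "dwell_limits": {
                    s: DwellLimits(mean=1e9, sd=1.0, min=3) for s in STATES
                },
            },
        )
        m = train(p, n_steps=300, seed=0)
        assert all(rec.state is BC for rec in m.trace)
        assert m.transition_model.total_transitions == 0

    def test_invalid_steps_rejected(self, novice_profile):
        with pytest.raises(ValidationError):
            train(novice_profile, n_steps=0, seed=0)

    def test_weights_stay_bounded(self, expert_models):
        for m in expert_models:
            assert np.all(m.weight_matrix.weights >= 0.0)
            assert np.all(m.weight_matrix.weights <= 1.1 * m.profile.omega_base)

    def test_episode_lengths_respect_dwell_caps(self, novice_models, expert_models):
        for m in novice_models + expert_models:
            stats = episode_durations(m)
            for state in STATES:
                cap = m.profile.dwell_limits[state].max
                assert all(d <= cap + 1 for d in stats.durations[state])

    def test_expertise_ensemble_orderings(self, novice_models, expert_models):
        nov = pooled_episode_mean([episode_durations(m) for m in novice_models])
        exp = pooled_episode_mean([episode_durations(m) for m in expert_models])
        assert exp[MW] < nov[MW]
        mu_nov = np.mean([rec.mu for m in novice_models for rec in m.trace])
        mu_exp = np.mean([rec.mu for m in expert_models for rec in m.trace])
        assert mu_exp > mu_nov


class TestDwellSampling:
    def test_samples_within_limits(self, novice_profile):
        rng = np.random.default_rng(0)
        lim = novice_profile.dwell_limits[MW]
        draws = [sample_dwell(MW, novice_profile, rng) for _ in range(2000)]
        assert all(lim.min <= d <= lim.max for d in draws)
        assert np.mean(draws) == pytest.approx(lim.mean, abs=3 * lim.sd / np.sqrt(2000) + 0.5)
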