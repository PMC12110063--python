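"""Hierarchical simulation with the trained model.

Runs the three-level dynamical system: thoughtseed targets combine the
learned state weight row, network influence from the interaction matrix,
a state-specific bias, and meta-awareness coupling (a Wilson–Cowan-style
competition); activations follow momentum updates with per-run
responsiveness; the dominant thoughtseed emerges winner-takes-all; state
transitions reuse the learner's natural/forced hybrid, preferring the
learned transition matrix and falling back to the packaged reference row
for states never exited during training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .learner import (
    ActivationState,
    LearnedModel,
    _activation_noise,
    distraction_growth,
    dominant_thoughtseed,
    forced_transition,
    meta_awareness_update,
    natural_transition_check,
    sample_dwell,
)
from .network import InteractionMatrix
from .profiles import (
    STATES,
    STATE_INDEX,
    THOUGHTSEEDS,
    TS_INDEX,
    ExpertiseProfile,
    MeditationState,
    Thoughtseed,
    ValidationError,
)

__all__ = [
    "SimulationTrace",
    "state_bias",
    "compute_target",
    "step_activation",
    "dominant_thoughtseed",
    "transition_step",
    "run",
]

#: Baseline-tendency boost for a state's own attractor thoughtseeds.
STATE_BIAS_VALUE = 0.1


def state_bias(state: MeditationState, model: LearnedModel) -> np.ndarray:
    """State-specific bias gamma_is: +0.1 on the state's attractors, else 0."""
    bias = np.zeros(len(THOUGHTSEEDS))
    for ts in model.weight_matrix.attractors.attractors(state):
        bias[TS_INDEX[ts]] = STATE_BIAS_VALUE
    return bias


def compute_target(
    alpha: np.ndarray,
    state: MeditationState,
    mu: float,
    model: LearnedModel,
    interactions: InteractionMatrix,
    profile: ExpertiseProfile,
) -> np.ndarray:
    """Network-level targets for all thoughtseeds (vectorized).

    ``Target_i = W[state, i] + (sum_j W_ji * alpha_j) * tau + gamma_is * tau
    + mu * beta_i``, clipped to [0, 1].  The interaction matrix is stored
    source-by-target, so the incoming influence on i sums over sources j.
    """
    tau = profile.network_gain_tau
    beta = np.array([profile.meta_coupling_beta[ts] for ts in THOUGHTSEEDS])
    target = (
        model.weight_matrix.row(state)
        + interactions.incoming(alpha) * tau
        + state_bias(state, model) * tau
        + mu * beta
    )
    return np.clip(target, 0.0, 1.0)


def step_activation(alpha: np.ndarray, target: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Momentum update with responsiveness r: r*target + (1-r)*alpha."""
    return r * target + (1.0 - r) * alpha


@dataclass
class SimulationTrace:
    """Full record of a simulation run."""

    steps: list[ActivationState]
    transitions: list[tuple[int, MeditationState, MeditationState, str]]
    profile: ExpertiseProfile
    seed: int
    responsiveness: np.ndarray  # per-thoughtseed r_i sampled for this run


def transition_step(
    state: MeditationState,
    alpha: np.ndarray,
    dwell: int,
    dwell_required: float,
    model: LearnedModel,
    profile: ExpertiseProfile,
    rng: np.random.Generator,
) -> tuple[MeditationState, Optional[str]]:
    """Hybrid transition rule: natural crossing first, else forced sampling.

    Below the episode's dwell requirement the state is kept.  At or beyond
    it, a threshold crossing yields a natural transition; otherwise the next
    state is sampled from the learned transition row (reference row when the
    learned row has no exits).
    """
    if dwell < dwell_required:
        return state, None
    nxt = natural_transition_check(
        state, alpha, dwell, dwell_required, model.weight_matrix, profile
    )
    if nxt is not None:
        return nxt, "natural"
    tm = model.transition_model
    row = tm.row(state) if tm.has_exits(state) else model.reference.row(state)
    nxt = forced_transition(state, dwell, dwell_required, row, rng)
    return nxt, "forced"


def run(
    model: LearnedModel,
    interactions: InteractionMatrix,
    profile: ExpertiseProfile,
    n_steps: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> SimulationTrace:
    """Simulate ``n_steps`` timesteps with the trained model.

    Responsiveness r_i is sampled once per run from the profile's level
    range.  The learned weight matrix stays frozen.  Bit-reproducible from
    ``seed``.
    """
    if n_steps < 1:
        raise ValidationError(f"n_steps must be >= 1, got {n_steps}")
    rng = np.random.default_rng(seed)
    lo, hi = profile.responsiveness_range
    r = rng.uniform(lo, hi, size=len(THOUGHTSEEDS))

    state = MeditationState.BREATH_CONTROL
    alpha = np.clip(model.weight_matrix.row(state), 0.0, 1.0).copy()
    dominant = dominant_thoughtseed(alpha)
    mu = meta_awareness_update(state, dominant, profile, rng)
    dwell = 1
    dwell_req = sample_dwell(state, profile, rng)

    steps: list[ActivationState] = [
        ActivationState(0, alpha.copy(), mu, state, dominant, dwell)
    ]
    transitions: list[tuple[int, MeditationState, MeditationState, str]] = []

    for t in range(1, n_steps):
        target = compute_target(alpha, state, mu, model, interactions, profile)
        delta = distraction_growth(profile, rng)
        alpha = np.clip(
            step_activation(alpha, target, r) + delta + _activation_noise(profile, rng),
            0.0,
            1.0,
        )
        dominant = dominant_thoughtseed(alpha)
        mu = meta_awareness_update(state, dominant, profile, rng)

        nxt, kind = transition_step(state, alpha, dwell, dwell_req, model, profile, rng)
        if kind is not None:
            transitions.append((t, state, nxt, kind))
            state = nxt
            dwell = 1
            dwell_req = sample_dwell(state, profile, rng)
        else:
            dwell += 1

        steps.append(ActivationState(t, alpha.copy(), mu, state, dominant, dwell, kind))

    return SimulationTrace(
        steps=steps,
        transitions=transitions,
        profile=profile,
        seed=seed if isinstance(seed, int) else -1,
        responsiveness=r,
    )
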