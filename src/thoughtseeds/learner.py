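"""Rule-based training phase.

A 200-timestep self-organizing run: state-conditioned weight rows define
attractor landscapes for the five thoughtseeds, activations relax toward
(meta-awareness-modulated) targets under momentum dynamics with distraction
spikes and bounded noise, meta-awareness follows a five-branch
state-dependent rule, and state transitions are either *natural* (a
candidate state's distinctive attractor evidence crosses a threshold once
the episode's dwell requirement is met) or *forced* (dwell requirement
reached without a crossing; next state sampled from the reference
transition row).  Observed transitions are tallied into a row-stochastic
transition matrix, and weight rows are blended 90/10 toward the observed
activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .profiles import (
    DISTRACTIONS,
    DEFAULT_ATTRACTORS,
    STATES,
    STATE_INDEX,
    THOUGHTSEEDS,
    TS_INDEX,
    AttractorSpec,
    ExpertiseProfile,
    MeditationState,
    ReferenceTransitionMatrix,
    Thoughtseed,
    ValidationError,
    reference_transition_matrix,
)

__all__ = [
    "StateWeightMatrix",
    "ActivationState",
    "TransitionModel",
    "LearnedModel",
    "init_weight_matrix",
    "distraction_growth",
    "modulated_target",
    "update_activations",
    "meta_awareness_update",
    "natural_transition_check",
    "forced_transition",
    "sample_dwell",
    "dominant_thoughtseed",
    "train",
]

_DIST_MASK = np.array([ts in DISTRACTIONS for ts in THOUGHTSEEDS])

#: Meta-awareness level below which mind-wandering modulation kicks in.
LOW_AWARENESS = 0.6


def dominant_thoughtseed(alpha: np.ndarray) -> Thoughtseed:
    """Winner-takes-all: the highest-activation thoughtseed.

    Ties resolve to the earlier thoughtseed in canonical order
    (breath_focus first).
    """
    return THOUGHTSEEDS[int(np.argmax(alpha))]


# ---------------------------------------------------------------------------
# Weight matrix
# ---------------------------------------------------------------------------


@dataclass
class StateWeightMatrix:
    """State x thoughtseed attractor weights W (4 x 5, nonnegative)."""

    weights: np.ndarray
    attractors: AttractorSpec
    omega_base: float = 1.0

    def row(self, state: MeditationState) -> np.ndarray:
        return self.weights[STATE_INDEX[state]]

    def __getitem__(self, key: tuple[MeditationState, Thoughtseed]) -> float:
        state, ts = key
        return float(self.weights[STATE_INDEX[state], TS_INDEX[ts]])

    def blend_row(self, state: MeditationState, alpha: np.ndarray, rate: float) -> None:
        """Momentum update: W[state] <- (1-rate)*W[state] + rate*alpha.

        Entries stay clipped to [0, 1.1 * omega_base].
        """
        i = STATE_INDEX[state]
        self.weights[i] = np.clip(
            (1.0 - rate) * self.weights[i] + rate * alpha, 0.0, 1.1 * self.omega_base
        )

    def copy(self) -> "StateWeightMatrix":
        return StateWeightMatrix(self.weights.copy(), self.attractors, self.omega_base)

    def to_dict(self) -> dict:
        return {
            "states": [s.value for s in STATES],
            "thoughtseeds": [ts.value for ts in THOUGHTSEEDS],
            "weights": self.weights.tolist(),
            "omega_base": self.omega_base,
        }


_ROLE_BANDS = {"primary": (0.9, 1.1), "secondary": (0.7, 0.9), "other": (0.05, 0.2)}


def init_weight_matrix(
    attractors: AttractorSpec = DEFAULT_ATTRACTORS,
    omega_base: float = 1.0,
    rng: np.random.Generator | None = None,
) -> StateWeightMatrix:
    """Draw an initial weight matrix from the attractor-role uniform bands.

    Primary attractors draw from ``omega_base * U(0.9, 1.1)``, secondary
    from ``omega_base * U(0.7, 0.9)``, all other entries from
    ``omega_base * U(0.05, 0.2)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    w = np.empty((len(STATES), len(THOUGHTSEEDS)))
    for i, state in enumerate(STATES):
        for j, ts in enumerate(THOUGHTSEEDS):
            lo, hi = _ROLE_BANDS[attractors.role(state, ts)]
            w[i, j] = omega_base * rng.uniform(lo, hi)
    return StateWeightMatrix(w, attractors, omega_base)


# ---------------------------------------------------------------------------
# Per-step dynamics
# ---------------------------------------------------------------------------


def distraction_growth(profile: ExpertiseProfile, rng: np.random.Generator) -> np.ndarray:
    """Spontaneous distraction spikes.

    Each distraction thoughtseed independently spikes with probability
    ``distraction_spike_prob`` by an amplitude drawn uniformly from
    ``distraction_spike_range``; all other entries are zero.
    """
    delta = np.zeros(len(THOUGHTSEEDS))
    lo, hi = profile.distraction_spike_range
    for j in np.flatnonzero(_DIST_MASK):
        if rng.random() < profile.distraction_spike_prob:
            delta[j] = rng.uniform(lo, hi)
    return delta


def modulated_target(
    state: MeditationState,
    mu: float,
    weight_matrix: StateWeightMatrix,
    profile: ExpertiseProfile,
) -> np.ndarray:
    """State-conditioned activation targets, modulated by low meta-awareness.

    The base target is the weight row clipped to [0, 1].  During
    mind-wandering with low meta-awareness (mu < 0.6) the breath_focus
    target is suppressed (x 0.05 by default) and distraction targets are
    enhanced (x 1.2), then re-clipped.
    """
    target = np.clip(weight_matrix.row(state), 0.0, 1.0).copy()
    if state is MeditationState.MIND_WANDERING and mu < LOW_AWARENESS:
        target[TS_INDEX[Thoughtseed.BREATH_FOCUS]] *= profile.suppression_factor
        target[_DIST_MASK] *= profile.enhancement_factor
        target = np.clip(target, 0.0, 1.0)
    return target


def _activation_noise(profile: ExpertiseProfile, rng: np.random.Generator) -> np.ndarray:
    n = len(THOUGHTSEEDS)
    if profile.noise_law == "uniform":
        return rng.uniform(-profile.noise_scale, profile.noise_scale, size=n)
    return rng.normal(0.0, profile.noise_scale, size=n)


def update_activations(
    alpha: np.ndarray,
    target: np.ndarray,
    delta_dist: np.ndarray,
    profile: ExpertiseProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """One momentum step: (1-gamma)*alpha + gamma*target + spikes + noise.

    The result is clipped to [0, 1] per thoughtseed.
    """
    g = profile.momentum_gamma
    nxt = (1.0 - g) * alpha + g * target + delta_dist + _activation_noise(profile, rng)
    return np.clip(nxt, 0.0, 1.0)


def meta_awareness_update(
    state: MeditationState,
    dominant: Thoughtseed,
    profile: ExpertiseProfile,
    rng: np.random.Generator | None = None,
    eps: float | None = None,
) -> float:
    """State-dependent meta-awareness regulation (five-branch rule).

    With noise eps ~ N(0, meta_noise_scale^2) (pass ``eps`` explicitly for a
    deterministic evaluation):

    * mind_wandering, distraction dominant: ``max(0.55, 0.55 + eps)``
    * mind_wandering, otherwise:            ``max(0.55, 1.0 + eps)``
    * redirect_breath:                      ``min(0.85, 0.85 + eps)``
    * breath_control:                       ``min(0.75, 0.80 + eps)``
    * meta_awareness:                       ``min(0.90, 0.90 + eps)``

    The result is finally clipped to [0, 1].
    """
    if eps is None:
        if rng is None:
            raise ValueError("provide either rng or eps")
        eps = float(rng.normal(0.0, profile.meta_noise_scale))
    if state is MeditationState.MIND_WANDERING:
        if dominant in DISTRACTIONS:
            mu = max(0.55, 0.55 + eps)  # baseline 0.6 lowered by 0.05
        else:
            mu = max(0.55, 1.0 + eps)  # baseline 0.6 raised by 0.4
    elif state is MeditationState.REDIRECT_BREATH:
        mu = min(0.85, 0.85 + eps)
    elif state is MeditationState.BREATH_CONTROL:
        mu = min(0.75, 0.8 + eps)
    else:  # meta_awareness
        mu = min(0.9, 0.9 + eps)
    return float(np.clip(mu, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------


def attractor_evidence(
    alpha: np.ndarray, state: MeditationState, attractors: AttractorSpec
) -> float:
    """Attractor evidence phi: mean activation over a state's attractors
    (primary and secondary)."""
    idx = [TS_INDEX[ts] for ts in attractors.attractors(state)]
    return float(np.mean(alpha[idx]))


def natural_transition_check(
    state: MeditationState,
    alpha: np.ndarray,
    dwell: int,
    dwell_required: float,
    weight_matrix: StateWeightMatrix,
    profile: ExpertiseProfile,
) -> Optional[MeditationState]:
    """Threshold-crossing transition candidate, or ``None``.

    A transition to state j is permitted iff ``dwell >= dwell_required``,
    phi_j(alpha) exceeds the per-target transition threshold, and
    phi_j(alpha) strictly exceeds the current state's own attractor
    support — a genuine basin takeover, not a shared-attractor echo.  The
    argmax-phi candidate is returned; ties resolve to the earlier state in
    canonical order.
    """
    if dwell < dwell_required:
        return None
    attractors = weight_matrix.attractors
    phi_current = attractor_evidence(alpha, state, attractors)
    best: Optional[MeditationState] = None
    best_phi = -np.inf
    for cand in STATES:
        if cand is state:
            continue
        phi = attractor_evidence(alpha, cand, attractors)
        if phi > profile.transition_threshold[cand] and phi > phi_current and phi > best_phi:
            best, best_phi = cand, phi
    return best


def forced_transition(
    state: MeditationState,
    dwell: int,
    dwell_required: float,
    row: np.ndarray,
    rng: np.random.Generator,
) -> MeditationState:
    """Sample the next state from a transition row, excluding the diagonal.

    ``row`` is a length-4 probability row (reference or learned); its
    off-diagonal mass is renormalized.  Calling before the episode's dwell
    requirement is reached is a contract violation.
    """
    if dwell < dwell_required:
        raise ValidationError(
            f"forced transition requested at dwell={dwell} < required {dwell_required}"
        )
    p = np.asarray(row, dtype=float).copy()
    p[STATE_INDEX[state]] = 0.0
    total = p.sum()
    if total <= 0.0:
        # fully degenerate row: uniform over the other states
        p = np.ones(len(STATES))
        p[STATE_INDEX[state]] = 0.0
        total = p.sum()
    p /= total
    return STATES[int(rng.choice(len(STATES), p=p))]


def sample_dwell(
    state: MeditationState, profile: ExpertiseProfile, rng: np.random.Generator
) -> int:
    """Draw an episode's dwell requirement: round(N(mean, sd)) in [min, max]."""
    lim = profile.dwell_limits[state]
    d = rng.normal(lim.mean, lim.sd)
    return int(np.clip(round(d), lim.min, lim.max))


# ---------------------------------------------------------------------------
# Bookkeeping containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationState:
    """One timestep of the system: activations, meta-awareness, state."""

    t: int
    alpha: np.ndarray
    mu: float
    state: MeditationState
    dominant: Thoughtseed
    dwell: int
    transition_kind: str | None = None  # "natural"/"forced" if a transition ended here


@dataclass
class TransitionModel:
    """Observed transition counts, the row-stochastic matrix T, and mean
    activations at transition points."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((len(STATES), len(STATES)), dtype=int)
    )
    _alpha_sums: dict = field(default_factory=dict)
    n_natural: int = 0
    n_forced: int = 0

    def record(
        self,
        src: MeditationState,
        dst: MeditationState,
        alpha: np.ndarray,
        kind: str,
    ) -> None:
        i, j = STATE_INDEX[src], STATE_INDEX[dst]
        self.counts[i, j] += 1
        key = (src, dst)
        self._alpha_sums[key] = self._alpha_sums.get(key, 0.0) + np.asarray(alpha)
        if kind == "natural":
            self.n_natural += 1
        else:
            self.n_forced += 1

    @property
    def T(self) -> np.ndarray:
        """Row-stochastic transition matrix; rows without exits stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(totals > 0, self.counts / np.maximum(totals, 1), 0.0)
        return t

    @property
    def total_transitions(self) -> int:
        return int(self.counts.sum())

    def mean_transition_alpha(
        self, src: MeditationState, dst: MeditationState
    ) -> np.ndarray | None:
        n = self.counts[STATE_INDEX[src], STATE_INDEX[dst]]
        if n == 0:
            return None
        return np.asarray(self._alpha_sums[(src, dst)]) / n

    def row(self, state: MeditationState) -> np.ndarray:
        return self.T[STATE_INDEX[state]]

    def has_exits(self, state: MeditationState) -> bool:
        return bool(self.counts[STATE_INDEX[state]].sum() > 0)

    def to_dict(self) -> dict:
        return {
            "states": [s.value for s in STATES],
            "matrix": self.T.tolist(),
            "counts": self.counts.tolist(),
            "n_natural": self.n_natural,
            "n_forced": self.n_forced,
        }


@dataclass
class LearnedModel:
    """Outcome of a training run: learned weights, transition model, trace."""

    weight_matrix: StateWeightMatrix
    transition_model: TransitionModel
    trace: list[ActivationState]
    transitions: list[tuple[int, MeditationState, MeditationState, str]]
    profile: ExpertiseProfile
    seed: int
    reference: ReferenceTransitionMatrix


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def train(
    profile: ExpertiseProfile,
    attractors: AttractorSpec = DEFAULT_ATTRACTORS,
    n_steps: int = 200,
    seed: int | np.random.SeedSequence = 0,
    reference: ReferenceTransitionMatrix | None = None,
    blend_rate: float = 0.1,
) -> LearnedModel:
    """Run the rule-based training phase for ``n_steps`` timesteps.

    The system starts in breath_control with activations equal to the
    clipped breath_control weight row.  Each step computes modulated
    targets, applies distraction spikes, updates activations and
    meta-awareness, blends the current state's weight row 90/10 toward the
    observed activations, and — once the episode's sampled dwell
    requirement is met — transitions naturally (threshold crossing) or
    forcedly (sampled from the reference row).  Fully reproducible from
    ``seed``.
    """
    if n_steps < 1:
        raise ValidationError(f"n_steps must be >= 1, got {n_steps}")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = reference_transition_matrix(profile.level)

    W = init_weight_matrix(attractors, profile.omega_base, rng)
    state = MeditationState.BREATH_CONTROL
    alpha = np.clip(W.row(state), 0.0, 1.0).copy()
    dominant = dominant_thoughtseed(alpha)
    mu = meta_awareness_update(state, dominant, profile, rng)
    dwell = 1
    dwell_req = sample_dwell(state, profile, rng)

    tm = TransitionModel()
    transitions: list[tuple[int, MeditationState, MeditationState, str]] = []
    trace: list[ActivationState] = [
        ActivationState(0, alpha.copy(), mu, state, dominant, dwell)
    ]

    for t in range(1, n_steps):
        target = modulated_target(state, mu, W, profile)
        delta = distraction_growth(profile, rng)
        alpha = update_activations(alpha, target, delta, profile, rng)
        dominant = dominant_thoughtseed(alpha)
        mu = meta_awareness_update(state, dominant, profile, rng)
        W.blend_row(state, alpha, blend_rate)

        kind: str | None = None
        if dwell >= dwell_req:
            nxt = natural_transition_check(state, alpha, dwell, dwell_req, W, profile)
            if nxt is not None:
                kind = "natural"
            else:
                nxt = forced_transition(
                    state, dwell, dwell_req, reference.row(state), rng
                )
                kind = "forced"
            tm.record(state, nxt, alpha, kind)
            transitions.append((t, state, nxt, kind))
            state = nxt
            dwell = 1
            dwell_req = sample_dwell(state, profile, rng)
        else:
            dwell += 1

        trace.append(ActivationState(t, alpha.copy(), mu, state, dominant, dwell, kind))

    return LearnedModel(
        weight_matrix=W,
        transition_model=tm,
        trace=trace,
        transitions=transitions,
        profile=profile,
        seed=seed if isinstance(seed, int) else -1,
        reference=reference,
    )
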