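"""Model vocabulary, expertise parameter bundles, and reference transition data.

The simulator's state space is fixed: five competing attentional agents
("thoughtseeds") and four macroscopic meditation states.  Everything that
differs between a novice and an expert meditator — noise amplitude,
responsiveness, dwell-time limits, distraction spike rates — lives in an
:class:`ExpertiseProfile`.  The empirically grounded state-transition
matrices used for forced transitions ship as packaged constants with
per-entry provenance flags.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Thoughtseed",
    "MeditationState",
    "THOUGHTSEEDS",
    "STATES",
    "DISTRACTIONS",
    "CATEGORIES",
    "DwellLimits",
    "AttractorSpec",
    "DEFAULT_ATTRACTORS",
    "ExpertiseProfile",
    "ReferenceTransitionMatrix",
    "make_profile",
    "reference_transition_matrix",
    "ConfigurationError",
    "ValidationError",
]


class ConfigurationError(ValueError):
    """Unknown expertise level or otherwise malformed configuration."""


class ValidationError(ValueError):
    """A parameter value violates a profile invariant."""


class Thoughtseed(str, enum.Enum):
    """The five attentional agents, in canonical (tie-break) order."""

    BREATH_FOCUS = "breath_focus"
    EQUANIMITY = "equanimity"
    PAIN_DISCOMFORT = "pain_discomfort"
    PENDING_TASKS = "pending_tasks"
    SELF_REFLECTION = "self_reflection"


class MeditationState(str, enum.Enum):
    """The four macroscopic meditation states, in canonical order."""

    BREATH_CONTROL = "breath_control"
    MIND_WANDERING = "mind_wandering"
    META_AWARENESS = "meta_awareness"
    REDIRECT_BREATH = "redirect_breath"


THOUGHTSEEDS: tuple[Thoughtseed, ...] = tuple(Thoughtseed)
STATES: tuple[MeditationState, ...] = tuple(MeditationState)

TS_INDEX: dict[Thoughtseed, int] = {ts: i for i, ts in enumerate(THOUGHTSEEDS)}
STATE_INDEX: dict[MeditationState, int] = {s: i for i, s in enumerate(STATES)}

DISTRACTIONS: frozenset[Thoughtseed] = frozenset(
    {Thoughtseed.PAIN_DISCOMFORT, Thoughtseed.PENDING_TASKS}
)

CATEGORIES: dict[Thoughtseed, str] = {
    Thoughtseed.BREATH_FOCUS: "focus",
    Thoughtseed.EQUANIMITY: "regulation",
    Thoughtseed.PAIN_DISCOMFORT: "distraction",
    Thoughtseed.PENDING_TASKS: "distraction",
    Thoughtseed.SELF_REFLECTION: "metacognition",
}


@dataclass(frozen=True)
class DwellLimits:
    """Dwell-time distribution for one state, in timesteps (1 step = 1 s).

    An episode's dwell requirement is drawn from N(mean, sd) and clipped to
    [min, max] with max = mean + 2*sd, so episode lengths concentrate around
    ``mean`` and never exceed the two-sigma cap.
    """

    mean: float
    sd: float
    min: int = 3

    @property
    def max(self) -> float:
        return self.mean + 2.0 * self.sd

    def validate(self, name: str) -> None:
        if not (0 < self.min <= self.mean <= self.max):
            raise ValidationError(
                f"dwell_limits[{name}]: need 0 < min <= mean <= max, "
                f"got min={self.min}, mean={self.mean}, max={self.max}"
            )


@dataclass(frozen=True)
class AttractorSpec:
    """Primary/secondary attractor thoughtseeds per meditation state."""

    primary: Mapping[MeditationState, frozenset[Thoughtseed]]
    secondary: Mapping[MeditationState, frozenset[Thoughtseed]]

    def __post_init__(self) -> None:
        for state in STATES:
            prim = self.primary.get(state, frozenset())
            sec = self.secondary.get(state, frozenset())
            if not prim:
                raise ValidationError(f"state {state.value} has no primary attractor")
            if prim & sec:
                raise ValidationError(
                    f"state {state.value}: primary and secondary attractors overlap"
                )

    def attractors(self, state: MeditationState) -> frozenset[Thoughtseed]:
        return self.primary[state] | self.secondary.get(state, frozenset())

    def role(self, state: MeditationState, ts: Thoughtseed) -> str:
        if ts in self.primary[state]:
            return "primary"
        if ts in self.secondary.get(state, frozenset()):
            return "secondary"
        return "other"


DEFAULT_ATTRACTORS = AttractorSpec(
    primary={
        MeditationState.BREATH_CONTROL: frozenset({Thoughtseed.BREATH_FOCUS}),
        MeditationState.MIND_WANDERING: frozenset(
            {Thoughtseed.PAIN_DISCOMFORT, Thoughtseed.PENDING_TASKS}
        ),
        MeditationState.META_AWARENESS: frozenset({Thoughtseed.SELF_REFLECTION}),
        MeditationState.REDIRECT_BREATH: frozenset(
            {Thoughtseed.EQUANIMITY, Thoughtseed.BREATH_FOCUS}
        ),
    },
    secondary={
        MeditationState.BREATH_CONTROL: frozenset({Thoughtseed.EQUANIMITY}),
    },
)


def _default_beta() -> dict[Thoughtseed, float]:
    # Meta-awareness couples positively into metacognitive/regulatory agents,
    # negatively into distractions, weakly into breath focus.
    return {
        Thoughtseed.BREATH_FOCUS: 0.1,
        Thoughtseed.EQUANIMITY: 0.3,
        Thoughtseed.PAIN_DISCOMFORT: -0.2,
        Thoughtseed.PENDING_TASKS: -0.2,
        Thoughtseed.SELF_REFLECTION: 0.3,
    }


@dataclass(frozen=True)
class ExpertiseProfile:
    """All expertise-dependent parameters of the model.

    Immutable after construction; build through :func:`make_profile`.
    """

    level: str
    noise_scale: float
    meta_noise_scale: float
    responsiveness_range: tuple[float, float]
    momentum_gamma: float
    omega_base: float
    dwell_limits: Mapping[MeditationState, DwellLimits]
    transition_threshold: Mapping[MeditationState, float]
    suppression_factor: float
    enhancement_factor: float
    distraction_spike_prob: float
    distraction_spike_range: tuple[float, float]
    meta_coupling_beta: Mapping[Thoughtseed, float]
    network_gain_tau: float = 1.0
    noise_law: str = "gaussian"  # or "uniform": eta ~ U(-noise_scale, noise_scale)

    def __post_init__(self) -> None:
        if self.noise_scale <= 0 or self.meta_noise_scale <= 0:
            raise ValidationError("noise_scale and meta_noise_scale must be > 0")
        if not (0.0 < self.momentum_gamma < 1.0):
            raise ValidationError("momentum_gamma must lie in (0, 1)")
        lo, hi = self.responsiveness_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("responsiveness_range must lie within (0, 1)")
        if not (self.suppression_factor < 1.0 < self.enhancement_factor):
            raise ValidationError(
                "need suppression_factor < 1 < enhancement_factor, got "
                f"{self.suppression_factor} / {self.enhancement_factor}"
            )
        if not (0.0 <= self.distraction_spike_prob <= 1.0):
            raise ValidationError("distraction_spike_prob must lie in [0, 1]")
        a, b = self.distraction_spike_range
        if not (0.0 <= a <= b):
            raise ValidationError("distraction_spike_range must satisfy 0 <= lo <= hi")
        if self.noise_law not in ("gaussian", "uniform"):
            raise ValidationError("noise_law must be 'gaussian' or 'uniform'")
        for state in STATES:
            self.dwell_limits[state].validate(state.value)
            theta = self.transition_threshold[state]
            if not (0.0 <= theta <= 1.0):
                raise ValidationError(
                    f"transition_threshold[{state.value}] must lie in [0, 1]"
                )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "noise_scale": self.noise_scale,
            "meta_noise_scale": self.meta_noise_scale,
            "responsiveness_range": list(self.responsiveness_range),
            "momentum_gamma": self.momentum_gamma,
            "omega_base": self.omega_base,
            "dwell_limits": {
                s.value: {"mean": d.mean, "sd": d.sd, "min": d.min}
                for s, d in self.dwell_limits.items()
            },
            "transition_threshold": {
                s.value: self.transition_threshold[s] for s in STATES
            },
            "suppression_factor": self.suppression_factor,
            "enhancement_factor": self.enhancement_factor,
            "distraction_spike_prob": self.distraction_spike_prob,
            "distraction_spike_range": list(self.distraction_spike_range),
            "meta_coupling_beta": {
                ts.value: self.meta_coupling_beta[ts] for ts in THOUGHTSEEDS
            },
            "network_gain_tau": self.network_gain_tau,
            "noise_law": self.noise_law,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExpertiseProfile":
        d = dict(d)
        d["responsiveness_range"] = tuple(d["responsiveness_range"])
        d["distraction_spike_range"] = tuple(d["distraction_spike_range"])
        d["dwell_limits"] = {
            MeditationState(k): DwellLimits(**v) for k, v in d["dwell_limits"].items()
        }
        d["transition_threshold"] = {
            MeditationState(k): float(v) for k, v in d["transition_threshold"].items()
        }
        d["meta_coupling_beta"] = {
            Thoughtseed(k): float(v) for k, v in d["meta_coupling_beta"].items()
        }
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_yaml(cls, text: str) -> "ExpertiseProfile":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_json(cls, text: str) -> "ExpertiseProfile":
        return cls.from_dict(json.loads(text))


_LEVEL_DEFAULTS: dict[str, dict] = {
    "novice": dict(
        noise_scale=0.08,
        responsiveness_range=(0.6, 0.7),
        distraction_spike_prob=0.10,
        mind_wandering_dwell=DwellLimits(mean=25.0, sd=5.0, min=3),
    ),
    "expert": dict(
        noise_scale=0.04,
        responsiveness_range=(0.7, 0.8),
        distraction_spike_prob=0.03,
        mind_wandering_dwell=DwellLimits(mean=10.0, sd=2.0, min=3),
    ),
}


def make_profile(level: str, overrides: Mapping | None = None) -> ExpertiseProfile:
    """Build a fully populated, validated :class:`ExpertiseProfile`.

    Parameters
    ----------
    level
        ``"novice"`` or ``"expert"``.
    overrides
        Optional mapping of field name to replacement value, applied after
        the level defaults.  Unknown field names raise
        :class:`ConfigurationError`; values violating an invariant raise
        :class:`ValidationError` naming the field.
    """
    if level not in _LEVEL_DEFAULTS:
        raise ConfigurationError(
            f"unknown expertise level {level!r}; expected 'novice' or 'expert'"
        )
    lv = _LEVEL_DEFAULTS[level]
    dwell = {s: DwellLimits(mean=10.0, sd=3.0, min=3) for s in STATES}
    dwell[MeditationState.MIND_WANDERING] = lv["mind_wandering_dwell"]
    profile = ExpertiseProfile(
        level=level,
        noise_scale=lv["noise_scale"],
        meta_noise_scale=0.03,
        responsiveness_range=lv["responsiveness_range"],
        momentum_gamma=0.1,
        omega_base=1.0,
        dwell_limits=dwell,
        transition_threshold={s: 0.45 for s in STATES},
        suppression_factor=0.05,
        enhancement_factor=1.2,
        distraction_spike_prob=lv["distraction_spike_prob"],
        distraction_spike_range=(0.2, 0.4),
        meta_coupling_beta=_default_beta(),
    )
    if overrides:
        known = {f.name for f in fields(ExpertiseProfile)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigurationError(
                f"unknown profile fields: {sorted(unknown)}; valid: {sorted(known)}"
            )
        profile = replace(profile, **dict(overrides))
    return profile


# ---------------------------------------------------------------------------
# Packaged reference transition matrices
# ---------------------------------------------------------------------------

#: Row/column order follows ``STATES``.  Entries marked ``printed`` are
#: taken verbatim from published empirical focused-attention transition
#: statistics; ``filled`` entries complete each row to a stochastic row
#: (two unprinted targets share the remainder equally; with three unprinted
#: targets the remainder goes to mind_wandering when unprinted, otherwise it
#: is split equally).
_REFERENCE_DATA = {
    "expert": {
        "matrix": [
            [0.55, 0.10, 0.25, 0.10],
            [0.125, 0.50, 0.25, 0.125],
            [0.00, 0.20, 0.00, 0.80],
            [0.90, 0.10, 0.00, 0.00],
        ],
        "provenance": [
            ["printed", "filled", "printed", "filled"],
            ["filled", "printed", "printed", "filled"],
            ["filled", "filled", "filled", "printed"],
            ["printed", "filled", "filled", "filled"],
        ],
    },
    "novice": {
        "matrix": [
            [0.50, 0.35, 0.075, 0.075],
            [0.10, 0.70, 0.10, 0.10],
            [0.00, 0.35, 0.00, 0.65],
            [0.70, 0.20, 0.05, 0.05],
        ],
        "provenance": [
            ["printed", "printed", "filled", "filled"],
            ["filled", "printed", "filled", "filled"],
            ["filled", "filled", "filled", "printed"],
            ["printed", "printed", "filled", "filled"],
        ],
    },
}


@dataclass(frozen=True)
class ReferenceTransitionMatrix:
    """4x4 row-stochastic reference transition matrix with provenance flags."""

    level: str
    matrix: np.ndarray = field(repr=False)
    provenance: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError("reference matrix must be 4x4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("reference matrix rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    def __getitem__(self, key: tuple[MeditationState, MeditationState]) -> float:
        i, j = key
        return float(self.matrix[STATE_INDEX[i], STATE_INDEX[j]])

    def row(self, state: MeditationState) -> np.ndarray:
        return self.matrix[STATE_INDEX[state]].copy()

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "states": [s.value for s in STATES],
            "matrix": self.matrix.tolist(),
            "provenance": [list(r) for r in self.provenance],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReferenceTransitionMatrix":
        return cls(
            level=d["level"],
            matrix=np.asarray(d["matrix"], dtype=float),
            provenance=tuple(tuple(r) for r in d["provenance"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def reference_transition_matrix(level: str) -> ReferenceTransitionMatrix:
    """Return the packaged reference transition matrix for an expertise level."""
    if level not in _REFERENCE_DATA:
        raise ConfigurationError(
            f"unknown expertise level {level!r}; expected 'novice' or 'expert'"
        )
    data = _REFERENCE_DATA[level]
    return ReferenceTransitionMatrix(
        level=level,
        matrix=np.asarray(data["matrix"], dtype=float),
        provenance=tuple(tuple(r) for r in data["provenance"]),
    )
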