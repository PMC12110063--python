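"""Summary surfaces over traces.

Dwell-time (episode) statistics, state-conditioned activation summaries,
meta-awareness bands, learned-vs-reference transition comparison, and
novice/expert contrast reports.  All functions are pure: the same traces
always yield the same report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .learner import ActivationState, LearnedModel, TransitionModel
from .profiles import (
    STATES,
    STATE_INDEX,
    THOUGHTSEEDS,
    TS_INDEX,
    MeditationState,
    ReferenceTransitionMatrix,
    Thoughtseed,
    ValidationError,
)
from .simulator import SimulationTrace

__all__ = [
    "EpisodeStats",
    "ActivationSummary",
    "ContrastReport",
    "episode_durations",
    "activation_summary",
    "compare_transition_matrices",
    "contrast_report",
]

Traceable = Union[LearnedModel, SimulationTrace, Sequence[ActivationState]]


def _steps(trace: Traceable) -> list[ActivationState]:
    if isinstance(trace, LearnedModel):
        return trace.trace
    if isinstance(trace, SimulationTrace):
        return trace.steps
    return list(trace)


@dataclass
class EpisodeStats:
    """Per-state episode durations from one trace (run-length encoding)."""

    durations: dict[MeditationState, list[int]]
    transition_kind_counts: dict[str, int]
    trace_length: int
    censored_last: bool = True  # last episode ends at the trace boundary

    def mean(self, state: MeditationState) -> float | None:
        d = self.durations[state]
        return float(np.mean(d)) if d else None

    def sd(self, state: MeditationState) -> float | None:
        d = self.durations[state]
        return float(np.std(d, ddof=1)) if len(d) > 1 else None

    def count(self, state: MeditationState) -> int:
        return len(self.durations[state])

    def to_dict(self) -> dict:
        return {
            "durations": {s.value: self.durations[s] for s in STATES},
            "mean": {s.value: self.mean(s) for s in STATES},
            "sd": {s.value: self.sd(s) for s in STATES},
            "count": {s.value: self.count(s) for s in STATES},
            "transition_kind_counts": dict(self.transition_kind_counts),
            "trace_length": self.trace_length,
        }


def episode_durations(trace: Traceable, drop_censored: bool = False) -> EpisodeStats:
    """Partition a trace into maximal constant-state runs.

    The final (right-censored) episode counts as complete unless
    ``drop_censored`` is set.  Durations always sum to the trace length
    when censored episodes are kept.
    """
    steps = _steps(trace)
    if not steps:
        raise ValidationError("empty trace")
    durations: dict[MeditationState, list[int]] = {s: [] for s in STATES}
    kinds: dict[str, int] = {"natural": 0, "forced": 0}
    cur_state = steps[0].state
    run_len = 1
    for rec in steps[1:]:
        if rec.transition_kind is not None:
            kinds[rec.transition_kind] += 1
        if rec.state is cur_state:
            run_len += 1
        else:
            durations[cur_state].append(run_len)
            cur_state = rec.state
            run_len = 1
    if not drop_censored:
        durations[cur_state].append(run_len)
    return EpisodeStats(
        durations=durations,
        transition_kind_counts=kinds,
        trace_length=len(steps),
    )


@dataclass(frozen=True)
class ActivationSummary:
    """Per-thoughtseed (mean, min, max) conditioned on one state.

    ``n_steps == 0`` marks a never-visited state (empty summary, no stats).
    """

    state: MeditationState
    n_steps: int
    mean: Mapping[Thoughtseed, float] | None
    min: Mapping[Thoughtseed, float] | None
    max: Mapping[Thoughtseed, float] | None

    @property
    def empty(self) -> bool:
        return self.n_steps == 0

    def to_dict(self) -> dict:
        if self.empty:
            return {"state": self.state.value, "n_steps": 0}
        return {
            "state": self.state.value,
            "n_steps": self.n_steps,
            "mean": {ts.value: self.mean[ts] for ts in THOUGHTSEEDS},
            "min": {ts.value: self.min[ts] for ts in THOUGHTSEEDS},
            "max": {ts.value: self.max[ts] for ts in THOUGHTSEEDS},
        }


def activation_summary(trace: Traceable, state: MeditationState) -> ActivationSummary:
    """Activation statistics over the timesteps spent in ``state``."""
    steps = _steps(trace)
    rows = np.array([rec.alpha for rec in steps if rec.state is state])
    if rows.size == 0:
        return ActivationSummary(state=state, n_steps=0, mean=None, min=None, max=None)
    return ActivationSummary(
        state=state,
        n_steps=rows.shape[0],
        mean={ts: float(rows[:, i].mean()) for i, ts in enumerate(THOUGHTSEEDS)},
        min={ts: float(rows[:, i].min()) for i, ts in enumerate(THOUGHTSEEDS)},
        max={ts: float(rows[:, i].max()) for i, ts in enumerate(THOUGHTSEEDS)},
    )


def meta_awareness_summary(trace: Traceable) -> dict:
    """Mean and range of meta-awareness over a trace."""
    mus = np.array([rec.mu for rec in _steps(trace)])
    return {
        "mean": float(mus.mean()),
        "min": float(mus.min()),
        "max": float(mus.max()),
    }


def compare_transition_matrices(
    learned: TransitionModel, reference: ReferenceTransitionMatrix
) -> dict[MeditationState, float | None]:
    """Per-row total-variation distance between learned T and the reference.

    ``TV(row) = 0.5 * sum_j |T_learned[i, j] - T_ref[i, j]|``; rows the
    learner never exited are reported as ``None``.
    """
    out: dict[MeditationState, float | None] = {}
    T = learned.T
    for state in STATES:
        i = STATE_INDEX[state]
        if not learned.has_exits(state):
            out[state] = None
        else:
            out[state] = float(0.5 * np.abs(T[i] - reference.matrix[i]).sum())
    return out


@dataclass
class ContrastReport:
    """Novice/expert contrast over trace ensembles."""

    episode_stats: dict[str, list[EpisodeStats]]
    pooled_episode_mean: dict[str, dict[MeditationState, float | None]]
    activation: dict[str, dict[MeditationState, dict[Thoughtseed, float] | None]]
    meta_awareness: dict[str, dict]
    transition_divergence: dict[str, list[dict] | None]

    def to_dict(self) -> dict:
        return {
            "pooled_episode_mean": {
                lvl: {s.value: v for s, v in d.items()}
                for lvl, d in self.pooled_episode_mean.items()
            },
            "activation_mean_by_state": {
                lvl: {
                    s.value: (None if m is None else {t.value: x for t, x in m.items()})
                    for s, m in d.items()
                }
                for lvl, d in self.activation.items()
            },
            "meta_awareness": self.meta_awareness,
            "transition_divergence": {
                lvl: (
                    None
                    if divs is None
                    else [
                        {k.value if isinstance(k, MeditationState) else k: v
                         for k, v in d.items()}
                        for d in divs
                    ]
                )
                for lvl, divs in self.transition_divergence.items()
            },
            "episode_counts": {
                lvl: {
                    s.value: int(sum(es.count(s) for es in stats))
                    for s in STATES
                }
                for lvl, stats in self.episode_stats.items()
            },
        }


def pooled_episode_mean(
    stats: Iterable[EpisodeStats],
) -> dict[MeditationState, float | None]:
    """Mean episode duration per state, pooling episodes across traces."""
    pooled: dict[MeditationState, list[int]] = {s: [] for s in STATES}
    for es in stats:
        for s in STATES:
            pooled[s].extend(es.durations[s])
    return {s: (float(np.mean(d)) if d else None) for s, d in pooled.items()}


def _pooled_activation(
    traces: Sequence[Traceable],
) -> dict[MeditationState, dict[Thoughtseed, float] | None]:
    out: dict[MeditationState, dict[Thoughtseed, float] | None] = {}
    for state in STATES:
        rows = [
            rec.alpha for tr in traces for rec in _steps(tr) if rec.state is state
        ]
        if not rows:
            out[state] = None
        else:
            arr = np.array(rows)
            out[state] = {
                ts: float(arr[:, i].mean()) for i, ts in enumerate(THOUGHTSEEDS)
            }
    return out


def contrast_report(
    novice_traces: Sequence[Traceable],
    expert_traces: Sequence[Traceable],
    drop_censored: bool = False,
) -> ContrastReport:
    """Aggregate per-level summaries from trace ensembles.

    Accepts learned models or simulation traces.  When learned models are
    passed, their transition matrices are compared against the packaged
    reference for that level.
    """
    if not novice_traces or not expert_traces:
        raise ValidationError("need at least one trace per expertise level")
    ensembles = {"novice": list(novice_traces), "expert": list(expert_traces)}

    episode_stats = {
        lvl: [episode_durations(tr, drop_censored=drop_censored) for tr in traces]
        for lvl, traces in ensembles.items()
    }
    pooled = {lvl: pooled_episode_mean(stats) for lvl, stats in episode_stats.items()}
    activation = {lvl: _pooled_activation(traces) for lvl, traces in ensembles.items()}
    mu = {
        lvl: {
            "mean": float(
                np.mean([rec.mu for tr in traces for rec in _steps(tr)])
            ),
            "min": float(np.min([rec.mu for tr in traces for rec in _steps(tr)])),
            "max": float(np.max([rec.mu for tr in traces for rec in _steps(tr)])),
        }
        for lvl, traces in ensembles.items()
    }
    divergence: dict[str, list[dict] | None] = {}
    for lvl, traces in ensembles.items():
        models = [tr for tr in traces if isinstance(tr, LearnedModel)]
        if models:
            divergence[lvl] = [
                compare_transition_matrices(m.transition_model, m.reference)
                for m in models
            ]
        else:
            divergence[lvl] = None

    return ContrastReport(
        episode_stats=episode_stats,
        pooled_episode_mean=pooled,
        activation=activation,
        meta_awareness=mu,
        transition_divergence=divergence,
    )


# ---------------------------------------------------------------------------
# Optional plotting (matplotlib imported lazily)
# ---------------------------------------------------------------------------


def plot_trace(trace: Traceable, path: str) -> None:
    """Write a PNG with activation trajectories, dominance, and meta-awareness."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    steps = _steps(trace)
    t = np.array([rec.t for rec in steps])
    alpha = np.array([rec.alpha for rec in steps])
    mu = np.array([rec.mu for rec in steps])
    dom = np.array([TS_INDEX[rec.dominant] for rec in steps])
    states = np.array([STATE_INDEX[rec.state] for rec in steps])

    fig, axes = plt.subplots(4, 1, figsize=(10, 9), sharex=True)
    for i, ts in enumerate(THOUGHTSEEDS):
        axes[0].plot(t, alpha[:, i], label=ts.value, lw=1)
    axes[0].set_ylabel("activation")
    axes[0].legend(fontsize=7, ncol=3)
    axes[1].scatter(t, dom, s=4, c=dom, cmap="tab10")
    axes[1].set_yticks(range(len(THOUGHTSEEDS)))
    axes[1].set_yticklabels([ts.value for ts in THOUGHTSEEDS], fontsize=7)
    axes[1].set_ylabel("dominant")
    axes[2].plot(t, mu, color="purple", lw=1)
    axes[2].set_ylabel("meta-awareness")
    axes[3].step(t, states, where="post", lw=1)
    axes[3].set_yticks(range(len(STATES)))
    axes[3].set_yticklabels([s.value for s in STATES], fontsize=7)
    axes[3].set_ylabel("state")
    axes[3].set_xlabel("timestep (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
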