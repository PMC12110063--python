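"""Trace / network / matrix file formats shared by the CLI and library.

trace.csv columns (fixed order): t, state, dominant, mu,
alpha_breath_focus, alpha_equanimity, alpha_pain_discomfort,
alpha_pending_tasks, alpha_self_reflection, transition_kind.
Every file embeds the config hash and seed of the run that produced it
(CSV: a leading ``#`` comment line; JSON: top-level ``meta`` object).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .learner import ActivationState, LearnedModel, TransitionModel
from .network import GrangerResult, InteractionMatrix
from .profiles import (
    STATES,
    THOUGHTSEEDS,
    MeditationState,
    Thoughtseed,
)

__all__ = [
    "TRACE_COLUMNS",
    "trace_to_frame",
    "write_trace_csv",
    "read_trace_csv",
    "write_network_json",
    "write_transition_json",
    "write_weights_json",
]

TRACE_COLUMNS = (
    ["t", "state", "dominant", "mu"]
    + [f"alpha_{ts.value}" for ts in THOUGHTSEEDS]
    + ["transition_kind"]
)


def _meta_line(meta: dict | None) -> str:
    meta = meta or {}
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# {parts}\n" if parts else ""


def trace_to_frame(steps: Sequence[ActivationState]) -> pd.DataFrame:
    rows = []
    for rec in steps:
        row = {
            "t": rec.t,
            "state": rec.state.value,
            "dominant": rec.dominant.value,
            "mu": rec.mu,
        }
        for i, ts in enumerate(THOUGHTSEEDS):
            row[f"alpha_{ts.value}"] = rec.alpha[i]
        row["transition_kind"] = rec.transition_kind or ""
        rows.append(row)
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def write_trace_csv(
    steps: Sequence[ActivationState], path: str | Path, meta: dict | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_line(meta))
        trace_to_frame(steps).to_csv(fh, index=False)


def read_trace_csv(path: str | Path) -> list[ActivationState]:
    df = pd.read_csv(path, comment="#")
    steps = []
    for _, row in df.iterrows():
        alpha = np.array([row[f"alpha_{ts.value}"] for ts in THOUGHTSEEDS])
        kind = row["transition_kind"]
        steps.append(
            ActivationState(
                t=int(row["t"]),
                alpha=alpha,
                mu=float(row["mu"]),
                state=MeditationState(row["state"]),
                dominant=Thoughtseed(row["dominant"]),
                dwell=1,  # dwell is not serialized; re-derivable from states
                transition_kind=None if pd.isna(kind) or kind == "" else str(kind),
            )
        )
    return steps


def _dump(path: str | Path, payload: dict, meta: dict | None) -> None:
    payload = {"meta": meta or {}, **payload}
    Path(path).write_text(json.dumps(payload, indent=2))


def write_network_json(
    matrix: InteractionMatrix,
    results: Sequence[GrangerResult],
    path: str | Path,
    meta: dict | None = None,
) -> None:
    p_by_pair = {(r.source, r.target): r.p_value for r in results}
    edges = []
    for e in matrix.edges():
        src, tgt = Thoughtseed(e["source"]), Thoughtseed(e["target"])
        edges.append({**e, "p_value": p_by_pair.get((src, tgt))})
    _dump(
        path,
        {
            "nodes": [ts.value for ts in THOUGHTSEEDS],
            "edges": edges,
            "weights": matrix.weights.tolist(),
        },
        meta,
    )


def write_transition_json(
    tm: TransitionModel, path: str | Path, meta: dict | None = None
) -> None:
    _dump(
        path,
        {
            "states": [s.value for s in STATES],
            "matrix": tm.T.tolist(),
            "counts": tm.counts.tolist(),
            "provenance": {"n_natural": tm.n_natural, "n_forced": tm.n_forced},
        },
        meta,
    )


def write_weights_json(
    model: LearnedModel, path: str | Path, meta: dict | None = None
) -> None:
    _dump(path, model.weight_matrix.to_dict(), meta)
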