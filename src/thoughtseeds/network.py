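"""Signed thoughtseed interaction network from activation traces.

A three-stage pairwise Granger-causality pipeline: (1) lagged least-squares
autoregressions compare a restricted model (a target series on its own L
lags) against an unrestricted one (own lags plus L lags of a source
series), with significance from a chi-squared likelihood-ratio test;
(2) significant pairs receive a causal strength inversely related to the
p-value, signed by the net cross-lag coefficient, bounded to (-0.7, 0.7),
with weak connections (< 0.1) filtered; (3) causal strengths are blended
70/30 with zero-lag Pearson baseline correlations, thresholded at
|W| > 0.15, and scaled into (-0.6, 0.6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .profiles import THOUGHTSEEDS, TS_INDEX, Thoughtseed

__all__ = [
    "GrangerResult",
    "InteractionMatrix",
    "DegenerateSeriesError",
    "granger_pair",
    "calibrate_strengths",
    "baseline_correlations",
    "combine_and_scale",
    "extract_network",
    "SIGNIFICANCE_LEVEL",
    "CAUSAL_BOUND",
    "WEAK_FILTER",
    "COMBINE_CAUSAL",
    "COMBINE_BASELINE",
    "COMBINED_THRESHOLD",
    "FINAL_BOUND",
]

SIGNIFICANCE_LEVEL = 0.05
CAUSAL_BOUND = 0.7  # causal strengths bounded to (-0.7, 0.7)
WEAK_FILTER = 0.1  # |strength| below this is dropped
COMBINE_CAUSAL = 0.7  # 70/30 causal/correlation blend
COMBINE_BASELINE = 0.3
COMBINED_THRESHOLD = 0.15  # strict: |combined| <= 0.15 is zeroed
FINAL_BOUND = 0.6  # final matrix scaled into (-0.6, 0.6)


class DegenerateSeriesError(ValueError):
    """A series (or residual) has no variance; the test is undefined."""


@dataclass(frozen=True)
class GrangerResult:
    """Outcome of one directed pairwise test."""

    source: Thoughtseed
    target: Thoughtseed
    G: float
    p_value: float
    coef_sum: float  # net sum of cross-lag coefficients (carries the sign)
    max_lag: int
    strength: float = 0.0  # filled by calibrate_strengths

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target must differ")


def _lag_matrix(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Columns: series lagged by 1..max_lag, rows aligned to t = max_lag..n-1."""
    n = len(series)
    return np.column_stack([series[max_lag - l : n - l] for l in range(1, max_lag + 1)])


def granger_pair(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int = 5,
    source: Thoughtseed = Thoughtseed.BREATH_FOCUS,
    target: Thoughtseed = Thoughtseed.EQUANIMITY,
) -> GrangerResult:
    """Test whether past values of ``x`` help predict ``y``.

    Fits the restricted model (y on an intercept and its own ``max_lag``
    lags) and the unrestricted model (plus ``max_lag`` lags of x) by least
    squares.  G is the aggregate relative RSS reduction
    ``(RSS_restricted - RSS_unrestricted) / RSS_unrestricted`` across the
    pooled-lag fit; the p-value comes from the likelihood-ratio statistic
    ``n * log(RSS_r / RSS_u)`` against a chi-squared distribution with
    ``max_lag`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(y) <= 3 * max_lag:
        raise ValueError(
            f"series too short: need length > {3 * max_lag}, got {len(y)}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateSeriesError("constant series: Granger test undefined")

    yt = y[max_lag:]
    n_eff = len(yt)
    ones = np.ones((n_eff, 1))
    y_lags = _lag_matrix(y, max_lag)
    x_lags = _lag_matrix(x, max_lag)

    X_r = np.hstack([ones, y_lags])
    X_u = np.hstack([ones, y_lags, x_lags])
    beta_r, _, _, _ = np.linalg.lstsq(X_r, yt, rcond=None)
    beta_u, _, _, _ = np.linalg.lstsq(X_u, yt, rcond=None)
    rss_r = float(np.sum((yt - X_r @ beta_r) ** 2))
    rss_u = float(np.sum((yt - X_u @ beta_u) ** 2))
    if rss_u <= 1e-300 or rss_r <= 1e-300:
        raise DegenerateSeriesError("zero-variance residuals: test degenerate")

    G = max(0.0, (rss_r - rss_u) / rss_u)
    lr = n_eff * np.log(rss_r / rss_u)
    p = float(stats.chi2.sf(max(lr, 0.0), df=max_lag))
    coef_sum = float(np.sum(beta_u[1 + max_lag :]))
    return GrangerResult(
        source=source, target=target, G=G, p_value=p, coef_sum=coef_sum, max_lag=max_lag
    )


def calibrate_strengths(
    results: Sequence[GrangerResult],
    significance: float = SIGNIFICANCE_LEVEL,
    bound: float = CAUSAL_BOUND,
    weak_filter: float = WEAK_FILTER,
    mapping: str = "linear",
) -> np.ndarray:
    """Map p-values to signed causal strengths; return the 5x5 causal matrix.

    Non-significant pairs (p >= 0.05) get strength 0.  Significant pairs
    receive magnitude ``bound * (1 - p / significance)`` ("linear"; the
    "log10" alternative uses a -log10(p) normalization capped at p = 1e-10),
    monotone decreasing in p, signed by the unrestricted-model net cross-lag
    coefficient.  Magnitudes below ``weak_filter`` are zeroed.
    """
    causal = np.zeros((len(THOUGHTSEEDS), len(THOUGHTSEEDS)))
    for r in results:
        if r.p_value >= significance:
            continue
        if mapping == "linear":
            mag = bound * (1.0 - r.p_value / significance)
        elif mapping == "log10":
            lo = -np.log10(significance)
            hi = 10.0  # p = 1e-10 saturates the scale
            mag = bound * min(1.0, (-np.log10(max(r.p_value, 1e-300)) - lo) / (hi - lo))
        else:
            raise ValueError(f"unknown calibration mapping {mapping!r}")
        if mag < weak_filter:
            continue
        sign = 1.0 if r.coef_sum >= 0 else -1.0
        causal[TS_INDEX[r.source], TS_INDEX[r.target]] = sign * mag
    return causal


def baseline_correlations(alpha: np.ndarray) -> np.ndarray:
    """Zero-lag Pearson correlations between activation series, diagonal zeroed.

    ``alpha`` is a (T, 5) activation history.  A zero-variance series gets a
    zero row and column, with a warning.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape[0] < 10:
        raise ValueError("need at least 10 timesteps for baseline correlations")
    k = alpha.shape[1]
    dead = np.ptp(alpha, axis=0) == 0.0
    if dead.any():
        names = [THOUGHTSEEDS[i].value for i in np.flatnonzero(dead)]
        warnings.warn(f"zero-variance series zeroed in correlations: {names}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(alpha, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    np.fill_diagonal(corr, 0.0)
    return corr


@dataclass
class InteractionMatrix:
    """Final signed 5x5 thoughtseed influence network.

    ``weights[i, j]`` is the influence of source thoughtseed i on target j.
    Intermediate stages are retained for audit.
    """

    weights: np.ndarray
    causal: np.ndarray = field(repr=False)
    baseline: np.ndarray = field(repr=False)
    combined: np.ndarray = field(repr=False)  # 0.7*causal + 0.3*baseline, pre-threshold

    def __getitem__(self, key: tuple[Thoughtseed, Thoughtseed]) -> float:
        i, j = key
        return float(self.weights[TS_INDEX[i], TS_INDEX[j]])

    def incoming(self, alpha: np.ndarray) -> np.ndarray:
        """Sum over sources of weight * activation, per target thoughtseed."""
        return self.weights.T @ np.asarray(alpha, dtype=float)

    def edges(self) -> list[dict]:
        out = []
        for i, src in enumerate(THOUGHTSEEDS):
            for j, tgt in enumerate(THOUGHTSEEDS):
                if i != j and self.weights[i, j] != 0.0:
                    out.append(
                        {
                            "source": src.value,
                            "target": tgt.value,
                            "weight": float(self.weights[i, j]),
                        }
                    )
        return out

    def to_dict(self) -> dict:
        return {
            "thoughtseeds": [ts.value for ts in THOUGHTSEEDS],
            "weights": self.weights.tolist(),
            "causal": self.causal.tolist(),
            "baseline": self.baseline.tolist(),
            "combined": self.combined.tolist(),
        }

    @classmethod
    def zeros(cls) -> "InteractionMatrix":
        z = np.zeros((len(THOUGHTSEEDS), len(THOUGHTSEEDS)))
        return cls(z.copy(), z.copy(), z.copy(), z.copy())


def combine_and_scale(causal: np.ndarray, baseline: np.ndarray) -> InteractionMatrix:
    """Blend causal and baseline matrices, threshold, and rescale.

    ``combined = 0.7 * causal + 0.3 * baseline``; entries with
    ``|combined| <= 0.15`` are zeroed (strict threshold); surviving entries
    are rescaled by ``min(1, 0.6 / max|combined|)`` so the final magnitude
    never exceeds 0.6.  Re-applying the scaling is a no-op.
    """
    causal = np.asarray(causal, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if causal.shape != baseline.shape:
        raise ValueError("matrices must be conformable")
    combined = COMBINE_CAUSAL * causal + COMBINE_BASELINE * baseline
    np.fill_diagonal(combined, 0.0)
    weights = np.where(np.abs(combined) > COMBINED_THRESHOLD, combined, 0.0)
    max_abs = np.max(np.abs(weights))
    if max_abs > 0.0:
        weights = weights * min(1.0, FINAL_BOUND / max_abs)
    return InteractionMatrix(
        weights=weights, causal=causal.copy(), baseline=baseline.copy(), combined=combined
    )


def extract_network(
    alpha: np.ndarray,
    max_lag: int = 5,
    calibration: str = "linear",
) -> tuple[InteractionMatrix, list[GrangerResult]]:
    """Full pipeline: all 20 ordered pairwise tests, calibration, blending.

    ``alpha`` is a (T, 5) activation history in canonical thoughtseed order.
    Degenerate pairs (constant series) contribute zero causal strength.
    """
    alpha = np.asarray(alpha, dtype=float)
    results: list[GrangerResult] = []
    for i, src in enumerate(THOUGHTSEEDS):
        for j, tgt in enumerate(THOUGHTSEEDS):
            if i == j:
                continue
            try:
                r = granger_pair(
                    alpha[:, i], alpha[:, j], max_lag=max_lag, source=src, target=tgt
                )
            except DegenerateSeriesError:
                warnings.warn(f"degenerate pair {src.value}->{tgt.value}; strength 0")
                r = GrangerResult(
                    source=src, target=tgt, G=0.0, p_value=1.0, coef_sum=0.0,
                    max_lag=max_lag,
                )
            results.append(r)
    causal = calibrate_strengths(results, mapping=calibration)
    baseline = baseline_correlations(alpha)
    matrix = combine_and_scale(causal, baseline)
    results = [
        GrangerResult(
            source=r.source, target=r.target, G=r.G, p_value=r.p_value,
            coef_sum=r.coef_sum, max_lag=r.max_lag,
            strength=float(causal[TS_INDEX[r.source], TS_INDEX[r.target]]),
        )
        for r in results
    ]
    return matrix, results
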