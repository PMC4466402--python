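"""Bioclim climate-envelope model.

A site is scored by how central its environment is within the calibration
records' per-variable percentile distribution. For each variable the tail
percentile ``p = min(F(x), 1 - F(x))`` is computed from the calibration
empirical CDF and mapped to a score ``min(2p, 1)``; the site score is the
minimum over variables, and any value outside the calibration min-max scores
zero.

CDF dialect (documented, tested): with ``n`` calibration values the empirical
CDF uses the midrank convention on an ``n + 1`` denominator,

    F(x) = (#{v < x} + 0.5 * (#{v == x} + 1)) / (n + 1),

so the envelope edge is soft — a point exactly at the calibration minimum or
maximum scores ``2 / (n + 1)`` rather than 0, and the per-variable median of
an odd-sized calibration set scores exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import EnvSample

__all__ = ["BioclimModel", "fit_bioclim", "predict_bioclim"]


@dataclass
class BioclimModel:
    """Per-variable sorted calibration values (the empirical distributions)."""

    variable_names: list[str]
    calibration_values: dict[str, np.ndarray]  # each sorted ascending
    degenerate: dict[str, bool]

    @property
    def n_calibration(self) -> int:
        return len(next(iter(self.calibration_values.values())))

    def predict(self, env: EnvSample) -> np.ndarray:
        return predict_bioclim(self, env)


def fit_bioclim(calib: EnvSample) -> BioclimModel:
    """Fit the envelope: store each variable's sorted calibration values.

    Variables with fewer than 2 distinct values are flagged degenerate (their
    envelope collapses to a point) and a warning is issued; prediction still
    works via the same percentile formula.
    """
    if len(calib) < 2:
        raise ValueError("Bioclim needs at least 2 calibration records")
    values: dict[str, np.ndarray] = {}
    degenerate: dict[str, bool] = {}
    for name in calib.variable_names:
        col = np.sort(calib.column(name))
        values[name] = col
        degenerate[name] = np.unique(col).size < 2
        if degenerate[name]:
            warnings.warn(
                f"variable {name!r} is constant over the calibration data; "
                "its envelope is degenerate",
                stacklevel=2,
            )
    return BioclimModel(
        variable_names=list(calib.variable_names),
        calibration_values=values,
        degenerate=degenerate,
    )


def _variable_scores(sorted_vals: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = sorted_vals.size
    c_lt = np.searchsorted(sorted_vals, x, side="left")
    c_le = np.searchsorted(sorted_vals, x, side="right")
    c_eq = c_le - c_lt
    F = (c_lt + 0.5 * (c_eq + 1)) / (n + 1)
    p = np.minimum(F, 1.0 - F)
    score = np.clip(2.0 * p, 0.0, 1.0)
    outside = (x < sorted_vals[0]) | (x > sorted_vals[-1])
    score[outside] = 0.0
    return score


def predict_bioclim(model: BioclimModel, env: EnvSample) -> np.ndarray:
    """Score each row of ``env`` in [0, 1]; minimum over per-variable scores."""
    for name in model.variable_names:
        if name not in env.variable_names:
            raise KeyError(f"variable {name!r} missing from sample {env.variable_names}")
    scores = np.ones(len(env))
    for name in model.variable_names:
        x = np.asarray(env.column(name), dtype=np.float64)
        scores = np.minimum(scores, _variable_scores(model.calibration_values[name], x))
    return scores
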