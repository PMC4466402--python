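"""Maximum-entropy presence-background niche model with L1 regularization.

The model is the Gibbs distribution over the landscape,
``p(x) = exp(eta(x)) / Z`` with ``eta`` a linear function of environmental
features (linear and quadratic terms per variable by default, optional
pairwise products), fitted to separate the presence records from a background
sample of the study extent. Overfitting is controlled by a per-feature L1
penalty ``lambda_j = beta_multiplier * s_j / sqrt(m)`` on the presence-scale
log-likelihood, where ``s_j`` is the feature's sample standard deviation over
presences plus background and ``m`` the presence count; the "beta multiplier"
dial therefore scales the whole penalty, and large values shrink every
coefficient to exactly zero.

Fitting goes through the weighted logistic-regression contrast of presences
(weight 1) against background (weight 100 per point), whose slope estimates
converge to the Gibbs coefficients as the background weight grows; the
absolute L1 weight in that objective is ``beta_multiplier * sqrt(m)`` per
standardized feature, which is the presence-scale penalty above times ``m``.
The solver is a proximal-Newton scheme: iteratively reweighted least squares
around the current fit, each quadratic subproblem solved by cyclic coordinate
descent with soft-thresholding, with segment backtracking so the penalized
objective decreases monotonically. Convergence when the largest coefficient
change drops below 1e-6 or the objective change below 1e-9.

Outputs: ``raw`` is the Gibbs density normalized to sum to one over the
fitting background; ``logistic`` is the classic sigmoid transform
``tau * e^(eta - avg_gain) / (1 - tau + tau * e^(eta - avg_gain))`` at
``tau = 0.5``, where ``avg_gain`` is the expectation of ``eta`` under the
fitted Gibbs distribution, so a featureless model scores 0.5 everywhere.
Both outputs are monotone in ``eta`` and rank sites identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logsumexp

from .grids import EnvSample

__all__ = [
    "Feature",
    "FeatureConfig",
    "MaxentModel",
    "MaxentConvergenceError",
    "fit_maxent",
    "predict_maxent",
    "count_parameters",
    "save_maxent",
    "load_maxent",
]


class MaxentConvergenceError(RuntimeError):
    """Raised when the solver hits the iteration cap; carries the objective trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class Feature:
    kind: str  # "linear", "quadratic" or "product"
    variables: tuple[str, ...]

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return self.variables[0]
        if self.kind == "quadratic":
            return f"{self.variables[0]}^2"
        return "*".join(self.variables)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature classes to build. Defaults keep the model deliberately simple:
    linear + quadratic per variable, no products or hinges. Variables listed
    in ``linear_only`` (e.g. a binary host-presence layer, whose square is
    itself) get a linear term only."""

    linear: bool = True
    quadratic: bool = True
    products: bool = False
    linear_only: frozenset = frozenset()


def build_features(variable_names: list[str], config: FeatureConfig) -> list[Feature]:
    features: list[Feature] = []
    if config.linear:
        features += [Feature("linear", (v,)) for v in variable_names]
    if config.quadratic:
        features += [
            Feature("quadratic", (v,))
            for v in variable_names
            if v not in config.linear_only
        ]
    if config.products:
        features += [
            Feature("product", (a, b))
            for i, a in enumerate(variable_names)
            for b in variable_names[i + 1 :]
            if a not in config.linear_only and b not in config.linear_only
        ]
    if not features:
        raise ValueError("feature configuration produced no features")
    return features


def feature_matrix(
    matrix: np.ndarray, variable_names: list[str], features: list[Feature]
) -> np.ndarray:
    cols = {name: matrix[:, j] for j, name in enumerate(variable_names)}
    out = np.empty((matrix.shape[0], len(features)))
    for k, f in enumerate(features):
        for v in f.variables:
            if v not in cols:
                raise KeyError(f"variable {v!r} required by feature {f.name!r} is missing")
        if f.kind == "linear":
            out[:, k] = cols[f.variables[0]]
        elif f.kind == "quadratic":
            out[:, k] = cols[f.variables[0]] ** 2
        else:
            out[:, k] = cols[f.variables[0]] * cols[f.variables[1]]
    return out


@dataclass
class MaxentModel:
    variable_names: list[str]
    features: list[Feature]
    coefficients: np.ndarray  # per standardized feature; exact zeros possible
    feature_means: np.ndarray
    feature_scales: np.ndarray
    beta_multiplier: float
    linear_predictor_normalizer: float  # log partition over the fit background
    avg_gain: float  # E[eta] under the fitted Gibbs distribution
    n_presence: int
    background_reference: EnvSample | None = None
    background_hash: str = ""
    variable_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def linear_predictor(self, env: EnvSample) -> np.ndarray:
        raw_feats = feature_matrix(
            np.column_stack([env.column(v) for v in self.variable_names]),
            self.variable_names,
            self.features,
        )
        z = (raw_feats - self.feature_means) / self.feature_scales
        return z @ self.coefficients

    def predict(self, env: EnvSample, output: str = "logistic") -> np.ndarray:
        return predict_maxent(self, env, output=output)


def _hash_matrix(matrix: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(matrix).tobytes()).hexdigest()[:16]


def _soft_threshold(u: float, lam: float) -> float:
    if u > lam:
        return u - lam
    if u < -lam:
        return u + lam
    return 0.0


def _penalty(beta: np.ndarray, lam: np.ndarray) -> float:
    nz = beta != 0
    return float(np.sum(lam[nz] * np.abs(beta[nz]))) if nz.any() else 0.0


def _objective(eta: np.ndarray, y: np.ndarray, w: np.ndarray,
               beta: np.ndarray, lam: np.ndarray) -> float:
    loss = float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))
    return loss + _penalty(beta, lam)


def _fit_weighted_l1_logistic(
    Z: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: np.ndarray,
    max_iter: int,
    tol_coef: float,
    tol_obj: float,
) -> tuple[float, np.ndarray, list[float], int]:
    """Minimize sum_i w_i * logistic_loss(eta_i) + sum_j lam_j |beta_j|.

    Prox-Newton with a cyclic coordinate-descent inner solver and segment
    backtracking; the intercept is unpenalized. Features with infinite lam
    (degenerate) are pinned at zero. Returns (intercept, beta, trace, iters).
    """
    n, p = Z.shape
    Z2 = Z * Z
    active = np.isfinite(lam)
    py = float(np.sum(w * y) / np.sum(w))
    py = min(max(py, 1e-12), 1 - 1e-12)
    beta0 = float(np.log(py / (1 - py)))
    beta = np.zeros(p)
    lam_eff = np.where(active, lam, 0.0)  # inactive handled by pinning
    eta = np.full(n, beta0)
    obj = _objective(eta, y, w, beta, lam_eff)
    trace = [obj]

    for outer in range(1, max_iter + 1):
        mu = expit(eta)
        wt = np.maximum(w * mu * (1.0 - mu), 1e-12)
        r = w * (y - mu) / wt  # working residual at the current fit
        H = wt @ Z2
        H0 = float(np.sum(wt))
        b0_new = beta0
        b_new = beta.copy()
        for _cycle in range(200):
            delta_max = 0.0
            for j in range(p):
                if not active[j]:
                    continue
                g = float(Z[:, j] @ (wt * r))
                u = H[j] * b_new[j] + g
                bj = _soft_threshold(u, lam[j]) / H[j]
                d = bj - b_new[j]
                if d != 0.0:
                    r = r - Z[:, j] * d
                    b_new[j] = bj
                    delta_max = max(delta_max, abs(d))
            d0 = float(np.sum(wt * r)) / H0
            if d0 != 0.0:
                b0_new += d0
                r = r - d0
                delta_max = max(delta_max, abs(d0))
            if delta_max < 1e-9:
                break

        # backtrack along the segment to the subproblem solution
        t = 1.0
        while True:
            b0_c = beta0 + t * (b0_new - beta0)
            b_c = beta + t * (b_new - beta)
            eta_c = b0_c + Z @ b_c
            obj_c = _objective(eta_c, y, w, b_c, lam_eff)
            if obj_c <= obj + 1e-12 or t < 1e-10:
                break
            t *= 0.5
        if obj_c > obj:  # no descent possible: we are at the optimum
            trace.append(obj)
            return beta0, beta, trace, outer

        delta_coef = max(float(np.max(np.abs(b_c - beta), initial=0.0)),
                         abs(b0_c - beta0))
        obj_drop = obj - obj_c
        beta0, beta, eta, obj = b0_c, b_c, eta_c, obj_c
        trace.append(obj)
        if delta_coef < tol_coef or obj_drop < tol_obj:
            return beta0, beta, trace, outer

    raise MaxentConvergenceError(
        f"no convergence after {max_iter} iterations "
        f"(last objective {trace[-1]:.10g})",
        trace,
    )


def fit_maxent(
    presences: EnvSample,
    background: EnvSample,
    beta_multiplier: float = 2.0,
    feature_config: FeatureConfig | None = None,
    *,
    background_weight: float = 100.0,
    max_iter: int = 500,
    tol_coef: float = 1e-6,
    tol_obj: float = 1e-9,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    ``presences`` and ``background`` must carry the same variables (background
    columns are aligned to the presence order by name). Constant features are
    flagged degenerate, warned about, and pinned at coefficient zero rather
    than rejected — synthetic configurations legitimately include inert decoy
    variables.
    """
    if beta_multiplier <= 0:
        raise ValueError("beta_multiplier must be positive")
    m = len(presences)
    if m < 2:
        raise ValueError("need at least 2 presence records")
    if len(background) == 0:
        raise ValueError("background sample is empty")
    if set(background.variable_names) != set(presences.variable_names):
        raise ValueError(
            "presence and background samples carry different variables: "
            f"{presences.variable_names} vs {background.variable_names}"
        )
    var_names = list(presences.variable_names)
    bg_matrix = np.column_stack([background.column(v) for v in var_names])

    config = feature_config or FeatureConfig()
    features = build_features(var_names, config)
    Fp = feature_matrix(presences.matrix, var_names, features)
    Fb = feature_matrix(bg_matrix, var_names, features)
    A = np.vstack([Fp, Fb])
    means = A.mean(axis=0)
    scales = A.std(axis=0)
    degenerate = scales == 0.0
    if degenerate.any():
        bad = [features[j].name for j in np.nonzero(degenerate)[0]]
        warnings.warn(
            f"degenerate (constant) features pinned at zero: {bad}", stacklevel=2
        )
    scales = np.where(degenerate, 1.0, scales)
    Z = (A - means) / scales

    y = np.concatenate([np.ones(m), np.zeros(len(background))])
    w = np.concatenate([np.ones(m), np.full(len(background), background_weight)])
    # s_j = 1 after standardization; presence-scale penalty beta/sqrt(m) times m
    lam = np.full(len(features), beta_multiplier * np.sqrt(m))
    lam[degenerate] = np.inf

    beta0, coef, trace, iters = _fit_weighted_l1_logistic(
        Z, y, w, lam, max_iter=max_iter, tol_coef=tol_coef, tol_obj=tol_obj
    )

    Zb = (Fb - means) / scales
    eta_bg = Zb @ coef
    log_partition = float(logsumexp(eta_bg))
    p_bg = np.exp(eta_bg - log_partition)
    avg_gain = float(p_bg @ eta_bg)

    var_matrix = np.vstack([presences.matrix, bg_matrix])
    ranges = {
        v: (float(var_matrix[:, j].min()), float(var_matrix[:, j].max()))
        for j, v in enumerate(var_names)
    }

    return MaxentModel(
        variable_names=var_names,
        features=features,
        coefficients=coef,
        feature_means=means,
        feature_scales=scales,
        beta_multiplier=float(beta_multiplier),
        linear_predictor_normalizer=log_partition,
        avg_gain=avg_gain,
        n_presence=m,
        background_reference=background,
        background_hash=_hash_matrix(bg_matrix),
        variable_ranges=ranges,
        objective_trace=trace,
        n_iterations=iters,
    )


def predict_maxent(model: MaxentModel, env: EnvSample, output: str = "logistic") -> np.ndarray:
    """Predict suitability scores for the rows of ``env``.

    ``raw`` is the Gibbs density standardized over the fitting background
    (raw scores over the background reference sum to 1); ``logistic`` is the
    sigmoid of ``eta - avg_gain`` (tau = 0.5). The two are monotone transforms
    of each other.
    """
    eta = model.linear_predictor(env)
    if output == "raw":
        return np.exp(eta - model.linear_predictor_normalizer)
    if output == "logistic":
        return expit(eta - model.avg_gain)
    raise ValueError(f"unknown output type {output!r} (use 'raw' or 'logistic')")


def count_parameters(model: MaxentModel) -> int:
    """Number of features with nonzero coefficient (the k that feeds AICc)."""
    return int(np.count_nonzero(model.coefficients))


# ---------------------------------------------------------------------------
# Serialization: plain JSON, exact reload (background kept only as a hash)
# ---------------------------------------------------------------------------


def save_maxent(model: MaxentModel, path: str | Path) -> None:
    payload = {
        "format": "paleosdm-maxent-1",
        "variable_names": model.variable_names,
        "features": [{"kind": f.kind, "variables": list(f.variables)} for f in model.features],
        "coefficients": model.coefficients.tolist(),
        "feature_means": model.feature_means.tolist(),
        "feature_scales": model.feature_scales.tolist(),
        "beta_multiplier": model.beta_multiplier,
        "linear_predictor_normalizer": model.linear_predictor_normalizer,
        "avg_gain": model.avg_gain,
        "n_presence": model.n_presence,
        "background_hash": model.background_hash,
        "variable_ranges": {k: list(v) for k, v in model.variable_ranges.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_maxent(path: str | Path) -> MaxentModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "paleosdm-maxent-1":
        raise ValueError(f"{path} is not a serialized maxent model")
    return MaxentModel(
        variable_names=list(payload["variable_names"]),
        features=[Feature(f["kind"], tuple(f["variables"])) for f in payload["features"]],
        coefficients=np.array(payload["coefficients"], dtype=np.float64),
        feature_means=np.array(payload["feature_means"], dtype=np.float64),
        feature_scales=np.array(payload["feature_scales"], dtype=np.float64),
        beta_multiplier=float(payload["beta_multiplier"]),
        linear_predictor_normalizer=float(payload["linear_predictor_normalizer"]),
        avg_gain=float(payload["avg_gain"]),
        n_presence=int(payload["n_presence"]),
        background_reference=None,
        background_hash=str(payload["background_hash"]),
        variable_ranges={k: (v[0], v[1]) for k, v in payload["variable_ranges"].items()},
    )
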