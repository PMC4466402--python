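"""Model evaluation and selection for presence-only niche models.

Covers the discrimination and selection statistics the workflow needs:
rank-based AUC at prevalence 0.5 (equal presence and pseudo-absence counts,
enforced structurally upstream), the threshold maximizing sensitivity +
specificity (maxSSS), omission rate, small-sample AIC (AICc) on landscape-
standardized Gibbs densities, relative likelihoods, and the two
variable-importance measures reported for maximum-entropy models.

One binary convention holds throughout the package: a site is predicted
suitable iff its score is >= the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .grids import EnvSample

__all__ = [
    "ThresholdResult",
    "EvaluationReport",
    "ModelComparison",
    "ContributionResult",
    "auc",
    "max_sss_threshold",
    "omission_rate",
    "aicc",
    "relative_likelihood",
    "permutation_importance",
    "variable_contribution",
]


@dataclass(frozen=True)
class ThresholdResult:
    """A suitability cutoff with the sensitivity/specificity attained at it."""

    threshold: float
    sensitivity: float
    specificity: float

    @property
    def objective(self) -> float:
        return self.sensitivity + self.specificity


@dataclass
class EvaluationReport:
    """One fitted model's evaluation summary (the Tables 1-3 shape)."""

    model_label: str
    train_auc: float
    test_auc: float | None
    omission_rate: float | None
    threshold: ThresholdResult | None
    n_occurrences: int
    k_parameters: int | None
    aicc: float | None
    variable_contribution: dict[str, float] = field(default_factory=dict)
    permutation_importance: dict[str, float] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"Model: {self.model_label}", "Model training"]
        lines.append(f"  Training occurrences\t{self.n_occurrences}")
        lines.append(f"  Training AUC\t{self.train_auc:.3f}")
        if self.k_parameters is not None:
            lines.append(f"  Nonzero parameters (k)\t{self.k_parameters}")
        if self.aicc is not None:
            lines.append(f"  AICc\t{self.aicc:.3f}")
        if self.variable_contribution:
            lines.append("Individual contribution of the variables")
            for v, pct in self.variable_contribution.items():
                lines.append(f"  {v}\t{pct:.3f}")
        if self.permutation_importance:
            lines.append("Permutation importance of the variables")
            for v, pct in self.permutation_importance.items():
                lines.append(f"  {v}\t{pct:.3f}")
        lines.append("Model testing")
        if self.test_auc is not None:
            lines.append(f"  Testing AUC\t{self.test_auc:.3f}")
        if self.omission_rate is not None:
            lines.append(f"  Omission rate\t{self.omission_rate:.3f}")
        if self.threshold is not None:
            lines.append(f"  maxSSS threshold\t{self.threshold.threshold:.4f}")
        return "\n".join(lines)


@dataclass
class ModelComparison:
    """AICc-based comparison across candidate models."""

    model_labels: list[str]
    aicc_values: list[float | None]
    delta_aicc: list[float | None] = field(init=False)
    relative_likelihoods: list[float | None] = field(init=False)

    def __post_init__(self) -> None:
        defined = [a for a in self.aicc_values if a is not None]
        if not defined:
            raise ValueError("no defined AICc values to compare")
        best = min(defined)
        self.delta_aicc = [None if a is None else a - best for a in self.aicc_values]
        self.relative_likelihoods = [
            None if d is None else math.exp(-d / 2.0) for d in self.delta_aicc
        ]

    @property
    def best_label(self) -> str:
        for label, d in zip(self.model_labels, self.delta_aicc):
            if d == 0.0:
                return label
        raise AssertionError("unreachable: some delta is 0 by construction")

    def to_text(self) -> str:
        lines = ["Model comparison (AICc)"]
        for label, a, d, rl in zip(
            self.model_labels, self.aicc_values, self.delta_aicc, self.relative_likelihoods
        ):
            if a is None:
                lines.append(f"  {label}\tAICc undefined")
            else:
                lines.append(f"  {label}\tAICc={a:.3f}\tdelta={d:.3f}\trel.lik={rl:.6g}")
        return "\n".join(lines)


def auc(presence_scores, absence_scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    p = np.asarray(presence_scores, dtype=np.float64)
    a = np.asarray(absence_scores, dtype=np.float64)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([p, a]))
    r1 = ranks[: p.size].sum()
    return float((r1 - p.size * (p.size + 1) / 2.0) / (p.size * a.size))


def max_sss_threshold(presence_scores, absence_scores) -> ThresholdResult:
    """Threshold maximizing sensitivity + specificity under the rule
    "suitable iff score >= threshold".

    Candidates are the midpoints between consecutive distinct pooled scores
    plus -inf/+inf sentinels; ties among maxima break toward the lowest
    threshold.
    """
    p = np.asarray(presence_scores, dtype=np.float64)
    a = np.asarray(absence_scores, dtype=np.float64)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be nonempty")
    pooled = np.unique(np.concatenate([p, a]))
    candidates = np.concatenate(
        [[-np.inf], (pooled[:-1] + pooled[1:]) / 2.0, [np.inf]]
    )
    best: ThresholdResult | None = None
    for thr in candidates:
        sens = float(np.mean(p >= thr))
        spec = float(np.mean(a < thr))
        if best is None or sens + spec > best.objective + 1e-12:
            best = ThresholdResult(float(thr), sens, spec)
    assert best is not None
    return best


def omission_rate(test_presence_scores, threshold: float | ThresholdResult) -> float:
    """Fraction of test presences predicted unsuitable (score < threshold)."""
    scores = np.asarray(test_presence_scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("presence score list must be nonempty")
    thr = threshold.threshold if isinstance(threshold, ThresholdResult) else float(threshold)
    return float(np.mean(scores < thr))


def aicc(occurrence_probs, k: int, n: int | None = None) -> float | None:
    """Small-sample AIC from landscape-standardized occurrence densities.

    ``occurrence_probs`` are the model's raw (Gibbs) scores at the occurrence
    sites after renormalization to sum to one over the prediction extent's
    valid cells; ``k`` is the number of nonzero coefficients. Returns None
    (undefined) when n <= k + 1, or when any occurrence has zero density
    (the site lies outside the model's support).
    """
    probs = np.asarray(occurrence_probs, dtype=np.float64)
    if n is None:
        n = probs.size
    if probs.size == 0:
        raise ValueError("need at least one occurrence score")
    if np.any(probs <= 0):
        return None
    if n <= k + 1:
        return None
    log_l = float(np.sum(np.log(probs)))
    aic = 2.0 * k - 2.0 * log_l
    return aic + (2.0 * k * (k + 1)) / (n - k - 1)


def relative_likelihood(aicc_values) -> list[float | None]:
    """exp((AICc_min - AICc_j) / 2) per model; undefined entries propagate."""
    values = list(aicc_values)
    defined = [a for a in values if a is not None]
    if len(defined) < 2:
        raise ValueError("need at least 2 defined AICc values")
    best = min(defined)
    return [None if a is None else math.exp((best - a) / 2.0) for a in values]


def _normalize_to_100(raw: dict[str, float]) -> dict[str, float]:
    total = sum(raw.values())
    if total <= 0:
        return {v: 0.0 for v in raw}
    return {v: 100.0 * x / total for v, x in raw.items()}


def permutation_importance(
    model,
    presences: EnvSample,
    background: EnvSample,
    seed: int = 0,
    n_reps: int = 10,
) -> dict[str, float]:
    """Per-variable permutation importance, normalized to sum 100.

    For each variable, its values are permuted jointly across presences and
    background, the training AUC recomputed, and the mean AUC drop over
    ``n_reps`` permutations (floored at zero) taken as that variable's raw
    importance. ``model`` may be any fitted model exposing
    ``predict(EnvSample)``.
    """
    rng = np.random.default_rng(seed)
    var_names = list(presences.variable_names)
    combined = np.vstack(
        [presences.matrix, np.column_stack([background.column(v) for v in var_names])]
    )
    m = len(presences)
    base = auc(model.predict(presences), model.predict(background))
    drops: dict[str, float] = {}
    for j, var in enumerate(var_names):
        acc = 0.0
        for _ in range(n_reps):
            perm = combined.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            sample = EnvSample(
                point_ids=list(range(perm.shape[0])), matrix=perm, variable_names=var_names
            )
            scores = model.predict(sample)
            acc += base - auc(scores[:m], scores[m:])
        drops[var] = max(acc / n_reps, 0.0)
    return _normalize_to_100(drops)


@dataclass
class ContributionResult:
    percent: dict[str, float]
    degenerate: bool  # True when every coefficient is zero


def variable_contribution(model) -> ContributionResult:
    """Per-variable share of summed |coefficient| over standardized features.

    A declared surrogate for the training-path "percent contribution"
    bookkeeping of the reference maximum-entropy implementation: each
    variable's score is the sum of absolute standardized coefficients over
    its features (product features split evenly between their two variables),
    normalized to 100. Invariant to rescaling any raw input variable.
    """
    raw = {v: 0.0 for v in model.variable_names}
    for f, c in zip(model.features, model.coefficients):
        share = abs(float(c)) / len(f.variables)
        for v in f.variables:
            raw[v] += share
    total = sum(raw.values())
    return ContributionResult(percent=_normalize_to_100(raw), degenerate=total == 0.0)
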