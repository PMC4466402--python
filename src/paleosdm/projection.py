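"""Projection onto climate scenarios, hindcast ensembles, and range stability.

A fitted niche model is projected cell-wise onto an environmental stack
(current climate or a glacial reconstruction), glacial projections from
different circulation models are ensemble-averaged *before* thresholding,
continuous suitability is binarized with the maxSSS threshold, and the binary
maps for two periods are classified into never / stable / lost / gained cells
— the 21-kyr range-stability summary. The host-parasite machinery lives here
too: turning a host's binary map into a 0/1 predictor layer, measuring
host-parasite range overlap change between scenarios, and the end-to-end
with/without-host model comparison.

Integer codes on disk and in arrays: 0 never/unsuitable, 1 stable/suitable,
2 lost, 3 gained; nodata cells carry -1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .evaluation import (
    EvaluationReport,
    ModelComparison,
    ThresholdResult,
    auc,
    aicc,
    max_sss_threshold,
    omission_rate,
    permutation_importance,
    variable_contribution,
)
from .filtering import sample_background, sample_pseudoabsences
from .grids import EnvSample, EnvStack, GridSpec, OccurrenceSet, Raster, extract_values
from .maxent import (
    FeatureConfig,
    MaxentModel,
    count_parameters,
    fit_maxent,
    predict_maxent,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NODATA_CODE",
    "CODE_NEVER",
    "CODE_STABLE",
    "CODE_LOST",
    "CODE_GAINED",
    "BinaryMap",
    "StabilityMap",
    "OverlapChange",
    "ComparisonSettings",
    "HostComparisonResult",
    "project",
    "ensemble_average",
    "binarize",
    "stability_classify",
    "overlap_change",
    "host_predictor_layer",
    "compare_with_without_host",
]

NODATA_CODE = -1
CODE_NEVER = 0
CODE_STABLE = 1
CODE_LOST = 2
CODE_GAINED = 3


@dataclass
class BinaryMap:
    """Suitable (1) / unsuitable (0) per cell; nodata cells are -1."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("values shape does not match grid")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != NODATA_CODE

    @property
    def suitable_mask(self) -> np.ndarray:
        return self.values == 1

    @property
    def n_suitable(self) -> int:
        return int(self.suitable_mask.sum())

    def to_raster(self, name: str = "binary") -> Raster:
        spec = GridSpec(
            self.spec.n_rows, self.spec.n_cols, self.spec.x_origin,
            self.spec.y_origin, self.spec.cell_size, nodata_value=float(NODATA_CODE),
        )
        return Raster(spec, self.values.astype(np.float64), name)


@dataclass
class StabilityMap:
    """Range-change classification between two periods.

    Codes: 0 never suitable, 1 stable, 2 lost since the past period,
    3 gained since the past period; -1 nodata.
    """

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("values shape does not match grid")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != NODATA_CODE

    def counts(self) -> dict[str, int]:
        v = self.values
        return {
            "never": int(np.sum(v == CODE_NEVER)),
            "stable": int(np.sum(v == CODE_STABLE)),
            "lost": int(np.sum(v == CODE_LOST)),
            "gained": int(np.sum(v == CODE_GAINED)),
        }

    def to_raster(self, name: str = "stability") -> Raster:
        spec = GridSpec(
            self.spec.n_rows, self.spec.n_cols, self.spec.x_origin,
            self.spec.y_origin, self.spec.cell_size, nodata_value=float(NODATA_CODE),
        )
        return Raster(spec, self.values.astype(np.float64), name)


def project(model, stack: EnvStack, output: str = "logistic") -> Raster:
    """Cell-wise prediction of a fitted model over a scenario stack.

    Masked cells stay masked. No clamping: values beyond the model's training
    range extrapolate, and the number of extrapolating cells is logged.
    """
    rows, cols = stack.valid_cells()
    matrix = stack.matrix_at_cells(rows, cols)
    env = EnvSample(
        point_ids=list(range(rows.size)),
        matrix=matrix,
        variable_names=stack.layer_names,
        cell_rows=rows,
        cell_cols=cols,
    )
    if isinstance(model, MaxentModel):
        scores = predict_maxent(model, env, output=output)
        ranges = model.variable_ranges
        if ranges:
            extrapolating = np.zeros(rows.size, dtype=bool)
            for v, (lo, hi) in ranges.items():
                if v in env.variable_names:
                    x = env.column(v)
                    extrapolating |= (x < lo) | (x > hi)
            n_out = int(extrapolating.sum())
            if n_out:
                logger.info(
                    "project: %d of %d cells extrapolate beyond the training range "
                    "on scenario %r", n_out, rows.size, stack.scenario_name,
                )
    else:
        scores = model.predict(env)
    spec = stack.spec
    out = np.full((spec.n_rows, spec.n_cols), spec.nodata_value)
    out[rows, cols] = scores
    return Raster(spec, out, name=f"suitability_{stack.scenario_name}")


def ensemble_average(predictions: list[Raster]) -> Raster:
    """Cell-wise arithmetic mean of continuous predictions (e.g. over the
    circulation-model reconstructions). Averaging precedes thresholding."""
    if not predictions:
        raise ValueError("need at least one prediction to average")
    first = predictions[0]
    for r in predictions[1:]:
        if not r.spec.aligned_with(first.spec):
            raise ValueError("ensemble members are not aligned")
    mask = np.ones_like(first.values, dtype=bool)
    for r in predictions:
        mask &= r.valid_mask
    acc = np.zeros_like(first.values)
    for r in predictions:
        acc += r.values
    acc /= len(predictions)
    acc[~mask] = first.spec.nodata_value
    return Raster(first.spec, acc, name="ensemble_mean")


def binarize(suitability: Raster, threshold: float | ThresholdResult) -> BinaryMap:
    """Suitable iff score >= threshold; mask preserved."""
    thr = threshold.threshold if isinstance(threshold, ThresholdResult) else float(threshold)
    valid = suitability.valid_mask
    out = np.full(suitability.values.shape, NODATA_CODE, dtype=np.int8)
    out[valid] = (suitability.values[valid] >= thr).astype(np.int8)
    return BinaryMap(suitability.spec, out)


def stability_classify(past: BinaryMap, present: BinaryMap) -> StabilityMap:
    """Classify each cell: stable (both), lost (past only), gained (present
    only), never (neither). The four categories partition the valid cells."""
    if not past.spec.aligned_with(present.spec):
        raise ValueError("past and present maps are not aligned")
    valid = past.valid_mask & present.valid_mask
    out = np.full(past.values.shape, NODATA_CODE, dtype=np.int8)
    p, q = past.values == 1, present.values == 1
    out[valid & p & q] = CODE_STABLE
    out[valid & p & ~q] = CODE_LOST
    out[valid & ~p & q] = CODE_GAINED
    out[valid & ~p & ~q] = CODE_NEVER
    return StabilityMap(past.spec, out)


@dataclass(frozen=True)
class OverlapChange:
    """Host-parasite range overlap per scenario and its change.

    Overlap is the fraction of the parasite's suitable cells where the host
    is also suitable (the parasite-centric quantity: where can the parasite
    find its host). ``change_percent`` is |present - past| x 100.
    """

    overlap_past: float | None
    overlap_present: float | None
    change_percent: float | None

    @property
    def defined(self) -> bool:
        return self.change_percent is not None


def _overlap(parasite: BinaryMap, host: BinaryMap) -> float | None:
    para = parasite.suitable_mask
    n_para = int(para.sum())
    if n_para == 0:
        return None
    return float(np.sum(para & host.suitable_mask) / n_para)


def overlap_change(
    parasite_past: BinaryMap,
    host_past: BinaryMap,
    parasite_present: BinaryMap,
    host_present: BinaryMap,
) -> OverlapChange:
    for other in (host_past, parasite_present, host_present):
        if not parasite_past.spec.aligned_with(other.spec):
            raise ValueError("overlap maps are not aligned")
    past = _overlap(parasite_past, host_past)
    present = _overlap(parasite_present, host_present)
    change = None if past is None or present is None else abs(present - past) * 100.0
    return OverlapChange(past, present, change)


def host_predictor_layer(host_map: BinaryMap, name: str = "host") -> Raster:
    """0/1 predictor layer from a host binary map, nodata preserved.

    One layer is built per scenario so hindcasts of the parasite use the
    host's scenario-matched prediction.
    """
    vals = np.where(host_map.valid_mask, host_map.values.astype(np.float64), np.nan)
    spec = host_map.spec
    out = np.where(np.isnan(vals), spec.nodata_value, vals)
    valid_vals = out[host_map.valid_mask]
    if valid_vals.size and (valid_vals == valid_vals[0]).all():
        warnings.warn(
            "host predictor layer has zero variance over the extent", stacklevel=2
        )
    full_spec = GridSpec(
        spec.n_rows, spec.n_cols, spec.x_origin, spec.y_origin,
        spec.cell_size, nodata_value=spec.nodata_value,
    )
    return Raster(full_spec, out, name=name)


@dataclass(frozen=True)
class ComparisonSettings:
    """Settings for the with/without-host model comparison."""

    beta_multiplier: float = 2.0
    n_background: int = 10_000
    seed: int = 0
    host_layer_name: str = "host"
    permutation_reps: int = 10


@dataclass
class HostComparisonResult:
    comparison: ModelComparison
    report_climate: EvaluationReport
    report_with_host: EvaluationReport
    model_climate: MaxentModel
    model_with_host: MaxentModel
    lost_by_host_map: BinaryMap  # suitable under climate-only, unsuitable with host


def _landscape_probs(model: MaxentModel, stack: EnvStack, occ_env: EnvSample) -> np.ndarray:
    """Occurrence densities standardized over the scenario's valid cells."""
    rows, cols = stack.valid_cells()
    cells = EnvSample(
        point_ids=list(range(rows.size)),
        matrix=stack.matrix_at_cells(rows, cols),
        variable_names=stack.layer_names,
    )
    eta_cells = model.linear_predictor(cells)
    eta_occ = model.linear_predictor(occ_env)
    shift = eta_cells.max()
    z = np.exp(eta_cells - shift).sum()
    return np.exp(eta_occ - shift) / z


def _evaluate(
    label: str,
    model: MaxentModel,
    stack: EnvStack,
    calib_env: EnvSample,
    bg_env: EnvSample,
    test_env: EnvSample | None,
    pseudo_env: EnvSample | None,
    settings: ComparisonSettings,
) -> tuple[EvaluationReport, float | None, ThresholdResult]:
    train_scores = predict_maxent(model, calib_env)
    bg_scores = predict_maxent(model, bg_env)
    train_auc = auc(train_scores, bg_scores)
    if test_env is not None and pseudo_env is not None:
        test_scores = predict_maxent(model, test_env)
        pseudo_scores = predict_maxent(model, pseudo_env)
        test_auc = auc(test_scores, pseudo_scores)
        thr = max_sss_threshold(test_scores, pseudo_scores)
        omission = omission_rate(test_scores, thr)
    else:
        test_auc = None
        thr = max_sss_threshold(train_scores, bg_scores)
        omission = None
    k = count_parameters(model)
    probs = _landscape_probs(model, stack, calib_env)
    aicc_value = aicc(probs, k=k, n=len(calib_env))
    report = EvaluationReport(
        model_label=label,
        train_auc=train_auc,
        test_auc=test_auc,
        omission_rate=omission,
        threshold=thr,
        n_occurrences=len(calib_env),
        k_parameters=k,
        aicc=aicc_value,
        variable_contribution=variable_contribution(model).percent,
        permutation_importance=permutation_importance(
            model, calib_env, bg_env, seed=settings.seed, n_reps=settings.permutation_reps
        ),
    )
    return report, aicc_value, thr


def compare_with_without_host(
    parasite_occ: OccurrenceSet,
    climate_stack: EnvStack,
    host_layer: Raster,
    settings: ComparisonSettings | None = None,
    testing_occ: OccurrenceSet | None = None,
) -> HostComparisonResult:
    """Fit and compare the parasite's climate-only and climate-plus-host models.

    Both models use identical occurrences, identical background cells and the
    same seeds; they differ only by the binary host-presence layer, which
    enters as a linear feature. Returns the AICc comparison, both evaluation
    reports, and the map of cells suitable under climate-only but unsuitable
    once the host is included.
    """
    settings = settings or ComparisonSettings()
    host_named = Raster(host_layer.spec, host_layer.values, settings.host_layer_name)
    stack_with_host = EnvStack(
        climate_stack.layers + [host_named],
        scenario_name=climate_stack.scenario_name,
    )

    extr_climate = extract_values(climate_stack, parasite_occ)
    extr_host = extract_values(stack_with_host, parasite_occ)
    if extr_climate.kept_indices != extr_host.kept_indices:
        # the host layer may mask extra cells; keep the common subset
        common = sorted(set(extr_climate.kept_indices) & set(extr_host.kept_indices))
        occ_common = parasite_occ.subset(common, role=parasite_occ.role)
        extr_climate = extract_values(climate_stack, occ_common)
        extr_host = extract_values(stack_with_host, occ_common)

    bg_with_host = sample_background(stack_with_host, settings.n_background, settings.seed)
    bg_climate = EnvSample(
        point_ids=bg_with_host.point_ids,
        matrix=climate_stack.matrix_at_cells(bg_with_host.cell_rows, bg_with_host.cell_cols),
        variable_names=climate_stack.layer_names,
        cell_rows=bg_with_host.cell_rows,
        cell_cols=bg_with_host.cell_cols,
    )

    model_climate = fit_maxent(
        extr_climate.sample, bg_climate, beta_multiplier=settings.beta_multiplier
    )
    model_host = fit_maxent(
        extr_host.sample,
        bg_with_host,
        beta_multiplier=settings.beta_multiplier,
        feature_config=FeatureConfig(linear_only=frozenset({settings.host_layer_name})),
    )

    test_climate = pseudo_climate = test_host = pseudo_host = None
    if testing_occ is not None and len(testing_occ) > 0:
        t_climate = extract_values(climate_stack, testing_occ)
        t_host = extract_values(stack_with_host, testing_occ)
        common = sorted(set(t_climate.kept_indices) & set(t_host.kept_indices))
        if common:
            occ_t = testing_occ.subset(common, role="testing")
            test_climate = extract_values(climate_stack, occ_t).sample
            test_host = extract_values(stack_with_host, occ_t).sample
            pa = sample_pseudoabsences(stack_with_host, len(occ_t), settings.seed + 1)
            pseudo_host = pa
            pseudo_climate = EnvSample(
                point_ids=pa.point_ids,
                matrix=climate_stack.matrix_at_cells(pa.cell_rows, pa.cell_cols),
                variable_names=climate_stack.layer_names,
                cell_rows=pa.cell_rows,
                cell_cols=pa.cell_cols,
            )

    report_climate, aicc_climate, thr_climate = _evaluate(
        "climate_only", model_climate, climate_stack, extr_climate.sample,
        bg_climate, test_climate, pseudo_climate, settings,
    )
    report_host, aicc_host, thr_host = _evaluate(
        "climate_plus_host", model_host, stack_with_host, extr_host.sample,
        bg_with_host, test_host, pseudo_host, settings,
    )

    comparison = ModelComparison(
        model_labels=["climate_only", "climate_plus_host"],
        aicc_values=[aicc_climate, aicc_host],
    )

    map_climate = binarize(project(model_climate, climate_stack), thr_climate)
    map_host = binarize(project(model_host, stack_with_host), thr_host)
    valid = map_climate.valid_mask & map_host.valid_mask
    lost = np.full(map_climate.values.shape, NODATA_CODE, dtype=np.int8)
    lost[valid] = (
        (map_climate.values[valid] == 1) & (map_host.values[valid] == 0)
    ).astype(np.int8)
    lost_map = BinaryMap(climate_stack.spec, lost)

    return HostComparisonResult(
        comparison=comparison,
        report_climate=report_climate,
        report_with_host=report_host,
        model_climate=model_climate,
        model_with_host=model_host,
        lost_by_host_map=lost_map,
    )
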