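"""Fit and evaluate the envelope and maximum-entropy models.

Runs the calibration/testing workflow for one virtual species: filter the
raw occurrences, fit Bioclim and the L1-penalized MaxEnt-style model
(beta multiplier 2, 10,000 background points), and evaluate with equal
numbers of testing presences and random pseudo-absences (prevalence 0.5).
Prints a report shaped like the standard model-output tables: training and
testing AUC, omission rate at the max-sensitivity-plus-specificity
threshold, and the two per-variable importance measures.
"""

from paleosdm import (
    ClimateSimConfig,
    FilterSpec,
    TrueNiche,
    auc,
    extract_values,
    filter_environmental,
    fit_bioclim,
    fit_maxent,
    generate_scenarios,
    max_sss_threshold,
    omission_rate,
    permutation_importance,
    sample_background,
    sample_occurrences,
    sample_pseudoabsences,
    true_suitability,
    variable_contribution,
)
from paleosdm.grids import EnvSample
from paleosdm.maxent import count_parameters

stack = generate_scenarios(ClimateSimConfig(seed=42))["current"]
niche = TrueNiche(
    optima={"bio4": 1700.0, "bio16": 1800.0, "bio17": 300.0},
    breadths={"bio4": 500.0, "bio16": 350.0, "bio17": 120.0},
)
occ = sample_occurrences(true_suitability(niche, stack), 200, seed=7)
extraction = extract_values(stack, occ)
filt = filter_environmental(
    extraction.sample, occ.subset(extraction.kept_indices), FilterSpec(seed=0)
)
calib = EnvSample(
    point_ids=filt.calibration_indices,
    matrix=extraction.sample.matrix[filt.calibration_indices],
    variable_names=list(extraction.sample.variable_names),
)
test = EnvSample(
    point_ids=filt.testing_indices,
    matrix=extraction.sample.matrix[filt.testing_indices],
    variable_names=list(extraction.sample.variable_names),
)
background = sample_background(stack, 10_000, seed=1)
pseudo = sample_pseudoabsences(stack, len(test), seed=2)

maxent = fit_maxent(calib, background, beta_multiplier=2.0)
bioclim = fit_bioclim(calib)

print(f"Training occurrences      {len(calib)}")
print(f"Background points         {len(background)}")
print(f"Nonzero parameters (k)    {count_parameters(maxent)}")
print(f"MaxEnt training AUC       {auc(maxent.predict(calib), maxent.predict(background)):.3f}")
print(f"Bioclim training AUC      {auc(bioclim.predict(calib), bioclim.predict(background)):.3f}")

test_scores = maxent.predict(test)
pseudo_scores = maxent.predict(pseudo)
thr = max_sss_threshold(test_scores, pseudo_scores)
print(f"MaxEnt testing AUC        {auc(test_scores, pseudo_scores):.3f} "
      f"({len(test)} presences vs {len(pseudo)} pseudo-absences, prevalence 0.5)")
print(f"maxSSS threshold          {thr.threshold:.4f} "
      f"(sens {thr.sensitivity:.2f}, spec {thr.specificity:.2f})")
print(f"Omission rate             {omission_rate(test_scores, thr):.3f}")

print("\nIndividual contribution of the variables (%)")
for var, pct in variable_contribution(maxent).percent.items():
    print(f"  {var:6s} {pct:7.3f}")
print("Permutation importance of the variables (%)")
for var, pct in permutation_importance(maxent, calib, background, seed=3).items():
    print(f"  {var:6s} {pct:7.3f}")
print("\nThe high-importance variables are truly active niche axes "
      "(bio4, bio16, bio17); bio8 and bio9 do not shape this species' niche, "
      "though spatial correlation with active axes can lend them weight at "
      "small sample sizes.")
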