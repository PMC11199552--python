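"""Two-stage instrumental-variable estimation of a pollution causal effect.

Pollution raises disease liability (relative risk 1.2 per SD of exposure at
5% prevalence) and is also confounded by an unmeasured, spatially smooth
community factor.  Wind speed/direction instruments break the confounding:
stage 1 predicts pollution from wind, stage 2 regresses disease on the
prediction inside the family mixed model (SMILE-2).  The parents-only
fixed-effects comparator (IND-FE) and a naive (non-instrumented) fit are
shown for contrast.
"""

import numpy as np

from smile import (
    SimulationScenario,
    VarianceComponents,
    first_stage_predict,
    fit_smile2,
    ind_fe_two_stage,
    simulate_cohort,
    simulate_exposure_instruments,
    simulate_phenotype,
)

rng = np.random.default_rng(11)
vc = VarianceComponents(0.2, 0.05, 0.05, 0.01, 0.69, 0.3, scale="liability")
scenario = SimulationScenario(
    n_families=5000, lattice=(20, 20), prevalence=0.05, rr=1.2,
    confounder_effect=0.15, vc=vc)
cohort, graph = simulate_cohort(scenario, rng)
exposures, instruments, confounder = simulate_exposure_instruments(
    graph, scenario, rng)
pm25 = exposures["pm25"]
exposure_z = ((pm25 - pm25.mean()) / pm25.std()).to_numpy()
Y, truth = simulate_phenotype(cohort, graph, scenario, rng,
                              exposure_z=exposure_z, confounder=confounder)

stage1 = first_stage_predict(pm25, instruments)
print(f"first stage: R^2 = {stage1.r_squared:.3f}, "
      f"F = {stage1.f_statistic:.1f} (instrument strength)")

sd = float(pm25.std())
iv = fit_smile2(cohort, Y, stage1.fitted, exposure_sd=sd, first_stage=stage1)
fe = ind_fe_two_stage(cohort, Y, stage1.fitted, exposure_sd=sd,
                      first_stage=stage1)
naive = fit_smile2(cohort, Y, pm25, exposure_sd=sd)

K, RR = scenario.prevalence, scenario.rr
true_or = (RR * K / (1 - RR * K)) / (K / (1 - K))
print(f"\ntrue odds ratio per SD of PM2.5: {true_or:.3f}")
for name, est in [("SMILE-2 (IV)", iv), ("IND-FE (IV, parents only)", fe),
                  ("naive (no instrument)", naive)]:
    print(f"  {name:26s} OR = {est.odds_ratio:.3f}  "
          f"beta = {est.beta:+.5f} (SE {est.se:.5f})  p = {est.p_value:.2e}")
print("\nthe naive fit absorbs the confounder (OR biased upward); "
      "both IV estimates recover the causal effect, SMILE-2 with the "
      "smaller standard error because it uses children as well as parents.")
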