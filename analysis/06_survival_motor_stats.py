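"""Survival and motor-behavior statistics with censoring-aware models.

Cox proportional hazards for humane-endpoint survival (group * sex) and for
the latency tasks at each timepoint (wire hang: fall = event; pole: descent =
event), Bonferroni-corrected across the task battery; mixed models for weight
and rotarod trajectories; GLM for motor-onset dpi.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import outdir, study_spec, study_truth

from dbmcov import generate_behavior, generate_cohort
from dbmcov.behavior import EVENT_DIRECTION, bonferroni, encode_task, fit_cox, fit_longitudinal_lme, fit_survival, motor_onset_glm

spec = study_spec()
truth = study_truth(spec)
cohort = generate_cohort(spec, truth)
behavior = generate_behavior(cohort, truth, spec)
out = outdir("06_behavior")

surv = fit_survival(cohort)
surv.km_curves.to_csv(out / "km_curves.csv", index=False)
print(f"survival ({surv.n_events} events / {surv.n_records} mice): "
      f"group HR = {surv.hazard_ratios['group[PFF]']:.2f}, "
      f"group x sex HR = {surv.hazard_ratios.get('group[PFF]:sex[M]', float('nan')):.2f} "
      f"(p = {surv.pvalues.get('group[PFF]:sex[M]', float('nan')):.3g})")

onset = motor_onset_glm(cohort)
print(f"motor onset ({onset.n_obs} symptomatic mice): "
      f"sex shift = {onset.params.get('sex[M]', float('nan')):.1f} dpi "
      f"(p = {onset.pvalues.get('sex[M]', float('nan')):.3g})")

for measure, quad in (("weight", True), ("rotarod", False)):
    res = fit_longitudinal_lme(measure, cohort, behavior, quadratic_time=quad)
    key = "group[PFF]:dpi2" if quad else "group[PFF]:dpi"
    print(f"{measure} trajectory: {key} = {res.params[key]:.4g} "
          f"(p = {res.pvalues[key]:.3g}, n = {res.n_obs} observations)")

rows = []
for task in ("wirehang", "pole"):
    records = encode_task(behavior, task)
    for dpi, sub in records.groupby("dpi"):
        try:
            fit = fit_cox(sub, covariates=["group", "sex", "group:sex", "trial", "weight_g"],
                          event_direction=EVENT_DIRECTION[task])
            rows.append({"task": task, "dpi": dpi,
                         "hr_group": float(fit.hazard_ratios.get("group[PFF]", np.nan)),
                         "p_group": float(fit.pvalues.get("group[PFF]", np.nan)),
                         "n_events": fit.n_events, "n_records": fit.n_records})
        except (ValueError, RuntimeError) as err:
            rows.append({"task": task, "dpi": dpi, "hr_group": np.nan,
                         "p_group": np.nan, "n_events": 0, "n_records": len(sub)})

cox = pd.DataFrame(rows)
ok = cox.p_group.notna()
adj = bonferroni(cox.loc[ok, "p_group"].to_numpy(), m=8)
cox.loc[ok, "p_bonferroni"] = adj["p_adjusted"].to_numpy()
cox.loc[ok, "significant"] = adj["significant"].to_numpy()
cox.to_csv(out / "motor_cox.csv", index=False)
print("\nper-timepoint task models (Bonferroni m=8):")
print(cox.round(4).to_string(index=False))
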