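"""Simulate the synthetic longitudinal study: cohort, survival, behavior.

Generates the full cohort with hazard-linked attrition and the per-trial
motor-behavior tables, and summarizes group sizes, events, and censoring.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import outdir, study_spec, study_truth

from dbmcov import generate_behavior, generate_cohort

spec = study_spec()
truth = study_truth(spec)
cohort = generate_cohort(spec, truth)
behavior = generate_behavior(cohort, truth, spec)

out = outdir("01_cohort")
cohort.to_csv(out / "cohort.csv", index=False)
# the full trial table is bulky and exactly regenerable; park it in scratch
from common import SCRATCH
SCRATCH.mkdir(exist_ok=True)
behavior.to_csv(SCRATCH / "behavior.csv", index=False)

cells = cohort.groupby(["group", "sex"]).agg(
    n=("subject_id", "size"),
    events=("event_flag", "sum"),
    median_survival_dpi=("survival_dpi", "median"),
)
cells.to_csv(out / "cell_summary.csv")

print(f"cohort: {len(cohort)} mice ({spec.n_per_cell}/sex/group), "
      f"{int(cohort.event_flag.sum())} humane endpoints before 130 dpi")
print(cells)
sympt = cohort.motor_onset_dpi.notna()
print(f"symptomatic mice: {int(sympt.sum())} "
      f"(mean onset {cohort.loc[sympt, 'motor_onset_dpi'].mean():.1f} dpi)")
print(f"behavior trials: {len(behavior)} "
      f"({behavior.task.nunique()} tasks x 3 trials x surviving subject-timepoints)")
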