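"""Leave-one-subject-out comparison of all estimators on a small cohort.

Reproduces the qualitative finding the package exists to demonstrate: a
stride-segmented kinematic model tracks energy expenditure where estimators
built on lagged physiological signals (heart rate, breath gas exchange) or
acceleration counts cannot.
"""

import warnings

warnings.filterwarnings("ignore", category=UserWarning)

from gaitmet.evaluation import RunConfig, orchestrate_evaluation

config = RunConfig(n_subjects=4, condition_duration=60.0,
                   recovery_standing_s=60.0, tv_duration=120.0,
                   steady_window=30.0, seed=3)
result = orchestrate_evaluation(config)
report = result["report"]

print(f"config hash {result['config_hash']}, seed {result['seed']}")
print(f"{len(report)} report rows "
      f"(one per subject × condition × method × metric)\n")

table = (report.groupby(["metric", "method"])["value"].mean().unstack()
         .round(1))
print(table.to_string())
print("\nabsolute_pct: steady-state error vs the EE law; tv_absolute_pct: "
      "time-varying error vs speed-interpolated truth; cumulative_pct: "
      "total-energy error vs per-breath respirometry.")
print("the wearable model holds a few-percent steady-state error and the "
      "lowest time-varying error; heart-rate, count and breath-based "
      "estimators lag every intensity change.")
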