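"""ROC analysis: how well does each EAT measure predict an adversely stiff
(>= median stiffness index) or inelastic (< median strain/distensibility)
aorta, and at what cutoff?"""

from aortastat import default_spec, derive_frame, generate, prediction_report
from aortastat.roc import report_to_frame

derived = derive_frame(generate(default_spec(seed=1)).frame)
report = report_to_frame(prediction_report(derived))

cols = ["predictor", "threshold", "outcome_variable", "auc",
        "sensitivity", "specificity", "accuracy"]
print(report[cols].round(3).to_string(index=False))
print()
print("Thresholds are accuracy-maximal operating points: a patient whose")
print("EAT measure is >= the threshold is called positive for the adverse")
print("aortic state. AUC > 0.5 throughout reflects the calibrated positive")
print("EAT-stiffness association.")
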