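"""ROC diagnostic accuracy of a selected change-score variable.

AUC with a Hanley-McNeil CI and p-value against chance, the Youden-optimal
cutoff with Wilson CIs on sensitivity/specificity, and LR+.
"""

import numpy as np

import evprofiler as ev
from evprofiler.pipeline import analysis_frame

cohort = ev.generate_cohort(seed=5)
fm = ev.default_manifest()
profiles = ev.reduce_cohort(cohort.manifest, fm, cohort.tables)
frame, scores, groups = analysis_frame(cohort.manifest, profiles, "change")
is_high = np.array([g == "high" for g in groups])

res = ev.roc_analysis(frame[ev.EFFECT_A_TARGET].to_numpy(), is_high,
                      variable=ev.EFFECT_A_TARGET)
print(f"variable: {res.variable}")
print(f"AUC = {res.auc:.2f} (95% CI {res.auc_ci[0]:.2f}-{res.auc_ci[1]:.2f}), "
      f"p = {res.p:.4f}")
print(f"optimal rule: value {res.direction} {res.cutoff:.2f}")
print(f"sensitivity {res.sensitivity:.0%} "
      f"(95% CI {res.sensitivity_ci[0]:.1%}-{res.sensitivity_ci[1]:.1%})")
print(f"specificity {res.specificity:.0%} "
      f"(95% CI {res.specificity_ci[0]:.1%}-{res.specificity_ci[1]:.1%})")
print(f"Youden J = {res.j:.2f}, LR+ = {res.lr_plus:.2f}")

# LR+ arithmetic at two reference operating points:
print(f"\nLR+ at 80%/90%: {ev.likelihood_ratio(0.80, 0.90):.2f}")
print(f"LR+ at 90%/60%: {ev.likelihood_ratio(0.90, 0.60):.2f}")
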