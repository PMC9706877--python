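"""Sensitivity-constrained threshold selection for MRI triage.

For GFAP in a simulated moderate-severe sub-cohort, finds the serum
concentration that maximises specificity while detecting at least 90% of
brainstem injuries, then repeats with a 100% floor.  Raising the floor can
only lower the achievable specificity (fewer transfers avoided).
"""

from tbitriage import default_config, select_cutpoint, simulate_cohort

records = simulate_cohort(default_config(), seed=1)
ms = [r for r in records if r.subcohort == "moderate_severe"]
values = [r.biomarkers.value("GFAP") for r in ms]
labels = [r.brainstem_injury for r in ms]

for floor in (0.90, 1.00):
    res = select_cutpoint(values, labels, floor, protein="GFAP")
    c = res.confusion
    print(f"min sensitivity {floor:.2f}: threshold {res.threshold:8.2f} ng/ml  "
          f"sens {c.sensitivity:.2f}  spec {c.specificity:.2f}  "
          f"{c.n_above_threshold}/{c.n} patients transferred")
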