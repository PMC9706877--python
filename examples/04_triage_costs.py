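"""Per-patient cost of 'test then selective MRI' versus 'MRI for all'.

Uses the shipped UK and US health-system configs at the published GFAP
operating point (21 of 30 patients above threshold).  Savings are per
patient: (1 - fraction transferred) x MRI cost - assay cost.
"""

from tbitriage import builtin_config, triage_cost

for system in ("uk", "us"):
    config = builtin_config(system)
    res = triage_cost(config, "GFAP", fraction_above=21 / 30)
    print(f"{config.system_name}: MRI-for-all {res.cost_mri_for_all:.2f} "
          f"{config.currency}/patient, triaged {res.cost_triage:.2f}, "
          f"saving {res.savings:.2f}")
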