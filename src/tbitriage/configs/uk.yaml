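# UK health-system unit costs (GBP per patient).  The MRI cost includes the
# intra-hospital transfer.  Per-protein assay costs are back-solved from the
# published per-patient strategy-cost table; they are research-assay prices.
system_name: UK
currency: GBP
cost_mri_per_patient: 385.80
assays:
  GFAP: 16.82
  NFL: 22.45
  NSE: 13.68
  S100B: 21.56
  Tau: 21.06
  UCHL1: 16.03
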