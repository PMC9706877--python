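# US health-system unit costs (USD per patient), based on the FDA-approved
# i-stat point-of-care platform, which measures only GFAP and UCH-L1; the
# remaining proteins have no licensed clinical assay and are left unpriced.
system_name: US
currency: USD
cost_mri_per_patient: 2758.56
assays:
  GFAP: 65.16
  NFL: null
  NSE: null
  S100B: null
  Tau: null
  UCHL1: 65.16
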