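# Demo run: synthetic denosumab cohort with on-treatment fracture-rate
# reductions matching a published effect profile.
seed: 1
output_dir: demo_run
simulate:
  n_patients: 20000
  drug_mix:
    denosumab: 1.0
    iv_ibandronate: 0.0
    iv_zoledronate: 0.0
    oral_bisphosphonate: 0.0
    teriparatide: 0.0
    raloxifene: 0.0
    hrt: 0.0
  estrogen_only_frac: 0.0
  hazard_ratio_by_window:
    m4_12: 0.62
    m13_24: 0.50
    m25_36: 0.44
    m37_48: 0.33
analysis:
  ci_method: auto
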