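# Relative PSA change (%) from baseline to 5 +/- 2 weeks after one Tb-161 cycle.
# Negative = decrease. Used for PCWG3 biochemical response classification.
patient_id,psa_change_percent
patient_a,-53.4
patient_b,-24.2
patient_c,-18.6
patient_d,18.0
patient_e,48.6
patient_f,73.2
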