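# Screening-like development cohort: 883 nodules, ~7.4% malignant.
n_nodules: 883
malignant_fraction: 0.07361268403171007
n_members: 20
cohort: development
seed: 7
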