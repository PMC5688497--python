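# Demo pipeline: simulate 12 surveys of 400 women each, aggregate,
# fit all three model variants, project scenarios A/B/C.
out_dir = demo_out
seed = 42
n_surveys = 12
n_women = 400
n_countries = 4
variants = m1,m2,m3
scenarios = A,B,C
delta_mcpr_pp = 10.0
fallback = zero
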