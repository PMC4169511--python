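# Run configuration for the lipokinetics CLI.
# Rates: a named preset (streamlined_slow, multilipoplex_fast,
# multilipoplex_slow) or an explicit mapping of the five free rates
# (fixed rates then take their literature defaults).
rates: multilipoplex_slow
design:
  L_ex0: 25.357      # reference dose: mean 6 lipoplexes attach in 1 h
  t_inc: 1.0         # incubation time before the wash (h)
  t_end: 30.0        # simulation horizon (h)
  S: 350             # mRNA molecules per lipoplex
  N_max: 10          # pit/endosome capacity
  dt_out: 0.1        # output sampling interval (h)
engine: hybrid       # ode | ssa | hybrid
n_cells: 1000
seed: 1
out_dir: results
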