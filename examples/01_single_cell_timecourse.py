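"""Simulate one cell's transfection: deterministic mean field vs one
stochastic realisation.

The deterministic solution describes fractional molecule numbers that no
single cell ever shows; the stochastic cell attaches a handful of
lipoplexes, loses most endosomes to degradation, and either expresses GFP
in 350-mRNA packets or not at all.
"""

import numpy as np

import lipokinetics as lk

rates = lk.get_preset("multilipoplex_slow")
design = lk.make_reference_design(rates)          # ~25.4 lipoplexes/cell => mean 6 attach
net = lk.build_network("multilipoplex", rates, design)

det = lk.simulate_deterministic(net)
cell = lk.simulate_hybrid(net, seed=1, init_mode="round")

print(f"reference dose: {design.L_ex0:.2f} external lipoplexes per cell")
print(f"{'t/h':>5} {'attached (ODE)':>15} {'attached (SSA)':>15} {'GFP (ODE)':>12} {'GFP (cell)':>12}")
att = net.observables["attached"]
for t in (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 30.0):
    i = int(round(t / design.dt_out))
    print(f"{t:5.1f} {det.observable(att)[i]:15.2f} {cell.observable(att)[i]:15.0f} "
          f"{det['Gstar'][i]:12.0f} {cell['Gstar'][i]:12.0f}")

d = cell.derived
print(f"\nthis cell: {d['n_attached']} attached, {d['n_endosomes']} endosomes, "
      f"{d['n_lysed']} lysed, {d['n_packets']} mRNA packet(s) of {design.S} released")
print("each released packet peaks at ~3.7e5 mature GFP about 17 h later;")
print("the ODE instead spreads the same mass over every fractional fate.")
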