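"""Expression-onset statistics of a 2000-cell ensemble.

Each transfected cell's mature-GFP trace is fitted with the analytic
expression solution (translation + degradation; the maturation delay is
part of the measured onset), giving an onset time without any detection
threshold.  Slow maturation (k_M = 5.5/h) narrows the onset distribution
relative to the fast literature value (k_M = 9.23/h).
"""

import numpy as np

import lipokinetics as lk

for preset in ("multilipoplex_slow", "multilipoplex_fast"):
    rates = lk.get_preset(preset)
    design = lk.make_reference_design(rates)
    net = lk.build_network("multilipoplex", rates, design)
    ens = lk.simulate_ensemble(net, 2000, seed=11)
    fits = [lk.fit_onset_maxgfp(ens.times, ens.gfp[i], rates)
            for i in np.flatnonzero(ens.transfected)]
    onset = lk.onset_distribution([f for f in fits if f.converged])
    print(f"{preset}: k_M = {rates.k_M}/h")
    print(f"  mean attached lipoplexes  {ens.mean_attached:.2f}  (calibrated to 6)")
    print(f"  transfection efficiency   {lk.transfection_efficiency(ens):.3f}")
    print(f"  onset time Gaussian       mean {onset.location:.2f} h, "
          f"width {onset.width:.2f} h  (n={onset.n})")
print("the onset mean is the delivery delay chain (attachment + endocytosis +"
      "\nlysis) plus the 1/k_M maturation lag; faster maturation shifts and"
      "\nwidens the distribution through the altered fitted rate set.")
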