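# lipokinetics

Stochastic multi-level kinetic modelling of mRNA transfection by lipoplexes:
simulation, single-cell expression analysis, and rate estimation.

## The problem

When cells are transfected with mRNA lipoplexes, the observable outcome —
whether a cell lights up with GFP, when its expression starts, and how high
it goes — is governed by a chain of rare events: a handful of lipoplexes
attach to the surface, are collected into clathrin-coated pits, endocytosed,
and each resulting endosome either lyses (releasing its cargo of ~350 mRNA
per lipoplex into the cytosol) or is degraded.  Copy numbers of 1–10 in the
delivery chain make the process intrinsically stochastic, and the nesting —
mRNA inside lipoplexes inside endosomes — makes naive species enumeration
explode combinatorially.  This package implements the flattened two-level
model that makes the problem tractable: all lipoplexes carry exactly
`S = 350` mRNA, and pits/endosomes are enumerated by occupancy
(`P_1..P_10`, `E_1..E_10`).

The reaction chain, with all rates in 1/h:

    L_ex --k_A--> P_i  --k_E--> E_i --k_L--> i x L_in --k_U--> S x M
                                  \--d_E--> (degraded with cargo)
    M --k_TL--> M + G,   G --k_M--> G*,   M,G,G* decay at d_M, d_G, d_G

Attachment is split over one new-pit channel plus one channel per existing
pit, each at rate `k_AX = k_A/(n_pits+1)`, so the total attachment rate is
dose-proportional regardless of pit count.  A wash removes the remaining
external lipoplexes after the incubation time (1 h).  Expression is the
linear cascade M → G → G*, whose closed-form solution both drives the fast
hybrid simulator and serves as the fitting model for measuring per-cell
expression onset times without arbitrary thresholds.

Three engines share one network representation: stiff ODE (deterministic
mean field), exact Gillespie SSA, and the default **hybrid** engine — exact
SSA for the low-copy delivery chain plus analytic superposition of packet
expression curves, which matches full-SSA ensemble means at ~1e-5 of the
cost.  On top sit the analysis layer (onset/max-GFP distributions,
transfection efficiency, single/double-Poissonian dose-response fits) and a
simulated-annealing estimator for the five free rates (`k_A`, `k_E`, `k_L`,
`d_E`, `k_M`) against five ensemble determinants.  Intended users: modellers
of nucleic-acid delivery and anyone needing a worked example of multi-level
stochastic kinetics with single-cell statistics.

## Worked example

```python
import numpy as np
import lipokinetics as lk

rates  = lk.get_preset("multilipoplex_slow")    # fitted: k_A=0.27, k_E=0.81,
                                                # k_L=0.11, d_E=0.67, k_M=5.5
design = lk.make_reference_design(rates)        # dose calibrated to 6 attached/cell
net    = lk.build_network("multilipoplex", rates, design)
ens    = lk.simulate_ensemble(net, 2000, seed=11)

fits = [lk.fit_onset_maxgfp(ens.times, ens.gfp[i], rates)
        for i in np.flatnonzero(ens.transfected)]
onset = lk.onset_distribution([f for f in fits if f.converged])
print(ens.mean_attached, lk.transfection_efficiency(ens))
print(onset.location, onset.width)
```

This prints (exact values for this seed):

    5.97 0.372
    3.06 1.71

i.e. a mean of ~6 lipoplexes attach per cell during the 1 h incubation,
37% of cells receive at least one mRNA packet, and GFP expression onsets
are distributed with mean ≈ 3.1 h and SD ≈ 1.7 h — the delivery delay
chain (attachment + endocytosis + lysis, ~2.9 h) plus the 1/k_M maturation
lag.  The `examples/` directory holds one narrative script per capability:
single-cell time courses, onset distributions, dose-response Poissonian
structure, annealing recovery, and SBML export.  A thin CLI mirrors the
library (`lipokinetics simulate|ensemble|dose-sweep|fit-traces|anneal|
export-sbml|make-fixtures|reproduce-figure`).

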