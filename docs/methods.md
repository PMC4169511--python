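# Methods

## The model

`lipokinetics` simulates mRNA transfection of single cells by cationic
lipid–mRNA particles (lipoplexes) as a chain of mass-action reactions, in
two variants.

**Streamlined variant.** Each external lipoplex (`L_ex`) attaches to the
cell surface forming a clathrin-coated pit (`P`, rate `k_A`), is
endocytosed into an endosome (`E`, rate `k_E`), and the endosome either
lyses, releasing the lipoplex into the cytosol (`L_in`, rate `k_L`), or is
degraded with its cargo (`d_E`).  A cytosolic lipoplex unpacks into `S`
free mRNA molecules (`k_U`, effectively instantaneous by default) or is
degraded (`d_L`, negligible by default).  Each mRNA translates immature GFP
(`G`) at `k_TL` per mRNA and decays at `d_M`; immature GFP matures by
folding and oxidation into fluorescent GFP (`G*`) at `k_M`; both GFP forms
decay at `d_G`.  A washing step removes the remaining external lipoplexes
at the incubation time `t_inc` (default 1 h).

**Multiple-lipoplex variant.** Pits and endosomes can hold up to `N_max`
(default 10) lipoplexes and are enumerated by occupancy as species
`P_1..P_Nmax`, `E_1..E_Nmax` (2·N_max+5 species, 4·N_max+8 reactions).
Attachment splits into one new-pit channel plus one join channel per
existing non-full pit, each with rate constant `k_AX = k_A/(n_pits+1)`, so
the *total* attachment propensity stays `k_A·L_ex` however many pits are
open.  Endocytosis moves `P_i -> E_i`; lysis of `E_i` releases all `i`
lipoplexes in a single event; endosome degradation destroys the whole
endosome and cargo.  Pits themselves do not degrade.

**The fixed-size simplification.** Real lipoplexes in the modelled
experiments carry roughly 270–445 mRNA (mean 350).  Tracking the size of
every lipoplex inside every endosome would require `size_states^N_max`
species (`count_full_nested_species`; 175^10 ≈ 2.7e22), so every lipoplex
carries exactly `S = 350` mRNA.  The visible consequence is that delivered
mRNA — and hence the per-cell maximum GFP — comes in discrete packets,
clustering the expression levels at multiples of ~3.7e5 molecules.

## Parameters

All rates in 1/h; counts are molecules or particles per cell.

| rate | meaning | default (fitted presets) |
|------|---------|--------------------------|
| `k_A` | attachment | 0.03 / 0.26 / 0.27 |
| `k_E` | endocytosis | 0.8 / 0.73 / 0.81 |
| `k_L` | endosomal lysis | 0.065 / 0.10 / 0.11 |
| `d_E` | endosome degradation (incl. in-endosome mRNA decay) | 0.65 / 0.60 / 0.67 |
| `k_M` | GFP maturation | 5.5 or 9.23 |
| `k_TL` | translation per mRNA | 170 (fixed) |
| `d_M` | mRNA degradation | 0.062 (fixed) |
| `d_G` | degradation of both GFP forms | 0.056 (fixed) |
| `k_U` / `d_L` | unpacking / lipoplex degradation | 1e6 / 1e-6 (fixed) |

The three presets (`streamlined_slow`, `multilipoplex_fast`,
`multilipoplex_slow`) are the published fitted columns and are the single
source of rate truth in the package.

**Reference dose.** The per-cell initial lipoplex count `L_ex0` is the dose
proxy.  The reference dose is calibrated so that the expected number of
attachment events over the 1 h incubation is 6
(`L_ex0 = 6/(1−exp(−k_A·t_inc))`, ≈ 25.4 for the multilipoplex presets).
Per-cell initial counts use stochastic rounding
(`floor + Bernoulli(frac)`) by default so the calibrated mean is exact in
expectation; deterministic rounding and Poisson draws are available.

## Engines

* **Deterministic** (`simulate_deterministic`): stiff ODE integration
  (LSODA, rtol=atol=1e-8; `k_U = 1e6` makes the system stiff).  The wash is
  an instantaneous removal of `L_ex` at `t_inc` by default (the large-`k_W`
  limit); the explicit finite washing-rate jump is retained for validation
  and agrees with the instant mode to <0.1%.
* **Exact SSA** (`simulate_ssa`): Gillespie direct method with
  state-recomputed propensities, the wash as a timed event, per-reaction
  firing counts, a delivery event log, and a configurable event budget that
  warns when exceeded (full SSA at `k_TL=170`, `S=350` generates ~1e6–1e7
  events per cell).  Identical seeds give bit-identical event sequences.
* **Hybrid** (`simulate_hybrid`, the default ensemble engine): exact SSA on
  the low-copy delivery subnetwork (through `L_in`), then each mRNA release
  event `(t_r, S)` contributes a closed-form expression curve; `M`, `G`,
  `G*` are superpositions of these curves.  Because the expression cascade
  is linear, the hybrid trace equals the conditional expectation of the
  full SSA given the delivery path; ensemble means agree with full SSA
  within Monte-Carlo error (verified at 100×-reduced `k_TL`), at ~1e2
  events/cell instead of ~1e7.  Delivery statistics are exact SSA by
  construction, though hybrid and full-SSA runs consume different random
  streams, so agreement is distributional, not per-seed.

Ensembles derive per-cell seeds from the master seed with
`SeedSequence.spawn`, so results are reproducible and cell `i` is
independent of the ensemble size.

## Expression analysis

The cascade `M -> G -> G*` with constant rates has the closed form

    G*(t) = k_TL·k_M·m0 · f[d_M, k_M+d_G, d_G](t−t0),

where `f[a,b,c]` is the second divided difference of `s ↦ exp(−s·τ)`.  It
is evaluated in a cancellation-safe form (expm1 anchored at the slower rate
of each pair); exactly coincident rates are separated by an infinitesimal
node perturbation (relative error ~1e-7), so degenerate inputs such as
`d_M = d_G` need no special casing by the caller.

**Onset fitting.** `fit_onset_maxgfp` least-squares fits the single-packet
solution over free `(t0, m0)` with all rates fixed; the amplitude is
profiled out analytically, leaving a 1-D search over `t0` (coarse grid +
bounded refinement).  Flat traces are flagged `converged=False`, never
silently zero.  By default the *measurement model omits the maturation
stage* (translation + degradation only): this mirrors the established
single-cell analysis convention in which the maturation delay is part of
the measured onset time, and it is the only convention under which the
maturation rate influences the onset distribution at all.  With
`include_maturation=True` the full cascade is fitted instead, and on
noiseless generated traces the fit recovers `t0` to 0.01 h and the maximum
to 0.1% (exact inversion).

**Summaries.** Onset times are summarised as a Gaussian (sample mean, SD);
maximum-GFP values as a two-parameter lognormal, location `exp(mean ln x)`
and width `SD(ln x)`.  The published expression-level figures quote
histogram-shape lognormal fits instead; on the simulator's noise-free,
packet-clustered data such a fit collapses onto the single-packet spike, so
the moment convention is used throughout and the difference is noted under
Limitations.

**Transfection efficiency** is, by ground truth, the fraction of cells with
at least one mRNA release event; a fit-based classifier (converged fit with
maximum ≥ 1e3 molecules, far below the ~3.7e5 single-packet amplitude) is
provided for trace-only inputs and agrees with the ground truth on
simulated data.

**Dose-response models.** TE(D) is fitted by the zero-class forms

    single:  TE = 1 − exp(−a·D/D_ref)
    double:  TE = 1 − exp(−N·(1 − exp(−L·D/D_ref)))

The double form nests the single one (L→0 with N·L fixed) and encodes a
dose-independent endosome capacity `N` with a per-endosome Poisson load
`L·D/D_ref` — the mechanistic consequence of the pit-normalised attachment
rule, under which the pit count grows sublinearly with dose.  A fit whose
parameter runs into its bounds (e.g. the double form on truly
single-Poissonian data, where `L` is unidentifiable) is flagged.

## Parameter estimation

`compute_goals` maps a candidate five-rate set to the five determinants
(mean attached lipoplexes; TE on a dose grid; onset mean; onset width; mean
maximum GFP) by hybrid ensembles at a *fixed* design — the dose is an
experimental control, so it is not re-calibrated per candidate, keeping
`mean_attached` informative about `k_A`.  The objective is the equally
weighted sum of squared relative deviations of the four scalar
determinants plus the mean squared TE deviation across the dose grid.

`anneal` is Metropolis simulated annealing: log-space Gaussian proposals
(σ = 0.2 by default) reflected at the bounds (`[1e-3, 10]`/h for the four
delivery rates, `[0.5, 20]`/h for `k_M`, spanning the literature ranges),
acceptance `min(1, exp(−Δ/T))`, geometric cooling (0.95/step), `T0` from a
pilot proposal scan unless given, and a *fresh* simulation sub-seed per
evaluation so the optimizer cannot overfit one noise realisation.  Runs are
fully reproducible given the master seed.

**Identifiability.** The determinants constrain the delay budget
`1/k_E + 1/(k_L+d_E) (+ 1/k_M)` and the fate ratio `k_L/(k_L+d_E)` tightly,
but the split of the delay budget is carried only by the onset width and by
second-order clustering effects on max-GFP and TE, whose signals sit near
the Monte-Carlo floor of desk-scale ensembles.  In practice `k_A` is pinned
within a few percent, `k_E`/`k_L`/`d_E` recover to ~10–25% when the
schedule is annealed in noise as well as temperature (increasing ensemble
sizes, 600 → 1500 → 3000 cells, with narrowing colder stages), and `k_M`
remains sloppy: its only first-order signal is a shift of the onset mean by
`Δ(1/k_M)` ~ 0.1 h, below the onset-mean standard error at these ensemble
sizes.  This mirrors the original caveat that the fitted rates are not
accurate measurements of the underlying biology; the recovery study in the
acceptance suite reports all five errors and the sloppiness is visible
there.

## Scale choices

Ensemble statistics stabilise well before the sizes used here: acceptance
statistics use 3000-cell hybrid ensembles (onset/peak summaries change by
<2% beyond that), dose-response points 600 cells, predictive sweeps
800–2000 cells, and the hybrid-vs-full-SSA check 120 cells at 100×-reduced
translation (full SSA is the expensive validation engine).  The annealing
recovery study uses the three-stage schedule above with a high-precision
synthetic target ensemble (8000 cells): target noise tilts the sloppy
valley and would otherwise dominate the recovery error.

## What the synthetic fixtures emulate

`make_fixtures` generates per-cell GFP traces from the analytic expression
solution with sampled onset times (truncated normal, default mean 3.2 h,
SD 1.6 h) and packet-quantised mRNA amounts, degraded by multiplicative
Gaussian noise and an additive floor, with the ground truth stored.  They
emulate the *shape* and noise character of single-cell fluorescence
time-lapse data for validating trace analysis by parameter recovery.  They
do not emulate: cell division and dilution, autofluorescence background
drift, bleaching, segmentation/tracking errors, extrinsic rate variability
between cells, or continuous lipoplex size variation.  Passing recovery
tests on fixtures therefore demonstrates correctness of the analysis
pipeline, not robustness to every artefact of real microscopy data.

## Numerical choices and degenerate inputs

* ODE: LSODA with rtol=atol=1e-8; trajectories clipped at 0 (integration
  can leave ~atol-sized negatives); integration failures raise with the
  failing time and state.
* SSA: direct method; sampling strictly before each event time; the wash
  boundary is inclusive (`t = t_inc` is post-wash on the output grid).
* Divided differences: pairwise expm1 forms; coincident nodes separated by
  `1e-9·max(|node|, 1e-3)`.
* Onset fit: coarse grid of 160 points (90 inside the optimizer loop, on a
  2×-thinned time grid) plus bounded refinement to xatol 1e-6; ties in the
  coarse grid resolve to the first minimum.
* Zero-dose ensembles give TE = 0 and no fits; distribution summaries
  require ≥2 converged (and, for the lognormal, positive) values and raise
  otherwise.
* Annealing bounds are enforced by reflection in log space, which preserves
  detailed balance of the proposal within the box.

## Known limitations

* Fixed lipoplex size: expression levels cluster in packets of 350 mRNA;
  real data show a continuum.  The lognormal *width* of the max-GFP
  distribution is therefore convention-sensitive (moments vs histogram
  shape), and the moment summaries here run ~25% above / ~30% below the
  published histogram-fit location/width for the multilipoplex and
  streamlined variants respectively.
* Under the uniform-channel attachment rule the mean number of lipoplexes
  per lysed endosome at the reference dose is ~2.3; the published
  expression-level statistics imply ~1.5 in the original implementation,
  whose exact channel bookkeeping is not fully specified.  Onset-time and
  peak-time statistics are insensitive to this difference.
* The per-cell GFP peak-time *mean* (~20 h) is reproduced; its published SD
  (~5.5 h) is not reproducible from this model's structure — the peak time
  is the release time plus a ~17 h cascade lag, and release times spread by
  only ~1.8 h.  The simulated SD is ~1.8 h.
* No spatial transport, no pit/endosome maturation stages, no toxicity at
  high dose, no cell division; the incubation-time linearity and
  degradation-rate extrapolations are model idealisations valid in limited
  windows.
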