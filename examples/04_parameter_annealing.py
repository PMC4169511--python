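"""Recover the five free rates by simulated annealing on synthetic goals.

Goal statistics (mean attached lipoplexes, dose-response TE curve, onset
mean/width, mean max GFP) are generated at known rates; annealing then
searches from a displaced start with Boltzmann acceptance exp(-delta/T) and
geometric cooling, using a fresh simulation seed per evaluation.  This is a
small demonstration run; the acceptance suite runs the full three-stage
schedule.
"""

import lipokinetics as lk
from lipokinetics.annealing import AnnealConfig, anneal, compute_goals

truth = {"k_A": 0.27, "k_E": 0.81, "k_L": 0.11, "d_E": 0.67, "k_M": 5.5}
design = lk.make_reference_design(lk.get_preset("multilipoplex_slow"))

targets = compute_goals(truth, design, n_cells=2000, seed=100, dose_cells=400)
print("synthetic goals:",
      f"attached {targets.mean_attached:.2f},",
      f"onset {targets.onset_mean:.2f}+-{targets.onset_width:.2f} h,",
      f"maxGFP {targets.mean_maxgfp:.3g}")

start = {k: v * (1.5 if i % 2 == 0 else 1 / 1.5)
         for i, (k, v) in enumerate(truth.items())}
config = AnnealConfig(x0=start, design=design, steps=40, n_cells=400,
                      dose_cells=120, t0=0.08, sigma=0.2, cooling=0.93, seed=7)
result = anneal(config, targets)

print(f"\nbest score {result.best_score:.4f} after {result.n_evals} evaluations")
print(f"{'rate':>5} {'true':>7} {'start':>7} {'estimate':>9}")
for k in truth:
    print(f"{k:>5} {truth[k]:7.3f} {start[k]:7.3f} {result.best_params[k]:9.3f}")
print("\nattachment (via mean attached) pins k_A tightly; the remaining rates"
      "\nshare compensating delay/fate directions and converge more slowly --"
      "\nthe model is deliberately 'sloppy' in those combinations.")
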