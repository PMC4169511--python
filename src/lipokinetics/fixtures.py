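"""Synthetic single-cell GFP trace tables with known ground truth.

Stand-in for experimental per-cell fluorescence time courses: each cell's
trace is an analytic expression curve with a sampled onset time and mRNA
amount, degraded by multiplicative Gaussian noise and an additive detection
floor.  The ground truth (t0, m0) is stored alongside, so trace-analysis
routines can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import expression_curve
from .parameters import RateConstants

__all__ = ["TraceTable", "make_fixtures"]


@dataclass
class TraceTable:
    """Long-format per-cell traces plus the generating ground truth."""

    traces: pd.DataFrame     # cell_id, time_h, gfp_count
    truth: pd.DataFrame      # cell_id, t0, m0

    def trace(self, cell_id: int) -> tuple[np.ndarray, np.ndarray]:
        sub = self.traces[self.traces.cell_id == cell_id]
        return sub.time_h.to_numpy(), sub.gfp_count.to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.truth.cell_id.to_numpy()


def make_fixtures(
    n_cells: int,
    rates: RateConstants,
    seed,
    noise_sigma: float = 0.05,
    noise_floor: float = 0.0,
    t_end: float = 30.0,
    dt: float = 0.1,
    onset_mean: float = 3.2,
    onset_sd: float = 1.6,
    packet_size: int = 350,
    extra_packet_mean: float = 0.45,
) -> TraceTable:
    """Generate ``n_cells`` noisy traces with stored (t0, m0) ground truth.

    t0 ~ Normal(onset_mean, onset_sd) truncated at 0; m0 = packet_size *
    (1 + Poisson(extra_packet_mean)), emulating delivery in whole-lipoplex
    packets.  Noise: trace * (1 + N(0, noise_sigma)) + |N(0, noise_floor)|,
    clipped at 0.  noise_sigma = noise_floor = 0 returns the exact curves.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end + dt / 2, dt)
    records = []
    truth = []
    for cid in range(n_cells):
        t0 = -1.0
        while t0 < 0:
            t0 = rng.normal(onset_mean, onset_sd)
        m0 = packet_size * (1 + rng.poisson(extra_packet_mean))
        y = expression_curve(times, t0, m0, rates)
        if noise_sigma > 0:
            y = y * (1.0 + rng.normal(0.0, noise_sigma, size=y.shape))
        if noise_floor > 0:
            y = y + np.abs(rng.normal(0.0, noise_floor, size=y.shape))
        y = np.clip(y, 0.0, None)
        records.append(pd.DataFrame({"cell_id": cid, "time_h": times, "gfp_count": y}))
        truth.append((cid, t0, m0))
    return TraceTable(
        traces=pd.concat(records, ignore_index=True),
        truth=pd.DataFrame(truth, columns=["cell_id", "t0", "m0"]),
    )
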