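"""Single-cell trajectory container shared by all simulation engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellTrajectory"]


@dataclass
class CellTrajectory:
    """Time grid, per-species counts and derived delivery record of one cell.

    ``counts`` has shape (len(times), len(species)); integer-valued for the
    stochastic engine, real-valued for the deterministic one (the hybrid
    engine mixes the two).  ``events`` is a log of (time, reaction label)
    pairs for the low-copy delivery reactions.  ``derived`` collects the
    per-cell bookkeeping: attachment/endocytosis/lysis times, mRNA release
    events ``(time, packet_size)``, cumulative reaction counts and the number
    of lipoplexes removed by the wash.
    """

    times: np.ndarray
    species: list[str]
    counts: np.ndarray
    engine: str
    events: list[tuple[float, str]] | None = None
    derived: dict = field(default_factory=dict)

    def __getitem__(self, species: str) -> np.ndarray:
        return self.counts[:, self.species.index(species)]

    def observable(self, combo: dict[str, float]) -> np.ndarray:
        out = np.zeros(len(self.times))
        for sp, w in combo.items():
            out += w * self[sp]
        return out
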