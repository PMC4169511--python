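"""Flattened reaction networks for the streamlined and multiple-lipoplex models.

The multi-level structure (mRNA inside lipoplexes inside pits/endosomes) is
flattened by two simplifications: every lipoplex carries exactly ``S`` mRNA
molecules, and pits/endosomes are enumerated by their occupancy ``i = 1..N_max``
as separate species ``P_i`` / ``E_i``.  Attachment of an external lipoplex is
split into one "new pit" channel plus one "join" channel per existing non-full
pit, each with rate constant ``k_AX = k_A / (n_pits + 1)``, which keeps the
total attachment propensity at ``k_A * L_ex`` however many pits are open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ExperimentDesign, RateConstants

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "CompiledNetwork",
    "build_network",
    "attach_propensity",
    "wash_rate",
    "count_full_nested_species",
    "mrna_equivalent_weight",
    "mrna_equivalent_change",
]

MASS_ACTION = "mass_action_first_order"
ATTACH = "attach_channel"
WASH = "wash"

#: reaction labels whose firing destroys mRNA equivalents (everything else
#: in the delivery chain conserves them; translation/maturation act on the
#: zero-weight protein species).
DEGRADATION_LABELS = ("wash", "endosome_degradation", "lipoplex_degradation", "mrna_degradation")


@dataclass(frozen=True)
class Reaction:
    reactants: dict[str, int]
    products: dict[str, int]
    rate_kind: str
    rate_constant: float
    label: str

    def __post_init__(self):
        if self.rate_kind not in (MASS_ACTION, ATTACH, WASH):
            raise ValueError(f"unknown rate_kind {self.rate_kind!r}")
        if self.rate_kind == MASS_ACTION and (
            len(self.reactants) != 1 or next(iter(self.reactants.values())) != 1
        ):
            raise ValueError(f"first-order reaction {self.label!r} must have one reactant with stoichiometry 1")
        if self.rate_constant < 0:
            raise ValueError(f"reaction {self.label!r} has negative rate constant")


@dataclass
class ReactionNetwork:
    """Species list, reaction list and named observables of one model variant."""

    variant: str
    species: list[str]
    reactions: list[Reaction]
    observables: dict[str, dict[str, float]]
    rates: RateConstants
    design: ExperimentDesign
    _compiled: "CompiledNetwork | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        declared = set(self.species)
        for r in self.reactions:
            undeclared = (set(r.reactants) | set(r.products)) - declared
            if undeclared:
                raise ValueError(f"reaction {r.label!r} references undeclared species {sorted(undeclared)}")

    def index(self, species: str) -> int:
        return self.species.index(species)

    def compiled(self) -> "CompiledNetwork":
        if self._compiled is None:
            self._compiled = CompiledNetwork(self)
        return self._compiled

    def observable_trace(self, name: str, counts: np.ndarray) -> np.ndarray:
        """Evaluate a named linear observable on a (time, species) count array."""
        combo = self.observables[name]
        out = np.zeros(counts.shape[0])
        for sp, w in combo.items():
            out += w * counts[:, self.index(sp)]
        return out

    def delivery_subnetwork(self) -> "ReactionNetwork":
        """Sub-network of the low-copy delivery chain (through ``L_in``).

        mRNA and the GFP species are dropped; the unpacking reaction is kept
        (its firing times are the mRNA release events) with its mRNA product
        removed.  Used by the hybrid engine.
        """
        keep = [s for s in self.species if s not in ("M", "G", "Gstar")]
        keepset = set(keep)
        reactions = []
        for r in self.reactions:
            if not set(r.reactants) <= keepset:
                continue
            products = {s: n for s, n in r.products.items() if s in keepset}
            reactions.append(Reaction(r.reactants, products, r.rate_kind, r.rate_constant, r.label))
        observables = {
            name: combo
            for name, combo in self.observables.items()
            if set(combo) <= keepset
        }
        return ReactionNetwork(self.variant, keep, reactions, observables, self.rates, self.design)


def build_network(variant: str, rates: RateConstants, design: ExperimentDesign) -> ReactionNetwork:
    """Construct the full species/reaction list for one model variant.

    ``variant`` is ``"streamlined"`` (single-lipoplex pits and endosomes) or
    ``"multilipoplex"`` (pits and endosomes of occupancy 1..N_max).
    """
    S = design.S
    if variant == "streamlined":
        species = ["L_ex", "P", "E", "L_in", "M", "G", "Gstar"]
        rx = [
            Reaction({"L_ex": 1}, {"P": 1}, MASS_ACTION, rates.k_A, "attach"),
            Reaction({"L_ex": 1}, {}, WASH, rates.k_W_high, "wash"),
            Reaction({"P": 1}, {"E": 1}, MASS_ACTION, rates.k_E, "endocytosis"),
            Reaction({"E": 1}, {"L_in": 1}, MASS_ACTION, rates.k_L, "lysis"),
            Reaction({"E": 1}, {}, MASS_ACTION, rates.d_E, "endosome_degradation"),
        ]
        observables = {
            "attached": {"P": 1.0},
            "in_endosomes": {"E": 1.0},
        }
    elif variant == "multilipoplex":
        N = design.N_max
        pits = [f"P_{i}" for i in range(1, N + 1)]
        endos = [f"E_{i}" for i in range(1, N + 1)]
        species = ["L_ex"] + pits + endos + ["L_in", "M", "G", "Gstar"]
        rx = [
            Reaction({"L_ex": 1}, {"P_1": 1}, ATTACH, rates.k_A, "attach_new_pit"),
        ]
        for i in range(1, N):
            rx.append(
                Reaction({"L_ex": 1, f"P_{i}": 1}, {f"P_{i+1}": 1}, ATTACH, rates.k_A, f"attach_join_{i}")
            )
        rx.append(Reaction({"L_ex": 1}, {}, WASH, rates.k_W_high, "wash"))
        for i in range(1, N + 1):
            rx.append(Reaction({f"P_{i}": 1}, {f"E_{i}": 1}, MASS_ACTION, rates.k_E, f"endocytosis_{i}"))
        for i in range(1, N + 1):
            rx.append(Reaction({f"E_{i}": 1}, {"L_in": i}, MASS_ACTION, rates.k_L, f"lysis_{i}"))
        for i in range(1, N + 1):
            rx.append(Reaction({f"E_{i}": 1}, {}, MASS_ACTION, rates.d_E, f"endosome_degradation_{i}"))
        observables = {
            "attached": {f"P_{i}": float(i) for i in range(1, N + 1)},
            "in_endosomes": {f"E_{i}": float(i) for i in range(1, N + 1)},
        }
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'streamlined' or 'multilipoplex'")

    rx += [
        Reaction({"L_in": 1}, {"M": S}, MASS_ACTION, rates.k_U, "unpacking"),
        Reaction({"L_in": 1}, {}, MASS_ACTION, rates.d_L, "lipoplex_degradation"),
        Reaction({"M": 1}, {}, MASS_ACTION, rates.d_M, "mrna_degradation"),
        Reaction({"M": 1}, {"M": 1, "G": 1}, MASS_ACTION, rates.k_TL, "translation"),
        Reaction({"G": 1}, {"Gstar": 1}, MASS_ACTION, rates.k_M, "maturation"),
        Reaction({"G": 1}, {}, MASS_ACTION, rates.d_G, "gfp_degradation_immature"),
        Reaction({"Gstar": 1}, {}, MASS_ACTION, rates.d_G, "gfp_degradation_mature"),
    ]
    observables["mrna"] = {"M": 1.0}
    observables["gfp"] = {"Gstar": 1.0}
    return ReactionNetwork(variant, species, rx, observables, rates, design)


def attach_propensity(k_A: float, L_ex_count: float, n_pits_occupied: int, n_full_pits: int = 0):
    """Per-channel and total attachment propensity under the pit-normalised rule.

    Returns ``(k_AX, per_channel, n_channels, total)``.  ``k_AX`` is
    ``k_A / (n_pits_occupied + 1)``; there is one new-pit channel plus one
    join channel per existing non-full pit, each firing at ``k_AX * L_ex``,
    so the total equals ``k_A * L_ex`` whenever no pit is at capacity.
    """
    if L_ex_count < 0 or n_pits_occupied < 0 or n_full_pits < 0:
        raise ValueError("counts must be >= 0")
    k_AX = k_A / (n_pits_occupied + 1)
    per_channel = k_AX * L_ex_count
    n_channels = n_pits_occupied - n_full_pits + 1
    return k_AX, per_channel, n_channels, per_channel * n_channels


def wash_rate(t: float, t_inc: float, k_W_high: float) -> float:
    """Washing rate: zero before the incubation time, ``k_W_high`` from it on."""
    return k_W_high if t >= t_inc else 0.0


def count_full_nested_species(size_states: int, N_max: int) -> int:
    """Number of distinct endosome states if per-lipoplex sizes were tracked.

    With each of up to ``N_max`` contained lipoplexes taking one of
    ``size_states`` sizes, the ordered listing needs ``size_states ** N_max``
    species -- the combinatorial explosion that motivates the fixed-size
    simplification.  Computed with exact big integers.
    """
    if size_states < 1 or N_max < 1:
        raise ValueError("size_states and N_max must be >= 1")
    return int(size_states) ** int(N_max)


def mrna_equivalent_weight(species: str, S: int) -> int:
    """mRNA equivalents carried by one unit of a species (proteins weigh 0)."""
    if species == "M":
        return 1
    if species in ("G", "Gstar"):
        return 0
    if species in ("L_ex", "L_in", "P", "E"):
        return S
    if species.startswith(("P_", "E_")):
        return int(species.split("_")[1]) * S
    raise KeyError(species)


def mrna_equivalent_change(reaction: Reaction, S: int) -> int:
    """Net change in mRNA equivalents caused by one firing of a reaction."""
    total = 0
    for sp, n in reaction.products.items():
        total += n * mrna_equivalent_weight(sp, S)
    for sp, n in reaction.reactants.items():
        total -= n * mrna_equivalent_weight(sp, S)
    return total


# ---------------------------------------------------------------------------
# compiled (array) form used by the simulation engines

K_FIRST, K_NEW, K_JOIN, K_WASH = 0, 1, 2, 3

#: labels whose firing times are recorded in the event log (the low-copy
#: delivery chain; the high-copy expression reactions would swamp it)
_RECORD_PREFIXES = ("attach", "wash", "endocytosis", "lysis", "endosome_degradation",
                    "unpacking", "lipoplex_degradation")


class CompiledNetwork:
    """Array representation of a :class:`ReactionNetwork` for the engines."""

    def __init__(self, network: ReactionNetwork):
        sp = network.species
        self.network = network
        self.species = sp
        self.n_species = len(sp)
        index = {s: i for i, s in enumerate(sp)}
        R = len(network.reactions)
        self.kind = np.zeros(R, dtype=np.int64)
        self.ridx = np.zeros(R, dtype=np.int64)
        self.k = np.zeros(R)
        self.delta = np.zeros((R, self.n_species), dtype=np.int64)
        self.labels = [r.label for r in network.reactions]
        self.lex = index["L_ex"]
        self.pit_idx = np.array(
            [index[s] for s in sp if s == "P" or s.startswith("P_")], dtype=np.int64
        )
        for j, r in enumerate(network.reactions):
            for s, n in r.reactants.items():
                self.delta[j, index[s]] -= n
            for s, n in r.products.items():
                self.delta[j, index[s]] += n
            self.k[j] = r.rate_constant
            if r.rate_kind == WASH:
                self.kind[j] = K_WASH
                self.ridx[j] = self.lex
            elif r.rate_kind == ATTACH:
                pit = [s for s in r.reactants if s != "L_ex"]
                if pit:
                    self.kind[j] = K_JOIN
                    self.ridx[j] = index[pit[0]]
                else:
                    self.kind[j] = K_NEW
                    self.ridx[j] = self.lex
            else:
                self.kind[j] = K_FIRST
                self.ridx[j] = next(index[s] for s in r.reactants)
        self.new_ids = np.flatnonzero(self.kind == K_NEW)
        self.join_ids = np.flatnonzero(self.kind == K_JOIN)
        self.wash_ids = np.flatnonzero(self.kind == K_WASH)
        self.has_attach = len(self.new_ids) + len(self.join_ids) > 0
        self.record_mask = np.array(
            [lbl.startswith(_RECORD_PREFIXES) for lbl in self.labels], dtype=bool
        )
        self.label_index = {lbl: j for j, lbl in enumerate(self.labels)}

    def propensities(self, x: np.ndarray, wash_on: bool) -> np.ndarray:
        """Propensity vector at integer/real state ``x``."""
        a = self.k * x[self.ridx]
        if self.has_attach:
            fac = x[self.lex] / (x[self.pit_idx].sum() + 1.0)
            a[self.new_ids] = self.k[self.new_ids] * fac
            a[self.join_ids] *= fac
        if len(self.wash_ids):
            if not wash_on:
                a[self.wash_ids] = 0.0
        return a

    def ids_with_prefix(self, prefix: str) -> np.ndarray:
        return np.flatnonzero([lbl == prefix or lbl.startswith(prefix + "_") for lbl in self.labels])
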