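"""Reaction network wiring: stoichiometry and rate-law kind per reaction.

Sixteen reactions over the eleven state variables.  SuSy runs in the
cleavage direction (Suc → Fru + UDPG, UDP implicit), trehalase cleaves
one trehalose into two glucose equivalents, and the SnRK1/PP pair forms
a conservative phospho-cycle over the two SPS peptide pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state import STATE_NAMES

__all__ = ["Reaction", "ReactionNetwork", "default_network", "RATE_LAW_KINDS"]

RATE_LAW_KINDS = (
    "constant_input",
    "mm_irrev",
    "mm_bisubstrate",
    "mass_action",
    "inv_mixed",
    "hxk_noncomp",
    "snrk1",
)


@dataclass(frozen=True)
class Reaction:
    """One reaction: name, rate-law kind and net stoichiometry."""

    name: str
    kind: str
    stoich: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in RATE_LAW_KINDS:
            raise ValueError(f"unknown rate-law kind {self.kind!r} for {self.name}")
        unknown = set(self.stoich) - set(STATE_NAMES)
        if unknown:
            raise ValueError(f"reaction {self.name}: unknown species {sorted(unknown)}")


class ReactionNetwork:
    """Ordered reaction list with a cached stoichiometry matrix N.

    The right-hand side of the ODE system is N·r, r being the vector of
    reaction rates in the same order.
    """

    def __init__(self, reactions: list[Reaction]):
        names = [r.name for r in reactions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reaction names")
        self.reactions = tuple(reactions)
        self.names = tuple(names)
        n = np.zeros((len(STATE_NAMES), len(reactions)))
        for j, rxn in enumerate(reactions):
            for sp, coeff in rxn.stoich.items():
                n[STATE_NAMES.index(sp), j] = coeff
        self._n = n
        self._n.setflags(write=False)

    @property
    def stoichiometry(self) -> np.ndarray:
        return self._n

    def __len__(self) -> int:
        return len(self.reactions)

    def index(self, name: str) -> int:
        return self.names.index(name)


_REACTIONS = [
    Reaction("Suc_import", "mm_irrev", {"Suc": +1}),
    Reaction("cFBPase_input", "constant_input", {"F6P": +1}),
    Reaction("PGI", "mass_action", {"F6P": -1, "G6P": +1}),
    Reaction("PGM", "mass_action", {"G6P": -1, "G1P": +1}),
    Reaction("UGPase", "mass_action", {"G1P": -1, "UDPG": +1}),
    Reaction("SPS", "mm_bisubstrate", {"F6P": -1, "UDPG": -1, "Suc": +1}),
    Reaction("TPS", "mm_bisubstrate", {"G6P": -1, "UDPG": -1, "T6P": +1}),
    Reaction("TPP", "mass_action", {"T6P": -1, "Tre": +1}),
    Reaction("Trehalase", "mm_irrev", {"Tre": -1, "Glc": +2}),
    Reaction("Inv", "inv_mixed", {"Suc": -1, "Glc": +1, "Fru": +1}),
    Reaction("GlcK", "hxk_noncomp", {"Glc": -1, "G6P": +1}),
    Reaction("FrcK", "hxk_noncomp", {"Fru": -1, "F6P": +1}),
    Reaction("SuSy", "mass_action", {"Suc": -1, "Fru": +1, "UDPG": +1}),
    Reaction("Suc_export", "mm_irrev", {"Suc": -1}),
    Reaction("SnRK1_phos", "snrk1", {"E_SPS_act": -1, "E_SPS_inact": +1}),
    Reaction("PP_dephos", "mm_irrev", {"E_SPS_inact": -1, "E_SPS_act": +1}),
]

_DEFAULT = ReactionNetwork(_REACTIONS)


def default_network() -> ReactionNetwork:
    """The shipped network topology (Figure-1-style wiring)."""
    return _DEFAULT
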