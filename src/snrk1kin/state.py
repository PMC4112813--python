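"""Model state: nine cytosolic metabolite pools plus the SPS phospho-cycle.

Sucrose-6-phosphate is deliberately absent: SPS and SPP are treated as a
single catalytic unit, so sucrose synthesis runs F6P + UDPG → Suc in one
lumped step and no free S6P pool exists.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

#: Canonical ordering of the state vector.
STATE_NAMES = (
    "F6P",
    "G6P",
    "G1P",
    "UDPG",
    "T6P",
    "Tre",
    "Suc",
    "Glc",
    "Fru",
    "E_SPS_act",
    "E_SPS_inact",
)

METABOLITE_NAMES = STATE_NAMES[:9]
PEPTIDE_NAMES = STATE_NAMES[9:]


@dataclass
class ModelState:
    """Concentrations in μmol gFW⁻¹ (metabolites) / peptide amounts (SPS).

    ``E_SPS_act`` is the dephosphorylated, catalytically active SPS
    peptide; ``E_SPS_inact`` the Ser-phosphorylated, inactive form.
    Their sum is conserved along any trajectory.
    """

    F6P: float
    G6P: float
    G1P: float
    UDPG: float
    T6P: float
    Tre: float
    Suc: float
    Glc: float
    Fru: float
    E_SPS_act: float
    E_SPS_inact: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"state field {f.name} is not finite: {v!r}")
            if v < 0:
                raise ValueError(f"state field {f.name} is negative: {v!r}")

    @property
    def e_sps_total(self) -> float:
        return self.E_SPS_act + self.E_SPS_inact

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_NAMES),):
            raise ValueError(
                f"expected state vector of length {len(STATE_NAMES)}, got shape {y.shape}"
            )
        return cls(**dict(zip(STATE_NAMES, y)))

    def replace(self, **kwargs: float) -> "ModelState":
        d = {n: getattr(self, n) for n in STATE_NAMES}
        d.update(kwargs)
        return ModelState(**d)


def default_initial_state(e_sps_total: float = 8.5e-6, active_fraction: float = 0.20) -> ModelState:
    """C-starved initial condition at the onset of external sucrose feeding.

    Metabolite values are a plausible low-sugar vector for carbon-starved
    Arabidopsis seedlings (sub-μmol sugar pools, trehalose and T6P in the
    nM range).  The active SPS fraction defaults to 20%, the midpoint of
    the 15–25% range estimated for C-starved tissue.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    return ModelState(
        F6P=0.04,
        G6P=0.06,
        G1P=0.02,
        UDPG=0.30,
        T6P=2.0e-5,
        Tre=1.0e-4,
        Suc=0.25,
        Glc=0.20,
        Fru=0.10,
        E_SPS_act=active_fraction * e_sps_total,
        E_SPS_inact=(1.0 - active_fraction) * e_sps_total,
    )
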