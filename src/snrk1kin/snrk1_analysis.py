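"""Inhibitor-sweep and operating-point analyses of the SnRK1 rate law.

The sweep reproduces the single/combined inhibitor titrations (all
member inhibitors of a combination varied jointly from 0 to 1 mM at
saturating substrate); the operating-point analysis evaluates the
realized SnRK1 phosphorylation rate along a simulated trajectory, i.e.
at the inhibitor and substrate levels the network actually visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import SnRK1Params
from .ratelaws import InhibitorVector, rate_snrk1
from .simulate import SimulationResult
from .state import ModelState

__all__ = ["SweepSpec", "DEFAULT_COMBINATIONS", "inhibitor_sweep", "operating_point"]

INHIBITORS = ("T6P", "G1P", "G6P")

#: The seven combinations of the titration figure.
DEFAULT_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("T6P",),
    ("G1P",),
    ("G6P",),
    ("T6P", "G1P"),
    ("T6P", "G6P"),
    ("G1P", "G6P"),
    ("T6P", "G1P", "G6P"),
)


@dataclass(frozen=True)
class SweepSpec:
    """Grid and combination set for an inhibitor titration.

    The substrate level defaults to 10³ × KM-scale saturation — the
    inhibition is purely of the v_max type, so the saturating choice
    isolates the inhibitor effect.
    """

    grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 201))
    combinations: tuple[tuple[str, ...], ...] = DEFAULT_COMBINATIONS
    substrate: float | None = None  # None -> 1e3 * km_e

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or g.size == 0:
            raise ValueError("grid must be a nonempty 1-D array")
        if np.any(g < 0):
            raise ValueError("grid concentrations must be nonnegative")
        if np.any(np.diff(g) <= 0) and g.size > 1:
            raise ValueError("grid must be strictly ascending")
        object.__setattr__(self, "grid", g)
        if len(self.combinations) == 0:
            raise ValueError("combination set must be nonempty")
        for combo in self.combinations:
            unknown = set(combo) - set(INHIBITORS)
            if unknown:
                raise ValueError(f"unknown inhibitor(s) {sorted(unknown)} in {combo}")


def combination_label(combo: Iterable[str]) -> str:
    return "+".join(combo)


def inhibitor_sweep(spec: SweepSpec, p: SnRK1Params) -> pd.DataFrame:
    """Tidy table of residual SnRK1 activity over the titration grid.

    Columns: ``combination``, ``conc_mM``, ``rate`` (μmol h⁻¹ gFW⁻¹) and
    ``fraction_of_vmax``.  Each curve starts at the uninhibited rate and
    is monotone non-increasing; a pure function of (spec, params).
    """
    e = spec.substrate if spec.substrate is not None else 1e3 * p.km_e
    rows = []
    for combo in spec.combinations:
        label = combination_label(combo)
        for c in spec.grid:
            inh = InhibitorVector(**{name: (c if name in combo else 0.0) for name in INHIBITORS})
            v = rate_snrk1(e, inh, p)
            rows.append((label, float(c), v, v / p.vmax))
    return pd.DataFrame(rows, columns=["combination", "conc_mM", "rate", "fraction_of_vmax"])


def operating_point(
    states: Sequence[ModelState] | SimulationResult,
    p: SnRK1Params,
    times: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Realized SnRK1 phosphorylation rate along a trajectory.

    Accepts either a sequence of states (with optional ``times``) or a
    :class:`SimulationResult` directly.  Returns a DataFrame with
    columns ``time_h`` and ``v_snrk1``.
    """
    if isinstance(states, SimulationResult):
        result = states
        times = result.time
        seq = [result.state_at(i) for i in range(len(result.time))]
    else:
        seq = list(states)
        if times is None:
            times = np.arange(len(seq), dtype=float)
    if len(seq) != len(times):
        raise ValueError("states and times must have equal length")
    rates = [
        rate_snrk1(s.E_SPS_act, InhibitorVector(T6P=s.T6P, G1P=s.G1P, G6P=s.G6P), p)
        for s in seq
    ]
    return pd.DataFrame({"time_h": np.asarray(times, dtype=float), "v_snrk1": rates})
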