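"""Time-course integration of the sucrose-feeding protocol.

The feeding experiment supplies C-starved seedlings with a constant
15 mM external sucrose reservoir for 3 or 8 hours.  The system is stiff:
metabolite pools span ~10⁻⁵–10⁰ μmol gFW⁻¹ while the SPS phospho-cycle
turns over its ~10⁻⁶ μmol gFW⁻¹ peptide pool on a sub-second timescale,
so an implicit/stiff-capable integrator with tight tolerances is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import ReactionNetwork, default_network
from .odes import ode_rhs, reaction_rates
from .params import ParameterSet
from .state import STATE_NAMES, ModelState, default_initial_state

__all__ = [
    "Protocol",
    "SimulationResult",
    "integrate",
    "activation_crossing_time",
    "t6p_vs_suc",
]


@dataclass(frozen=True)
class Protocol:
    """Feeding protocol: when and how much external sucrose is supplied."""

    t_start: float = 0.0
    t_end: float = 3.0
    suc_external: float = 15.0
    onset: float = 0.0
    n_points: int = 1000

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.suc_external < 0:
            raise ValueError("suc_external must be nonnegative")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")

    def grid(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_points)


def feeding_protocol(hours: float = 3.0, suc_external: float = 15.0, n_points: int = 1000) -> Protocol:
    """Standard protocol: feeding from t = 0 for ``hours`` hours."""
    return Protocol(0.0, hours, suc_external, 0.0, n_points)


@dataclass
class SimulationResult:
    """Trajectory on the output grid plus solver diagnostics.

    ``states``/``fluxes`` are tidy DataFrames indexed by time (hours);
    fluxes are recomputed from the stored states, so the two matrices
    are always mutually consistent.
    """

    time: np.ndarray
    states: pd.DataFrame
    fluxes: pd.DataFrame
    params: ParameterSet
    protocol: Protocol
    diagnostics: dict = field(default_factory=dict)

    def state_at(self, i: int) -> ModelState:
        return ModelState.from_array(np.clip(self.states.iloc[i].to_numpy(), 0.0, None))

    def final_state(self) -> ModelState:
        return self.state_at(-1)

    @property
    def e_sps_total(self) -> np.ndarray:
        return (self.states["E_SPS_act"] + self.states["E_SPS_inact"]).to_numpy()


def integrate(
    params: ParameterSet,
    init: ModelState | None = None,
    protocol: Protocol | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    network: ReactionNetwork | None = None,
) -> SimulationResult:
    """Integrate the model over the protocol span.

    Raises
    ------
    RuntimeError
        On solver failure, reporting the last accepted time.
    """
    if init is None:
        init = default_initial_state(e_sps_total=params.e_sps_total)
    if protocol is None:
        protocol = Protocol()
    init.validate()
    net = network if network is not None else default_network()
    t_grid = protocol.grid()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return ode_rhs(
            t, y, params, net,
            suc_external=protocol.suc_external,
            feeding_onset=protocol.onset,
        )

    sol = solve_ivp(
        rhs,
        (protocol.t_start, protocol.t_end),
        init.to_array(),
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else protocol.t_start
        raise RuntimeError(
            f"integration failed at t = {last_t:.6g} h: {sol.message}"
        )

    states = pd.DataFrame(sol.y.T, index=pd.Index(sol.t, name="time_h"), columns=STATE_NAMES)
    flux_rows = np.empty((sol.t.size, len(net)))
    for i, (t, y) in enumerate(zip(sol.t, sol.y.T)):
        s_ext = protocol.suc_external if t >= protocol.onset else 0.0
        flux_rows[i] = reaction_rates(y, params, suc_external=s_ext)
    fluxes = pd.DataFrame(flux_rows, index=states.index, columns=net.names)

    diagnostics = {
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "n_rhs_evaluations": int(sol.nfev),
        "n_jacobian_evaluations": int(getattr(sol, "njev", 0) or 0),
        "message": sol.message,
    }
    return SimulationResult(sol.t, states, fluxes, params, protocol, diagnostics)


def activation_crossing_time(result: SimulationResult) -> float:
    """First time at which E_SPS_act reaches E_SPS_inact.

    Returns 0 if the initial state is already at or past the crossing;
    the crossing inside a grid interval is located by linear
    interpolation of the (E_act − E_inact) difference on the stored
    grid.

    Raises
    ------
    ValueError
        If no crossing occurs within the simulated span.
    """
    diff = (result.states["E_SPS_act"] - result.states["E_SPS_inact"]).to_numpy()
    t = result.time
    if diff[0] >= 0:
        return 0.0
    idx = np.nonzero(diff >= 0)[0]
    if idx.size == 0:
        raise ValueError(
            "active SPS peptide never reaches the inactive pool within "
            f"[{t[0]:.4g}, {t[-1]:.4g}] h"
        )
    j = idx[0]
    t0, t1 = t[j - 1], t[j]
    d0, d1 = diff[j - 1], diff[j]
    if d1 == d0:
        return float(t1)
    return float(t0 + (0.0 - d0) / (d1 - d0) * (t1 - t0))


def t6p_vs_suc(result: SimulationResult) -> pd.DataFrame:
    """Phase-plane curve (Suc, T6P) along the trajectory, time-ordered."""
    return pd.DataFrame(
        {
            "Suc": result.states["Suc"].to_numpy(),
            "T6P": result.states["T6P"].to_numpy(),
        },
        index=result.states.index,
    )
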