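"""ODE right-hand side: stoichiometry × rate vector.

The rate expressions here mirror :mod:`snrk1kin.ratelaws` but are
evaluated without argument validation so the integrator may probe
slightly negative trial states; every law vanishes continuously at zero
substrate, so no clipping or artificial floors are needed.  The two
phospho-cycle derivatives are exact negatives of each other by
construction, which keeps E_act + E_inact conserved to rounding.
"""

from __future__ import annotations

import numpy as np

from .network import ReactionNetwork, default_network
from .params import ParameterSet
from .state import STATE_NAMES, ModelState

__all__ = ["reaction_rates", "ode_rhs", "rhs_from_state"]

_I = {name: i for i, name in enumerate(STATE_NAMES)}
_iF6P, _iG6P, _iG1P, _iUDPG = _I["F6P"], _I["G6P"], _I["G1P"], _I["UDPG"]
_iT6P, _iTre, _iSuc, _iGlc, _iFru = _I["T6P"], _I["Tre"], _I["Suc"], _I["Glc"], _I["Fru"]
_iEact, _iEinact = _I["E_SPS_act"], _I["E_SPS_inact"]


def reaction_rates(
    y: np.ndarray, p: ParameterSet, suc_external: float | None = None
) -> np.ndarray:
    """All 16 reaction rates (μmol gFW⁻¹ h⁻¹) at state vector ``y``.

    ``suc_external`` overrides the parameter value (used to switch the
    feeding input off before the onset of the protocol).
    """
    f6p, g6p, g1p, udpg = y[_iF6P], y[_iG6P], y[_iG1P], y[_iUDPG]
    t6p, tre, suc, glc, fru = y[_iT6P], y[_iTre], y[_iSuc], y[_iGlc], y[_iFru]
    e_act, e_inact = y[_iEact], y[_iEinact]

    s_ext = p.suc_external if suc_external is None else suc_external

    v_import = p.vmax_suc_import * s_ext / (p.km_suc_import + s_ext) if s_ext > 0 else 0.0
    v_cfbp = p.v_cfbpase
    v_pgi = p.k_pgi * f6p
    v_pgm = p.k_pgm * g6p
    v_ugp = p.k_ugpase * g1p
    v_sps = (
        p.k_sps * e_act
        * (f6p / (p.km_sps_f6p + f6p))
        * (udpg / (p.km_sps_udpg + udpg))
    )
    v_tps = (
        p.vmax_tps
        * (g6p / (p.km_tps_g6p + g6p))
        * (udpg / (p.km_tps_udpg + udpg))
    )
    v_tpp = p.k_tpp * t6p
    v_th = p.vmax_trehalase * tre / (p.km_trehalase + tre)
    v_inv = (
        p.vmax_inv * suc
        / ((1.0 + glc / p.ki_inv_glc) * (p.km_inv * (1.0 + fru / p.ki_inv_fru) + suc))
    )
    v_glck = p.vmax_glck * glc / ((p.km_glck + glc) * (1.0 + g6p / p.ki_glck_g6p))
    v_frck = p.vmax_frck * fru / ((p.km_frck + fru) * (1.0 + f6p / p.ki_frck_f6p))
    v_susy = p.k_susy * suc
    v_exp = p.vmax_suc_export * suc / (p.km_suc_export + suc)

    x_t = t6p / p.ki_t6p
    x_g1 = g1p / p.ki_g1p
    x_g6 = g6p / p.ki_g6p
    v_snrk1 = (
        p.vmax_snrk1 * e_act * (1.0 + p.k_partial * x_t)
        / (p.km_snrk1 + e_act * (1.0 + x_t + x_g1 + x_g6 + x_t * x_g1 + x_t * x_g6))
    )
    v_pp = p.vmax_pp * e_inact / (p.km_pp + e_inact)

    return np.array(
        [
            v_import, v_cfbp, v_pgi, v_pgm, v_ugp, v_sps, v_tps, v_tpp,
            v_th, v_inv, v_glck, v_frck, v_susy, v_exp, v_snrk1, v_pp,
        ]
    )


def ode_rhs(
    t: float,
    y: np.ndarray,
    p: ParameterSet,
    network: ReactionNetwork | None = None,
    suc_external: float | None = None,
    feeding_onset: float = 0.0,
) -> np.ndarray:
    """d(state)/dt at time ``t`` (hours).

    Before ``feeding_onset`` the external sucrose reservoir is empty and
    the import flux is zero; from the onset on it is held at the
    (constant, non-depleting) external concentration.
    """
    if network is None:
        network = default_network()
    if not np.all(np.isfinite(y)):
        bad = [STATE_NAMES[i] for i in np.nonzero(~np.isfinite(y))[0]]
        raise FloatingPointError(
            f"non-finite state at t={t!r}: {bad} (integration diverged)"
        )
    if t < feeding_onset:
        suc_external = 0.0
    r = reaction_rates(y, p, suc_external=suc_external)
    dy = network.stoichiometry @ r
    # exact antisymmetry of the phospho-cycle: overwrite the matrix product
    # with the directly assembled difference so the pair sums to 0.0 in
    # floating point
    v_snrk1, v_pp = r[14], r[15]
    dy[_iEact] = v_pp - v_snrk1
    dy[_iEinact] = -dy[_iEact]
    return dy


def rhs_from_state(
    state: ModelState,
    p: ParameterSet,
    network: ReactionNetwork | None = None,
    t: float = 0.0,
    suc_external: float | None = None,
) -> np.ndarray:
    """Convenience wrapper taking a :class:`ModelState` (validates it)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    state.validate()
    return ode_rhs(t, state.to_array(), p, network, suc_external=suc_external)
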