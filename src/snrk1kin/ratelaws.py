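"""Enzyme rate laws of the cytosolic carbohydrate network.

Five kinetic forms cover every reaction in the network:

* irreversible, non-inhibited Michaelis–Menten (import, export,
  trehalase, PP);
* irreversible mass action, v = k·[S] (PGI, PGM, UGPase, TPP, SuSy);
* bi-substrate Michaelis–Menten as a product of saturation factors
  (SPS, with v_max tied to the active peptide amount; TPS);
* Michaelis–Menten with mixed product inhibition — Glc non-competitive,
  Fru competitive (invertase);
* Michaelis–Menten with non-competitive product inhibition (the two
  hexokinase activities, GlcK inhibited by G6P and FrcK by F6P);

plus the SnRK1 law: partial non-competitive mixed-type inhibition by
T6P combined with non-competitive inhibition by G1P and G6P, including
the T6P·G1P and T6P·G6P interaction terms.  At saturating T6P the SnRK1
rate does not vanish but approaches the fraction ``k_partial`` of its
uninhibited maximum; none of the inhibitors changes the substrate
affinity, only the apparent v_max.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import SnRK1Params

__all__ = [
    "InhibitorVector",
    "rate_mm_irrev",
    "rate_mass_action",
    "rate_sps",
    "rate_tps",
    "rate_snrk1",
    "rate_inv_mixed",
    "rate_hxk_noncomp",
]


@dataclass(frozen=True)
class InhibitorVector:
    """Concentrations (mM) of the three sugar-phosphate inhibitors of SnRK1."""

    T6P: float = 0.0
    G1P: float = 0.0
    G6P: float = 0.0

    def __post_init__(self) -> None:
        for name in ("T6P", "G1P", "G6P"):
            if getattr(self, name) < 0:
                raise ValueError(f"inhibitor {name} must be nonnegative")


def _check_positive(**constants: float) -> None:
    for name, v in constants.items():
        if not v > 0:
            raise ValueError(f"kinetic constant {name} must be positive, got {v!r}")


def _check_nonnegative(**concs: float) -> None:
    for name, v in concs.items():
        if v < 0:
            raise ValueError(f"concentration {name} must be nonnegative, got {v!r}")


def rate_mm_irrev(vmax: float, km: float, s: float) -> float:
    """Irreversible non-inhibited Michaelis–Menten rate v = vmax·S/(KM+S)."""
    _check_positive(vmax=vmax, km=km)
    _check_nonnegative(S=s)
    return vmax * s / (km + s)


def rate_mass_action(k: float, s: float) -> float:
    """First-order mass-action rate v = k·S."""
    _check_positive(k=k)
    _check_nonnegative(S=s)
    return k * s


def rate_sps(
    e_act: float,
    f6p: float,
    udpg: float,
    k_sps: float,
    km_f6p: float,
    km_udpg: float,
) -> float:
    """SPS bi-substrate rate with v_max proportional to the active peptide.

    v = k_SPS·E_act · F6P/(KM_F6P+F6P) · UDPG/(KM_UDPG+UDPG).  The
    maximal velocity is not a constant: it is k_SPS times the current
    amount of dephosphorylated (active) SPS peptide, which couples
    sucrose synthesis to the SnRK1/PP phospho-cycle.
    """
    _check_positive(k_sps=k_sps, km_f6p=km_f6p, km_udpg=km_udpg)
    _check_nonnegative(E_act=e_act, F6P=f6p, UDPG=udpg)
    return k_sps * e_act * (f6p / (km_f6p + f6p)) * (udpg / (km_udpg + udpg))


def rate_tps(
    vmax: float, g6p: float, udpg: float, km_g6p: float, km_udpg: float
) -> float:
    """TPS bi-substrate Michaelis–Menten rate on G6P and UDPG."""
    _check_positive(vmax=vmax, km_g6p=km_g6p, km_udpg=km_udpg)
    _check_nonnegative(G6P=g6p, UDPG=udpg)
    return vmax * (g6p / (km_g6p + g6p)) * (udpg / (km_udpg + udpg))


def rate_snrk1(e_act: float, inh: InhibitorVector, p: SnRK1Params) -> float:
    """SPS-phosphorylation rate of SnRK1 under sugar-phosphate inhibition.

    Partial non-competitive mixed-type inhibition by T6P (residual
    fraction ``k_partial`` at saturation) combined with non-competitive
    inhibition by G1P and G6P, with T6P·G1P and T6P·G6P cross terms::

        v = vmax·E·(1 + k_p·T/Ki_T)
            / ( KM_E + E·(1 + T/Ki_T + G1/Ki_G1 + G6/Ki_G6
                          + T·G1/(Ki_T·Ki_G1) + T·G6/(Ki_T·Ki_G6)) )

    The rate is monotone non-increasing in each inhibitor and vanishes
    with the substrate E (active SPS peptide).
    """
    _check_nonnegative(E_act=e_act)
    x_t = inh.T6P / p.ki_t6p
    x_g1 = inh.G1P / p.ki_g1p
    x_g6 = inh.G6P / p.ki_g6p
    numer = p.vmax * e_act * (1.0 + p.k_partial * x_t)
    denom = p.km_e + e_act * (1.0 + x_t + x_g1 + x_g6 + x_t * x_g1 + x_t * x_g6)
    return numer / denom


def rate_inv_mixed(
    vmax: float,
    km: float,
    suc: float,
    glc: float,
    fru: float,
    ki_glc_nc: float,
    ki_fru_c: float,
) -> float:
    """Invertase rate with mixed product inhibition.

    Glc acts non-competitively (scales the apparent v_max), Fru acts
    competitively (scales the apparent K_M); at Glc = Fru = 0 the law
    reduces to plain Michaelis–Menten.
    """
    _check_positive(vmax=vmax, km=km, ki_glc_nc=ki_glc_nc, ki_fru_c=ki_fru_c)
    _check_nonnegative(Suc=suc, Glc=glc, Fru=fru)
    return vmax * suc / ((1.0 + glc / ki_glc_nc) * (km * (1.0 + fru / ki_fru_c) + suc))


def rate_hxk_noncomp(vmax: float, km: float, s: float, i: float, ki_i: float) -> float:
    """Hexokinase rate: Michaelis–Menten, non-competitively inhibited.

    Used for both activities: glucokinase (S = Glc, I = G6P) and
    fructokinase (S = Fru, I = F6P).
    """
    _check_positive(vmax=vmax, km=km, ki_i=ki_i)
    _check_nonnegative(S=s, I=i)
    return vmax * s / ((km + s) * (1.0 + i / ki_i))
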