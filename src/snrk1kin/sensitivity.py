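"""Steady-state sensitivity analysis and in-silico hexokinase overexpression.

A parameter is perturbed by a small fraction (1% by default), both the
reference and the perturbed system are brought to steady state, and the
relative change of every state and flux per relative parameter change
is reported (one-sided forward difference, matching the
perturb-and-compare procedure of classical systems-biology toolboxes).
The hexokinase-overexpression comparison multiplies the v_max of
glucokinase and fructokinase (threefold by default) and tabulates the
ratio of overexpressed to wild-type sensitivities, sorted descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet
from .state import STATE_NAMES, ModelState
from .steady_state import SteadyStateResult, find_steady_state

__all__ = [
    "SensitivityReport",
    "steady_sensitivity",
    "hxk_overexpress",
    "sensitivity_ratio_table",
]

#: Denominator threshold below which a sensitivity ratio is flagged.
NEAR_ZERO = 1e-9


@dataclass
class SensitivityReport:
    """Per-state/per-flux relative sensitivities (and, for comparisons,
    overexpressed/wild-type ratios)."""

    perturbed_parameter: str
    fraction: float
    sensitivities: pd.Series  # states then fluxes
    variant: str = "wild-type"
    ratios: pd.Series | None = None
    near_zero_flags: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Ratio table sorted descending (comparison reports only)."""
        if self.ratios is None:
            raise ValueError("this report carries no overexpression ratios")
        df = pd.DataFrame(
            {"sensitivity_ratio": self.ratios, "near_zero_reference": self.near_zero_flags}
        )
        return df.sort_values("sensitivity_ratio", ascending=False)


def _steady_profile(params: ParameterSet, guess: ModelState | None, label: str) -> tuple[pd.Series, SteadyStateResult]:
    res = find_steady_state(params, guess=guess, variant_label=label)
    if not res.converged:
        raise RuntimeError(f"steady state failed for the {label} case: {res.message}")
    values = {name: getattr(res.state, name) for name in STATE_NAMES}
    values.update({f"v_{k}": v for k, v in res.fluxes.items()})
    return pd.Series(values), res


def steady_sensitivity(
    params: ParameterSet,
    perturb_param: str,
    fraction: float = 0.01,
    guess: ModelState | None = None,
    variant: str = "wild-type",
) -> SensitivityReport:
    """Relative steady-state sensitivities to a fractional perturbation.

    S_x = [(x_pert − x_ref)/x_ref] / fraction, with both the reference
    and the perturbed system at their converged steady states.
    """
    if fraction <= 0:
        raise ValueError("perturbation fraction must be positive")
    if perturb_param not in params:
        raise ValueError(f"unknown parameter {perturb_param!r}")

    ref_profile, ref_res = _steady_profile(params, guess, f"{variant} reference")
    pert_params = params.update(
        **{perturb_param: params[perturb_param] * (1.0 + fraction)}, validate=False
    )
    pert_profile, _ = _steady_profile(pert_params, ref_res.state, f"{variant} perturbed")

    with np.errstate(divide="ignore", invalid="ignore"):
        sens = ((pert_profile - ref_profile) / ref_profile) / fraction
    sens = sens.where(ref_profile.abs() > 0.0, 0.0)
    return SensitivityReport(
        perturbed_parameter=perturb_param,
        fraction=fraction,
        sensitivities=sens,
        variant=variant,
        metadata={"reference_profile": ref_profile, "steady_state": ref_res},
    )


def hxk_overexpress(params: ParameterSet, factor: float = 3.0) -> ParameterSet:
    """Multiply the v_max of glucokinase and fructokinase by ``factor``.

    Emulates hexokinase overexpression; no other parameter is touched.
    """
    if factor <= 0:
        raise ValueError("overexpression factor must be positive")
    return params.update(
        vmax_glck=params.vmax_glck * factor,
        vmax_frck=params.vmax_frck * factor,
        validate=False,
    )


def sensitivity_ratio_table(
    params: ParameterSet,
    factor: float = 3.0,
    perturb_param: str = "suc_external",
    fraction: float = 0.01,
    guess: ModelState | None = None,
) -> SensitivityReport:
    """Overexpressed/wild-type sensitivity ratios for every state and flux.

    ``params`` must admit a steady state (use the invertase-modified
    variant).  Ratios where the wild-type sensitivity is numerically
    zero are flagged and reported as NaN.
    """
    wt = steady_sensitivity(params, perturb_param, fraction, guess, variant="wild-type")
    ox_params = hxk_overexpress(params, factor)
    # the wild-type root is a good starting point for the overexpressed solve
    wt_root = wt.metadata["steady_state"].state
    ox = steady_sensitivity(
        ox_params, perturb_param, fraction, guess or wt_root,
        variant="Hxk-overexpressed",
    )

    ref = wt.sensitivities
    flags = ref.abs() < NEAR_ZERO
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = ox.sensitivities / ref
    ratios = ratios.where(~flags, np.nan)
    return SensitivityReport(
        perturbed_parameter=perturb_param,
        fraction=fraction,
        sensitivities=ox.sensitivities,
        variant=f"Hxk x{factor:g} vs wild-type",
        ratios=ratios,
        near_zero_flags=flags,
        metadata={"wild_type": wt, "overexpressed": ox, "factor": factor},
    )
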