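"""Kinetic parameters: named constants with units and bounds, plus YAML I/O.

The parameter values fixed by published measurements are:

* ``k_sps`` = 2.98×10⁶ h⁻¹, from v_max,SPS = 422 nmol gFW⁻¹ min⁻¹
  (= 25.32 μmol gFW⁻¹ h⁻¹) divided by E_SPS,total = 8.5×10⁻⁶ μmol gFW⁻¹;
* ``vmax_snrk1`` = 1.35 μmol peptide h⁻¹ gFW⁻¹ (2.25 nmol min⁻¹
  mgProtein⁻¹ at 10 mg protein gFW⁻¹);
* ``km_snrk1`` = 10⁻⁷ mM and ``k_partial`` = 0.29 (partial non-competitive
  mixed-type inhibition by T6P);
* ``ki_t6p`` = 0.005 mM, ``ki_g1p`` = 0.48 mM, ``ki_g6p`` > 1 mM
  (default 1.5 mM, only a lower bound is published).

All remaining constants are this package's default calibration of the
feeding experiment (15 mM external sucrose supplied to C-starved
seedlings); see docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ParamSpec",
    "PARAM_TABLE",
    "SnRK1Params",
    "ParameterSet",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]


@dataclass(frozen=True)
class ParamSpec:
    unit: str
    default: float
    lower: float
    upper: float
    description: str


def _spec(unit: str, default: float, lower: float, upper: float, desc: str) -> ParamSpec:
    return ParamSpec(unit, default, lower, upper, desc)


#: Full schema of the model's kinetic constants.  Bounds are the fitting
#: box used by the estimator and enforced at load time.
PARAM_TABLE: dict[str, ParamSpec] = {
    # --- sucrose import (Michaelis-Menten on the external reservoir) ---
    "vmax_suc_import": _spec("umol/gFW/h", 2.5, 0.1, 25.0, "max sucrose uptake rate"),
    "km_suc_import": _spec("mM", 5.0, 0.5, 50.0, "uptake affinity for external sucrose"),
    "suc_external": _spec("mM", 15.0, 0.0, 100.0, "external sucrose during feeding"),
    # --- cFBPase input flux (F16P is not a state) ---
    "v_cfbpase": _spec("umol/gFW/h", 0.3, 0.0, 2.0, "constant cFBPase input flux to F6P"),
    # --- mass-action steps (not rate limiting) ---
    "k_pgi": _spec("1/h", 2.5, 0.01, 250.0, "phosphoglucoisomerase F6P->G6P"),
    "k_pgm": _spec("1/h", 4.4, 0.01, 440.0, "phosphoglucomutase G6P->G1P"),
    "k_ugpase": _spec("1/h", 15.4, 0.01, 1540.0, "UGPase G1P->UDPG"),
    "k_tpp": _spec("1/h", 407.0, 0.01, 2000.0, "trehalose-6-phosphate phosphatase T6P->Tre"),
    "k_susy": _spec("1/h", 0.0126, 1e-5, 5.0, "sucrose synthase cleavage Suc->Fru+UDPG"),
    # --- SPS / phospho-cycle ---
    "k_sps": _spec("1/h", 2.98e6, 1.0e6, 6.0e6, "SPS turnover constant (vmax_SPS/E_total)"),
    "km_sps_f6p": _spec("mM", 0.316, 0.01, 10.0, "SPS affinity for F6P"),
    "km_sps_udpg": _spec("mM", 1.9, 0.01, 10.0, "SPS affinity for UDPG"),
    "e_sps_total": _spec("umol/gFW", 8.5e-6, 5.0e-6, 2.0e-5, "total SPS peptide amount"),
    "vmax_snrk1": _spec("umol/gFW/h", 1.35, 0.1, 13.5, "max SPS phosphorylation rate by SnRK1"),
    "km_snrk1": _spec("mM", 1.0e-7, 1.0e-9, 1.0e-5, "SnRK1 affinity for active SPS peptide"),
    "ki_t6p": _spec("mM", 0.005, 0.0005, 0.05, "SnRK1 inhibition constant for T6P"),
    "ki_g1p": _spec("mM", 0.48, 0.048, 4.8, "SnRK1 inhibition constant for G1P"),
    "ki_g6p": _spec("mM", 1.5, 1.0, 15.0, "SnRK1 inhibition constant for G6P (>1 mM)"),
    "k_partial": _spec("-", 0.29, 0.01, 1.0, "partial-inhibition ratio for T6P"),
    "vmax_pp": _spec("umol/gFW/h", 1.41, 0.1, 13.8, "max SPS dephosphorylation rate by PP"),
    "km_pp": _spec("umol/gFW", 5e-08, 1.0e-9, 1.0e-5, "PP affinity for inactive SPS peptide"),
    # --- trehalose pathway ---
    "vmax_tps": _spec("umol/gFW/h", 2.26, 0.001, 10.0, "max T6P synthesis rate (TPS)"),
    "km_tps_g6p": _spec("mM", 0.131, 0.01, 10.0, "TPS affinity for G6P"),
    "km_tps_udpg": _spec("mM", 4.24, 0.01, 10.0, "TPS affinity for UDPG"),
    "vmax_trehalase": _spec("umol/gFW/h", 0.716, 0.001, 10.0, "max trehalose cleavage rate"),
    "km_trehalase": _spec("mM", 0.053, 0.001, 5.0, "trehalase affinity for Tre"),
    # --- invertase (mixed product inhibition) ---
    "vmax_inv": _spec("umol/gFW/h", 1.68, 0.05, 15.0, "max sucrose cleavage rate (Inv)"),
    "km_inv": _spec("mM", 1.78, 0.1, 50.0, "invertase affinity for Suc"),
    "ki_inv_glc": _spec("mM", 1000.0, 1.0, 1.0e4, "non-competitive product inhibition by Glc"),
    "ki_inv_fru": _spec("mM", 1000.0, 1.0, 1.0e4, "competitive product inhibition by Fru"),
    # --- hexokinase activities ---
    "vmax_glck": _spec("umol/gFW/h", 0.846, 0.01, 10.0, "max glucokinase rate"),
    "km_glck": _spec("mM", 0.12, 0.01, 5.0, "glucokinase affinity for Glc"),
    "ki_glck_g6p": _spec("mM", 1.97, 0.01, 50.0, "non-competitive inhibition of GlcK by G6P"),
    "vmax_frck": _spec("umol/gFW/h", 0.799, 0.01, 10.0, "max fructokinase rate"),
    "km_frck": _spec("mM", 0.228, 0.01, 5.0, "fructokinase affinity for Fru"),
    "ki_frck_f6p": _spec("mM", 0.3, 0.01, 50.0, "non-competitive inhibition of FrcK by F6P"),
    # --- sucrose export to sinks ---
    "vmax_suc_export": _spec("umol/gFW/h", 2.44, 0.1, 25.0, "max sucrose export rate"),
    "km_suc_export": _spec("mM", 4.59, 0.1, 50.0, "export affinity for Suc"),
    # --- invertase modification that admits a metabolic steady state ---
    "steady_inv_vmax_factor": _spec("-", 0.47, 0.01, 1.0, "vmax_inv scale for steady variant"),
    "steady_inv_km_factor": _spec("-", 3.22, 1.0, 100.0, "km_inv scale for steady variant"),
    "steady_inv_ki_glc_factor": _spec("-", 0.027, 1e-4, 1.0, "ki_inv_glc scale for steady variant"),
    "steady_inv_ki_fru_factor": _spec("-", 0.00308, 1e-4, 1.0, "ki_inv_fru scale for steady variant"),
}

#: Plausible range for v_max,SPS = k_sps * e_sps_total (μmol gFW⁻¹ h⁻¹),
#: bracketing the published 25.32.
VMAX_SPS_RANGE = (10.0, 40.0)

INVERTASE_PARAMS = ("vmax_inv", "km_inv", "ki_inv_glc", "ki_inv_fru")


@dataclass(frozen=True)
class SnRK1Params:
    """Constants of the SnRK1 rate law (partial non-competitive mixed-type
    inhibition by T6P; non-competitive inhibition by G1P and G6P)."""

    vmax: float
    km_e: float
    ki_t6p: float
    ki_g1p: float
    ki_g6p: float
    k_partial: float

    def __post_init__(self) -> None:
        for name in ("vmax", "km_e", "ki_t6p", "ki_g1p", "ki_g6p", "k_partial"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"SnRK1 parameter {name} must be positive, got {v!r}")
        if self.k_partial > 1.0:
            raise ValueError(f"k_partial must be <= 1, got {self.k_partial!r}")


class ParameterSet:
    """All kinetic constants of the model, with per-parameter bounds.

    Behaves like an immutable record: values are read via attribute or
    item access; modified copies are produced with :meth:`update`.
    """

    __slots__ = ("_values", "_bounds")

    def __init__(
        self,
        values: Mapping[str, float],
        bounds: Mapping[str, tuple[float, float]] | None = None,
        validate: bool = True,
    ) -> None:
        unknown = set(values) - set(PARAM_TABLE)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        missing = set(PARAM_TABLE) - set(values)
        if missing:
            raise ValueError(f"missing parameter(s): {sorted(missing)}")
        object.__setattr__(self, "_values", {k: float(values[k]) for k in PARAM_TABLE})
        if bounds is None:
            bounds = {k: (s.lower, s.upper) for k, s in PARAM_TABLE.items()}
        object.__setattr__(
            self, "_bounds", {k: (float(lo), float(hi)) for k, (lo, hi) in bounds.items()}
        )
        if validate:
            self.validate()

    # -- access ---------------------------------------------------------
    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def names(self) -> tuple[str, ...]:
        return tuple(self._values)

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def bounds(self, name: str) -> tuple[float, float]:
        return self._bounds[name]

    @property
    def snrk1(self) -> SnRK1Params:
        return SnRK1Params(
            vmax=self.vmax_snrk1,
            km_e=self.km_snrk1,
            ki_t6p=self.ki_t6p,
            ki_g1p=self.ki_g1p,
            ki_g6p=self.ki_g6p,
            k_partial=self.k_partial,
        )

    # -- modification ---------------------------------------------------
    def update(self, validate: bool = True, **changes: float) -> "ParameterSet":
        vals = dict(self._values)
        for k, v in changes.items():
            if k not in vals:
                raise ValueError(f"unknown parameter: {k}")
            vals[k] = float(v)
        return ParameterSet(vals, self._bounds, validate=validate)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for k, v in self._values.items():
            if not math.isfinite(v):
                raise ValueError(f"parameter {k} is not finite: {v!r}")
            if v <= 0 and k not in ("suc_external", "v_cfbpase"):
                raise ValueError(f"parameter {k} must be positive: {v!r}")
            if v < 0:
                raise ValueError(f"parameter {k} must be nonnegative: {v!r}")
            lo, hi = self._bounds[k]
            if not lo <= v <= hi:
                raise ValueError(f"parameter {k}={v!r} outside bounds [{lo}, {hi}]")
        self.snrk1  # raises on inconsistent SnRK1 block
        vmax_sps = self.k_sps * self.e_sps_total
        lo, hi = VMAX_SPS_RANGE
        if not lo <= vmax_sps <= hi:
            raise ValueError(
                f"k_sps*e_sps_total = {vmax_sps:.3g} umol/gFW/h outside the plausible "
                f"v_max,SPS range [{lo}, {hi}]"
            )

    def at_bounds(self, names: Iterable[str] | None = None, rel: float = 1e-6) -> dict[str, bool]:
        """Flag parameters sitting at (or numerically on) a bound."""
        names = self.names() if names is None else tuple(names)
        out = {}
        for k in names:
            lo, hi = self._bounds[k]
            v = self._values[k]
            span = hi - lo
            out[k] = (v - lo) <= rel * span or (hi - v) <= rel * span
        return out


def default_parameters() -> ParameterSet:
    """The shipped default parameterization of the feeding experiment."""
    return ParameterSet({k: s.default for k, s in PARAM_TABLE.items()})


# ---------------------------------------------------------------------------
# YAML round-tripping
# ---------------------------------------------------------------------------

_KNOWN_UNITS = {"umol/gFW/h", "umol/gFW", "mM", "1/h", "-"}


def load_parameters(path: str) -> ParameterSet:
    """Load a parameter file (name → value/unit/lower/upper mapping).

    Unknown parameter names, malformed units, and values outside their
    bounds are rejected with descriptive errors.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'parameters' section")
    entries = doc["parameters"]
    values: dict[str, float] = {}
    bounds: dict[str, tuple[float, float]] = {}
    for name, entry in entries.items():
        if name not in PARAM_TABLE:
            raise ValueError(f"{path}: unknown parameter {name!r}")
        spec = PARAM_TABLE[name]
        if isinstance(entry, (int, float)):
            entry = {"value": entry}
        if not isinstance(entry, dict) or "value" not in entry:
            raise ValueError(f"{path}: parameter {name!r} needs at least a 'value' field")
        extra = set(entry) - {"value", "unit", "lower", "upper", "description"}
        if extra:
            raise ValueError(f"{path}: parameter {name!r} has unknown field(s) {sorted(extra)}")
        unit = entry.get("unit", spec.unit)
        if unit not in _KNOWN_UNITS:
            raise ValueError(f"{path}: parameter {name!r} has malformed unit {unit!r}")
        if unit != spec.unit:
            raise ValueError(
                f"{path}: parameter {name!r} has unit {unit!r}, expected {spec.unit!r}"
            )
        values[name] = float(entry["value"])
        bounds[name] = (
            float(entry.get("lower", spec.lower)),
            float(entry.get("upper", spec.upper)),
        )
    missing = set(PARAM_TABLE) - set(values)
    if missing:
        raise ValueError(f"{path}: missing required parameter(s): {sorted(missing)}")
    return ParameterSet(values, bounds)


def save_parameters(params: ParameterSet, path: str, header: str | None = None) -> None:
    """Write a parameter set to YAML in the package's file format."""
    entries = {}
    for name in params.names():
        spec = PARAM_TABLE[name]
        lo, hi = params.bounds(name)
        entries[name] = {
            "value": params[name],
            "unit": spec.unit,
            "lower": lo,
            "upper": hi,
            "description": spec.description,
        }
    doc = {"parameters": entries}
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# concentrations in umol/gFW; 1 umol/gFW == 1 mM (1 gFW ~ 1 mL)\n")
        yaml.safe_dump(doc, fh, sort_keys=False)


def shipped_parameter_path():
    """Path to the versioned default parameter file shipped in the package."""
    return resources.files("snrk1kin").joinpath("data/parameters.yaml")
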