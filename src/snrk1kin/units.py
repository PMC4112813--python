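"""Unit conventions and conversions.

All pool sizes are expressed in μmol gFW⁻¹ (micromole per gram fresh
weight) and all rates in μmol gFW⁻¹ h⁻¹.  Published affinity and
inhibition constants for the soluble enzymes are given in mM; the two
scales are bridged by the standard approximation that one gram of fresh
leaf tissue corresponds to roughly one millilitre of aqueous volume, so

    1 μmol gFW⁻¹  ≡  1 mM.

Every place in the package that mixes the two unit systems goes through
this module, which is the single point where the equivalence is defined.
"""

from __future__ import annotations

#: μmol gFW⁻¹ per mM under the 1 gFW ≡ 1 mL tissue-volume convention.
UMOL_PER_GFW_PER_MM = 1.0

MIN_PER_H = 60.0
NMOL_PER_UMOL = 1000.0


def mm_to_umol_per_gfw(conc_mm: float) -> float:
    """Convert a concentration in mM to μmol gFW⁻¹."""
    return conc_mm * UMOL_PER_GFW_PER_MM


def umol_per_gfw_to_mm(pool: float) -> float:
    """Convert a pool size in μmol gFW⁻¹ to mM."""
    return pool / UMOL_PER_GFW_PER_MM


def nmol_min_to_umol_h(rate_nmol_min: float) -> float:
    """Convert a rate from nmol gFW⁻¹ min⁻¹ to μmol gFW⁻¹ h⁻¹.

    >>> nmol_min_to_umol_h(422.0)
    25.32
    """
    return rate_nmol_min * MIN_PER_H / NMOL_PER_UMOL


def specific_activity_to_tissue_rate(
    rate_nmol_min_mg: float, protein_mg_per_gfw: float = 10.0
) -> float:
    """Convert a protein-specific activity to a tissue-based rate.

    Parameters
    ----------
    rate_nmol_min_mg:
        Activity in nmol min⁻¹ (mg protein)⁻¹.
    protein_mg_per_gfw:
        Soluble protein content of the tissue, mg gFW⁻¹.  The default of
        10 mg gFW⁻¹ (≈1% w/w) is typical for Arabidopsis seedlings.

    Returns
    -------
    float
        Rate in μmol h⁻¹ gFW⁻¹.
    """
    return nmol_min_to_umol_h(rate_nmol_min_mg * protein_mg_per_gfw)
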