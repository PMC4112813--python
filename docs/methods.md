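# Model and methods

## Scope and model structure

`snrk1kin` models the cytosolic carbohydrate metabolism of *Arabidopsis*
seedlings during a sucrose-feeding experiment: carbon-starved seedlings
are supplied with a constant 15 mM external sucrose reservoir and the
network relaxes from the starved state towards sugar repletion.  The
state vector holds nine metabolite pools — F6P, G6P, G1P, UDPG, T6P,
Tre, Suc, Glc, Fru — and the two SPS peptide pools (active/
dephosphorylated and inactive/phosphorylated), all in μmol gFW⁻¹.
Published affinity constants are given in mM; the two unit systems are
bridged once, in `snrk1kin.units`, by the 1 gFW ≈ 1 mL tissue-volume
approximation (1 μmol gFW⁻¹ ≡ 1 mM).

Sixteen reactions connect the pools (see `snrk1kin.network`):

* **Inputs.** Sucrose import is irreversible Michaelis–Menten on the
  (constant, non-depleting) external concentration; the cFBPase step is
  a constant input flux into F6P, since F16P is not a state and cFBPase
  is the rate-limiting entry into the hexose-phosphate pool.
* **Non-limiting interconversions.** PGI, PGM, UGPase, TPP and SuSy are
  irreversible forward mass action (v = k·[S]).  SuSy operates in the
  cleavage direction Suc → Fru + UDPG with the nucleotide implicit,
  which keeps the UDPG balance closed without introducing nucleotide
  states.
* **SPS.** Free S6P is assumed absent (SPS and SPP acting as one
  complex), so sucrose synthesis is a single lumped step
  F6P + UDPG → Suc with a bi-substrate product-of-saturations law and
  v_max,SPS = k_SPS·E_act tied to the active peptide
  (k_SPS = 2.98×10⁶ h⁻¹ = 25.32 μmol gFW⁻¹ h⁻¹ / 8.5×10⁻⁶ μmol gFW⁻¹).
* **TPS** is bi-substrate Michaelis–Menten on G6P and UDPG; trehalase
  cleaves Tre into two Glc equivalents.
* **Invertase** carries mixed product inhibition — Glc non-competitive,
  Fru competitive — in the standard multiplicative reading
  v = v_max·S / ((1+Glc/Ki)·(K_M(1+Fru/Ki′)+S)).
* **Hexokinase** appears as two activities: glucokinase
  (non-competitively inhibited by G6P) and fructokinase (by F6P).
* **Export** of sucrose to sinks is irreversible Michaelis–Menten, so
  export saturates at a finite capacity.
* **Phospho-cycle.** SnRK1 phosphorylates active SPS peptide under
  partial non-competitive mixed-type inhibition by T6P (residual
  fraction k_partial = 0.29 at saturation) combined with non-competitive
  inhibition by G1P and G6P, including the T6P·G1P and T6P·G6P cross
  terms; a protein phosphatase dephosphorylates the inactive peptide by
  plain Michaelis–Menten.  The two stoichiometries are exact negatives,
  so E_act + E_inact is conserved along any trajectory (to rounding;
  the integration tests require relative drift < 10⁻⁹).

Out of scope by design: F2KP/PFP/PFK kinetics, transcriptional
regulation, SnAK/PP2C control of SnRK1, 14-3-3 binding, and vacuolar
compartmentation.

## Parameters

Fixed by published measurements: the SnRK1 block (v_max = 1.35 μmol
peptide h⁻¹ gFW⁻¹ from 2.25 nmol min⁻¹ mg protein⁻¹ at 10 mg protein
gFW⁻¹; K_M = 10⁻⁷ mM; Ki_T6P = 0.005 mM; Ki_G1P = 0.48 mM; Ki_G6P > 1 mM,
default 1.5 mM; k_partial = 0.29), k_SPS and E_SPS,total as above.
E_SPS,total is reported both as 8.5×10⁻⁶ (methods value, used here) and
8.2×10⁻⁶ μmol gFW⁻¹ elsewhere; the bounds admit both.

Everything else is this package's own calibration, chosen once so that
the shipped defaults reproduce the study conditions and then frozen
(the full set, with units and fitting bounds, is the versioned
`src/snrk1kin/data/parameters.yaml`):

* C-starved initial state: sub-μmol sugar pools (Suc 0.25, Glc 0.2,
  Fru 0.1 μmol gFW⁻¹), hexose phosphates a few ×10⁻² and T6P/Tre in the
  10⁻⁵–10⁻⁴ range; active SPS starts at 20 % of total, the midpoint of
  the 15–25 % starved-tissue estimate.
* The phospho-cycle runs with both converting enzymes close to
  saturation (K_M ≪ peptide pools), i.e. as a zero-order-ultrasensitive
  switch.  In the starved state the phosphatase slightly outruns SnRK1,
  so feeding tips the balance essentially immediately: the active pool
  crosses the inactive pool within well under 0.01 h, and the realized
  SnRK1 rate then declines from 1.18 to ≈1.06 μmol peptide h⁻¹ gFW⁻¹
  over 3 h of feeding as T6P, G1P and G6P accumulate.
* Import/export capacities and the mass-action constants were set so
  that over 8 h of feeding sucrose and T6P follow saturating (concave)
  time courses while the free hexoses grow near-linearly (linear-fit
  R² > 0.99 on the 1–8 h window): sucrose cleavage outruns the finite
  hexokinase capacities, which is also why the unmodified
  parameterization has no physiological steady state.
* Product inhibition of invertase is negligible at dynamic-model pool
  sizes (Ki defaults of 1000 mM); see the variant below.

## Steady states

`find_steady_state` eliminates E_inact through the conservation law,
relaxes the guess by a short integration, runs a Powell hybrid root
iteration on the reduced 10-dimensional system, and falls back to a
long relaxation before retrying.  Success additionally requires the
scaled residual (relative rate of change per hour) below tolerance and
the root inside a validity domain (metabolite pools ≤ 50 μmol gFW⁻¹).
The domain matters: with weak product inhibition the vector field does
vanish formally at molar-scale hexose levels where invertase is finally
throttled, but that root lies far outside the concentration range the
model was calibrated for, so it is reported as "no physiological steady
state" — matching the observed open-ended hexose accumulation.

The invertase-modified variant (`make_steady_variant`) scales only the
invertase parameters: v_max ×0.47, K_M ×3.22, and the two product-
inhibition constants down to ≈27 mM (Glc) and ≈3.1 mM (Fru).  This
emulates replacing the cytosolic activity with a lower-capacity,
lower-affinity and more strongly product-inhibited (vacuolar-type)
activity.  The variant admits a locally stable steady state (all
Jacobian eigenvalues in the left half-plane, verified numerically), and
the root agrees with a 10 h integration endpoint to < 10⁻⁶ relative.

## Sensitivity analysis

`steady_sensitivity` perturbs one parameter by a fraction (1 % by
default), re-solves both steady states, and reports
S_x = [(x_pert − x_ref)/x_ref]/fraction for every state and flux — a
one-sided forward difference, matching the perturb-and-compare
procedure of the classical systems-biology toolboxes.  The companion
check at 0.5 % confirms the finite-difference regime.  In-silico
hexokinase overexpression multiplies the gluco- and fructokinase v_max
threefold; `sensitivity_ratio_table` tabulates overexpressed/wild-type
sensitivity ratios to an external-sucrose perturbation, sorted
descending.

With the shipped defaults the table's top is v_SPS > UDPG > v_FrcK
(≈7.5, 7.2, 7.1), the glucokinase-flux ratio is below one while the
fructokinase-flux ratio is above one, and the glucose pool sits in the
weakly-affected lower half.  Two caveats are documented rather than
hidden.  First, steady-state stoichiometry imposes exact identities on
the finite differences (e.g. Δv_SPS = Δv_Inv + Δv_SuSy = Δv_FrcK, and
the PGI flux and F6P pool are pinned by the constant cFBPase input, so
their sensitivities vanish identically and their ratios are reported as
flagged NaNs).  These identities couple the table entries and make some
combinations of orderings unattainable in principle for this
stoichiometry; in particular the glucose pool cannot simultaneously be
the least-affected entry while the SPS flux is the most-affected one,
because the large SPS ratio arises from a near-cancellation in the
wild-type response that forces sign reversals in the glucokinase/
trehalose branch of the table.  Second, several lower-half entries are
ratios of responses that reverse direction between wild type and
overexpressor and are therefore negative; their magnitude, not their
sign, measures the change in responsiveness.

## Parameter estimation and synthetic data

The objective is weighted least squares over the observed points,
scale = per-species data maximum, with bound violations and solver
failures mapped to a large finite penalty.  `fit_simplex` runs
Nelder–Mead in log₁₀ parameter space (the constants span seven orders
of magnitude), is deterministic for a given data/init/options triple,
and flags parameters that finish on a bound.  Degenerate bounds pin a
parameter exactly.

`generate_synthetic_timecourse` simulates the feeding protocol and
samples a 15-minute observation grid over 3 h (13 points), applying
mean-one multiplicative lognormal noise (σ² = ln(1+cv²), μ = −σ²/2):
concentrations stay positive without clipping and replicate averages
converge to the noiseless trajectory.  The generator emulates the
sampling density and multiplicative error structure of enzymatic/LC-MS
metabolite assays; it does not emulate biological replicate-to-replicate
variation, missing values, limits of detection, or correlated
measurement error, so recovery tests certify the estimator's behaviour
under the stated noise model, not performance on real feeding data.
Recovery with three free parameters (invertase and glucokinase
capacities and the cFBPase input) displaced twofold from truth is
within 10 % on noiseless data and within 15 % median error across ten
seeds at 2 % noise.

## Numerical choices

* Integration: stiff-capable LSODA with rtol 10⁻⁸ / atol 10⁻¹² by
  default — the pools span ~10⁻⁵…10¹ μmol gFW⁻¹ and the peptide cycle
  turns over its 10⁻⁶-scale pool on sub-second timescales.  Objective
  evaluations during fitting use rtol 10⁻⁶ / atol 10⁻¹⁰.
* Feeding onset is a parameter switch (import rate zero before onset);
  the input enters smoothly through the import law, so no event
  handling is needed.
* Rate laws are evaluated without clipping inside the right-hand side;
  every law vanishes continuously at zero substrate, which is the
  negative-state protection (plus a NaN guard with a clear diagnostic).
* Activation-crossing times are located by sign bracketing plus linear
  interpolation on the stored grid; use a fine grid (the shipped
  examples use 10⁻⁵ h spacing) to resolve the sub-second switch.
* Steady-state tolerance is expressed as a relative rate of change
  (|dx/dt|/max(x, 10⁻⁹) < 10⁻⁶ h⁻¹), which handles the nine-decade
  spread of pool sizes uniformly.

## Known limitations

* The supplementary model files of the original study are not machine-
  readable here; the defaults are a re-calibration against the printed
  anchor values and qualitative outcomes, so quantities that depend on
  the unpublished parameter set (exact activation half-time, final
  activation percentage, exact sensitivity-ratio magnitudes) agree
  directionally, not bit-exactly.
* One cell type, one compartment: no vacuole, no plastid, and no
  day/night forcing.
* The external reservoir never depletes; long simulations (≫8 h) are
  outside the model's intended range.
* SBML export snapshots the feeding phase (constant external sucrose)
  and is written directly as SBML L3V2 XML; it is validated
  structurally in the test suite, not against the full SBML schema.
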