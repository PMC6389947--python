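# Methods

`amypore` implements the quantitative analysis chain for studies of
membrane pore formation by the amyloid-β fragment Aβ25–35
(GSNKGAIIGLM): dye-influx pore-formation kinetics, polarized ATR-FTIR
secondary-structure and orientation analysis, CD difference
spectroscopy, and closed-form β-barrel pore geometry. This note records
the models, the assumptions behind them, the defaults and the open
design choices.

## Pore-formation kinetics

**Measurement model.** Vesicles entrap a Ca²⁺-sensitive dye (Quin-2);
external Ca²⁺ enters through peptide-formed pores and the fluorescence
F_t rises from a flat baseline after peptide addition at t_add. A
Ca²⁺ ionophore defines the maximal signal F_max; all analysis runs on
the normalized scale F/F_max. Normalization subtracts the pre-addition
mean from both the trace and F_max before dividing, so a non-zero
instrument baseline does not distort F_rel.

**Two rate estimators.** The normalized rise is fitted two independent
ways and the package deliberately does not force one model:

1. *Saturating exponential*, F_t = F_eq(1 − e^{−k_exp(t−t_add)}),
   giving the equilibrium level F_rel = F_eq/F_max and the observed
   rate constant k_exp (s⁻¹).
2. *Second-order association*. Treating pore assembly as a
   second-order process in the membrane-bound peptide-particle
   concentration [P_b] (measured independently, e.g. by
   microelectrophoresis; always a user input), the rise linearizes as

       F_eq / ([P_b](F_eq − F_t)) = 1/[P_b] + k_a·t ,

   with time re-zeroed at t_add. The slope of an ordinary
   least-squares line through the transformed points is the
   second-order pore-formation rate constant k_a (M⁻¹s⁻¹), and the
   intercept must equal 1/[P_b] — reported as a model-consistency
   check. The R² of the line and the normalized quadratic curvature of
   a parabola fit are reported as linearity diagnostics; exponential
   data transform to a convex curve (y = e^{kτ}/[P_b]) and are flagged
   by positive curvature rather than rejected.

**Numerical safeguards for the transform.** The transform divides by
F_eq − F_t, which vanishes at saturation. Points with
F_t ≥ 0.99·F_eq (configurable fraction) or with F_eq − F_t below an
absolute floor are dropped and logged. Points at or above F_eq violate
the model: by default they raise an error naming the offending times;
`saturated="drop"` discards them instead, which is the appropriate
setting for noisy traces whose plateau scatter crosses F_eq. For noisy
data a floor of about 5 noise standard deviations keeps the transform
bias (≈(σ/(F_eq−F_t))²) at the per-mille level.

**Weighted fitting.** OLS is the default. Because the transform
amplifies noise as σ_y = y²[P_b]σ/F_eq, an optional
`weights="inverse_variance"` mode performs iteratively-reweighted least
squares: weights come from the *fitted line's* predictions (three
passes after an OLS start), not from the observed y, since
observed-value weights correlate with the noise and bias the slope
downward severely. With IRLS, a 5σ floor and σ = 0.01, the mean k_a
recovery error stays below 1% across k_a ∈ [10⁴, 2.5×10⁵] M⁻¹s⁻¹ and
[P_b] ∈ [0.5, 5] µM (200 seeds per condition).

**Affinity and pore stoichiometry.** When stable-pore formation is the
rate-limiting step of a reversible association, the in-membrane
peptide–peptide affinity constant is K_p = k_a/k_exp (M⁻¹). The mean
number of peptide units per pore, n, is estimated from K_p and [P_b]
under a pluggable association model. The default is the isodesmic
(equal stepwise affinity) closed form

    n = (1 + sqrt(1 + 4·K_p·[P_b])) / 2 ,

an explicit modelling assumption: it guarantees n → 1 as
K_p[P_b] → 0 and monotone growth with K_p[P_b], but other association
schemes (cooperative, nucleated) would give different absolute n; any
`n(K_p, [P_b])` can be registered under a name and selected per call.

## Polarized ATR-FTIR

**Band decomposition.** Amide I spectra (1700–1600 cm⁻¹) are
decomposed into five pseudo-Voigt components with the standard
assignments: β/γ-turns 1700–1670, α-helix 1660–1654, irregular
1644–1642, β-sheet 1630–1628 and side chains 1620–1600 cm⁻¹. Peak
positions and widths are *shared* between the ∥ and ⊥ polarizations
while the areas are free — without shared shapes the per-component
dichroic ratios would be ill-defined. The line shape is Gaussian by
default with an optional Lorentzian fraction; widths are bounded
(default 4–40 cm⁻¹ FWHM) and a width pinned at its bound flags a
collapsed component. Baseline correction (none / linear through the
region endpoints / rubber-band lower convex hull) is applied per
polarization before fitting; for synthetic spectra generated without a
baseline, `none` is the faithful setting — endpoint-anchored
subtraction would remove real band tails.

**Structure fractions.** Each conformation's fraction is its component
area divided by the sum over the four backbone conformations, side
chains excluded. Since it is not fixed which polarization weighting
feeds published fraction plots, the combination is configurable:
pseudo-isotropic a_∥ + 2a_⊥ (default, the rotationally averaged
absorbance), ∥-only or ⊥-only, and the choice is recorded in the
output.

**Order parameters.** For a uniaxial orientation distribution in the
thick-film ATR limit with relative interface field amplitudes
(E_x, E_y, E_z), a transition dipole with order parameter S_d about
the membrane normal produces the dichroic ratio

    R = [E_x²(1−C)/2 + E_z²C] / [E_y²(1−C)/2],   C = (2S_d + 1)/3 .

The relation is inverted in closed form; R below E_x²/E_y²
(the S_d = −0.5 limit) is flagged unattainable rather than clipped.
The molecular-axis order parameter follows from the dipole angle α off
that axis, S = 2S_d/(3cos²α − 1); α at the magic angle (54.7°) is
rejected because the molecular axis is then undetermined. Field
amplitudes default to the thick-film values for a germanium element at
45° incidence, E = (1.398, 1.516, 0.629) — the standard convention for
this geometry, fully configurable because published analyses often use
instrument-specific values. Lipid chain order S_L uses the total CH₂
stretching areas (antisymmetric ≈2922, symmetric ≈2852 cm⁻¹) with
α = 90°; the antisymmetric peak position is reported as an independent
fluidity marker.

**Strand tilt in a (possibly tilted) barrel.** For a β-barrel the
orientational order factorizes along nested axes,

    S_d = S(γ)·S(β)·S(θ_d),   S(x) = (3cos²x − 1)/2 ,

with γ the barrel tilt from the membrane normal, β the strand tilt
from the barrel axis, and θ_d the amide I dipole angle from the strand
axis (default 90°, configurable). Given a measured β-sheet dichroic
ratio R_β, β is solved per assumed γ over a 0–20° scan; when the
required S(β) leaves [−0.5, 1] the combination is flagged as having no
solution. This factorization stands in one function
(`solve_strand_tilt_at`) so an alternative formalism can replace it
wholesale.

*Known convention dependence.* With the default field amplitudes,
R_β = 0.89 gives β = 27.0° at γ = 0 and remains solvable up to
γ ≈ 27°; analyses using other field-amplitude conventions place the
no-solution boundary much lower (near 10°) for the same R_β. The
boundary location is therefore *not* a robust output of this
formalism — it shifts with (E_x, E_y, E_z) and θ_d — whereas the
existence of a sharp solvability limit, the 20–27° tilt band for
film-scale ratios at γ = 0, and the monotone decrease of β with γ are
robust and are what the tests assert.

## CD difference spectroscopy

With a bound fraction f_bound, the bound-peptide spectrum is isolated
as bound = (measured − (1−f_bound)·free)/f_bound on the intersection
of the wavelength ranges (linear interpolation, never extrapolation).
The division by f_bound restores the per-residue scale — an extension
beyond plain subtraction, switchable off and recorded in the output
metadata. Minima are located on the (optionally moving-average
smoothed) spectrum with a prominence filter defaulting to 2% of the
dynamic range, and returned deepest first. The module is unit-agnostic
(mdeg vs mean-residue ellipticity) and carries the unit label through.

## β-barrel geometry

For z strands tilted by β from the barrel axis with interstrand
distance d = 4.72 Å and rise per residue a = 3.48 Å (standard β-barrel
lattice constants), the inner backbone radius, height and internal
volume are

    R = d/(2 sin(π/z) cos β),  h_b = m·a·cos β,  V = πR²h_b .

The barrel is an ideal cylinder; tilt enters only through the 1/cosβ
widening and cosβ shortening (no shear-number/Cα-lattice model).
Side chains alternate in/out along a strand, so an 11-mer strand has
exactly two packing topologies: for GSNKGAIIGLM, topology 1 points
S26, K28, A30, I32, L34 inward (523 Å³/strand of van der Waals volume)
and topology 2 the complementary six (488 Å³/strand), using the vdW
volumes Gly 48, Ala 67, Ser 73, Asn 96, Ile/Leu/Met 124, Lys 135 Å³.
Feasibility is the comparison V ≥ z·(inward volume per strand); excess
free volume is expressed as the radius of an equivalent cylinder of
height h_b.

**Ring-of-barrels pores.** Tightly packed barrels can assemble into a
ring whose central hole conducts ions. The implemented convention:
barrels of outer radius R_out = R + t (t ≈ 2 Å of side-chain lining)
are tangent, centres at ρ = R_out/sin(π/n); the raw hole radius is
ρ − R_out (equal to R_out exactly for a hexamer) and a lined value
subtracts the pore-facing side-chain layer once more. No unique
convention exists for where the conducting surface lies, so both are
reported and the physical pore radius is taken to lie between them;
for a hexamer of 6-stranded barrels (R = 5.09 Å, t = 2 Å) the bracket
is 5.1–7.1 Å.

## Synthetic data

The generators emulate the study conditions: traces with addition at
248 s, 1 s sampling over 1500 s, ionophore-normalized scale with
F_eq = 0.6 by default; amide I ∥/⊥ pairs on a 1 cm⁻¹ grid over
1550–1750 cm⁻¹ with a 40% β-sheet conformational share, R_β = 0.89
on the sheet component and near-unity ratios elsewhere; CH₂ pairs over
2790–3010 cm⁻¹ encoding a chosen S_L; CD mixtures with a 222 nm dip in
the bound spectrum. Per-component dichroic ratios and the
pseudo-isotropic areas are exact before noise. Noise is additive
i.i.d. Gaussian (spectral noise scaled to the ∥ peak), and every
generator is a deterministic function of its integer seed.

What the generators do **not** emulate: vesicle aggregation and light
scattering, photobleaching or drift, correlated (1/f) instrument
noise, water-vapour lines and imperfect atmospheric compensation,
H/D-exchange band shifts, or heterogeneous pore populations. Passing
round-trip tests therefore demonstrates estimator correctness and
noise robustness under the stated noise model, not robustness to these
real-data artifacts.

## Problem sizes and numerical choices

Monte-Carlo tests use 200 seeds per kinetics condition and 500 for the
exponential-fit bias check; spectral recovery uses 10 noise
realizations — sizes at which the Monte-Carlo means are stable to well
inside the asserted tolerances while the whole suite runs in seconds.
Nonlinear fits run through `lmfit`/`scipy` least squares with analytic
initial guesses (plateau tail mean and half-rise time for traces;
window centres and local heights for bands). Ties and degenerate
inputs: flat traces are flagged degenerate rather than fitted; a
negative linearization slope reports k_a as not determined; fraction
denominators of zero, empty spectral regions, magic-angle dipoles and
f_bound = 0 raise with actionable messages.

## Limitations

* The isodesmic form for n is a stand-in for the (unpublished)
  association model behind reported oligomer counts; absolute n values
  depend on it.
* Strand-tilt absolute values and the solvable-γ boundary depend on
  the field-amplitude convention (see above).
* The full chain applied to second-order traces feeds the
  exponential-fit F_eq into the linearization; a slightly biased F_eq
  inflates the transform near saturation, so chain-level k_a on
  model-mismatched data is order-of-magnitude (the diagnostics expose
  the mismatch). Parameter recovery is exact when the true F_eq is
  supplied.
* The geometry is a rigid ideal cylinder: no strand twist, shear
  number, or energetic evaluation.
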