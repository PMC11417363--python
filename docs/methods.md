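# Methods

`spinrelax` analyses protein and nucleic-acid spin-relaxation data of the
kind collected to characterise microsecond–millisecond conformational
exchange and picosecond–nanosecond internal motion in an RNA-binding
domain: longitudinal/transverse relaxation and heteronuclear NOE, Hahn-echo
(RCZZ) exchange maps, CPMG and spin-lock relaxation dispersion, reduced
spectral density mapping and model-free analysis.  This note records the
models, unit conventions, numerical choices and known limitations.

## Spin interactions and unit conventions

All spectral densities are in s/rad, rates in s⁻¹, frequencies internally
in rad/s; chemical-shift differences are stored in ppm and converted per
field and nucleus through `FieldContext`.  The dipolar and CSA interaction
constants are

    d = μ₀ h γ_H γ_X / (8π² r³_XH),      c = ω_X (σ∥ − σ⊥) / √3 .

Gyromagnetic ratios are stored as magnitudes with a separate sign flag:
`d` is a positive magnitude, `c` carries the sign of Δσ (negative for the
backbone amide ¹⁵N defaults, Δσ = −164 ppm, r = 1.02 Å, β = 18°).  The
signed ratio γ_H/γ_X enters only the NOE expression and the σ term of the
reduced mapping, which is what allows ¹⁵N NOE < 1.  With these conventions
the CSA/dipolar correction factor

    κ = −6[(d²/8) + (c²/6)] / (√3 c d P₂(cos β))

is positive; at 750 MHz with CODATA constants it evaluates to 1.22836,
matching the value 1.2283 used in the RCZZ analysis to within 1×10⁻⁴
(the fourth-decimal difference is within the uncertainty of the
constants/carrier frequency a given spectrometer implies).

## Relaxation rates and reduced spectral density mapping

`rates_from_j` implements the standard isolated X–H dipolar + CSA
expressions for R1, R2 (plus an additive Rex) and NOE.  The reduced mapping
assumes the spectral density is flat across the three proton-frequency
combinations (J(ω_H−ω_X) ≈ J(ω_H) ≈ J(ω_H+ω_X) ≈ J(0.87 ω_H)) and Rex = 0,
and is implemented as the *exact algebraic inverse* of the forward rates
under that assumption:

    σ = (NOE−1) R1 (γ_X/γ_H)
    J(0.87ω_H) = 4σ/(5d²)
    J(ω_X) = [4R1 − (28/5)σ] / (3d² + 4c²)
    J(0)   = [6R2 − 3R1 − (18/5)σ] / (3d² + 4c²)

Literature variants differ slightly in the σ coefficients; exact forward ∘
inverse identity (tested to machine precision) was chosen as the
correctness contract because it makes the mapping self-consistent with the
package's own rate expressions.  A negative J(0) is returned flagged — it
signals exchange or noise, not an error.

## Cross-correlated relaxation and the RCZZ exchange map

η_xy is normalised through the κ identity,
κ·η_xy = [(d²/8)+(c²/6)][4J(0)+3J(ω_X)], rather than through an
independently chosen literature prefactor.  This guarantees the slow-
exchange map Rex = R2^RCZZ − κη_xy + R1/2 cancels *exactly* (to 10⁻⁶ s⁻¹)
for exchange-free spins built from the same spectral density — the
internal-consistency property the pipeline's tests rely on.  η_xy is fitted
from intensity ratios I_B/I_A = tanh(η_xy T) (closed form for a single
delay), and R2^RCZZ = −ln(I/I_ref)/(2τ_he) with the Hahn-echo period
2τ_he = 129.6 ms by default.

## Relaxation dispersion

**CPMG.** The general two-site model is the Carver–Richards closed form
with ψ containing R_a − R_b (the difference, as required for the Δω = 0
limit to give exactly flat dispersion) and the η± prefactor 1/(√8 ν_CP),
where ν_CP is the 180°-pulse repetition frequency (inter-pulse delay
1/(2ν_CP)).  Overflow of cosh at η₊ > 300 is handled by the asymptotic
arccosh(z) ≈ η₊ + ln D₊; an arccosh argument below 1 (roundoff) is clamped
with a warning.  The closed form is validated against a numerical
Bloch–McConnell pulse-train propagator (complex 2×2 evolution + conjugation
pulses) within 2% in intermediate/fast exchange and 3% in slow exchange.
Note that in deep slow exchange (k_ex ≪ Δω, large p_b) the true R2eff(ν_CP)
oscillates — the propagator shows the same oscillation — so monotonicity in
ν_CP is only a property of the k_ex ≳ Δω regime.

**Spin lock.** R1ρ-derived R2eff uses the two-site fast-exchange form
R2eff = R2⁰ + φ_ex k_ex/(ω²_SL + ω²_off + k²_ex) with φ_ex = p_a p_b Δω².
ω_SL, ω_off are accepted in Hz and converted to angular units, since the
denominator mixes them additively with k_ex.  For ¹⁵N sites R2⁰ is fixed to
κη_xy; for ¹³C sites R2⁰ is fitted and R1 fixed.  An on-resonance alignment
pre-filter keeps points with |ω_off|/ω_SL ≤ 0.4 (configurable).

**Fitting.** All dispersion fits are weighted least squares
(scipy `least_squares`, bounds, `x_scale="jac"`), with a two-stage
multi-start: cheap exploration from a log-spaced k_ex grid (10²–10⁵ s⁻¹) ×
p_b grid (10⁻³–0.5) × Δω grid, then full-precision polish of the best
basins — the Carver–Richards χ² surface is multimodal.  k_ex is bounded to
[10², 10⁵] s⁻¹ (the range CPMG is sensitive to).  Global fits share k_ex
(optionally p_b) across residues with per-residue Δω (in ppm, so one
parameter serves both fields) and per-residue-per-field intrinsic rates
with R_a = R_b.  Consistency with the shared process is reported as
χ²_g/χ²_i per residue; residues above the cutoff (default 2.0) are flagged,
excluded, and the fit rerun.  Model comparison uses AIC = χ² + 2p with
measurement errors treated as known (AICc available).  Parameter
uncertainties come from seeded Monte-Carlo refits of Gaussian-perturbed
datasets (flagged if >20% of draws fail).

### Identifiability at the emulated study conditions

For four residues sharing (k_ex = 850 s⁻¹, p_b = 0.3%) with Δω of 2–3.4 ppm
at 750/900 MHz and σ = 0.4 s⁻¹ per point — the conditions of the global
C-terminal-group recovery experiment — the Cramér–Rao bound on k_ex is
≈18–25% *per dataset* (free Δω) even when each dispersion is recorded twice
(the two-offset acquisition the generator emulates).  Recovery is therefore
assessed on the median of the fitted values across 20 noise seeds, which
lands within a few percent of the truth; a per-dataset 10–20% guarantee is
not information-theoretically available at this noise level.

## Rotational diffusion and model-free analysis

τ_c is estimated by root-finding on the rigid-rotor R2/R1 ratio
(monotone in τ_c), restricted to residues with NOE ≥ 0.65 and R2/R1 within
1.5 SD of the 10%-trimmed mean (excludes fast internal motion and
exchange).  The axially symmetric tensor fit adds D∥/D⊥ and the symmetry
axis (polar angles), using Woessner three-Lorentzian spectral densities
with weights from the N–H vector/axis angle; the isotropic model is kept
when AIC prefers it, and the axis is reported in the upper hemisphere
(v ≡ −v).  N–H vectors come from a user-supplied PDB file (first model);
residues without an amide proton are skipped, never rebuilt.

Per-residue model-free fitting uses the ladder 1 (S²), 2 (S², τ_i),
3 (S², Rex), 4 (S², τ_i, Rex), 5 (S_f², S_s², τ_s — extended form with the
fast internal time in its τ_f → 0 limit): the simplest model whose χ²
passes the α = 0.05 critical value for its degrees of freedom is accepted
(ties by AIC); the three-parameter models, which have zero degrees of
freedom against single-field (R1, R2, NOE), are compared by AIC when all
simpler models are rejected.  With single-field data Rex and τ_i are
partially confounded; fitted Rex is reported at the measurement field with
no B₀² rescaling.  Internal times are bounded below 0.95 τ_c.  τ_c
temperature scaling uses the water-viscosity ratio 0.653/1.002 mPa·s
(313 K / 293 K), configurable.

## The synthetic-data generator

`make_profile` builds seeded pseudo-proteins with the dynamic architecture
of an RRM domain with a binding-coupled disorder–order transition:

- `free_rrm1_like` (default 120 residues): isotropic τ_c = 6.5 ns; core
  S² ∈ [0.85, 0.95] with τ_i 10–50 ps; termini extended-model motion with
  S² ∈ [0.3, 0.7] and τ_s 0.5–2 ns; a β4-strand exchange group
  (k_ex = 900 s⁻¹, p_b = 2%) and a C-terminal-helix group (k_ex = 850 s⁻¹,
  p_b = 0.3%) with per-residue Δω and ground-truth Rex of 2–6 s⁻¹.
- `bound_rrm1_like`: τ_c = 11.8 ns, axial D∥/D⊥ = 1.26; an interface group
  in fast exchange (k_ex = 7000 s⁻¹).
- `uniform_rigid`: all S² = 0.9, no exchange.

Simulators emit exact closed-form observables plus independent Gaussian
noise (defaults: 2% on R1/R2, ±0.02 on NOE, 0.4 s⁻¹ per CPMG point, 3%
on R1ρ, with two CPMG grid copies per field emulating the two-offset
acquisition).  Identical seeds give byte-identical outputs.  What the
generator does *not* emulate: correlated noise, temperature drift,
off-resonance pulse imperfections, baseline artifacts, anisotropic CSA
tensors, or multi-site exchange — so passing recovery tests demonstrates
correctness of the inference machinery under the stated noise model, not
robustness to every systematic error of real spectra.

## Problem sizes used by the test suite

Recovery checks use 20 noise seeds for the CPMG, R1ρ and tensor
experiments and 8 seeds × 120 residues for the model-free map; these sizes
keep each check in the minutes range while leaving the standard error of
the across-seed medians well below the asserted tolerances.

## Known limitations

- Three-site or unequal-R₂ exchange models, rhombic diffusion tensors and
  multi-field simultaneous model-free fitting are out of scope.
- The fast-exchange R1ρ form is used as-is outside its asymptotic regime if
  the caller so chooses; the Bloch–McConnell propagator is available for
  checking.
- Peak intensities are assumed pre-extracted (heights); no spectral
  processing or peak picking.
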