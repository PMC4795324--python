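# Methods

`aunp-radiodose` models two uses of PEG-coated radioactive gold
nanoparticles (¹⁹⁸AuNPs) bound to the surface of an early, avascular
small-bowel tumor: optical **detection** via the plasmonic near field of
the gold cores, and beta-particle **therapy** via the activity they carry.
This note records the models, the defaults and why, what the synthetic
inputs do and do not emulate, and the numerical choices.

## Physical reference data

**Au-198.** Beta emitter, endpoint energy E_max = 0.96 MeV, half-life
2.7 d (64.8 h) by default. The literature this work draws on also quotes
2.67 d; the half-life is therefore a constructor argument, not a constant.
`particles_per_decay` defaults to 1.0 (one beta per disintegration) and is
configurable; gamma emissions are deliberately ignored (the dose chain is
beta-only, a known low-single-percent underestimate).

**Beta emission spectrum.** Only the endpoint is tabulated; transport
needs a shape. We use the allowed-transition form
N(E) ∝ p W (Q−E)² F(Z,W) with the relativistic point-charge Fermi
function for the daughter Z = 80 (mercury), evaluated in log space with a
finite p→0 limit. The resulting mean energy is 0.315 MeV, close to the
accepted ≈0.312 MeV for ¹⁹⁸Au; a nonrelativistic Fermi function was tried
first and overestimates the mean (0.337 MeV), which is why the
relativistic form is the default. A flat `shape="uniform"` spectrum exists
for debugging only. Sampling is inverse-CDF on the tabulated grid; the
spectrum object exposes its own piecewise-linear CDF so goodness-of-fit
tests are exactly consistent with the sampler.

**Gold dielectric function.** The experimental n,k compilation of Johnson
& Christy (1972) is embedded as a permittivity table (≈188–1937 nm) and
interpolated with monotone PCHIP separately on Re ε and Im ε, so
interpolated values never overshoot neighboring knots. Queries outside the
span raise rather than extrapolate. The original study does not say which
optical-constants dataset it used, so absolute field values of its plotted
map are not recoverable; all tests on the optics are structural
(surface peaking, r⁻³ decay, coupling) or closed-form.

**Medium permittivity.** ε_m = 1.77 (water at visible wavelengths) by
default, overridable. This is an assumption: the original field map does
not state its host medium.

## Plasmonics (diagnosis)

A sphere of radius a ≪ λ in the quasi-static limit has polarizability
α = a³ (ε_p − ε_m)/(ε_p + 2ε_m). For a unit incident field along x̂ the
exterior field is

    E(r)/E₀ = x̂ + (3 r̂ (r̂·m) − m)/r³,   m = α x̂,

which reduces on the polarization axis to 1 + 2α/r³ and transverse to it
to 1 − α/r³. A lossless denominator zero (Fröhlich resonance) raises
`SingularResonanceError` instead of returning infinity. Interior points
are out of contract (`GeometryError`): the quasi-static exterior solution
says nothing about the field inside the metal.

Several particles are coupled self-consistently with one dipole per
particle: m_i = α_i (x̂ + Σ_{j≠i} G_ij m_j), solved as a dense 3N×3N
complex linear system. This captures the particle–particle interaction
(gap hot spots) at desk scale without re-implementing a full polarizable
cubic-lattice discrete-dipole code; it is exact in the point-dipole limit
and validated against the closed-form two-particle solution. Retardation
and higher multipoles are out of scope — fields are reliable for
separations and distances down to roughly one radius, qualitative below.

## Dosimetry chain (therapy)

**Range–energy.** The public function `beta_mass_range` keeps both
published branches exactly as printed: R = 0.542E − 0.133 g/cm² for
E ≥ 0.8 MeV, and the Katz–Penfold form 0.412·E^(1.265 − 0.0954 ln E)
below. The branches disagree by ≈2.9% at the seam (0.30060 vs
0.30923 g/cm²); this discontinuity is documented, not hidden. For
E_max = 0.96 MeV the mass range is 0.38732 g/cm², i.e. 0.369 cm (≈3.7 mm)
in 1.05 g/cm³ soft tissue.

**Transport range.** CSDA energy bookkeeping needs a strictly monotone,
exactly invertible R(E). The transport stage therefore uses the printed
branch above 0.8 MeV and the Katz–Penfold branch *scaled by
R_printed(0.8)/R_KP(0.8) ≈ 0.9721* below, which joins the branches
continuously. The quadratic-in-ln E Katz–Penfold form is inverted in
closed form, so `transport_energy(transport_range(E)) = E` to machine
precision and each history's deposits telescope exactly to its initial
energy. The ≤2.9% low-energy rescale is well inside the empirical
relation's own accuracy.

**Atoms per nanoparticle.** N = (π/6)(ρ/M) N_A D³; with ρ = 19.3 g/cm³,
M = 197 g/mol and CODATA N_A this is 30.8916·D³ for D in nm (the commonly
printed coefficient 30.89602 reflects an older Avogadro value; the
difference is 0.016%). A 30 nm core holds ≈8.34×10⁵ atoms.

**Surface activity.** A[mCi] = λ_phys[s⁻¹]·n_a·n_bv·f_uptake/3.7×10⁷ with
n_a = c_r ρ_molecule (4πr³/3) radioactive atoms per bound vector and
n_bv = 4πR²f_c/footprint vectors on the tumor surface. The decay constant
is converted to s⁻¹ inside the formula — a millicurie is a per-second
unit, and mixing it with per-hour decay constants (as the source text
does) silently inflates activities by 3600×.

Unpublished inputs, chosen once and exposed as configuration:

| parameter | default | rationale |
|---|---|---|
| covering fraction f_c | 0.5 | half the surface reachable by vectors |
| per-vector footprint | π(35 nm)² | close-packing of the 70 nm PEG shell |
| c_r | 1 | one radioactive atom per "molecule" (atom) |
| specific-activity fraction | 1.0 | every core atom counted ¹⁹⁸Au-equivalent |
| uptake fraction | 0.6 | the stated 60% reaching the tumor |
| λ_bio | 0 /h | no biological clearance unless configured |

With these defaults the two reference tumors (R = 0.25/0.5 cm) carry
410 and 1640 mCi. The study this package re-implements prints
185.6/212.4 mCi (and elsewhere 187.9/300 mCi) with doses 71.5/89.9 Gy
(elsewhere 72/118 Gy); those absolute pairs are **not reproducible**: the
four inputs above are unpublished, the two printed sets disagree with each
other, and an energy-balance check (A·T̄·p·X/λ_eff against the printed
doses) is inconsistent with both. The printed pairs ship as annotated
reference CSVs in `data/` and are used nowhere as expected values. All
dose-level acceptance is therefore structural: monotone depth falloff,
hard range cutoff, exact energy conservation, linearity in A, T, p.

**Dose conversion.** D = X·T·p·A/λ_eff with λ_eff = λ_phys + λ_bio and
X = 21.34 (mCi·MeV/g/dis → Gy/h), re-derived in code from
3.7×10⁷ × 3600 × 1.602×10⁻¹³ × 10³ = 21.339. This is the total dose from
complete decay of the deposited activity (integral of the dose rate over
an exponential).

## Monte Carlo transport

Histories start uniformly on the tumor sphere (normalized Gaussian
triples), with isotropic directions — so half the emissions head outward
into healthy tissue, which can be scored by extending the shell tally
beyond the tumor radius — and spectrum-sampled energies.

* **Straight-line CSDA (default).** One straight segment of length
  R(E)/ρ. Deposition is scored *analytically*: segment–sphere chord
  intersections give the path intervals inside each region, and the
  deposit is the difference of residual energies at the interval ends.
  No step-length discretization error; 10⁵ histories with a 10-shell
  tally run in well under a second.
* **Multiple scattering (optional).** The track is chopped into
  `step_cm` segments (default 0.01 cm) and the direction deflected after
  each by a Gaussian kick with the Highland RMS angle
  (13.6 MeV/βpc)·√(ρh/X₀), X₀ = 36.08 g/cm² (water). Detours shorten
  radial penetration somewhat; energy conservation is unaffected.
* **Cutoff.** Below 0.01 MeV (residual range ~ µm) the electron deposits
  locally.
* **End-of-range guard.** The inverse range relation is logarithmically
  slow near zero, so 10⁻¹⁷ g/cm² of floating-point dust in the residual
  at the exact track end would map to ~10⁻⁶ MeV. Residuals below
  10⁻¹² g/cm² are treated as zero; any physical residual at the cutoff is
  ≥1.5×10⁻⁴ g/cm², three orders of magnitude away from the guard.

**Tallies.** Default: concentric shells 0.5 mm thick centered at depths
0.3, 0.8, … mm below the surface (the deepest shell clips at the center);
masses are density × exact shell volume. A micro-cell mode places
0.02 cm-radius spheres at the same depths along one radius (0.1 mm
surface-to-surface gap at the 0.5 mm spacing), matching the discrete
scoring layout of the original simulation; shells are the default because
they see every history and have far lower variance. Standard errors come
from the history-level variance and scale as n⁻¹/².

**Verification.** For a monoenergetic isotropic point source the MC shell
profile is compared with the closed-form residual-energy kernel
Eres(r₁) − Eres(r₂) (exact for straight-line CSDA); with a tally tiling
the reachable ball, summed deposits equal the mean emitted energy to
machine precision.

## Problem sizes

The reference scenarios and the acceptance checks use 10⁵ histories
(straight-line mode), chosen because the deepest nonzero shell of the
0.5 cm tumor then has ≳30% relative precision while the profile shape is
resolved to ~1%; the smoke scenario uses 10³ histories for a sub-second
end-to-end run. Field maps default to 21³ points over ±60 nm (pipeline)
and 41³ over ±4a (analysis).

## What the synthetic inputs do not emulate

The generator reproduces the *stated study conditions* — geometry, decay
data, spectrum shape, surface loading — not real tissue or real optics:
no gamma/bremsstrahlung photons, no tissue heterogeneity or voxelized
anatomy, no pharmacokinetics beyond a single λ_bio rate, no nanoparticle
size dispersion, no retardation in the optics, and no fluorophore
photophysics (no emission model exists to implement). Passing tests
demonstrate internal consistency of the implemented models at the stated
conditions, not clinical accuracy.

## Known limitations

* Absolute activities/doses depend linearly on four unpublished loading
  inputs; only ratios and profile shapes are meaningful without them.
* The stopping power is the inverse of an empirical range fit, not an
  ICRU table; `run_tally` accepts a custom spectrum, and the transport
  functions are isolated so a table-driven variant can be swapped in.
* The coupled-dipole optics is point-dipole only; sub-nanometer gaps
  exaggerate hot spots relative to full multipole solutions.
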