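# Methods

This note records the models implemented in `filmcharge`, the conventions
and defaults that required a decision, what the synthetic generators do
and do not emulate, and the known limitations.

## Gyration-tensor shape descriptors

All descriptors are built on the mass-weighted gyration tensor
G = Σ m_i (r_i − r_CM)(r_i − r_CM)ᵀ / Σ m_i, whose eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ (nm²) are the squared principal radii of gyration and sum
to Rg². The asphericity Δ = (3/2)Σ(λ_i−λ_m)²/(Σλ_i)² and shape
S = 27Π(λ_i−λ_m)/(Σλ_i)³ use these gyration eigenvalues, **not** the
inertia-tensor moments. The literature often words these formulas in
terms of "principal moments of inertia"; only the gyration-eigenvalue
normalization reproduces the canonical limits (rod: Δ = 1, S = 2;
sphere: 0, 0) and the values published for globular proteins, so it is
the one implemented, with the cubic denominator read as (Σλ_i)³ = (3λ_m)³.
Degenerate input (all atoms coincident) yields Rg = 0 with an explicit
`shape_defined = False` flag instead of NaNs. Eigenvalue ties are broken
by the descending sort plus a fixed sign convention (largest component of
each principal axis positive, right-handed frame).

Superposition uses the least-squares rigid (Kabsch) transform via
`scipy.spatial.transform.Rotation.align_vectors`; RMSD is over all atoms
by default (backbone flags allow a backbone-only profile/selection).
SASA is a Shrake–Rupley estimate with a deterministic golden-spiral
quadrature: defaults probe 0.14 nm, 960 points per atom, Bondi van der
Waals radii. Published protein SASA values depend on the radius set and
probe convention of the original tool, so agreement is expected only at
the few-percent level. Fewer than 32 quadrature points is rejected.

Density profiles are normalized histograms of atom distances from a
stated surface plane (origin configurable; which atom defines the zero
is a convention the user controls). The film thickness is the width of
the smallest interval [surface, t] containing a coverage fraction
(default 0.90) of the probability mass, interpolated inside the crossing
bin.

## Titration

Protein charge versus pH uses an independent-site Henderson–Hasselbalch
model with intrinsic pKa values (Asp 3.65, Glu 4.25, His 6.0, Cys 8.3,
Tyr 10.1, Lys 10.5, Arg 12.5, N-term 9.0, C-term 3.6), overridable
globally or per site. Structure- and environment-dependent pKa shifts
(the province of semi-empirical structure-based predictors) are
deliberately out of scope: computed isoelectric points are expected to
land within about one pH unit of structure-aware predictions for
ordinary globular proteins, not to match them exactly. Q(pH) is strictly
decreasing, so the pI is the unique bisection root on [0, 14]
(tolerance 1e-4) when both acids and bases are present.

## QCM-D reduction

Steady state is the mean over the final window (default: last 10% of the
segment); a windowed linear drift exceeding 1% of the signal flags
non-stationarity. Overtone dispersion is (max−min)/|mean| of Δf_n/n. A
film is declared rigid when dispersion < 0.05 **and** max|ΔD_n| < 2×10⁻⁶;
these thresholds are package choices (instrument practice varies) and
are configurable. A non-rigid film is still reduced — the Sauerbrey mass
of a viscoelastic film is a useful but biased estimate — with an
explicit caution note rather than a hard error. The mass constant
defaults to 18 ng cm⁻² Hz⁻¹ and can be recomputed from crystal
properties as C = √(ρ_q μ_q)/(2f₀²) (AT-cut quartz at 5 MHz gives 17.7).
The Sauerbrey mass is the wet mass: bound solvent is included, which is
why a QCM mass can exceed what a dry-height measurement implies.

Packing verdicts compare the protein cross-section a_c with the
footprint a_p = M_w/(N_A m_f): compact when a_c/a_p ∈ [0.8, 1.2]
(configurable), sparse below, crowded above. The film pipeline calls a
film "multilayer suspected" when it is non-rigid **and** an externally
measured thickness (e.g. a dry AFM height) exceeds twice the monolayer
scale (density-profile thickness when multi-conformation input is
available, else 2Rg).

## Electrokinetics

The mobility of a sphere of radius a at reduced potential
y = zeζ/k_BT uses Ohshima's closed-form approximation

μ = (2ε₀ε_r ζ/3η) [f₁(κa) − y²(f₃(κa) + (m₊+m₋)/2 · f₄(κa))],

with f₁ the Henry-function fit 1 + 1/(2[1+2.5/{κa(1+2e^{−κa})}]³) and
f₃, f₄ the standard exponential fits of the relaxation correction. The
implementation is validated against the Hückel (κa→0) and Smoluchowski
(κa→∞) limits at small ζ to 0.5%. Because of the y² terms the mobility
is non-monotonic in ζ at moderate-to-large κa; inversion therefore scans
|ζ| ≤ 200 mV, returns the smallest-|ζ| root (standard practice), records
any second root in a branch note, and raises with the attainable range
when the requested mobility exceeds the curve's extremum. Round trips
are exact (to the 1e-3 mV root tolerance) below the mobility maximum,
which sits near 95 mV at κa ≈ 7; above it the smallest-|ζ| branch is
returned by design.

The ζ→σ_ek map is the Ohshima–Healy–White sphere charge–potential
relation: flat-plate Gouy–Chapman times the square root of the curvature
bracket in 1/κa and 1/(κa)². Its small-ζ linearization is the
Debye–Hückel sphere expression ε₀ε_rζ(1+κa)/a (verified to 1% at 5 mV),
and the κa→∞ limit is the flat plate. This map is strictly monotonic, so
σ→ζ inversion is a plain bracketed root find.

Counterion valence is fixed at z = 1 in both formulas — in the dilute
buffers this package targets, monovalent ions dominate — while κ is
always computed from the full ionic composition (multivalent ions count
in the ionic strength). Drag coefficients m± default to the K⁺/Cl⁻-like
pair (0.18, 0.17) and can be derived from limiting molar conductivities
via m = 2ε_rε₀k_BT N_A/(3ηΛ⁰).

## Counterion condensation

Manning: σ_crit = e(1+κa)(−ln κλ_B)/(2π|z|λ_B a), valid only for
κλ_B < 1 (outside the dilute regime the logarithm changes sign and the
call errors). Bocquet: σ_crit = e(1+κa)/(πaλ_B). Both are implemented as
positive magnitudes — a sign in front of a critical *magnitude* is a
typographical artifact — and the rule |σ_eff| = min(|σ₀|, σ_crit)
preserves the sign of the bare charge; it is idempotent and never
increases |σ|. Their ratio is −ln(κλ_B)/2 exactly. The complex analysis
defaults to the Bocquet theory (the better match for protein-coated
particles in this regime) but always reports Manning alongside. For
asymmetric electrolytes the formulas are evaluated anyway; the
inversion-side branch note is the place where validity caveats surface.

Physical constants are CODATA (scipy.constants); water defaults
ε_r = 78.5, η = 0.89×10⁻³ Pa·s at 298 K (overridable per `Medium`). The
bundled buffer table (dilute acetate pH 4–5, monosodium phosphate
pH 6–7, borate pH 8–10, HCl pH 3, ionic strength ≤ 2 mM) is an
explicitly approximate stand-in for typical low-ionic-strength recipes,
editable via the `IonSpecies` API or config.

## Synthetic data

Generators are fully seeded (`numpy.random.default_rng(seed)`; identical
seeds give identical bytes) and record their ground truth in metadata so
recovery tests never re-derive it from noisy output.

- **Ellipsoid clouds**: uniform unit-mass points; eigenvalues converge to
  (a²/5, b²/5, c²/5). Emulates protein size/shape, not atomic packing,
  mass heterogeneity or surface chemistry.
- **Chains**: freely rotating chains with stiffness = cos(bond angle);
  0 reproduces ideal-chain statistics (⟨Rg²⟩ ≈ nb²/6), 1 is the rod
  limit. A stand-in for flexible/disordered conformers, without excluded
  volume.
- **QCM traces**: exponential approach to a target mass with a linear
  overtone spread sized to a chosen dispersion metric, i.i.d. Gaussian
  noise per sample, and (multilayer mode) an early overshoot pulse,
  ten-fold larger dissipation and a rinse event removing 20% of the
  mass. No instrument drift, temperature transients or viscoelastic
  physics.
- **Mobility curves**: the exact forward model of the condensation
  analysis (Q/a_p → Bocquet σ_eff → ζ → μ) plus multiplicative Gaussian
  noise, default relative scale 5% — the typical reproducibility of
  electrophoretic mobility measurements on latex suspensions. Because
  the noise is multiplicative the sign structure (and hence the pI
  bracketing) is preserved.
- **Sequences**: the three bundled protein surrogates are *synthetic*:
  they match the literature titratable-residue compositions of the
  corresponding real proteins (β-casein-, β-lactoglobulin- and serum-
  albumin-like) padded with inert Gly/Ala, which is sufficient for a
  context-free titration model. They are not the real sequences.

Passing closed-loop tests therefore demonstrates internal consistency of
the analysis chain under realistic noise, not agreement with any
particular instrument's systematics.

## Problem sizes and numerics

Default test problem sizes are desk-scale by design: 10⁵-point clouds
for moment convergence (1% tolerance), 150-chain ensembles for polymer
statistics, 20 replicates for the noisy-pI bias check, 6-point exact
clouds wherever an eigenvalue identity is needed exactly. Root finding
uses Brent's method (ζ tolerance 1e-3 mV, pI tolerance 1e-4 pH).
Histogram bin edges are anchored at a bin_width multiple below the data
minimum so degenerate (single-bin) profiles remain valid.

## Known limitations

- No viscoelastic (Voigt-type) QCM modelling; non-rigid films get a
  cautioned Sauerbrey estimate only.
- No structure-based pKa shifts; pI values are intrinsic-model estimates.
- The mobility approximation is used within its published validity
  (spherical colloids, symmetric electrolytes, moderate ζ); no full
  numerical electrokinetic solution is attempted.
- Charge regulation at the latex-protein contact (dielectric suppression
  of latex ionization) is discussed conceptually in the docstrings but
  not modelled; measured σ_ek below σ_eff is the expected signature.
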