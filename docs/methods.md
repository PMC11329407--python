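# Methods

This note documents the models, parameter choices and numerical decisions
behind `kneedeg`, and what the synthetic validation does and does not show.

## Scope and overall design

The package forecasts knee-cartilage degeneration from subject-level inputs
(demographics, gait, simple MRI measurements) through four stages: template
geometry scaling, stance-phase compartmental loading, a contact-mechanics
surrogate producing maximum principal solid stress (σ_I) fields, and an
age-dependent tensile-failure criterion yielding a degenerated-volume
biomarker that feeds a classification/statistics layer. A full biphasic
fibril-reinforced finite-element solve is deliberately *not* performed; see
"Contact surrogate" for the rationale and the exporter that preserves a path
to full fidelity.

## Coordinate convention

X is anterior(+)–posterior(−), Y is axial (the loading direction and the
through-thickness direction), Z is mediolateral. All lengths are mm, forces
N, stresses MPa. The intercondylar-distance ratio scales Z and the
anterior–posterior ratio scales X; the joint space rescales thickness along
Y for the tibial cartilage and along local articular-surface normals
("radially") for the femoral cartilage. All knees are treated in a single
canonical frame; the generator records knee side but no mirroring is
applied.

## Template geometry

Each compartment is a parametric two-block mesh: an ellipsoidal-cap femoral
condyle surface above a gently concave tibial plateau, both extruded into
layered hexahedra (default 3 layers per tissue, 16 × 14 in-plane divisions,
≈1 300 elements per compartment — chosen so a full cohort × variant grid
runs in minutes on one core while the degenerated-volume fractions are
mesh-converged to within a few percent). Default shape constants:

| parameter | medial | lateral | note |
|---|---|---|---|
| condyle semi-axes (a, b, c) mm | 36, 30, 24 | 32, 24, 19 | lateral more curved = less congruent |
| plateau dish depth mm | 0.5 | 0.2 | |
| modeled plate | 0.58 × A-P by 26 mm | same | central contact region |
| apex clearance mm | 0.05 | 0.05 | nominal separation at build |

Template anatomic measurements default to the population medians (ICD
40.6 mm, A-P 53.05/62.59 mm, JS 4.79/5.38 mm, femoral fraction 0.55/0.40),
so a median subject is a near-identity scaling. The semi-axes were chosen
so that (i) the sagittal apex curvature radius a²/b ≈ 43 mm keeps the
flexion-driven posterior migration of the contact point inside the modeled
plate at the flexion angles where force peaks, and (ii) a median subject
under a 2.6-body-weight total load reaches peak contact pressures of
~8–12 MPa, the physiological range for gait.

Thickness is uniform per tissue with joint space = femoral + tibial
thickness. Both thickness modes use one mechanism — target thicknesses
applied along Y (tibia, about the articular surface) and along per-column
surface normals (femur) — differing only in how the joint space is split:
`fixed_ratio` uses the template's femoral fraction, `scaled_ratio` the
subject's. This makes the two modes bitwise identical when the fractions
coincide. A consequence of the normal-direction femoral rescaling is that
the femoral block volume tracks affine scaling factors only approximately
(within a few percent for anatomically plausible ratios); the tibial block
scales exactly. After scaling, the femoral body is shifted vertically to
restore the template's apex clearance.

Surface gradients are stored per column so that in-plane scaling re-tilts
the femoral normals consistently (∂y/∂x divides by the X ratio, ∂y/∂z by
the Z ratio).

## Stance loading

A normalized total-JCF shape over 51 stance grid points (piecewise linear
between points) with two humps near 25 % and 75 % of stance and a midstance
trough ≈ 0.55 of the peak; the push-off hump is a fraction of a percent
lower so the global maximum is a single grid point. The flexion trajectory
(fixed across subjects and schemes) peaks at ~15° near 15 % stance and
settles to ~5° at midstance; both curves are CSV-overridable since the
exact experimental trajectories are instrumentation-specific. The default
peak multiplier is 2.6 body weights, a typical instrumented-implant value
for walking; it is configurable. A `contact_fraction` factor (default 1.0)
is available to represent load bypassing cartilage–cartilage contact
through the menisci.

The peak predictor is a single-hidden-layer (width 10) tanh network with
standardized inputs (height, mass, walking speed, frontal-plane alignment,
age, sex encoded female = 1) and standardized outputs (medial, lateral,
total stance peaks in body weights), trained by L-BFGS with a fixed seed
and serialized to JSON (prediction is a plain numpy forward pass).
Training targets come from a synthetic musculoskeletal surrogate: peaks
linear in walking speed, mass, height, age and sex, with frontal-plane
(varus-positive) alignment shifting the medial share at 0.018 per degree,
plus Gaussian noise calibrated per output so that the correlation between
observed and noise-free targets equals the attainable ceilings 0.61
(medial), 0.67 (lateral) and 0.80 (total). Compartment load shares are
ratios of independently predicted maxima and are deliberately *not*
renormalized to sum to one, because compartment maxima occur at different
gait instants.

## Contact surrogate

Over the ~1 s of a stance phase, fluid exchange in cartilage is negligible,
so the instantaneous (incompressible) response dominates the stress. The
surrogate therefore treats the contact interface as independent vertical
columns (elastic foundation). Per tissue sub-column at compressive
engineering strain e (λ = 1 − e, isochoric in-plane stretch λ_t = λ^(−1/2)):

- fibril Green–Lagrange strain E_f = (λ_t² − 1)/2, tension-only;
- primary/secondary fibril stresses ξ_fp·E_f^β_fp and ξ_fs·E_f^β_fs;
- matrix shear μ = E_nf / (2(1 + ν_nf)), in-plane deviatoric stress
  μ(λ_t² − λ²);
- surface σ_I = fibril + matrix terms; column pressure
  p = μ(λ^(−1) − λ²) + fibril terms.

With these kinematics λ^(−1) = λ_t², so p and the surface σ_I coincide; the
tissues are distinguished by their constants and by which elements receive
the stress. The femoral and tibial sub-columns act in series: the total
column strain is partitioned so that the two pressures match (the softer
tibial matrix takes the larger strain share). Material constants (MPa
unless noted):

| | ξ_fp | β_fp | ξ_fs | β_fs | E_nf | ν_nf | κ₀ (10⁻¹⁵ m⁴ N⁻¹ s⁻¹) | M | φ₀ |
|---|---|---|---|---|---|---|---|---|---|
| tibia | 32 | 2.6 | 1.0 | 2.6 | 0.106 | 0.15 | 18 | 15.24 | 0.2 |
| femur | 215 | 2.6 | 3.0 | 2.6 | 0.215 | 0.15 | 6 | 5.06 | 0.2 |

κ₀, M and φ₀ describe fluid flow and are unused by the instantaneous
surrogate; they are carried so the solver-deck exporter (FEBio-dialect XML
with the hex mesh, tibial base fixation and the stance force/flexion
curves) emits a complete material description for full poroelastic runs.

Per stance frame the femoral articular surface is rotated about Z through
the condyle-surface centroid by the frame's flexion angle (positive flexion
migrates contact posteriorly, i.e. femoral rollback); the rotation center
is a modeling choice since only curvature, not center, controls the contact
migration. Vertical gaps to the tibial facets are interpolated along
mediolateral node rows (Z is invariant under the rotation). A rigid axial
approach δ is then found so that Σ p(ε(δ))·A equals the applied compartment
force, with ε = max(0, (δ − gap)/total thickness) capped at 0.6 (forces
beyond the capacity at the cap raise an error naming the frame). δ may be
negative (lift-off) because flexion rotation can create slight interference
at the 0°-calibrated clearance.

Numerics: the strain partition is solved by 55-step vectorized bisection;
for speed, the partition and the pressure are tabulated once per mesh on a
3001-point monotone-cubic (PCHIP) grid, the equilibrium root is bracketed
by 45-step bisection on the tabulated pressure, then polished by Newton
steps against the constitutive evaluation to a relative force residual
below 10⁻⁹ (the solver contract tested is 10⁻⁶). All 51 frames are solved
as one vectorized batch.

Per-element σ_I is the column surface value times a depth-weight profile
(1.0 superficial, 0.5 middle, 0.25 deep, interpolated for other layer
counts) standing in for the depth-dependent arcade-like collagen
orientation; the profile is configurable. The surrogate reproduces the
qualitative behaviour of the full model (load-response ordering,
medial/lateral shift under individualized loading) but no quantitative
field agreement with a poroelastic FE solve is claimed.

## Degeneration criterion

An element is degenerated if its σ_I envelope (maximum over stance frames)
exceeds the threshold — a one-shot exceedance criterion, not cumulative
damage. Thresholds are evaluated at the subject's baseline age. Only
central-region elements count: the central band covers one third (default)
of the tibial plateau's A-P extent, mirroring MRI-score joint partitioning,
because the template constrains contact to that region. The reference
volume is the central-region cartilage of *both* tissues of the
compartment, so femoral + tibial fractions sum to the compartment fraction;
the whole-knee fraction pools degenerated and reference volumes over both
compartments. A per-tissue reference is available by dividing the reported
per-tissue fractions by the tissue's share of the reference volume.

The monotonic-tension threshold is piecewise linear in age — 30 MPa up to
30 years, then slopes −20/15, −3/20 and −2/100 MPa/year on (30, 45],
(45, 65] and (65, 75], constant 6.8 MPa above 75 — continuous at every
breakpoint. The fatigue threshold is 25.4 − 0.15·Age − 1.65·log₁₀(N) MPa
and raises an error when exhausted (non-positive).

## Radiographic verification

Joint-space width is the vertical femur-to-tibia distance at the femoral
point over the compartment ROI's mediolateral midpoint (a lowest-point
alternative is provided, since "central point of the condyle surface" is
ambiguous); narrowing is the percentage JSW loss from baseline to
follow-up. The synthetic contour generator draws circular condyle arcs over
a flat plateau with the true JSW equal to the subject's joint space, a
prescribed narrowing at follow-up, and additive Gaussian point noise;
measurement is translation-invariant and unbiased under point noise.

## Statistics

AUC uses the pairwise Mann–Whitney construction with midrank tie handling;
a single-predictor logistic model would yield the identical ROC by
monotonicity, so the scalar score (degenerated fraction) is used directly.
DeLong's placement-value variance estimator is implemented natively, both
against a null AUC and pairwise between two correlated AUCs on the same
knees (both uses are exposed because either reading is defensible).
Friedman (across model variants), Wilcoxon signed-rank (medial vs lateral,
paired) and Kruskal–Wallis (across KL groups, Bonferroni-corrected per
variant family) are delegated to scipy; the JSN regression (ordinary least
squares, adjusted R²) to statsmodels.

## Synthetic cohort

Marginals are matched to published median/IQR summaries: log-normal for
positively skewed lengths and mass, normal (range-truncated) for age, speed
and alignment; height and mass share a Gaussian copula (ρ = 0.5 default).
Sex is 71 % female, knee side 57 % right, baseline KL ∈ {0, 1}. Follow-up
KL is planted: a latent score = effect_size × standardized(noise-free peak
medial force per unit medial cartilage thickness) + standard-normal noise
is split at the 29/97 and 66/97 quantiles into KL 0–1 / KL 2 / KL 3–4.
This link is an artifact construct — a real study observes outcomes — and
effect_size = 0 severs it, giving chance-level downstream AUCs. The
generator does not emulate joint distributions beyond the height–mass
copula, measurement error in the MRI variables, or any real covariance
between anatomy and gait; passing end-to-end tests therefore demonstrates
internal consistency and recoverability of a planted signal at study scale,
not clinical validity.

## Known limitations

- Elastic-foundation columns ignore shear coupling between columns, sliding
  friction, menisci bodies and bone compliance.
- The depth-weight profile is a stand-in for the collagen arcade, not a
  reconstruction of fibril orientation.
- Uniform per-tissue thickness; no regional thickness maps.
- One-shot exceedance; no damage accumulation or remodeling over the
  follow-up interval.
- The published element counts of segmented templates are not reproduced;
  the parametric template is a stand-in for an undistributed segmented
  geometry.
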