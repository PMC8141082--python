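# Methods

This note records the model as implemented: its assumptions, the
parameters that matter, the protocol design choices that were
genuinely open, and what the synthetic-data tests do and do not show
about real traced molecules.

## Units and constants

Lengths in nm, forces in pN, energies and torques in pN·nm, charges in
elementary charges. The Gaussian electrostatic prefactor is carried by
`l_B·kT` (0.71 nm × 4.11 pN·nm ≈ 2.92 pN·nm² at 295 K), so the water
dielectric constant never appears explicitly. Debye length for the
monovalent electrolytes used throughout: `L_D = 0.304/√I` nm. Default
ionic strength is 2 mM — the geometric middle of the 0.2–20 mM range
the deposition experiments span — giving L_D = 6.80 nm.

Key defaults: persistence length P = 53 nm; DNA rise 0.34 nm (charge
spacing b_DNA = 0.17 nm, q_DNA = 5.88 e/nm); helical period
p_DNA = 3.57 nm; backbone radius 1.0 nm; amine spacing along a
lamellar row b_row = 0.53 nm; critical torque τ_K = 30 pN·nm; critical
radius R_K = 3.5 nm; kink energy E_K = 7 kT; torsional persistence
length C = 100 nm; plectoneme tension threshold F_p = 3 pN ("several
pN"); unzip threshold F_u = 10 pN.

## Crossing-rod torque

The closed form `τ = k_C π l_B kT q_DNA q_L L_D cosθ/sin²θ` is, up to
the condensation factor, the θ-derivative of the screened interaction
energy of two crossing line charges, taken per DNA arm: the Yukawa
line potential is `2λ l_B kT K₀(ρ/L_D)`, the arm energy integrates to
`π λ_D λ_L l_B kT L_D / sinθ`, and differentiation gives the π
prefactor exactly. This identification fixes the numerical oracle:
`torque_by_integration` sums pairwise Yukawa forces
`exp(−r/L_D)(1/r² + 1/(r L_D))` between discrete charges on one DNA
arm and the row, and agrees with the closed form to <1% at 0.05-nm
quadrature steps. A sharp-cutoff kernel (bare 1/r² restricted to
|x| ≤ L_D/θ along the row) is also provided; it reproduces the angular
scaling of the back-of-envelope derivation but differs from the closed
form by the factor (2/π)(sinθ/θ) and is not used as an oracle.

**Condensation.** k_C is the product of the two Manning fractions
min(1, b/l_B). With b_DNA = 0.17 nm this requires b_row = 0.53 nm to
give the monovalent-salt value k_C ≈ 0.18; 0.53 nm is a plausible
side-by-side molecular packing spacing for the rod-like film molecules
on graphite, and the package treats it as the calibrated default.

**Helical evaluation.** The ~50 pN·nm scale at θ = 15° is computed
with phosphates placed explicitly on the two backbone helices (140°
azimuthal strand offset, axis at backbone radius + 0.25 nm interfacial
gap above the charge plane), summed against the complete lamellar row
set (period 7 nm, pair separation 4 nm), with the torque taken about
the crossing on the *local* DNA segment — truncated halfway to the
neighbouring row crossing, where that crossing's own torque takes
over. The opposing pull of adjacent rows is what saturates the torque
at low salt: the result varies by <15% over 0.2–20 mM while the
single-row closed form is linear in L_D. Values are averaged over
eight helix phase registers (register scatter ≈ ±10%).

**Critical tilt.** θ_K solves τ(θ) = τ_K by bracketed root finding to
10⁻⁴ degrees; the boundary θ = θ_K is classified as kink (closed set
on the nonlinear side). Because τ diverges at 0° and vanishes at 90°,
the root always exists.

**Compression broadening.** The width multiplier of DNA compressed to
a height fraction f conserves the per-turn backbone strand length on a
cross-section deformed from circle to ellipse at fixed height, solving
for the ellipse half-width; it gives 1.27 at f = 2/3 and 1.44 at
f = 1/3. A perimeter-conserving variant sits behind the same flag and
gives 1.28/1.48 — the data cannot distinguish the two at the "about"
precision of the estimates, and strand-length conservation is the
default on physical grounds.

## Surface model

The lamellar template is a set of parallel charged rows along x,
repeating in y as {0, 4, 7, 11, …} nm; discrete +1 e charges sit every
b_row along each row. Epitaxial domains take one of six orientations
60° apart. The probe (a DNA site) rides at a fixed closest-approach
height of 1.0 nm; no number is given for this in the source imagery,
and it enters all screened distances.

Template evaluations use the exact screened line-charge potential
`2λ l_B kT K₀(ρ/L_D)` per row (indistinguishable from the discrete sum
at b_row ≪ L_D); `lateral_force_at` keeps the fully discrete pairwise
sum with a 6 L_D cutoff as the contract implementation, checked
against the brute-force sum.

The granular adlayer is a Poisson field of oligomer grains
(aggregation number uniform on [2, 10], charge 2 e per molecule — the
two terminal amines). The standard two-layer film
(`two_layer_film`) uses an incomplete adlayer at 0.015 grains/nm².
Large grain fields are pre-tabulated on a 0.5-nm bilinear energy/force
grid; the grid spacing is small against both L_D and the probe height,
and the gridded and exact paths agree.

## Trapping protocol

Kinetic trapping is one-pass sequential adsorption with no global
moves: segment i arrives carrying the quenched turn angle of the input
conformation (a freely generated 2D or projected chain — the shape the
coil brings from solution) and the realised turn minimises

    E(δ) = ½ (kT·P/a) δ²  +  q_site · U_surf

over a bounded candidate grid (±0.6 rad, 25 candidates), where U_surf
is averaged over a 5-nm lookahead along the candidate direction. Three
protocol choices deserve explanation:

* **Zero-temperature quench.** Boltzmann-resampling the turn angles at
  full thermal weight would re-thermalise the chain even at zero
  surface charge (roughly halving the apparent persistence length), so
  the default is the T → 0 limit: at zero charge the input
  conformation is reproduced exactly, which is the correct null.
  `trap_temperature > 0` restores finite-temperature sampling.
* **Lookahead.** The incoming section of a stiff coil feels the field
  over nanometres, not at a point; without the 5-nm horizon the
  deposition cannot sense the row corrugation (the trough bottom is
  locally flat) and no orientational bias develops.
* **Kink pairing and trough gating.** The lateral force transverse to
  the chain is accumulated into a running torque over a trailing 10-nm
  window, but only while the chain is *outside* a trough core
  (row distance ≥ 1 nm): inside a trough the transverse force is a
  confining restoring oscillation already relieved by smooth bending
  (the B sites of the undulations), and counting it produces spurious
  in-trough kinks. When the accumulated torque reaches τ_K, the turn
  is replaced by a discrete kink (uniform 85–105°, oriented with the
  torque, formation torque recorded) — and the pair's anti-kink
  re-attaches the crossing segment along the next row it reaches.
  Without the anti-kink the model strands chains perpendicular to the
  rows (a perpendicular chain feels zero transverse force from a
  translation-invariant row), inverting the observed orientational
  statistics.

Per-site bookkeeping: B labels for strong local turns and kinks, S for
straight pinned runs in troughs; pinned intervals carry a quenched
residual twist drawn from N(0, S₁₂/C) — the thermal twist variance of
the interval frozen in at adsorption; tension and unzip stress are
recorded per site. Anomaly classification then flags a pinned interval
as a collapsed plectoneme when its tension reaches F_p while its
residual twist exceeds the thermal scale √(S₁₂/C), and an interval as
a melting bubble when the opposing row pulls reach F_u; spans never
overlap (plectonemes take precedence).

## Reference ensembles and discretisation

2D equilibrated chains use Gaussian turn angles of variance a/P per
1-nm segment, giving the in-plane tangent correlation exp(−s/2P) and
the 4PL asymptote of the 2D law — the variance is a/P rather than a/2P
precisely so the 2D correlation length is 2P. 3D chains bend by
Gaussian polar angles of variance 2a/P about uniform azimuths
(tangent correlation exp(−s/P) to O((a/P)²) per step) and are
flattened by dropping z; the in-plane mean-square end-to-end distance
is exactly 2/3 of the 3D one for any isotropic ensemble. Projected
chains keep the 3D arc parameterisation, so their in-plane step
lengths vary; fixed-spacing invariants apply only to fixed-spacing
chains.

The confined zigzag generator is a *geometric* model of the observed
template-directed shapes — no energetic derivation of the zero-tilt
instability exists — with segment length W/sin((180° − v)/2) for
vertex angle v and one kink per vertex.

## Contour statistics

⟨R²(L)⟩ follows the all-pairs rule: contours are resampled by linear
interpolation at a fine uniform arc spacing (≤ step/10), squared chord
distances are averaged over all point pairs at each 25-nm arc
separation and pooled across molecules with pair-count weights.
Standard errors come from the between-molecule scatter of per-molecule
means — pairs within one molecule are strongly correlated, and naive
pair-count errors would be absurdly small; the pooling rule is
recorded in the curve metadata. Persistence-length fits minimise the
1/SE²-weighted squared residual against the chosen reference law over
L ≤ half the shortest trace (end effects), with the confidence
interval from the curvature of the objective.

Kink detection estimates tangents as chords over a 4-nm window on each
side of each point and calls a kink where the turn angle reaches 60°
or the implied osculating radius w/(2 sin(angle/2)) falls to 3.5 nm,
with non-maximum suppression at one call per window. The *reported*
angle is re-measured with a 2-nm chord: thermal bending contributes
~13° of noise to the 4-nm window at P = 53 nm but only ~9° at 2 nm,
and detection robustness and angle accuracy want different windows.

Extended segments for the orientation statistic are maximal runs with
all 2-nm turn angles below 20° and length ≥ 20 nm; the anisotropy
score is the length-weighted n-fold circular order parameter
|⟨e^{i n φ}⟩| (n = 6 for the epitaxial template), tested against a
Monte Carlo isotropic null with the same weights.

Height-profile analysis Gaussian-smooths the longitudinal profile
(1 nm default) before locating minima; heights must lie within
(0, d_DNA] with d_DNA = 2 nm for B-form DNA.

## Synthetic data: what it does and does not emulate

Fixtures reproduce the *geometric and statistical* structure of traced
molecules: correct WLC statistics at P = 53 nm, planted kinks at the
observed 85–105° angles with ground truth, trapped ensembles on the
two-layer film, zigzag undulations (W = 4 nm, vertices 85–105°), and
quasi-periodic height profiles (8-nm depressions between d/3 and
2d/3). They do not emulate AFM tip convolution, drift, finite pixel
sampling beyond an isotropic Gaussian jitter, tracing-algorithm
artefacts, or molecule–molecule crossings. Passing the recovery and
recall tests therefore shows the estimators are correct on clean
geometry at realistic noise scales, not that they are robust to every
instrumental artefact of real images.

Typical problem sizes (500 molecules × 900 nm for ensemble fidelity,
120 molecules × 450 nm for trapping statistics, 999 permutations for
the anisotropy null) were chosen so the statistical tolerances are
comfortably resolved while a full run stays in the minutes range on a
single CPU.

## Known limitations

* The trapping protocol is a plausible quench dynamics, not a derived
  one; the source material describes trapping during adsorption but
  gives no equations of motion. Kink-pair insertion and trough gating
  are coarse-grained rules justified by the behaviours they reproduce
  (kink density, compactification, template alignment), not by a
  microscopic derivation.
* Twist is bookkeeping only — no torque–bend coupling; plectoneme and
  bubble calls are threshold rules on recorded stress, with no melting
  thermodynamics.
* The interfacial dielectric amplification (ε_⊥ ≈ 2) enters only as an
  optional multiplicative factor on normal forces; no formula exists
  for it in this geometry.
* Helical-model absolute torques depend on closest-approach geometry
  (gap, backbone radius) at the tens-of-percent level; the package's
  defaults are canonical B-DNA values plus a 0.25-nm interfacial gap,
  and the ~50 pN·nm figure should be read at that precision.
* The θ = 0 confined instability is represented by the geometric
  zigzag generator only.
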