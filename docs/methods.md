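# Methods

## The center of excess charge

An excess proton in water (or next to a protonatable acid) is a charge
defect, not an atom. `cectrack` represents it as a weighted average over
diabatic bonding topologies. State |1⟩ is the topology actually realized in
the frame: every hydrogen is assigned to its nearest oxygen
(minimum-image; ties within 1e-9 Å broken by lower atom index, which keeps
the assignment deterministic for stored frames), oxygens with two hydrogens
are waters, an oxygen with three is the hydronium, and a declared acid group
is neutral when one of its oxygens holds a hydrogen. Exactly one protonated
species must exist; hydroxide (proton holes) and multi-proton inputs are
rejected.

Further states are generated breadth-first: every hydrogen of the protonated
species that sits within 2.5 Å of another oxygen (a shared-H⋯acceptor-O
hydrogen-bond criterion; no additional O–O cutoff is applied) can transfer,
making the acceptor molecule the protonated species of a child state. The
search stops after three shells — populations are already negligible in the
fourth — and obeys two rules: a transferred hydrogen may not immediately hop
back to its donor, and a path never revisits a molecule it already
protonated (simple paths). Two simple paths that close a ring reach the same
protonated species and therefore the same center of charge; normalization
sums their weights, so keeping them as separate states is exactly equivalent
to merging them, and no merge option is exposed.

Each state's center of charge (COC) uses fixed per-atom excess charges.
Excess charges are defined as protonated-species charges minus
deprotonated-parent charges and sum to +1 e; using them (rather than the raw
charges of a neutral species, which sum to zero) keeps the COC denominator
regular. The shipped defaults,

| species  | role | q (e) |
|----------|------|-------|
| hydronium| O    | 0.334 |
| hydronium| each H | 0.222 |
| acid (glu)| C   | 0.10  |
| acid (glu)| O–H  | 0.35 |
| acid (glu)| O (carbonyl) | 0.11 |
| acid (glu)| H   | 0.44  |

are *stand-ins* constructed from typical fixed-charge force-field values;
they are plain JSON and meant to be overridden with the user's own charge
model. All tests that assert positions, not conventions, pass charge tables
explicitly.

## Charge-transfer weights

The weight carried across one hop is modeled as f_CT(δ) = exp(k (δ − δ₀))
in the proton-transfer coordinate δ = |r_H − r_donorO| − |r_H − r_acceptorO|
(negative while donor-bound, zero at equal sharing). f_CT is a weight
*ratio* between the two states a hop connects and may exceed 1; the global
normalization Σ c_i² = 1 absorbs that. A state's unnormalized weight is the
product of f_CT over its path (the root's empty product is 1), so
c₁² = 1 / (1 + Σ_paths Π f_CT). The exponent is clipped at ±50: the factor
at the clip (~5e21) is far beyond any physically reachable geometry, and the
clip only exists so that pathological inputs cannot overflow. Where the
derivative is needed the clipped branch contributes zero slope, consistent
with the clipped value.

Shipped (k, δ₀): hydronium–water k = 4.234 Å⁻¹, δ₀ = 0 (BLYP; the default,
matching the AIMD the model was built for) and k = 4.898 Å⁻¹, δ₀ = 0 (ωB97X,
selectable by config — the two give very similar CEC dynamics); Glu–water
k = 2.946 Å⁻¹, δ₀ = 0.5361 Å. δ₀ = 0 encodes the symmetry of equal sharing
between two waters; the positive δ₀ of the weak acid delays charge transfer
until the proton is well past the midpoint. Sign conventions for δ and the
exponent are gauge partners — flipping both changes nothing observable; the
contractual facts are f_CT(δ₀) = 1, monotone increase toward the acceptor,
and equal populations at equal sharing.

A hop from a hydronium *onto* a deprotonated acid oxygen is evaluated with
the mirrored convention f = 1/f_fwd(−δ) = exp(k (δ + δ₀)) using the same
acid–water parameters; the reverse direction is not independently
parametrized, which is the natural reciprocity of a weight ratio.

Periodic frames (orthorhombic boxes only; anything else is rejected loudly)
are handled by evaluating every distance under minimum image and by
unwrapping the whole state network — each acceptor molecule placed relative
to its donor oxygen, anchored at the root — before any position average, so
COCs, the CEC and the excess-charge dipole share one consistent set of
images. The dipole of the per-atom excess charges Σ_i c_i² q_I^i then equals
+1 e times the CEC exactly (the tests assert 1e-9 Å), a useful internal
consistency check. The CEC is strictly local: atoms outside every
three-shell path carry zero excess charge and zero gradient, so bulk-like
water motion cannot leak into the CV.

Analytic gradients ∂r_CEC/∂r_I combine the per-state COC term (q_I^i times
the identity) with the weight term obtained by the chain rule through every
hop's δ. The blocks over all involved atoms sum to the identity
(translational covariance); the suite verifies them against central finite
differences (step 1e-5 Å) to 1e-6 relative error, including geometries with
δ ≈ 0 where populations change fastest.

## Excess-charge IR spectrum

The spectrum is the Fourier transform of the CEC velocity autocorrelation
function. Velocities come from central differences (one-sided at the ends);
`vacf` exposes the unbiased per-lag estimator ⟨v(0)·v(τ)⟩. The transform
itself uses the *biased* autocorrelation, whose symmetric extension equals
the periodogram of the velocity series: intensities are then non-negative by
construction and total spectral power equals VACF(0) exactly for the
untapered transform. A Hann lag-window is applied by default to suppress
leakage (the data source is silent on windowing; this is standard practice
and `window="none"` disables it). No ω-dependent prefactor and no quantum
correction are applied — band *positions and shapes* are the object of
interest and intensities are reported in arbitrary units; an optional ω²
weighting flag exists and is off by default. Spectra are reported on a cm⁻¹
grid (1 fs⁻¹ = 33356.41 cm⁻¹) and the standard presentation applies a
33 cm⁻¹ boxcar running average whose edge bins average over the available
span.

## Proton-dissociation CV and well-tempered metadynamics

ξ = softmin(|r_CEC − r_O1|, |r_CEC − r_O2|) over the two carboxyl oxygens,
softmin(a, b) = −(1/κ) ln(e^{−κa} + e^{−κb}) with κ = 40 Å⁻¹, evaluated by
shifting by the true minimum so no finite input overflows. softmin ≤ min
everywhere with maximal gap ln 2 / κ ≈ 0.017 Å on the diagonal. Gradients
with respect to the CEC and both oxygens are analytic and sum to zero;
`xi_atom_gradient` composes them with the CEC Jacobian for per-atom forces.
That composition is provided for analysis of stored frames — driving a live
MD engine is out of scope.

The well-tempered bias deposits Gaussians of width σ = 0.1 Å every 50 fs
with initial height 0.2 kcal/mol, damped by exp(−V(s)/(k_B ΔT)) with
ΔT = (γ−1)T and bias factor γ = 12 (sized for dissociation barriers of
order 9 kcal/mol). The free energy is recovered as
F(s) = −(γ/(γ−1)) V(s) + const. Hills are stored unmerged;
`evaluate_bias` always performs the exact sum over hills. (A grid-accumulated
evaluator cannot reproduce the exact sum to high precision at any sane grid
spacing, so none is offered at the API level.)

One caveat worth recording: repeated deposition at a *fixed* point does not
converge to a finite bias — the recursion V ← V + h₀ e^{−V/c} with
c = k_B ΔT grows as c ln(1 + n h₀/c), with hill heights decaying like 1/n.
The suite asserts this logarithmic law. Boundedness in practice is a
property of the coupled dynamics (the walker leaves regions it has filled),
which is what the demonstration below shows.

The demonstration runs overdamped Langevin dynamics,
ds = βD F dt + sqrt(2D dt) dW, on a symmetric double well
U(s) = B((s/a)² − 1)² with B = 3 kcal/mol and minima at ±1 Å, at 300 K.
Inside the driver the accumulated bias and its derivative live on a fine
grid (spacing 1e-3 Å, linear interpolation error ~1e-5 kcal/mol) so each
step costs O(1); the hill list itself remains exact and unmerged. The
diffusion coefficient default, D = 5e-5 Å²/fs, is chosen for timescale
separation: the Kramers escape time from a well (~0.7 ns) is far longer than
the 40 ps unbiased comparison window — reproducing the trapped behavior a
weak acid shows on AIMD timescales — while the 800 ps biased run completes
several barrier crossings. The free-energy estimate averages the bias over
the second half of the run, which suppresses the hill-by-hill oscillation of
the instantaneous well-tempered estimator; the suite recovers the 3 kcal/mol
barrier within 0.3 kcal/mol (three-seed average) and observes a biased
visited range more than 3× the unbiased one.

## Calibration

Training geometries are collinear donor–H–acceptor scans: hydronium–water
over r_OO ∈ {2.2, …, 3.2} Å with six shared-proton positions evenly from
r_OH = 0.9 Å to the midpoint (36 points), and carboxyl–water over seven
r_OO evenly in [2.2, 2.8] Å with nine positions in [1.0, r_OO − 1.0] Å
(63 points). Spectator atoms are idealized (0.97 Å O–H; mirror-symmetric
spectators so the midpoint geometry is exactly symmetric; planar carboxyl):
only δ enters the fit, but the frames are emitted as valid XYZ (with r_OO,
r_OH labels in the comments) so an external electronic-structure code can
evaluate charge-transfer factors on them. Computing f_CT from electron
densities is explicitly out of scope — the fit consumes tabulated
(δ, f_CT) pairs.

The least-squares fit of f_CT = exp(k(δ − δ₀)) is initialized from the
exact log-linear regression and refined on the factor itself (the default;
a log-space fit is available by flag, and is the right choice when the
noise is symmetric in log — the two agree to 1e-6 on noiseless data). For
symmetric pairs δ₀ can be pinned to zero. Estimated covariance assumes the
residual weights reflect the noise model; for multiplicative noise pass
weights ∝ 1/f. Degenerate inputs (fewer than 3 points, all-equal δ,
non-positive factors, data that decrease with δ) raise configuration
errors rather than returning nonsense. A scale identity is useful for
validation: multiplying all factors by a constant changes δ₀ by −ln c / k
and leaves k untouched.

## Synthetic fixtures: what they do and do not show

The generators produce geometries with *known* combinatorics and kinematics:
an ideal ring-free network (hydronium donating 3, waters donating 2 onward,
all acceptor H⋯O distances 1.6 Å ⇒ exactly 1+3+6+12 = 22 states), Zundel
scans, pure-tone CEC tracks for the spectral pipeline, and a water-wire
shuttle whose proton moves with a minimum-jerk profile so continuity is
meaningful at every frame. Internal geometries are idealized; the CEC
mathematics depends only on the distances entering δ and the species
positions, so idealization does not weaken the properties being tested. The
fixtures are deterministic under a fixed seed and self-describing (their
parameters live in the XYZ comment lines). They do *not* emulate thermal
disorder, realistic hydrogen-bond statistics, polarization, or condensed-
phase spectra: passing tests establish the correctness of the machinery
(counts, conservation laws, gradients, transforms), not quantitative
agreement with experimental or AIMD observables, which requires real
trajectories as input.

## Numerical choices, in one place

- Units: Å, fs, kcal/mol, charges in e; spectra in cm⁻¹.
- Atom indexing 0-based internally; file formats keep native conventions
  (XYZ parse errors cite 1-based frame/line).
- Only orthorhombic boxes; triclinic inputs raise immediately.
- H-to-O assignment tie-break: lower atom index (1e-9 Å tolerance).
- f_CT exponent clip ±50; clipped branch has zero derivative.
- Charge-table and weight-normalization tolerances: 1e-9 and 1e-12.
- Hann lag-window default, 33 cm⁻¹ boxcar presentation default.
- Langevin driver: dt = 1 fs, bias grid 1e-3 Å, FES from tail-averaged bias.
- All randomness flows through `numpy.random.default_rng(seed)`.

## Known limitations

- No live coupling to an MD engine; gradients are exposed for analysis and
  for downstream integration, not applied to forces here.
- One excess proton only; no hydroxide transport, no simultaneous defects.
- The acid group must be declared (atom indices); titratable-group
  perception from residue templates is not attempted.
- Shipped excess charges are stand-ins; quantitative per-system work should
  supply its own table.
- The exponential f_CT form is an approximation fitted to gas-phase charge
  transfer; systems where it fits poorly need a different switching form.
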