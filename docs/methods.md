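# Methods

This note documents the models implemented in `tubeflex`, their assumptions,
the parameter conventions, and the numerical choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Relaxation-rate estimation and dispersion fitting

**Decay model.** Peak heights of a pseudo-3D relaxation series are fitted to
h(t) = A·e^(−R·t) by unweighted nonlinear least squares, initialised from a
log-linear regression of the positive heights. The experimental grids are
shipped as defaults: delays 0.5, 1, 1.5, 2, 3, 4, 8, 16, 32 s for R₁ and
spinlock strengths 9, 7, 5.5, 5, 4.5, 4, 3.5, 3, 2.5, 2 kHz for R₁ρ. A fit
that fails to converge, or converges to a negative rate, is returned with
`converged=False` and is excluded from downstream combined fits rather than
imputed; it is never silently zeroed.

**Rate errors.** Each series is refit `n_repeats` (default 1000) times with
Gaussian noise of the series' stated σ added to the heights; the standard
deviation of the refitted rates is the rate error. σ = 0 yields exactly zero
error.

**On-resonance correction.** The effective field during a spinlock tilts by
θ = tan⁻¹(ω₁/Ω) from the static field; the observed rate mixes R₁ρ and R₁ as
R₁ρ,obs = R₁ρ sin²θ + R₁ cos²θ. The correction inverts this, with
first-order error propagation. When sin²θ < 0.0075 (tilt under ~5° — the
offset dwarfs the spinlock) the inversion amplifies noise by >130× and the
call is rejected instead of returning a meaningless number. Ω = 0 is the
exact on-resonance identity.

**Two-site dispersion model.** On-resonance R₁ρ versus spinlock strength is
described by the fast-exchange two-site expression
R₁ρ(ω₁) = R₁ρ,0 + φ_ex·k_ex/(ω₁² + k_ex²), valid when exchange is fast on
the chemical-shift timescale so that only φ_ex = p_A·p_B·Δδ² (not the
individual populations or shift difference) is identifiable. Spinlock
strengths and offsets are converted to angular frequency (rad/s =
2π·10³·ν[kHz]) before entering the model, so ω₁² and k_ex² are commensurate;
φ_ex is then in rad²·s⁻².

**Global fit.** All residues share one k_ex; each residue has its own φ_ex
and R₁ρ,0. The χ² = Σ((data − model)/σ)² uses per-point σ (a per-series σ is
broadcast). At fixed k_ex the model is linear in each residue's
(R₁ρ,0, φ_ex), so the objective is profiled: every k_ex evaluation solves
closed-form 2×2 weighted normal equations per residue, with a negative φ_ex
solution pinned to zero and the baseline re-solved (this enforces
non-negativity without log-reparameterising the linear block; k_ex itself is
searched in log space, which enforces k_ex > 0). The resulting 1-D profile
is minimised from seven log-spaced starting points (10²–10⁵ s⁻¹, each
bracketed ±1.6 decades) because the full objective can be multimodal.
Identifiability is judged by the dispersion amplitude the fitted φ_ex
actually produces across the measured ω₁ range: if it is below 10⁻⁸ of the
data scale, the profiles are flat, φ_ex is pinned at 0 and k_ex is flagged
unidentifiable.

**Monte-Carlo parameter errors.** The fit is repeated `n_repeats` (default
250) times with every R₁ρ point perturbed, and the parameter spread over
repeats reported as the error. Two perturbation schemes are provided. The
default, `gaussian`, draws err·N(0, 1) — a parametric bootstrap at the
nominal noise level, so the spread estimates the sampling distribution and
"within 3 MC standard deviations" carries its usual ≈99.7 % meaning. The
alternative, `signed_uniform`, draws err·U(0, 1) with a random sign; its
variance is err²/3, so it understates the sampling spread by √3 and a 3-SD
interval from it covers only ≈92 % — it is kept because perturbation
prescriptions of this form appear in the literature, but it is not the
default. MC refits re-optimise k_ex locally (±2 decades around the base
fit), which is valid because the perturbations are small relative to the
basin of attraction.

## Helical assembly and ambiguous restraints

The tube axis is +z with ring 0 at z = 0. Slot k of ring r is the subunit
rotated by (k·360°/c_sym + r·twist) about +z — right-handed by default, the
sign flipping for left-handed assemblies — and translated by (0, 0, r·rise).
Defaults are the tube's optimised symmetry: C6, rise 38.46 Å, twist 21.89°.
Pose (0,0) is the exact identity; chain identifiers are assigned
sequentially (A…Z, AA…) in pose order, deterministically.

A cross-peak between two atoms cannot be assigned to subunits under this
symmetry. It is expanded into an ambiguous restraint: atom A in the
reference subunit against atom B in *every* subunit of the assembly —
c_sym × n_rings candidates (12 for the standard two-ring C6 case, the self
pair included, since an intramolecular origin cannot be excluded for
homogeneously labelled samples). Peaks from heterogeneously mixed samples
are known intermolecular and drop the self pair (11 candidates). Candidates
are combined by r⁻⁶ sum averaging, d_eff = (Σ dᵢ⁻⁶)^(−1/6) — the standard
treatment for ambiguous NMR restraints, under which the closest candidate
dominates and d_eff ≤ min(dᵢ) always. Violations are reported against a
hard upper bound (default 7 Å, the generous bound appropriate for such
data), sorted by excess. A soft (logistic) restraint potential for
refinement engines is deliberately out of scope.

**β-strand register inference.** For two adjacent antiparallel strands, a
register r pairs residue a_lo+i with b_hi−i−r. Each observed contact between
strand residues is scored by a Gaussian in distance: a contact whose
partners mismatch the register by m residues would sit at
√(d_pair² + (s·m)²) in idealised antiparallel geometry (cross-strand pair
distance d_pair = 5.0 Å, per-residue ladder spacing s = 3.3 Å), and the
log-likelihood penalty is (d_pred − d_pair)²/(2σ_reg²) with σ_reg = 1.0 Å by
default. Registers within ±(longest run) are enumerated and the scores
normalised to a posterior. This is a deliberately simple, transparent
stand-in for a full probabilistic register restraint; with no contacts
touching both strands it returns a uniform posterior flagged
`uninformative`. The assembly argument is used to validate that restraint
atoms exist; the score itself uses idealised strand geometry, not model
coordinates, so it remains meaningful before a converged structure exists.

## Bent-tube model

**Arc geometry.** The bent tube is a rigid arc in a single bending plane
(curved filaments are observed via in-plane 2D class averages, so one plane
suffices). With curvature radius R_c measured to the tube axis and tube
diameter d: inner radius = R_c − d/2, outer radius = R_c + d/2. The
constraint that the *inside* edge keeps the straight-tube ring spacing Δ
gives the per-ring bend angle α = Δ / inner_radius (radians); the arc then
predicts an outside spacing α·outer_radius. The formula is scale-equivariant
(scaling all lengths leaves α unchanged) and reproduces both observed
angles: 3.5° at R_c = 655 Å and 4.2° at R_c = 560 Å (d = 63.3 Å,
Δ = 38.5 Å). An independently *measured* outside spacing can be attached as
metadata (`measured_outer_spacing`); it is not forced to match the arc
prediction, because a measured value folds in local deformation the rigid
arc cannot express.

**Model building.** Ring r of the bent model is ring 0 rotated by r·α about
the axis through the curvature centre (at (−R_c, 0, 0)) perpendicular to
the bending plane. Copies are exactly rigid. The rotation is applied as a
displacement using 1 − cos a = 2 sin²(a/2), so the straight-tube limit
(R_c → ∞) is numerically exact rather than destroyed by cancellation.
Building fails if the ring's own radial extent reaches the inner radius.

**Restraint network and fulfilment.** Random atom pairs between 3 and 15 Å
apart in the straight tube (sampled without replacement, seeded) become
harmonic restraints with straight-tube target distances; designated atoms
(e.g. the luminal β-sheets — the user supplies the selection, since no
general rule identifies them) can be position-restrained. All force
constants default to 1 (arbitrary units): only relative energies matter for
the analysis. `relax_under_restraints` minimises Σk(d−d₀)² + Σk|x−x₀|² by
L-BFGS with analytic gradients; the energy trace over accepted iterations is
recorded and non-increasing. A pair is *fulfilled* in the bent model when
|d − d₀| ≤ 0.5 Å (configurable; a value well below the ~4 Å per-ring
outside stretch at the observed curvature, so genuinely stretched contacts
are counted as broken). Per-residue fulfilment is the fulfilled fraction of
incident pairs; residues with no incident pairs report NaN, not zero.
Because rings move rigidly, low fulfilment concentrates in inter-ring
contacts on the outside of the curve — the signature of bending by
stretching, and the proxy this package uses for hinge-region detection.

## Density-map analytics

Maps are voxel grids with a physical voxel size and origin; MRC/CCP4 I/O
goes through gemmi with voxel size and origin preserved. Rendering sums one
isotropic unit-height Gaussian per atom (default width σ = 1 voxel,
configurable — resolution realism is irrelevant to the invariants tested),
truncated at 4σ.

**Filters.** Sharpening scales Fourier amplitudes by exp(−B·s²/4) (B < 0
sharpens; B = 0 is the identity; ±B round-trips to numerical precision).
The low-pass filter is a raised-cosine soft mask centred at 1/cutoff with a
default transition width of two reciprocal voxels; the DC component is
untouched and a cutoff at or below 2·voxel (Nyquist) is rejected.

**FSC and resolution.** The Fourier shell correlation uses shells one
reciprocal voxel wide from the first shell to Nyquist:
FSC_n = Re Σ F₁F₂* / √(Σ|F₁|² Σ|F₂|²). The sigmoid
FSC(x) = 1/[e^((x−A)/B) + 1]^C is fitted by bounded least squares with
multi-start over candidate inflection points; A is the inflection frequency,
B the transition width (flagged when it falls below the shell spacing —
the curve is then effectively a step at the data's resolution) and C a shape
exponent. Resolution at a criterion t is the reciprocal of the crossing
frequency — closed form x* = A + B·ln(t^(−1/C) − 1) for a fit, first
downward crossing by linear interpolation for a raw curve; the closed form
is cross-checked against independent bisection in the tests and the
acceptance script.

**Bootstrap and isosurface variance.** Reimplementing a reconstruction
engine is out of scope, so the bootstrap operates one level up: member maps
stand in for per-segment contributions, and each replicate is the mean of a
with-replacement resample of the members — preserving the
resample/reconstruct/compare structure of a reconstruction-level bootstrap.
Raw per-voxel density variance is artifact-prone (noise outside the
particle, symmetry axes), so the isosurface variance is computed instead:
each replicate is low-pass filtered (default 8 Å), binarised at a density
threshold (0.162 for maps on the original deposit's intensity scale — no
normalisation is imposed, so the threshold is always explicit), the binary
mask smoothed with a Gaussian (default 2 voxels), and the per-voxel variance
across replicates taken. The low-pass cutoff and smoothing width are not
prescribed anywhere authoritative; both defaults are recorded in output
metadata and configurable. Identical replicates give an identically zero
map; variance concentrates where the isosurface moves. The default
replicate count is 300; the bundled tests use 50 replicates on small grids,
which exercises the same estimator at lower Monte-Carlo precision.

## Synthetic data: what it does and does not show

The generators are pure functions of explicit integer seeds (no global RNG
state) and reproduce exactly the statistical structure the estimators
assume: monoexponential decays and two-site dispersion profiles with
additive Gaussian noise on heights (the simplest model consistent with
"average spectral noise" error estimation), pseudo-atom subunits with
designated strand runs, and Gaussian-atom maps with optional rigid jitter of
a designated substructure. Passing tests therefore demonstrate estimator
correctness — recovery of generating parameters, correct limits, correct
localisation — under the assumed noise model. They do not demonstrate
robustness to what real data add: non-Gaussian and correlated spectral
noise, peak overlap, model error in the exchange mechanism (slow exchange,
>2 states), CTF and alignment errors in maps, or solvent background. The
synthetic monomer is a labelled point cloud, not a protein fold.

## Pipeline conventions

The end-to-end pipeline takes one JSON config (root seed, stage toggles,
per-stage parameter blocks; CLI flags override). Per-stage seeds are derived
deterministically from the root seed, so reruns are bit-identical; every
output file is hashed (SHA-256) into a run manifest together with the config
and package versions. Stage parameters are validated against each module's
preconditions before any stage executes, and a stage failure aborts the run
naming the stage. Demo problem sizes (48-atom monomer, 10 residues, 8 member
maps, 50 bootstrap replicates, ~2 Å voxels on ~25³–40³ grids) keep a full
run around a second on one CPU while exercising every code path; all sizes
scale up by config.

## Known limitations

- The dispersion model is the fast-exchange limit; k_ex and φ_ex are the
  only identifiable exchange parameters, and data outside that regime will
  bias both.
- Register inference uses idealised antiparallel geometry; twisted or
  β-bulged sheets shift the effective ladder spacing.
- The bent tube is a rigid-arc model: it cannot express intra-ring
  deformation, and its arc-predicted outside spacing need not match a
  measured one.
- The map bootstrap resamples member maps, not raw segment images; variance
  below the member-map granularity is invisible, and symmetry-breaking
  variance is not observable when members were built symmetrised.
- Local (windowed) resolution mapping is not implemented; model-vs-map FSC
  is global.
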