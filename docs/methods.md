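# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `hybridqmt`, and what the synthetic-data tests do and do
not establish about real acquisitions.

## Spin model

The two-pool system is propagated in the augmented state
`s = (x^f, y^f, z^f, x^s, z^s, 1)`; `y^s` is omitted (valid when the RF
field is applied about the y axis and the semisolid transverse decay rate
far exceeds the off-resonance frequency).  All internal units are SI
(seconds, rad/s); `T2s` appears in microseconds only at I/O boundaries and
in printed output.

Rectangular pulses are assumed: the Rabi frequency is constant,
`ωy = α/T_RF`, which is the parameterization under which the linearized
semisolid rate is defined.  During free precession the semisolid transverse
component decays at the raw rate `R2s = 1/T2s` (it is negligible within a
fraction of a repetition).

**Inversion preparation.** The preparation pulse is modeled as an
instantaneous ideal π rotation of the free pool combined with
generalized-Bloch saturation of `(x^s, z^s)` over the pulse's nominal
duration (500 µs default, configurable); relaxation and exchange during the
pulse are neglected.  Echo timing follows the balanced convention: the echo
is read TR/2 after the pulse center, with 0/π RF phase alternation on by
default and echoes demodulated by the pulse phase.  These are stand-in
conventions — the source acquisitions do not pin down the echo or inversion
details — and are isolated behind `SequenceSchedule` fields.

**Cyclic steady state.** The hybrid-state cycle repeats, so simulation
starts from the fixed point of the full-cycle affine propagator
`P = [[A, b], [0, 1]]`, solved exactly as `s₅ = (I − A)⁻¹ b` rather than by
iteration (speed and determinism); equivalence with 60-fold power iteration
is a test.

**Matrix exponentials.** A batched Padé-13 scaling-and-squaring
implementation exponentiates all per-repetition matrices of a schedule in
one call; scipy's `expm` is the per-slice oracle in the tests.  With the
semisolid rate ~10⁵ 1/s the matrix norm over long durations forces many
squarings, which limits fixed-point accuracy to ~10⁻¹² at 0.1 s and ~10⁻¹¹
at 1 s — irrelevant at repetition-time scales but visible in
equilibrium-preservation checks at artificial durations.

## Lineshape and linearized rate

The super-Lorentzian kernel is evaluated by fixed 500-node Gauss–Legendre
quadrature over the orientation angle (deterministic; agrees with a
10⁴-node trapezoid oracle to <10⁻⁸).  The generalized-Bloch
integro-differential equation for `z^s` under constant `ωy` is solved with
an implicit-trapezoidal Volterra scheme (second order; default 10⁴ steps
for the exact path), and `R2s,l` is obtained by bracketed Brent root-finding
on the closed-form exponential-pool solution (relative tolerance 10⁻¹⁰,
bracket 1–10⁷ 1/s, widened downward if needed).  The match is on the
end-of-pulse longitudinal magnetization `z^s` alone, from `z^s(0) = 1`, with
relaxation and exchange off — the evolution matrix handles those.  Anyone
comparing against other implementations should check this convention; a
match on the full semisolid state would differ at the few-percent level for
long pulses.

Because time enters only as ratios, `R2s,l(c·T2s, α, c·T_RF) =
R2s,l(T2s, α, T_RF)/c` exactly.  Schedule-level simulation therefore uses a
precomputed 40×48 cubic spline of `log(R2s,l·T2s)` over
(α ∈ [0.005, π], log(T_RF/T2s) ∈ [log 2, log 2000]), built once per process
(~9 s) and accurate to ~10⁻⁶ relative against the exact path (tests bound
it at 10⁻³).  The exact memoized path (`r2sl="exact"`) remains available
and is the reference in all oracle comparisons.

## Schedules

`default_schedule` is a documented stand-in, not the numerically optimized
flip-angle train used on scanners: inversion preparation, a sin² flip-angle
envelope modulated by a seed-dependent harmonic (1.5°–60°), a smoothly
varying pulse duration (200 µs–1 ms), and constant TR summing to the cycle
duration (3.5 s default).  Its six-parameter Fisher information is full
rank (smallest/largest relative-sensitivity singular value ≈ 4×10⁻⁴ for the
64-repetition test schedule), but the weakest directions mix `R1f`, `Rx`
and `R1s`; noise therefore lands disproportionately on those parameters.
Test and acceptance workloads use 64–100 repetitions as the problem size.

## Subspace

Dictionaries are simulated over a Cartesian grid; the default spans
m0s 0.05–0.35, R1f 0.3–2 /s, R2f 5–25 /s, Rx 5–100 /s, R1s 0.2–5 /s,
T2s 5–20 µs (5 points per axis), literature-plausible ranges chosen here —
only the ~10 µs order of `T2s` is externally anchored.  Atoms are normalized
to unit norm before the SVD (configurable), the SVD runs on the
real/imaginary-stacked real matrix, and the folded complex basis is
re-orthonormalized by QR with a deterministic phase convention
(largest-magnitude element positive real).  Rank 15 reconstructs held-out
off-grid fingerprints to ~10⁻⁴ relative RMS for the default schedule/grid
(tested bound 10⁻³).  The optional gradient-augmented dictionary used in
some reconstruction pipelines is not implemented; plain fingerprint SVD is
sufficient at these ranks.

## Estimation

Bounded trust-region nonlinear least squares with variable projection of
the complex amplitude (`c = ⟨M, y⟩/‖M‖²` per evaluation) replaces learned
regressors deliberately: the forward model is fully specified, so NLLS is
the transparent, testable estimator, and it provides CRLB-style
uncertainties from the Jacobian at the optimum.  Defaults: bounds = default
grid box widened 20%; 64 uniform probe candidates ranked by residual; 5
local starts (best probe, bounds center, 3 perturbations, perturbation SD
15% of the box); finite-difference Jacobians with `x_scale` set to the box
widths; tolerances 10⁻¹⁰; 400 function evaluations per start.  Voxels with
relative residual above 0.5 (near-zero signal, CSF-like) are flagged
`converged=False` rather than raising.  Per-voxel seeds derive from the
master seed and the voxel's linear index through `SeedSequence`, so any
traversal or parallelization order yields identical maps.

Noiseless recovery is exact to optimizer precision (<10⁻⁵ relative; tested
bound 0.5%).  Under noise, errors concentrate in the weakly encoded
`R1f/Rx/R1s` directions — with the stand-in 64-repetition schedule, median
errors of several percent for those parameters persist even at
per-coefficient SNR in the thousands.  This is a property of the schedule's
encoding, not of the estimator, and is why the end-to-end phantom check
asserts tight recovery only for `m0s`, `R2f`, `T2s`.

## Apparent parameters

The closed forms are evaluated exactly as written, element-wise over maps.
Note the deliberate preservation of the `R1s = R1f` limit
`Rx,a = Rx + R1f` (an `R1f` offset on the exchange rate); no sign or offset
"fixes" are applied even where limits look surprising.

## Synthetic cohort

The generator emulates the study design the statistics target: 6 vs 9
subjects, two hemisphere values each with intra-subject correlation ρ
(default 0.7), per-ROI means scattered around the hemisphere-lobe value
(scatter 10% of σ) with χ²-distributed sample variances (200 samples/ROI),
and group effects programmed as target Hedge's g via a mean shift `g·σ` on
the positive group.  Default programmed effects: SUVR g = +2.5 in all
lobes; Rx g = −0.86 (temporal); R1s g = −0.78/−0.81/−0.94
(frontal/parietal/temporal); m0s and thickness null.  Control means and SDs
(e.g. m0s 0.10 ± 0.012, Rx 55 ± 7 /s, SUVR 1.00 ± 0.06) are
literature-plausible placeholders — no group means or SDs are externally
available to anchor them.  A t(5) subject-effect option exists for
robustness checks.

Effects are programmed on the four primary (disjoint) lobes; the
AD-signature composite inherits its effect from member ROIs, and the ground
truth reports the implied composite g
(`Σ f_L g_L / √(Σ f_L²)` over member fractions `f_L`), which neglects ROI
scatter and inverse-variance weight jitter — empirically a ~1%
attenuation.

**What passing tests show and don't.** Calibration and recovery tests
establish that the statistics engine is correct on data matching its
assumptions (independent subjects, Gaussian lobe values, exchangeable
observations).  They do not establish robustness to real-data features the
generator omits: spatially correlated artifacts, partial-volume effects,
non-Gaussian tails, or hemisphere asymmetries.  In particular, pooling left
and right hemispheres as separate observations is pseudo-replication: with
ρ = 0.7 the measured null type-I error is ~13% at nominal 5%.  The
calibration test therefore uses ρ = 0 (exchangeable pooling); the pooled
convention is retained as the default because it mirrors the lobar-scatter
analysis convention, and a `hemisphere_mode="averaged"` option provides the
conservative alternative.

## Statistics

Two-sided tests throughout.  The exact Mann–Whitney mode enumerates all
`C(n₁+n₂, n₁)` labelings (ties via the ½ convention; feasible to n₁+n₂ ≤ 14,
auto-selected at ≤ 12); the normal mode is scipy's tie-corrected Gaussian
approximation.  At the study's 12 vs 18 pooled observations the discrete
attainable level just below 0.05 is ≈ 0.0476 for exact and asymptotic
variants alike.  Hedge's g uses the common small-sample factor
`J = 1 − 3/(4N − 9)` rather than the exact gamma-function factor
(difference < 10⁻³ at these sizes).  Inverse-variance weighting uses the
variance of the ROI mean (`w = n/s²`) by default; plain `1/s²` is a config
switch since the convention is ambiguous in the field.  Zero variances get
a capped weight (10¹²) with a warning.  Bonferroni families: 5 lobar
(four lobes + AD signature), 7 subcortical (six structures + global white
matter), with three-decimal reporting for the latter (0.007).

## Problem sizes

Defaults used by the test suite and acceptance script: 64–100-repetition
schedules, 3⁶–5⁶-atom dictionaries, 8³ phantoms, 400–2000 cohort
replicates, 50-replicate Monte-Carlo noise studies.  These sizes were
chosen to exercise every code path at full fidelity while keeping the
default runs desk-scale; all are parameters, not limits.

## Known limitations

- Arbitrary pulse shapes, off-resonance CW saturation experiments, k-space
  reconstruction, and B0/B1 estimation are out of scope; B0/B1 enter only
  as known per-voxel inputs (`omega_z`, `b1_scale`).
- The linearization convention (end-of-pulse `z^s` match) is one of several
  defensible choices; see above.
- The apparent-parameter limit behavior is preserved as written.
- No covariate adjustment or mixed-effects modeling of hemisphere nesting;
  Bonferroni is the only multiplicity control.
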