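# hybridqmt

Unconstrained 2-pool quantitative magnetization transfer (qMT) analysis:
hybrid-state signal simulation, voxel-wise parameter estimation, and
amyloid-cohort statistics, with a synthetic-data generator that makes the
whole pipeline testable without any acquired data.

## The scientific problem

Magnetization transfer MRI sensitizes the signal to "semisolid" protons
bound in macromolecules — myelin lipids, protein aggregates, and notably
amyloid-β plaques.  Quantitative MT disentangles the biophysical
contributions by fitting a two-pool model: a free water pool (fractional
size `m0f`, relaxation rates `R1f`, `R2f`) exchanging at rate `Rx` with a
semisolid pool (`m0s = 1 − m0f`, `R1s`, transverse decay time `T2s ≈ 10 µs`).
Most of the literature fixes `R1s` because it is hard to encode; this
package implements the *unconstrained* six-parameter model
(`m0s, R1f, R2f, Rx, R1s, T2s`), in which `R1s` itself becomes an
estimable — and, in preclinical Alzheimer's disease, informative —
biomarker.

The package targets researchers who want to (a) simulate hybrid-state qMT
signals from first principles, (b) estimate parameter maps from
subspace-compressed acquisitions, and (c) run the ROI-level group/correlation
statistics used in small amyloid-PET-characterized cohorts.

## The model

Spin dynamics follow the 2-pool Bloch–McConnell equations for the state
`(x^f, y^f, z^f, x^s, z^s, 1)`:

```
∂t s = A(θ; ωy, ωz) s,          θ = (m0s, R1f, R2f, Rx, R1s, T2s)
```

with exchange terms `Rx·m0s`, `Rx·m0f` coupling the longitudinal
components and recovery terms `m0f·R1f`, `m0s·R1s` in the augmented column.
The semisolid pool's non-exponential decay (super-Lorentzian lineshape,

```
G(t) = ∫₀^{π/2} sinθ · exp(−(t²/(8 T2s²)) (3cos²θ − 1)²) dθ
```

) enters through the generalized Bloch model, linearized per RF pulse: the
effective rate `R2s,l(T2s, α, T_RF)` is root-found so an exponential pool
ends the pulse with the same `z^s` as the integro-differential solution
`ż^s(t) = −ωy² ∫₀ᵗ G(t−τ) z^s(τ) dτ`.

An inversion-prepared hybrid-state schedule (smoothly varying flip angle
and pulse duration, balanced per TR) is simulated by piecewise-constant
matrix exponentials from the cyclic steady state; the per-repetition echo
signals form a *fingerprint*.  A dictionary of fingerprints over a
parameter grid yields a rank-15 SVD subspace; voxels are stored as
coefficient vectors `c = Uᴴ s`.  Estimation minimizes
`‖y − c·M(θ)‖²` by bounded trust-region least squares with the complex
amplitude projected out in closed form.

Constrained-model *apparent* parameters are evaluated in closed form:

```
m0s,a = m0s (1 − 2 m0f (R1s − R1f)/Rx)
Rx,a  = (Rx + R1f) + m0f (R1s − R1f) + m0f m0s (R1s − R1f)²/Rx
R1f,a = R1f + m0s (R1s − R1f) − m0f m0s (R1s − R1f)²/Rx
```

Statistics: ROI summaries are combined into lobar values by inverse-variance
weighting (`wᵢ = nᵢ/sᵢ²`); groups are compared with the two-sided
Mann–Whitney U test (exact enumeration for small samples) and Hedge's g
(`J = 1 − 3/(4N − 9)`; |g| bands 0.5/0.8/1.2 = medium/large/very large);
Bonferroni families of 5 (lobar) and 7 (subcortical + global WM) control
the family-wise error; associations with amyloid burden (PET SUVR) use
Pearson's r.

## Worked example

`examples/06_cohort_statistics.py` generates a synthetic cohort (6
amyloid-negative vs 9 amyloid-positive subjects, two hemispheres each) with
the default programmed effects and runs the full statistical pipeline:

```
measure         lobe  p_value  hedges_g   category significant significant_bonferroni
    R1s      frontal 0.018799 -0.959944      large           *
    R1s     temporal 0.014926 -0.982323      large           *
     Rx     temporal 0.000090 -2.004015 very_large           *                     **
   SUVR     temporal 0.000008  3.247564 very_large           *                     **
   ...
```

Reading it: amyloid burden (SUVR) is strongly elevated in the positive
group in every lobe; the exchange rate `Rx` and semisolid `R1s` are
significantly reduced in the programmed lobes (negative g = lower in the
amyloid-positive group); `*` marks p < 0.05 and `**` the Bonferroni level
0.05/5 = 0.01.  At n = 6 vs 9 a single draw scatters around the programmed
effect sizes — averaging recovered g over many seeded cohorts converges to
the programmed values (see the test suite).

The other examples demonstrate the decay kernel and linearized rate
(`01`), fingerprint simulation (`02`), subspace compression (`03`),
phantom fitting (`04`), and apparent parameters (`05`); each prints the
numbers it computes with a line of interpretation.

A thin CLI mirrors the library for shell pipelines:
`hybridqmt simulate-dictionary | make-basis | simulate-phantom | fit |
apparent | simulate-cohort | analyze-groups | analyze-correlations |
report` (see `--help` on each).

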