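# Methods

## The model

`chinpaint` restores damaged binary images by evolving a modified
Cahn–Hilliard equation. The image is encoded as a phase field φ on a grid
of finite-volume cells (one cell per pixel), with φ = −1 for background,
φ = +1 for ink, via the fixed affine map φ = 2·(I/255) − 1 of 8-bit
intensities. The evolution is

    ∂φ/∂t = −∇²(ε²∇²φ − H′(φ)) + λ(x)·(φ⁰ − φ),

with the Ginzburg–Landau double well H(φ) = (φ²−1)²/4, no-flux boundary
conditions for both φ and the free-energy variation
ξ = H′(φ) − ε²∇²φ, and a fidelity field λ that is 0 on the damaged
(inpainting) domain D and λ₀ elsewhere. Outside D the penalty pins the
solution to the damaged input φ⁰; inside D the fourth-order
Cahn–Hilliard dynamics interpolates edges across the damage while the
double well pushes cell values back to the two pure colours. Damage is
non-blind: D is an explicit input (a boolean mask), never inferred.

The driving functional is the discrete Ginzburg–Landau free energy

    E[φ] = ΔxΔy·Σ H(φ) + (ε²/2)·ΔxΔy·Σ_faces (Δ_face φ)²,

with the gradient term accumulated over interior faces by forward
differences — the same stencil as the discrete Laplacian, which is what
makes the decay argument below exact. With λ₀ = 0 the scheme is a discrete
H⁻¹ gradient flow of E; with the fidelity term it is not a gradient flow,
but retains its robustness in practice (the energy-decay property is
asserted by tests only for λ₀ = 0).

## The discretization

One implicit time step solves the cell balance

    (φⁿ⁺¹ − φⁿ)/Δt = −div F(ξⁿ⁺¹) + λ·(φ⁰ − φⁿ⁺¹),

where face fluxes are upwinded face velocities v = −Δξ/Δx (with unit
mobility the upwind decomposition (v)⁺ + (v)⁻ is identically v, so the
divergence collapses to the five-point Laplacian of ξ; the decomposition
is kept in the code so degenerate mobilities can be added later), and ξ is
assembled semi-implicitly by convex splitting:

    ξⁿ⁺¹ = H_c′(φⁿ⁺¹) − H_e′(φⁿ) − (ε²/2)·(Δφⁿ + Δφⁿ⁺¹),

with H_c = (φ⁴+1)/4 implicit and H_e = φ²/2 explicit. The convex/concave
split plus the averaged Laplacian give unconditional decay of the discrete
free energy for λ₀ = 0: the averaged Laplacian is the exact discrete
variational derivative of the quadratic gradient term, and the split signs
control the double-well terms. Mass ΣφΔxΔy is conserved exactly by the
conservative flux form with zero boundary fluxes (reflecting ghost cells,
ghost = adjacent interior value). The tests exercise both properties over
random fields at Δt up to 100× the production step.

Two sign conventions for ξ circulate (ξ = H′ − ε²Δφ and its negative);
this package uses ξ = H′ − ε²Δφ together with v = −∇ξ, so that the pair
is consistent with the continuum equation above.

### Fidelity term: implicit, not explicit

The fidelity term is discretized implicitly, λ·(φ⁰ − φⁿ⁺¹), adding only a
diagonal to the Jacobian. The explicit alternative λ·(φ⁰ − φⁿ) is a
forward Euler step of the stiff relaxation φ̇ = −λ(φ − φ⁰) with
amplification factor 1 − λ₀Δt; at the production settings λ₀ = 1000,
Δt = 0.1 that factor is −99 and the iteration diverges within two steps
(deviations outside the damage grow ~100× per step). The explicit form is
kept behind `SolverConfig(implicit_fidelity=False)` (CLI
`--fidelity explicit`) for small λ₀Δt, and the solver logs a warning when
λ₀ leaves the well-tested range [1, 1000].

### Nonlinear solve

Each step is solved by Newton's method on the full residual with an
analytically assembled sparse Jacobian

    J = I/Δt − L·diag(3φ²) + (ε²/2)·L² [+ diag(λ)],

where L is the no-flux five-point Laplacian (L² gives the 13-point
biharmonic coupling). Convergence is declared at max-norm residual
≤ 1e−8. The LU factorization of J is cached and reused across Newton
iterations and across time steps (the state changes little near steady
state); whenever the residual contraction per iteration is worse than 0.5
the Jacobian is refactored at the current iterate, so the method is exact
Newton with a fresh factorization and a cheap quasi-Newton otherwise. A
damped line search (step halving, up to 8 times) guards against
overshoot far from the solution. A step whose solve fails outright is
retried once at Δt/2; a second failure propagates as `StepFailure`.

### Dimensional splitting

`scheme="split"` replaces the coupled 2-D solve by one implicit 1-D solve
per row (in index order, each row seeing the latest values of its
neighbours), then one per column. Within a line solve only the along-line
coupling is implicit; the transverse part of the Laplacian is held
explicit at the latest available values, keeping each Jacobian N×N as the
cost argument requires. The update of each line keeps the conservative
flux form along the line, so mass conservation is exact for the split
scheme too. Non-adjacent lines are independent, so odd/even batches could
be processed in parallel without changing the result; the reference
implementation is single-threaded with identical update semantics. The
splitting error at a fixed final time is first order in Δt: the measured
gap to the full 2-D solution halves (ratio 0.50 ± 0.01 in the shipped
test) when Δt is halved. The fidelity relaxation appears in both sweeps,
as the sweep equations prescribe; with the implicit discretization this
only tightens the pinning and is harmless. The sweep updates are applied
over a full Δt with the Δt·λ scaling of the unsplit equation — a sweep
update without the Δt factor on the fidelity term would not be
dimensionally consistent with the time-continuous model.

## The two-step method

Production inpainting runs the steady-state driver twice: stage 1 with a
large interface width ε₁ = 1.5 performs the large-scale topological
reconnection (edges diffuse across the damage and join); stage 2 restarts
from the stage-1 state with ε₂ = 0.5 to sharpen the interfaces. Both
stages share λ₀ and are anchored to the original damaged image. Each
stage iterates until the cell-area-weighted L¹ change between successive
states falls below 1e−4 (or `max_steps` = 4000 is reached, in which case
the result is flagged, not raised — partially converged restorations are
still useful downstream and the benchmark treats them as such).

Calibrated parameters (28×28 digit images, Δx = Δy = 1, Δt = 0.1):
ε₁ = 1.5, ε₂ = 0.5 for all damage types; λ₀ = 1000 for line and row
damage, λ₀ = 9000 for scattered pixel damage. On the 50×50 cross-line
calibration image the steady state's L¹ distance from the damaged input
decreases monotonically in λ₀ over {1, 10, 100, 1000}, and so does the
step count to convergence — stronger pinning converges faster and changes
less.

## Damage model and fixtures

All simulators overwrite cells with mid-grey intensity 128 (phase
≈ 0.004, the neutral state between the wells); the printed benchmark
never fixes the grey value and 128 is the midpoint choice. Customized
damages A–D (thin/double vertical lines, thick/thin horizontal bands) use
parameterized default geometries that scale proportionally with image
size; their exact extents are approximations read off the benchmark's
illustrations, and nothing downstream depends on the precise geometry.
Random row/pixel damage samples uniformly without replacement with a
seeded generator; per-image seeds in the benchmark derive from a master
seed plus the (setting, image) indices, so batches are reproducible and
damage is i.i.d. across images.

The glyph fixture renders digits 0–9 from a built-in 5×7 dot-matrix font
at 3× scale onto 28×28 canvases with seeded ±2-pixel translations and
random 1-pixel dilation. It is a synthetic stand-in for handwritten-digit
data that makes every end-to-end test self-contained. It reproduces the
format (binary 28×28, balanced labels 0–9) but not the intra-class
variability of handwriting: the classification task is nearly separable,
accuracies are higher and improvement percentages smaller than on real
handwritten data, so end-to-end tests assert directions and orderings,
never the published accuracy values. Scale is also reduced (40 test
images per setting rather than 10 000), chosen to keep a full benchmark
run in minutes on one CPU; the directional conclusions are stable at this
size for the moderate-damage settings the tests pin.

## Classifier

A deliberately plain dense network — flatten(784) → 64 ReLU → 64 ReLU →
10 softmax — implemented directly in numpy with analytic backprop:
the benchmark measures the filter's effect on prediction, not
state-of-the-art accuracy, and a frozen, fully deterministic model makes
the with/without comparison exact. Loss is categorical cross-entropy
−Σ_k y_k log ŷ_k with probabilities floored at 1e−12; the softmax is
computed shift-invariantly. Training uses Adam (lr 1e−3, β₁ 0.9,
β₂ 0.999, ε 1e−8), batch size 32, 10 epochs, Glorot-uniform
initialization, all driven by seeded generators. Inpainted images are
classified as continuous intensities without binarization — residual grey
pixels from partially converged runs are part of what the filter hands
downstream.

The improvement metric is the relative accuracy gain
100·(acc_with − acc_without)/acc_without, rounded to the nearest integer
percent with halves away from zero (the published tables require
17.5 → 18, so bankers' rounding is not used; the ratio is snapped at nine
decimals first to undo binary round-off). It is undefined at
acc_without = 0; the metric raises and the benchmark records the cell as
missing.

## Numerical choices and degenerate inputs

- Phase values are not clamped during evolution (boundedness is only
  guaranteed for degenerate mobilities, which are out of scope); clipping
  to [−1, 1] happens at image export only.
- Uniform fields at −1, 0, +1 are exact fixed points of both schemes and
  are tested as such; an all-grey, all-damaged image therefore stays
  uniform.
- 1×N and N×1 grids are supported (the transverse stencil contribution
  vanishes); the split scheme degenerates to the 1-D solve and matches
  the full scheme there.
- Identical inputs and configuration produce bit-identical outputs: there
  is no hidden randomness anywhere in the solver.

## Known limitations

- Binary images only: one double well, two colours. Grey-value or colour
  inpainting needs a different potential and is out of scope.
- The benchmark's published MNIST accuracies are not recomputed by the
  test suite (they require the external dataset and a full-scale run);
  the optional full-scale path is implemented and runs when IDX files
  are supplied under `data/mnist/`.
- Energy decay is guaranteed (and tested) only without the fidelity term;
  with fidelity the dynamics is not a gradient flow.
- The adaptive response to solver failure is a single Δt/2 retry, not a
  full adaptive time stepper.
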