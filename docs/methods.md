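# Methods

## Problem setting and assumptions

`rayshell` reconstructs one closed boundary per slice of a 3D grayscale
stack and assembles them into a surface. It relies on three assumptions:

1. the boundary within a slice is smooth — the offset function r(s) along
   the boundary changes slowly with s;
2. the boundary changes little between adjacent slices, so each slice's
   result is a good initialization for the next;
3. the interior is generally brighter than the exterior, so the outward
   intensity difference at the true boundary is negative.

Nothing is assumed about the *absolute* intensity level at the boundary:
all gradient evidence is computed and normalized per ray, which is what
distinguishes the approach from threshold/level-set formulations and makes
it robust to strong low-frequency intensity inhomogeneity along the shell.

## The resampling chain

For a boundary discretized into N points (equal arc-length resampling,
first vertex preserved), the exterior normal at point i is the outward
perpendicular of the chord from point i−1 to point i+1. Along each normal
the image is sampled at integer offsets m ∈ [−M, M] (negative = interior).
A sample's value is the mean over the 5×5 pixel window centered on the
pixel containing the sample position; windows are clipped at image borders
and the mean is taken over in-image pixels only. Pixel centers sit at
integer coordinates and "containing pixel" means nearest-integer rounding
with ties toward +∞, so sampling is reproducible bit for bit.

Each raw profile v(m) is conditioned in three stages:

* **Clamp.** L1 = mean of v over m = 1…M (exterior), L2 = mean over
  m = −M…−1 (interior); every sample, including m = 0, is clipped to
  [min(L1,L2), max(L1,L2)]. This suppresses extreme values (e.g. bright
  interference just outside the boundary) before any differencing. The
  bounds are per ray: a pooled, image-wide bound would reintroduce exactly
  the inhomogeneity sensitivity the method is designed to avoid.
* **Smooth.** Ten passes of the 3-point moving average, endpoints by edge
  replication (replication preserves constant profiles; the alternative,
  shrinking the profile per pass, would change the offset grid).
* **Valid gradient.** g(m+½) = max(0, v(m) − v(m+1)): positive only where
  intensity drops outward. Gradient samples live on the half-integer
  midpoint grid.

## The solver

The discrete objective per slice is

    E(r) = Σᵢ (r_{i+1} − r_i)²/2 − Σᵢ (βᵢ/α) E_ext(gᵢ, rᵢ; σ),
    E_ext(g, r; σ) = Σₘ g(pₘ) exp(−(pₘ − r)²/(2σ²)),

with the arc-length metric Δs/α fixed to one and
βᵢ = β₀ / (ε + maxₘ gᵢ), ε = 10⁻⁶. The normalization by the per-ray
gradient maximum makes the external pull comparable across rays with very
different boundary contrast.

One iteration updates all offsets simultaneously via the semi-implicit step

    (1 + 2Δt) rᵢᵏ⁺¹ − Δt (rᵢ₊₁ᵏ⁺¹ + rᵢ₋₁ᵏ⁺¹) = rᵢᵏ + Δt (βᵢ/α) Fᵢ(rᵏ),

where F = dE_ext/dr. The cyclic tridiagonal system is circulant and is
solved exactly with the real FFT. The implicit treatment of the smoothness
term is unconditionally stable, which matters because the explicit update
is unstable at the default Δt = 1; both schemes share the same fixed
points. Offsets are clipped to [−M+1, M−1] each iteration so the external
force never needs gradient values outside the sampled range — this is also
what confines each element to its predetermined ray segment and lets the
smoothness force bridge exterior interference.

At the final kernel width σ = 0.5 px the external force's capture radius is
sub-pixel, so σ is annealed over the schedule (3.0, 1.5, 0.5): each stage
runs to convergence (max |Δr| < 10⁻³ px, at most 500 iterations) and
warm-starts the next. A single-stage schedule `(0.5,)` is available for
strict fixed-width runs. The iteration is a descent scheme for E; the test
suite verifies E is non-increasing across iterations at every stage
(tolerance 10⁻⁹) on randomized phantoms.

Near convergence the offsets can enter a period-2 oscillation of amplitude
just above the tolerance (the gradient evidence lives on a 1-px midpoint
grid, so the energy surface has faint pixel-scale ripples). A stage that
hits the iteration cap this way is reported with `converged=False` and a
warning, not an error; the boundary error involved is far below the
evaluation resolution.

## Parameters

| name | default | units | role |
| --- | --- | --- | --- |
| α | 0.8 | — | smoothness weight |
| β₀ | 0.2 | — | external weight base (per-ray β = β₀/(ε + max g)) |
| σ | 0.5 | px | final kernel width |
| schedule | 3.0, 1.5, 0.5 | px | σ annealing stages |
| Δt | 1.0 | — | time step (Δs/α ≡ 1) |
| N | 540 | points | boundary discretization (robust over 360–720) |
| M | 30 | px | ray half-width; must cover the inter-slice drift |
| passes | 10 | — | 3-point smoothing repetitions |
| tol | 10⁻³ | px | convergence threshold on max |Δr| |

M should be large enough that the true boundary lies inside every ray
(|true offset| < M) yet small enough that rays do not cross distant
structure; 30 px covers inter-slice drifts up to ~25 px.

## The synthetic phantom

The generator renders star-convex truth shapes
ρ(θ) = R·(1 + Σⱼ aⱼ cos(jθ + φⱼ)), scaled per slice by a geometric drift
z_drift^z, onto the pixel grid (pixel center in polygon, even-odd rule).
Interior pixels get intensity_in modulated by a low-frequency multiplicative
field 1 + A·sin(θ + 0.25·z); exterior pixels get intensity_out; optional
bright discs are placed just outside the boundary (inner edge at a stated
radial offset, diameter matched to a stated arc span); zero-mean Gaussian
noise is added and values are clipped at 0. All randomness comes from one
seeded generator, so stacks are bit-reproducible.

The standard phantom used by the evaluation scripts is 220×220×20, R = 60,
harmonics (3, 0.12, 0) and (5, 0.05, 1.0), z_drift 1.003, intensities
120/20, 30 % inhomogeneity, one blob (θ = π/4, 20° arc, 5 px outside,
intensity 110, slices 8–12), noise sd 6.

The phantom emulates the geometry and intensity statistics the method is
sensitive to — non-convexity, slow z-drift, boundary-contrast inhomogeneity,
exterior interference, additive noise — but not realistic tissue texture,
vasculature, point-spread blur, or montaging artifacts. Passing tests on the
phantom therefore demonstrate the solver's behavior under the model's own
assumptions, not performance on any particular microscope's data.

## Numerical choices and degenerate inputs

* Boundaries are canonicalized to counter-clockwise orientation (positive
  shoelace area with x = column, y = row); self-intersecting polygons are
  rejected at construction.
* Equal-arc resampling with the requested count equal to the current count
  and spacing already uniform (≤ 10⁻⁶ relative) returns the input
  unchanged, making resampling idempotent and the uniform-image case an
  exact fixed point of slice reconstruction.
* A displaced boundary that self-intersects is re-resampled once; if still
  not simple, the slice is flagged as failed and the previous boundary is
  reused, so a single bad slice cannot terminate a long propagation run.
* Rasterization for evaluation counts pixels whose centers lie inside the
  polygon; recall/precision are undefined (an error) for zero-area regions.
* All image intensities are promoted to float64 on read; integer inputs are
  widened losslessly.

## Known limitations

* Single connected domain only: no contour splitting or merging.
* When the initial boundary sits several pixels off the true edge, the
  per-ray clamp reshapes the intensity descent and biases the localized
  edge outward by up to ~0.5 px on an ideal step (the bias shrinks as the
  initialization approaches the truth, the propagation regime). At default
  parameters the standard disc test localizes within 0.45 px RMS.
* Rays are strictly in-plane; there is no 3D coupling in the solver beyond
  the slice-to-slice initialization.
* The evaluation stack sizes used throughout (220×220×20 phantom, N up to
  720) are desk-scale choices; the method itself is local per ray and
  scales linearly in N·M per slice.
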