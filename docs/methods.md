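# Methods

`colonytrack` quantifies the spatio-temporal development of stem-cell
colonies in phase-contrast time-lapse sequences. Colonies — in particular
the compact, spherical ones formed under 2i culture — cannot be resolved
into single cells, so the package works at the level of whole colony
regions and of dense pixel-wise motion between consecutive frames. This
note records the models, the numerical choices, and the limits of what the
synthetic validation shows.

## Fluid-like registration

Given a source frame S and the next (template) frame T, both with gray
values in [0, 1], the registration seeks a dense displacement field u that
minimizes the matching energy

    E(u) = 1/2 Σ_x (S(x − u(x)) − T(x))²  +  α/2 Σ_x Σ_l (Δ v_l)²,

where the curvature penalty acts on the *velocity* field v = du/dt rather
than on u itself. Regularizing the velocity yields a fluid rather than an
elastic model: the material can keep flowing, so large inter-frame
deformations (colony growth, internal swirling, partial fusion) can be
absorbed without the displacement itself being penalized. In the
over-damped limit with damping γ the flow reduces to

    (γ + η Δ²) v = f(x, u),    f(x, u) = (S(x − u) − T) ∇S|_{x−u},

integrated in pseudo-time until the relative SSD decrease per accepted
step falls below a threshold. `f` is the negative variational gradient of
the matching term under the Eulerian `S(x − u)` sampling convention, so
the flow descends the SSD by construction; a pseudo-time step is only
accepted when the embedded Runge–Kutta error estimate passes *and* the SSD
does not increase.

Numerical choices:

- **Spectral biharmonic solve.** The 5-point Neumann Laplacian is
  diagonal in the type-II cosine basis, so (γ + η Δ²)⁻¹ is a pointwise
  division between one forward and one inverse DCT per field component.
  Neumann (reflective) boundaries fit microscopy frames, which are not
  periodic.
- **Time integration.** Embedded Cash–Karp 4(5) pair, relative tolerance
  `rk_rel_tol` (default 1e-3), step rejection on error excess and on SSD
  increase. The initial step is scaled so the first displacement increment
  is about 0.5 px — the damped velocity sets the natural time unit, and a
  fixed initial step would either stall or overshoot depending on image
  contrast.
- **Warping and gradients.** Bilinear sampling at x − u(x) with edge
  clamping; ∇S at the pulled-back point is computed as the central-
  difference gradient of the warped source (one-sided at borders).
- **Regularization weight.** Default α = η = 10, γ = 0.1. The weight was
  chosen on synthetic recovery problems: for smooth colony-scale motion
  (≤ 8 px/frame) a stiff regularizer recovers the true field about three
  times more accurately than α = 1 (mean endpoint error 0.32 px vs
  1.0 px on the 10-pair suite) at essentially the same SSD reduction,
  because the SSD term alone leaves the field unconstrained wherever the
  texture gradient is weak. For data with genuinely rough motion fields
  a smaller α is appropriate; it is a plain parameter.
- **Pre-smoothing.** Inputs are Gaussian-smoothed (σ = 1 px) before
  registration; SSD forces on raw phase contrast are noise-dominated.
  With smoothing enabled the descent guarantee applies to the smoothed
  objective, not bit-exactly to the raw SSD. σ = 0 disables it.
- **No regridding.** The Jacobian det ∇(x − u) is monitored and a warning
  logged below 0.1, but the field is never regridded. Near colony fusions
  the background noise can drive locally folding fields; the tracker is
  robust to this because label propagation only needs pixel-level overlap,
  not diffeomorphic warps.
- **Aperture limit.** On textureless radially-symmetric objects only the
  gradient-parallel component of motion is observable; recovery accuracy
  is therefore always quoted on textured support.

An optional `advection` flag switches the update to the classical fluid
transport du/dt = v − (∇u)v; the default is the plain Eulerian update
du/dt = v, which is the form the over-damped variational derivation
regularizes directly.

## Segmentation

Phase-contrast imaging produces bright halos and slow illumination drift.
The detection chain is: single-scale retinex (log image minus log of a
σ = 30 px Gaussian illumination estimate, rescaled to [0, 1]; a constant
image maps to 0.5) → Rudin–Osher–Fatemi total-variation denoising
(Chambolle projection, weight 0.1) → two-phase piecewise-constant active
contour (morphological Chan–Vese implementation, 200 iterations,
smoothing 2, checkerboard initialization; the brighter phase is
foreground, a constant image yields an empty mask) → morphological hole
filling → 8-connected labeling, discarding objects under `min_object_px`
(default 30 px, roughly the area of a few cells at 10×). Labels are
assigned 1..K in raster-scan order of each component's first pixel, which
makes segmentation bit-deterministic.

During tracking, the re-segmentation of each new frame is initialized
with the propagated mask instead of the checkerboard, but runs *without*
morphological smoothing: the TV step already regularizes the data term,
and the smoothing operator welds shut exactly the narrow gaps that signal
a genuine colony split when the initialization happens to cover them. A
4-connected binary opening afterwards removes single-pixel strands, which
are fixed points of the unsmoothed discrete evolution.

## Tracking

The tracker iterates per frame pair: register → propagate the label mask
through the displacement field (nearest-neighbour sampling, so no
interpolated label values) → re-segment → reconcile. Reconciliation
compares propagated labels with segmented objects through a pixel-overlap
table (correspondences under `min_overlap_px` = 10 px are ignored — they
are warping slivers, not evidence) and resolves four cases:

- **one-to-one** — segmented shape, propagated label (`continue` edge);
- **merge** — one segmented blob over ≥ 2 propagated labels: the
  propagated masks are kept and partition the blob (unclaimed pixels go
  to the nearest propagated label, ties to the smaller id), so fused
  colonies keep their identities;
- **split** — one propagated label over ≥ 2 segmented objects: the
  segmented shapes are kept and *every* sub-object receives a fresh
  label, recording clonal inheritance;
- **new** — a segmented object with no propagated counterpart gets a
  fresh label (`appear`); propagated labels with no counterpart vanish.

Merges are resolved before splits when an object participates in both. A
fusion is only reported as a `merge` event the first time a label group
shares one blob; afterwards the co-resident labels `continue`. Labels come
from a strictly increasing counter and are never reused.

Backward mode reverses the sequence before processing, because a
forward-time fusion becomes a split in reverse and the split case takes
its masks from the segmentation — which delineates separated objects far
better than warped masks delineate fused ones. Output masks are
re-indexed to original frame order, graph edges keep processing order
(recorded in the graph's `direction` attribute), and a processing-order
split is reported as a forward-time merge and vice versa. A registration
failure on one pair logs a warning and substitutes the identity field so
the rest of the sequence still gets processed.

## Colony statistics

Per frame: the covered-area fraction (nonzero mask pixels over frame
pixels). Per colony j with pixel set χ_j:

- **area** a in pixels;
- **elongation** ξ = 1 − minor/major axis of the moment-matched ellipse
  (second-order central moments, axes 4·√eigenvalue, plus the 1/12
  single-pixel variance so 1-px-wide shapes stay finite); 0 for a disc,
  → 1 for a line. The ratio is oriented so that larger means more
  elongated;
- **circularity** γ = 4πa/p², with the perimeter p from the 4-direction
  Crofton estimator — naive boundary-pixel counting biases a disc's
  circularity to ~0.8, while the Crofton estimate gives 0.99 for a
  radius-50 disc. Discretization overshoot is capped at 1.1;
- **gray-level entropy** H_j = −Σ_i p(g_i) ln p(g_i) in nats over the
  raw frame values inside χ_j, quantized to `n_levels` = 256 uniform bins
  on [0, 1] (the native 8-bit resolution); 0·ln 0 ≡ 0;
- **mean and population standard deviation** of ‖u(x)‖ over χ_j, from
  the field of the pair (t, t+1), attached to frame t; the terminal
  frame's motion features are NaN (missing, not zero).

Per-frame summaries use the median and 0.25/0.75 quantiles (linear
interpolation) over colonies. Condition comparisons pool per-colony
values over time and apply the two-sided Wilcoxon rank-sum test — exact
enumeration for tie-free pools of at most 20, otherwise the tie-corrected
normal approximation.

## Stream visualization

Each colony is a vertical stream flowing downward in time. At each frame
the stream width is the chosen feature divided by the frame pixel count,
so with the default area feature the widths at a frame sum exactly to that
frame's covered-area fraction (1 = confluent); a fixed 1 %-of-plot-width
gap separates adjacent streams and sits outside that budget. The color
encodes a second feature (default circularity) min–max normalized over
the whole sequence on a blue-to-red map — red round, blue irregular.
Ordering: the first frame sorts by centroid column; later frames inherit
the order, split children take the parent's slot, merge partners stay
adjacent so their bands converge, new colonies append on the right.
Boundaries between frames are interpolated with a monotone cubic (PCHIP),
chosen for smoothness without overshoot and pinned for determinism.
Rendering fixes the SVG hash salt and strips timestamps, so identical
inputs give identical bytes.

## Synthetic fixtures

The generator emulates what the pipeline needs from phase-contrast colony
data: roughly circular colonies with band-limited interior texture
(interior mean 0.6 on background 0.2, giving the ≥ 0.3 contrast the
segmentation suite assumes), optional bright halo rings, Gaussian pixel
noise (default σ = 0.03), smooth inter-frame motion composed of rigid
translation plus isotropic growth, and scripted splits; merges arise from
colonies drifting into contact. Ground truth — exact rasterized masks,
closed-form displacement fields, an event log derived from mask
connectivity — is recorded alongside. Scripted merges are made decisive
(the gap between discs goes from +6 px to −4 px across the event frame),
because a grazing contact leaves the true fusion frame ambiguous at
rasterization scale. Restricting motion to translation + growth keeps the
truth masks analytic; rotation and swirl fields exist for registration
tests only.

What passing these fixtures does *not* show: robustness to real
phase-contrast optics (the halo model is a cosmetic ring, not a physical
point-spread function), to stage drift, focus drift or illumination
flicker, to colonies whose appearance changes faster than the frame rate,
or to textures that decorrelate between frames. The fixtures validate
the algorithmic contracts, not the biology.

## Problem sizes and defaults used in validation

The validation suite registers 10 textured 128×128 pairs with fields of
3–5 px, tracks five scripted 8-frame 160×160 scenarios in both
directions (registration budget 40 steps, contour budget 100 iterations
per frame — propagation needs pixel-level accuracy, not full
convergence), and runs the end-to-end pipeline twice on a 4-frame
128×128 sequence to confirm bit-identical artifacts. The velocity solver
is checked against its closed form on single cosine eigenmodes (exact to
~1e-14) and the rank-sum test against full enumeration for all pool
sizes up to 8.

## Known limitations

- Single-resolution registration: displacements well beyond ~8 px/frame
  need either more pseudo-time or a pyramid, which is deliberately out of
  scope.
- The merge case inherits warped masks, so colony boundaries inside
  long-fused clusters degrade over time — the reason backward processing
  is the default.
- The two-phase segmentation assumes colonies brighter than background
  after retinex; dark objects on bright background would need the
  opposite phase orientation.
- Event detection is overlap-based with a fixed pixel threshold; very
  small colonies (area near `min_overlap_px`) can drop out of lineages.
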