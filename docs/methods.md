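# Methods

## The measurement

Slippage quantifies membrane–cytoskeleton coupling during apical
constriction as the difference between two velocities measured along the
same centripetal vector ("Spyderleg"):

- `v_myo` — the mean centripetal component (µm/min, positive toward the
  cell center) of dense optical-flow vectors inside a window at the outer
  end of the vector, after filtering;
- `v_mem` — the signed inward displacement rate of the cell boundary
  crossing along the same ray between consecutive membrane frames.

`slippage = v_myo − v_mem` holds exactly for every record by construction.
Zero means the membrane moves in concert with the contracting cortex;
positive values mean cortical flow outruns the membrane (uncoupled,
conveyor-belt regime).

The acquisition scheme the pipeline assumes: the myosin channel is imaged
every frame (interval ≈ 5.7 s), the membrane channel every
`membrane_stride`-th frame (stride 6 ⇒ ≈ 34.2 s), each as a short apical
Z-stack (5 × 0.5 µm) that is maximum-projected before analysis. Frame
indices map to a developmental clock (minutes post MSxx birth) through
`msxx_birth_offset`; measurements are binned early = [3, 7] min (both ends
inclusive), late = ≥ 13 min, otherwise excluded. Each membrane frame pair
is assigned the midpoint time of its interval.

## Pipeline stages and the choices behind them

**Segmentation.** A random-forest pixel classifier (100 trees, seeded) over
a fixed feature bank — raw intensity, Gaussian blurs σ = 1, 2, 4 px,
gradient magnitude σ = 1, 2 px, Laplacian σ = 2 px — predicts
interior/border/background per pixel. Interior components ≥ 200 px² become
cell labels; hollow "halo" components (filled area > 1.5× the component)
are rejected as classifier artifacts; labels are then grown up to 2 px into
the border class by nearest label, so the cell edge sits near the middle of
the membrane signal and the shared border between adjacent cells is split
equidistantly without merging. Frames with no acceptable component are
flagged for curation, never silently emptied. Curation is a replayable
script of idempotent edits (merge, relabel, seeded-watershed split, paint,
erase); centroid tracking starts from a manual seed, follows the area
centroid of the tracked label, and accepts per-frame manual overrides used
verbatim and flagged. The feature bank and forest size are pipeline
defaults, configurable; no claim is made that they match any particular
interactive tool's internals.

**Flow.** Dense two-frame motion is estimated by the Farnebäck
polynomial-expansion method, implemented here directly in numpy/scipy:
quadratic expansion f(x) ≈ xᵀAx + bᵀx + c by Gaussian-weighted least
squares (5×5 neighborhood, applicability σ = 1.1), per-pixel solve of the
displacement normal equations accumulated over a Gaussian window
(window 15 px), 3 iterations with warped coefficients, embedded in a
3-level pyramid (scale 0.5). Reflective-border regions are down-weighted in
the accumulation. On smooth textures the estimator recovers 0.5–3 px shifts
with median error well below 0.05 px; the test suite cross-checks it
against an independent iterative-Lucas–Kanade implementation. Denoising
defaults to passthrough so the core pipeline has no hidden smoothing;
Gaussian and plugin denoisers (the attachment point for external
self-supervised methods) are available. Order is fixed: denoise 3D →
max-project → flow, for every consecutive myosin frame pair.

**Coupling.** At each membrane frame pair, 36 rays are cast from the
tracked center of the earlier frame's mask at uniform 10° spacing (legs are
rebuilt every pair because the boundary contracts). The anchor is the
sub-pixel 0.5-crossing of the bilinearly-interpolated label indicator along
the ray; the window is the set of in-cell pixels whose projection on the
leg axis lies within 2.0 µm inward of the anchor, restricted to the leg's
angular wedge (±180°/36) so windows tile the border band without
double-counting. Flow displacements are converted at sample level by
µm/min = px/frame × pixel_size × 60 / myosin_interval. A sample is retained
iff its vector magnitude ≥ 1.5 µm/min **and** its centripetal component is
positive; the retained sample is the centripetal component. The 1.5 µm/min
cutoff on the raw magnitude (rather than on the centripetal component) is
the default reading of "flow vectors moving slower than …"; the alternative
is implemented behind `threshold_on="centripetal"`. `v_myo` pools retained
samples across the (stride) myosin pairs of the membrane interval —
per-pair averaging is a config switch. Legs whose ray leaves the image
while still inside the cell are skipped with a logged warning; records with
zero retained samples or no boundary crossing at the later frame carry an
explicit flag and are excluded from aggregation.

**Statistics.** Aggregation respects the replicate hierarchy: leg records →
cell means → embryo (replicate) means → condition means. 95% confidence
intervals use Student's t on replicate means (the superplot convention; the
level of nesting for published CIs is not otherwise specified, so replicate
level was chosen). Welch's t (with Welch–Satterthwaite df) and the paired t
are computed from their closed forms, two-sided; scipy supplies only the t
distribution, so scipy's tests serve as an independent oracle in the test
suite. Gad proportions are reported as 100·n/N rounded half-up to one
decimal. Chi-square comparisons default to a 1-df goodness-of-fit of the
experimental counts against proportions expected from the comparison group
— this is the literal reading of "chi-square goodness of fit", and it
reproduces published p-values that a 2×2 contingency chi-square does not;
the contingency form is available as an option.

**Junction intensity.** Line scans are length × width rectangles (default
50 × 5 px, width odd) sampled bilinearly at 1 px pitch; background
correction subtracts the same geometry placed off-specimen (negative
results are kept but flagged, not clamped); per-group normalization divides
by the group maximum; paired embryo ratios are experimental/control with
control ≤ 0 flagged; the apical:basal ratio splits the junction line at a
configurable fraction (default half/half — the windowing of the prior
method this emulates is not published, so the default is explicit but
unverified against it).

## The synthetic generator

`myoslip.synthetic` renders a single contracting cell: a closed circular
membrane boundary shrinking at `v_mem_true` (piecewise-constant on the
developmental clock) rendered as a 3 px anti-aliased ring with a dim
cytosolic haze, and `density × π r₀²` punctate myosin spots (Gaussian,
σ = 0.15 µm) advected centripetally at `v_myo_true` with per-frame Brownian
jitter. Particles reaching within one spot-width of the center, or left
outside the contracting boundary, respawn on the boundary at a uniform
random angle, so the particle count is exactly constant (conveyor-belt
cortex). Five optical sections with intensity falloff exercise the
projection step. Defaults are the study conditions: 0.1 µm/px, 5.7 s myosin
interval, stride 6, v_myo 1.8 µm/min, v_mem 0.3 µm/min accelerating to
1.0 µm/min at 13 min, Gaussian read noise σ = 10 on a spot amplitude of 150
over baseline 100, jitter σ = 0.03 µm/frame, initial radius 10 µm in a
25.6 µm field.

What the generator does **not** emulate: realistic PSFs and photobleaching,
3D (unprojected) flow, myosin pulsing/coalescence, irregular (non-circular)
cell shapes, neighboring cells, and uneven illumination. Passing tests
therefore bound the pipeline's algorithmic bias under idealized imaging —
they do not certify accuracy on real microscopy, where segmentation quality
and flow texture are less favorable.

## Benchmark and problem sizes

`myoslip.validation.run_synthetic_benchmark` simulates replicate embryos on
a 256² px field for 144 myosin frames (3 → ≈16.7 min post MSxx birth, 24
membrane frames), samples classifier annotations from the ground-truth
masks on three frames (beginning/middle/end, 300 px per class), and runs
the full pipeline per replicate. Six replicates complete in a few minutes
on one CPU. Typical recovery under default conditions: v_myo within ~5%
(slightly high, because the 1.5 µm/min filter truncates the slow tail of
the jittered speed distribution), v_mem within ~0.01 µm/min, slippage
within ~7% early and ~3% late, and the early > late slippage difference
detected by the paired test at p ≪ 0.05.

## Numerical conventions, degenerate inputs

- Coordinates: 0-based pixel indices, origin top-left, x rightward (cols),
  y downward (rows); continuous positions at pixel centers. One convention,
  used everywhere.
- Boundary crossings: first outward 0.5-crossing of the bilinear label
  indicator, sampled at 0.25 px steps, refined by linear interpolation.
- Ties/degeneracies: rays that never leave the cell inside the image are
  skipped (open contour); velocity records that cannot be measured are
  flagged, never imputed; empty aggregation groups are reported as missing,
  not zero; stage times between 7 and 13 min are excluded by definition.
- Determinism: a single integer seed drives simulation, annotation
  sampling, and classifier training; identical spec + seed reproduces
  bit-identical image stacks, and superplot CSV export is byte-stable
  across re-runs.

## Known limitations

- The flow estimator is this package's own implementation of the Farnebäck
  method; numeric equality with other implementations is not claimed (their
  parameter conventions differ), only accuracy against ground-truth motion.
- `v_mem` relies on segmentation: a systematic boundary offset cancels in
  the frame-to-frame difference, but frame-to-frame segmentation jitter
  enters the membrane velocity noise floor.
- The "centers of myosin flow" centroid override is a user-supplied point
  list; no automatic flow-sink detection is attempted.
- Real early/late comparisons from published imaging are not reproducible
  here because the underlying movies are not distributed with the text; the
  acceptance machinery therefore validates against synthetic ground truth
  and the published count-derived arithmetic.
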