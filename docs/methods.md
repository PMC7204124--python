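# Methods

## Problem and overall procedure

`vdsmon` monitors grayscale video of a patient's throat for the irregular,
high-velocity laryngeal movement associated with phlegm stagnation
(airway obstruction by sputum) and raises an alarm so a caregiver can
intervene.  The chain is:

1. **Motion detection** — three-frame differencing finds the moving
   throat marker in each frame.
2. **Feature extraction** — the detected region's centroid is tracked and
   converted to a scalar speed per frame pair, v = l / t.
3. **Classification** — an SVM with a combined DTW/velocity kernel labels
   each velocity sequence as phlegm stagnation (+1) or normal (−1).
4. **Alerting** — a sliding-window monitor raises alerts on positive
   windows per a debouncing policy.

## Motion detection

For frames f_{k−1}, f_k, f_{k+1} the two absolute differences are
thresholded at a preset gray level T and intersected:

    R1 = |f_k − f_{k−1}| ≥ T,   R2 = |f_{k+1} − f_k| ≥ T,   R = R1 ∧ R2.

The AND removes the "image tail" (the ghost of the previous position a
two-frame difference drags along).  The absolute value is essential:
without it, motion that darkens pixels would be invisible.  The binary
mask is cleaned by morphological closing then opening with a disk
(radius 1 by default — closing first fills pinholes inside the target,
opening then removes isolated noise speckle), 8-connected components are
labeled, components below `min_area` (default 5 px) are dropped and the
largest survivor is the target.  Area ties are broken by the smallest
top-left bounding-box corner (row, then column) so selection is
deterministic.  T defaults to 25 gray levels on 8-bit frames; an
automatic mode derives T from the difference histogram by Otsu's method.
An empty selection is a valid "no motion" outcome, never an error.

A geometric fact governs what this detector can see: for a *uniformly
colored* target the AND mask only contains pixels covered at frame k but
not at k−1 or k+1, which is empty unless the per-frame displacement
exceeds the target's extent along the motion.  Small or textured markers
(the sticker condition) are therefore much easier to detect than large
uniform regions — the reason the synthetic marker is small and the
recommended practice is to fix a high-contrast sticker to the throat.

## Velocity features

The selected region is treated as a point particle at its unweighted
centroid.  Between detections at frames k_a < k_b the speed is

    v = l / t,   l = sqrt((x_b − x_a)² + (y_b − y_a)²),   t = (k_b − k_a) / f_w,

with f_w the frame rate.  Timing is gap-aware: a missed detection
lengthens t rather than inflating v.  Speeds are unsigned scalars in
pixels/second; direction, shape and texture are deliberately not used.
An optional normalization by frame height (off by default) is provided
for cross-camera comparability.

## DTW distance

Sequences of different lengths and paces are compared with plain table
DTW: D(i,j) = min{D(i,j−1), D(i−1,j), D(i−1,j−1)} + d(a_i, b_j), local
cost d = |a_i − b_j| by default (squared optional), path recovered by
backtracking with a fixed tie-break (diagonal, then vertical, then
horizontal).  Two boundary rules are implemented.  The *standard* rule
(single zero-cost origin outside (0,0); first row/column accumulate) is
the default because it preserves D(a,a) = 0 and symmetry.  The
*paper_literal* rule (every cell outside the table is 0) is retained as
an option; it permits cost-free skipping of arbitrary prefixes, so
self-distance is no longer zero and the distance never exceeds the
standard one.  An alternative Itakura-style step set
{(i−1,j−1), (i−2,j−1), (i−1,j−2)} is available (`extended_b`); because
every step advances both indices it cannot align sequences whose lengths
differ by more than a factor of two, in which case the distance is `inf`
with an empty path.  No global band constraint is applied.  Correctness
is checked against exhaustive enumeration of all admissible warping
paths on short sequences.

## The VDS kernel and classifier

The kernel between velocity sequences a and b is

    K(a,b) = exp(−(α·D(a,b) + (1−α)·V(a,b)) / (2σ²)),

with D the DTW distance, V = (mean(a) − mean(b))² the squared difference
of mean speeds, and α ∈ [0,1] the mixing weight.  α interpolates between
a pure sequence-shape kernel (α = 1) and a pure overall-speed RBF
(α = 0).  Two scale choices make one bandwidth σ serve both terms:

* D is divided by M + N (the sequence lengths), making it a per-step
  alignment cost;
* by default all speed values are z-scored by the global mean/sd of the
  training speeds before either term is computed (`zscore_over_training`).
  This is the package's reading of "normalize the inputs": it puts both
  the DTW term and the mean-speed term on a unit scale, so σ = 1 is a
  meaningful default.  Raw-speed and raw-D modes are retained.

Defaults are α = 0.5, σ = 1.0, C = 10; a cross-validated grid-search
helper is provided for retuning on new data.

Training precomputes the Gram matrix and solves the standard soft-margin
dual (penalty C).  DTW is not an inner-product distance, so the Gram
matrix is not guaranteed positive semidefinite; if its smallest
eigenvalue is materially negative (below −1e−8 relative to the largest)
the spectrum is clipped at zero before solving — a standard repair for
indefinite-similarity SVMs — and the model records that this happened.
Out-of-sample kernel rows are used as computed, without repair.  On the
synthetic study conditions used here no repair has been necessary.  The
decision rule is sign(Σ a_i* y_i K(x_i, x) + b*) with sign(0) mapped to
+1.  Training rejects single-class and all-identical-sequence inputs by
name.

Two baselines are provided for comparison, never as the implementation:
nearest-neighbour classification by DTW distance to labeled templates,
and a conventional RBF SVM on sequences linearly resampled to the median
training length.

## Synthetic study conditions

No patient videos are distributable, so the generator renders the
stand-in scene described in `vdsmon.synthetic`: an anti-aliased uniform
ellipse (the sticker marker, default semi-axes 4×2 px, contrast 120 gray
levels over a level-60 background) oscillating vertically in a 64×64
frame at 10 fps, with additive Gaussian pixel noise (σ = 4) clipped to
[0,255] and quantized to 8 bits.  Normal-class motion is a sinusoid
(amplitude 12 px, 1 Hz) with 1 px positional jitter; the phlegm class
adds one-frame excursions of 8 px with per-frame probability 0.15
("bursts").  These numbers were chosen once, on two grounds: (i) the
detectability constraint above — mid-cycle displacements must exceed the
2 px blob semi-axis, which amplitude 12 px at 1 Hz and 10 fps satisfies
(peak ≈ 7.5 px/frame) while still leaving realistic detection gaps at
the turning points; (ii) class overlap — sharing the base sinusoid and
jitter between classes makes the bursts the only discriminating signal,
giving a moderately hard problem (held-out accuracy well below 100%).
Two presets fix the regimes used by the tests and the acceptance script:
`separable_profiles` (amplitudes 16 vs 8 px, frequent bursts —
non-overlapping per-video mean speeds) and `overlapping_profiles` (the
moderate regime above).

What the generator does *not* emulate: real laryngeal appearance and
deformation, illumination changes, camera shake, occlusion, multiple
moving structures, and — most importantly — clinically validated
phlegm-vs-normal kinematics, which no public description quantifies.
Passing results on this data show that the chain recovers the kinds of
kinematic differences it parameterizes; they are not evidence of
clinical performance.

## Monitoring pipeline

A recording is cut into windows (default 30 frames, stride 15 — an
engineering choice; the temporal extent of one "action" in deployment is
not externally defined) and each window is detected, tracked and
classified independently.  Alert policies: `any_positive` (alarm on
every positive window) and the default `k_of_m` (alarm only when at
least k = 2 of the last m = 3 windows, including the current one, are
positive), which damps single-window flips.  Windows without trackable
motion are reported as "no-motion" and count as negative.

## Numerical and engineering choices

* Pixel coordinates are (x, y) = (column, row), 0-based, everywhere.
* DTW path indices are 0-based pairs from the start cell to (M−1, N−1).
* The DTW table fill is JIT-compiled with numba when available, with an
  identical pure-Python fallback.
* Frames are 8-bit; differencing is computed in float to avoid wrap.
* Problem sizes in the test suite and acceptance script (40-frame 64×64
  videos, 25–75 samples per class, 5–10 replicates) keep a full run in
  the low minutes on one CPU while leaving the measured orderings stable
  across seeds.

## Known limitations

* Single target only; a second moving structure of larger area would
  capture the track.
* Uniform large targets moving slowly are invisible to three-frame
  differencing (see above); the method depends on a compact
  high-contrast marker.
* The DTW Gram repair changes training geometry when triggered;
  out-of-sample rows are not consistently repaired (standard practice,
  but a known theoretical blemish of indefinite-kernel SVMs).
* The `paper_literal` DTW boundary is provided for fidelity but is not
  recommended: it breaks the identity D(a,a) = 0 that the kernel's
  K(a,a) = 1 contract relies on.
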