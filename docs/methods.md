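# Methods

## Drift model

Sample drift during an SMLM acquisition is treated as purely
translational.  The acquisition is divided into *datasets* — contiguous
frame blocks, typically bounded by brightfield-registration events — and
the drift at (dataset *d*, frame *f*) is modelled as

    drift(d, f) = s_d + Σ_{p=1..P} a_{d,p} f^p

with `s_0 = 0`.  The intra-dataset polynomial has no constant term, so it
vanishes at each dataset's first frame; the per-dataset constant `s_d`
absorbs the discontinuities that registration (or its residual error)
introduces between datasets.  Corrected positions are `observed −
drift`.  Rotational and non-rigid drift are out of scope.

## Cost function

Both fits minimize the thresholded nearest-neighbor distance sum
`sumNND = Σ_i min(d_i, l)`:

* **intra**: all localizations of one dataset are projected to t = 0
  with the candidate coefficients and queried against themselves
  (self-match excluded *by index*, so coincident distinct localizations
  still count at distance zero).  If the model is right, re-blinks of an
  emitter collapse and the sum is small; a wrong model disperses them.
  The spatial index is rebuilt per evaluation since every point moves.
* **inter**: the candidate constant shift is applied to the (already
  intra-corrected) target dataset, which is queried against a k-d tree
  of the corrected *first* dataset.  Orienting the query this way lets
  one tree decomposition serve every dataset and every trial shift.

The threshold caps the contribution of localizations whose nearest
neighbor is not a re-blink of the same emitter (blinking makes such
false pairings unavoidable); defaults `l_intra = 1` px, `l_inter = 2` px.
Search depth is one neighbor (k = 1); deeper searches add cost without
measurable benefit.  The cost is bounded by `0 ≤ sumNND ≤ n·l` for any
parameters, which the property tests assert.

All internal coordinates are **pixels** (the thresholds are
pixel-defined); nm conversion happens only at I/O boundaries with a
default pixel size of 100 nm.  z is expressed in the same lateral pixel
units, making the NN metric and the thresholds isotropic — the simplest
consistent 3D choice.

## Optimization

Both fits use derivative-free Nelder–Mead simplex minimization
(`xatol = fatol = 1e-6`, `max_iter = 2000`).  The cost landscapes are
funnel-shaped with a broad plateau, so local search from a sensible
initial guess suffices: zero for intra fits; for inter fits, zero when
registration kept datasets aligned, else the accumulated end-of-dataset
drift of the previous dataset.  The initial simplex is scaled to the
problem — 0.25 px steps for shifts, and per-coefficient steps producing
~0.5 px displacement at the dataset's last frame for polynomials —
because the library default (5 % of the start value, an absolute 2.5e-4
at zero) can start far below the funnel width.  The returned parameters
never cost more than the initial guess (guarded explicitly, asserted in
tests).  Datasets with fewer than two localizations get zero
coefficients and a warning; their inter fit is skipped.

## Brightfield registration

Registration estimates the 3D offset between a reference z-stack and a
new z-stack of the same field:

1. every slice is divided by its own pixel sum (removes z-dependent
   illumination bias in the z peak location);
2. each stack is whitened: `(v − mean) / (stdev·sqrt(N−1))`, equivalent
   to dividing the centered stack by the square root of its
   autocorrelation maximum, so correlation values range over [−1, 1];
3. the full linear (zero-padded) cross-correlation is computed by FFT
   and multiplied by `max(ones⋆ones)/(ones⋆ones)` — the overlap count —
   to remove the small-lag bias of linear correlation.  Linear rather
   than circular correlation is essential: the overlap scaling is
   meaningless for circular wrap-around;
4. the argmax is searched where the overlap is at least 10 % of the full
   stack (the scaling inflates variance at extreme lags; the cutoff
   suppresses spurious border maxima — the volume itself is returned
   unmasked);
5. each axis is refined by the vertex of a parabola through the 3
   correlation values straddling the maximum.  The parabola is fit on
   the *un-scaled* whitened correlation: across a 3-voxel window the
   overlap scaling is an outward-increasing ramp that systematically
   inflates the vertex, while at the integer-search scale it is exactly
   the bias correction intended.  Border maxima and curvature-free
   neighborhoods fall back to the integer lag with a warning.

Sign convention (fixed and unit-tested): a positive shift means the
sample content appears moved by +shift in the new stack; the stage is
commanded to move by −shift.  The closed loop
acquire → register → move repeats until the measured shift is below
5 nm in x, y and 50 nm in z (configurable), or 10 iterations.
Convergence is declared on the *measured* residual; the true residual
additionally carries the one-shot estimator error (a few nm on the
synthetic scenes).  The stage is an abstract interface; the shipped
implementation is a simulator with configurable move error and image
noise — no hardware drivers are included.

## Synthetic data

The generator reproduces the statistical structure of the validation
studies at the localization level:

* **Emitter fields** — uniform Poisson fields over a square ROI;
  star-shaped (Siemens-star, 8 alternating wedges by default — the
  concrete realization of an otherwise unspecified "star" geometry)
  domains obtained by exact thinning, so the in-domain density equals
  the nominal one; 40 nm diameter rings at linear density 1000
  fluorophores per pixel of contour length, in coaxial pairs separated
  80 nm (or 120 nm) along z.
* **Blinking** — each emitter is an alternating renewal process: dark
  times ~ Exp(mean 1/K_on), on times ~ Exp(mean 1/K_off), defaults
  K_on = 0.0005/frame, K_off = 1/frame.  Exponential dark times are
  memoryless, so starting each trace dark is equivalent to a random
  phase (the ~0.05 % stationary chance of being on at t = 0 is
  neglected).  Expected events per emitter over n frames:
  λ = n·K_on·K_off/(K_on+K_off); on-fraction K_on/(K_on+K_off); expected
  same-emitter event pairs ⟨N_p⟩ = λ²/2 (Poisson second factorial
  moment).  `kon_for_lambda` inverts the renewal rate when a study
  prescribes λ.
* **Drift curves** — constant (e.g. 0.3/0.4 nm/frame), polynomial
  α f + β f², and cubic splines through ~35 Poisson-distributed nodes
  per 50,000 frames with values uniform in ±100 nm.  Spline node times
  are a jittered partition snapped to whole frames with both endpoints
  pinned (no extrapolation); natural boundary conditions plus a redraw
  of node values when the interpolant exceeds 1.5× the amplitude keep
  the curves within the stated range.  β as printed in the quadratic
  study (10 nm/frame²) implies kilometer-scale cumulative drift and is
  treated as a unit inconsistency: the generator accepts β as given,
  but all shipped studies use linear or spline drift.
* **Localizations** — one row per (emitter, frame with on-overlap):
  position = truth + drift(frame) + N(0, σ) per axis, σ = 10 nm by
  default ("±10 nm" scatter is read as Gaussian σ = 10 nm, untruncated),
  with an optionally larger σ_z to emulate astigmatic 3D fitting.
  Camera-frame physics (PSF rendering, 12,000-photon signal /
  1000-photon background shot noise, MLE fitting) is *not* modelled; the
  Gaussian scatter emulates its end effect.  Consequently the validation
  results show algorithmic accuracy under clean localization statistics
  — they do not probe mislocalizations, sample-dependent PSF aberrations
  or detection-threshold effects, and accuracies on real data are
  expected to be somewhat worse (axial in particular).
* **Brightfield stacks** — smooth random Gaussian-blob volumes
  (64×64×21 by default, 150 fine blobs) sampled analytically at exact
  sub-voxel shifts; labelled synthetic, standing in for real cell
  brightfield images in registration tests.

Every generator is a pure function of (parameters, seed).

## Frame connection

Repeated localizations of one on-event in consecutive frames are
consolidated by a greedy centroid merge (nearest candidate first, within
a radius, gap-tolerant), keeping the first frame of the run.  This is a
simplified, unweighted variant of the usual precision-weighted
consolidation — it is pre-processing convenience, not part of the drift
math.  The merge radius must stay below the structure scale: the shipped
3D ring study uses 0.05 px (noiseless localizations on a 0.4 px
structure), the noisy 2D studies 0.5 px (≈ 5σ of the 10 nm scatter).

## Validation studies and problem sizes

The studies shipped in `evaluation` (and recomputed by
`scripts/acceptance.py`) use these desk-scale sizes, chosen to keep each
study in the minutes range on one CPU while preserving the governing
statistics (pair counts, per-frame drift velocities):

* **Intra rate accuracy / pairs plateau** — single 1000-frame dataset,
  uniform field on a 25,600 × 25,600 nm ROI, α = (0.05, 0.02) nm/frame,
  σ = 10 nm, N_e = 1e5 and λ = 0.45 (⟨N_p⟩·N_e ≈ 1e4 pairs); 10 and 20
  seeds respectively.  Expected: rate error well below 1e-4 px/frame,
  RMSE well below the ~1 nm plateau (a linear model fitted to linear
  truth is limited only by sampling noise, not model mismatch).
* **Star-domain rate recovery** — 6400 × 6400 nm ROI, density
  0.125e-4 /nm² (~250 emitters in the star), λ = 2 per 1000-frame
  dataset (a typical DNA-PAINT event count; the study prescribes
  densities but not λ), drift 0.3/0.4 nm/frame, 20 replicates.
* **3D two-ring benchmark** — 20 datasets × 500 frames (reference
  condition: 100 × 500), spline drift with node count *and* amplitude
  scaled by covered-frames/50,000 (7 nodes, ±20 nm), so per-frame drift
  velocities match the reference; noiseless localizations; full 3D
  correction with accumulated-drift inter initialization.  Compressing
  the full ±100 nm excursion into 10k frames instead would quintuple the
  within-dataset drift and measure a different (harder) condition.
* **Segmentation sweep** — a long single-dataset acquisition under
  spline drift re-chunked at several frames-per-dataset values;
  reproduces the qualitative optimum at moderate chunking (one huge
  dataset forces a single low-order polynomial onto a wiggly curve).

Drift-curve errors are computed per axis over all frames, with both
curves anchored to zero at frame 0 (an absolute offset is unobservable
to the algorithm; note this convention nulls any constant bias shared by
every frame).  Pooled RMSE is the root mean square across axes.

## Numerical choices and edge cases

* NN tie-breaking follows the k-d tree's native order; ties cannot
  change the cost value (sums of distances).
* Self-exclusion queries two neighbors and discards the self *index*,
  never a zero distance.
* `exclude_self` with fewer than 2 points returns the saturated cost
  n·l; empty queries cost 0.
* Whitening rejects constant stacks; slice normalization rejects
  zero-sum slices; stacks need ≥ 3 slices (the z parabola needs 3
  points).
* Re-segmentation infers a uniform original dataset length only when
  unambiguous, otherwise demands it explicitly; re-assembly restores the
  original indices exactly and requires unchanged row order.

## Known limitations

* The intra cost has a genuine degenerate attractor for dense compact
  structures: stretching a dense blob into a filament can lower sumNND.
  Realistic per-dataset drift (≲ structure scale per dataset, as the
  registration loop guarantees) keeps the optimizer in the true basin;
  very steep drift over a long unregistered dataset can trip it, and the
  re-segmentation tool exists precisely to shorten such datasets.
* Accuracy claims derive from the localization-level simulator (see
  above); PSF- and detection-level artifacts are not represented.
* PALM-style single-activation probes provide no re-blinks and are out
  of scope by construction.
* The inter model is a constant shift; drift *within* the gap between
  datasets is invisible to it.
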