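# Methods

`wormfreq` estimates the locomotor (undulation) frequency of a single
*C. elegans* from dark-field video without segmenting the animal. This note
documents the model, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## The estimator

**Background subtraction.** The video is treated as a (H·W)×T matrix and its
best rank-1 approximation — the first principal component of the uncentered
pixel-by-time matrix — is taken as the background. For a mostly static scene
this component is the stationary illumination pattern; subtracting its
per-frame reconstruction and clamping negatives at zero leaves the bright,
moving animal. The clamp encodes the dark-field assumption (object brighter
than background). The component is computed through the T×T Gram matrix,
which is exact and cheap for T up to a few thousand frames.

**Shape invariants.** Each background-subtracted frame is summarised by
P = 8 + N numbers that are invariant to where the animal is, which way it
points, and how large it appears:

- the 8 Hu moment invariants h1..h8 of the gray intensities (not a binary
  mask), built from scaled central moments η_pq = μ_pq / μ00^(1+(p+q)/2) up
  to order 3. h1..h6 are even under reflection; h7 and h8 flip sign. The
  eighth invariant's leading factor is taken as η11 so that h8 shares the
  scale invariance of the others; a `h8_prefactor="mu11"` option preserves
  the raw-moment variant for comparison.
- N orientation invariants from maximally stable extremal regions (MSERs):
  connected components of the threshold sweep whose area changes least over
  `delta` gray levels. Each region is summarised by the major-axis angle of
  its minimal circumscribed ellipse. Because the number of detected regions
  varies between frames, orientations are resampled at N fixed query areas
  (piecewise-linear in area, linearly extrapolated at the ends) and then
  recentered by their circular mean, which removes the animal's overall
  orientation and leaves only relative, posture-driven structure.

Orientations are axial (defined modulo π); interpolation and the circular
mean are computed on doubled angles by default to avoid the wrap artifact at
±π/2 (`angle_mode="raw"` reproduces the plain-radian convention).

The query-area range is anchored at the scales the detector actually
returns: by default the 0.2 quantile of the per-frame smallest and largest
region areas (`area_range_mode="detected"`). Anchoring at, say, 1% of the
largest area forces linear extrapolation far below the smallest detectable
region and amplifies orientation jitter into the profile
(`area_range_mode="largest_frac"` keeps that convention available).

**Ensemble autocorrelation.** The P per-frame invariants are z-scored per
row (population variance; constant rows map to zero) and stacked into a P×T
ensemble. The autocorrelation at lag τ is the average cosine similarity
between ensemble columns τ frames apart, R(τ) for τ = 0..τ_max (default
⌊T/2⌋; larger lags average too few column pairs). Columns of zero norm
contribute zero but still count in the normaliser.

**Extrema runs and frequency.** Peaks and troughs of R(τ) — including the
lag-0 peak and, when the series arrives rising or falling, the far endpoint —
are assigned topographic prominences (contours truncated at the series
boundary; plateaus reduced to their midpoint sample). Extrema with prominence
below 0.14 are discarded. Survivors are grouped into maximal alternating
runs; runs shorter than two extrema are dropped. If nothing survives the
animal is scored quiescent: f = 0 Hz. Otherwise the mean adjacent-extremum
spacing Δ (in lags) is Σ(last − first) / Σ(run length − 1) over runs, and

    f = fps / (2 Δ),

because neighbouring peak–trough spacings of the autocorrelation of a
periodic signal are half its period. A `full_period` conversion (f = fps/Δ)
is available for comparison.

Two details matter in practice:

- *Adjacency among survivors.* Low-prominence noise wiggles always appear as
  adjacent peak+trough pairs with equal prominences, so discarding them
  preserves the alternation of the surviving major extrema. Runs are
  therefore formed on the re-indexed survivor list and split wherever two
  consecutive survivors have the same kind (such neighbours are a full
  period apart, not the half period the estimator averages). The stricter
  convention — requiring survivors to be adjacent in the full extrema list,
  where any discarded wiggle breaks a run — is available as
  `adjacency="original"`, but it collapses to 0 Hz on any autocorrelation
  with small noise wiggles, which makes it unusable on realistic input.
- *Sub-frame lag refinement.* Extremum locations are refined by a 3-point
  parabolic fit (`refine_extrema`, on by default). This matters when the
  half period is a non-integer number of frames (a 2 Hz animal at 30 fps has
  a 7.5-frame half period); the refinement is exact on sampled cosines.

**Thresholds and defaults.** Prominence threshold 0.14 (applied alike to
peaks and troughs on the R scale); N = 4 orientation invariants; MSER
`delta` = 5 quantized gray levels, `min_area` = 30 px, maximum area 25% of
the frame, `max_variation` = 0.25, sweep floor at quantized level 8 (pixels
below ~3% of the video maximum are background residue and are excluded from
the component sweep). All are config knobs.

`min_area` is deliberately not scaled with image resolution: when the animal
shrinks below the floor (e.g. 6 px per body length) no region qualifies,
every orientation profile is flagged empty, imputation makes those rows
constant, z-scoring zeroes them, and the MSER block drops out of the cosine
similarity. The pipeline then degrades gracefully to the moment invariants,
which is also why it keeps working at resolutions where orientation
estimates carry no signal.

**Missing frames.** Frames with zero intensity ("zero-mass") or no detected
regions are imputed with the row's mean over valid frames before
standardization, so single bad frames never poison the ensemble.

## MSER implementation

No MSER detector is available in the installed stack, so the detector is
implemented here: pixels at or above the sweep floor are processed in
descending gray order through a union–find component forest; each component
root records its area at every level once it reaches `min_area` (smaller
components can neither be emitted nor absorb anything larger, so their
history is irrelevant — this keeps the record store linear in the number of
meaningful components). Stability is the relative area change across
±`delta` levels, with the containing component's area looked up through the
absorber chain below a root's death level and clamped at its birth level
above. Each maximal run of acceptable levels emits one region at its
minimum-variation level (midpoint on ties), so nested structures (bright
segment inside whole body) yield nested regions. The numeric core is
numba-compiled.

The minimal circumscribed ellipse is the minimum-volume enclosing ellipse of
the region's pixel centers (Khachiyan's iteration on the convex hull,
optimality gap 1e-3, final rescale to guarantee containment). Collinear
regions fall back to the fitted line with a configurable minor semi-axis.

## Segmentation baseline

The comparison method follows the standard morphometric recipe: Gaussian
smoothing (σ = 1 px), Otsu threshold, largest connected component, hole
fill; head and tail as the two sharpest convex boundary points (boundary
resampled to 200 points, smoothed, signed curvature; a non-elongated mask —
eigenvalue ratio < 2.5 — raises "ends not found" since a coiled shape has no
meaningful ends); centerline as midpoints of the two boundary sides,
spline-smoothed and resampled to M = 50 equidistant points; signed curvature
κ = (x′y″ − y′x″)/|r′|³ per body coordinate; anterior curvature = mean κ
over body coordinate 0.1–0.3 (excluding the noisy tip). Frequency is
fps / (mean spacing of anterior-curvature maxima) — signed curvature peaks
once per full period, so no half-period factor — with a minimal prominence
of 10% of the series SD guarding against noise peaks, and 0 Hz with fewer
than two peaks. The head end is tracked across frames (nearest endpoint to
the previous head) to keep the curvature sign consistent. Frames where
segmentation or end-finding fails contribute NaN (interpolated over for the
frequency; reported in `n_failed_frames`); if more than half the frames
fail, the estimate is NaN. In benchmark error summaries a NaN estimate
counts as a relative error of 1.

## Synthetic videos

The generator renders a bright, tapered ribbon whose centerline carries a
traveling sine wave y(s,t) = A·sin(2πs/λ − 2πf0·t + φ0) in the body frame,
rigid-transformed by a drifting heading and translation with reflection at
the frame borders. Defaults: body length 60 px, λ = 0.9 L, A = 0.12 L, peak
half-width 0.06 L with an elliptical taper, 30 fps, 10 s, 240×240 frames,
peak intensity 200, and a static stray-light background at 10% of body
intensity (a dim pedestal with a gentle gradient and one broad bump, so
background subtraction is exercised nontrivially). Translation speed
defaults to 20 px/s ≈ one third of a body length per second, typical of
swimming adults. All randomness (initial phase, heading, trajectory,
texture) derives from a single seed; identical configs are bitwise
reproducible.

Three rendering choices exist specifically to reproduce features of real
dark-field footage that the estimator relies on:

- **Body-fixed brightness texture** — a dominant bright segment (the
  anterior gut region), small bright granules scattered over the body, an
  along-body brightness modulation, and a mild dorsoventral brightness bias.
  A perfectly uniform ribbon is exactly mirror-symmetric half an undulation
  period apart, something no real worm image is; on such input the
  reflection-even invariants oscillate at 2·f0 and any interval-based reader
  of the autocorrelation reports the second harmonic. The bright segment
  also gives the smallest MSER a stable anatomical anchor.
- **Posture-locked brightness modulation** (`scatter_modulation`, default
  0.2) — dark-field scattering depends on the body's tilt, which cycles with
  the undulation, so whole-body brightness oscillates at f0.
- **Field size** — at 240×240 with a 60 px animal the worm occupies ~1% of
  the frame, as in real fields of view, so the rank-1 background model is
  dominated by the static background rather than by a "ghost" of the
  animal's time-averaged silhouette. In much tighter crops the ghost
  contaminates the subtraction and with it the intensity moments.

Degradation utilities reproduce the robustness protocol: spatial
downsampling by block averaging, temporal downsampling by frame decimation
(fps divided accordingly), and additive zero-mean Gaussian noise at a
requested SNR. SNR is defined on the whole frame: σ² = P_signal/10^(SNR/10)
with P_signal the mean squared intensity over all frames, and the noisy
video is clamped at zero. Because frames are mostly dark, a given dB value
is milder relative to the animal's brightness than the same number computed
on the body alone; noise levels quoted for this simulator are not
comparable to SNRs computed with other conventions.

What the simulator does **not** emulate: three-dimensional rolling and
out-of-focus blur, self-occluding (coiled or omega) postures, non-sinusoidal
curvature waveforms, multiple animals, illumination flicker, and camera shot
noise statistics. Passing recovery tests on this generator demonstrates the
estimator's mechanics under controlled, realistic-contrast conditions; it
does not certify performance on any particular microscope.

## Benchmark batteries

`wormfreq.bench` drives the study conditions used by the tests, the
acceptance script and the `bench` CLI subcommand:

- *Clean recovery*: f0 ∈ {0.5, 1.0, 1.7, 2.0} Hz at 30 fps, 60 px per body
  length, 10 s.
- *Nyquist sweep*: f0 = 1.7 Hz rendered at 30 fps for 20 s, decimated to
  5 fps (fs/f0 = 2.94, the passable regime) and 3 fps (fs/f0 = 1.76, below
  the Nyquist limit where recovery collapses).
- *Method comparison*: 1 Hz animals, 8 s; "coarse" downsamples 10× to ~6 px
  per body length; "noise" adds 12 dB whole-frame noise; both methods
  analyze the same degraded videos.
- *Ablation battery*: the feature blocks complement each other across
  conditions, so the battery pairs a slow swimmer (0.5 Hz at 5 fps, 20 s —
  orientation rows and background subtraction carry the estimate) with a
  coarse recording (1.7 Hz at 12 px per body length — moment rows carry it),
  both at 8 dB noise. Disabling any one module increases the battery-mean
  error; single conditions can favour single blocks.

Problem sizes (seeds per condition, durations) are chosen so the full
benchmark suite runs in minutes on one CPU; estimates stabilise well below
these sizes because per-video errors are strongly bimodal (sub-percent or
gross).

## Known limitations

- The estimator reports one frequency per analysis window; it does not track
  instantaneous frequency within a window, and mixed behaviour inside a
  window biases the mean-interval statistic toward the dominant rhythm.
- Sampling near twice the locomotor frequency aliases; accuracy collapses
  at fs/f0 ≤ 2 by construction (this is a property of the problem, not of
  the implementation).
- The prominence threshold 0.14 is kept constant across frame rates and
  conditions.
- Reflection-symmetric, strictly sinusoidal gaits with symmetric brightness
  would be read at twice their undulation frequency; real animals (and the
  simulator's default texture) break this symmetry.
- The segmentation baseline requires non-coiled postures and fails loudly
  (never silently) when ends cannot be found.
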