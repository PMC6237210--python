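# Methods

## The two readouts

**Cell deformation index.** A tracked cell's binarized footprint is
compared between a start frame and the frame one window later (default
window 5 frames; with the default frame interval of 1 min this is the
5-minute interval the readout was designed for). Pixels split into
*A* = initial-only, *B* = overlap, *C* = final-only, and the index is
(A + C)/(A + B) — the area changed over the window relative to the
initial area. It is exactly 0 iff the two masks are identical, always
≥ 0, and conserves areas (A + B = initial area, B + C = final area; both
are asserted on every record). Windows slide one frame at a time, so a
track of length L yields L − window records; the per-cell summary is the
mean over a track's records (the aggregation rule is a config choice —
nothing forces one window per cell). A cell whose final mask is empty
gets A = initial area, B = C = 0, hence index 1.0, and is emitted with a
`disappeared` flag rather than dropped, since the formula stays defined.
The index is computed on pixel counts; µm² conversion via `pixel_size²`
is presentation-only.

**Bone-resorbing index.** Per frame, signal = mean pH-probe intensity
over the union of segmented osteoclast areas, noise = mean over pixels
outside that union dilated by an exclusion ring (default 2 px). The ring
removes boundary bleed-through from the noise estimate; ring = 0
reproduces the literal inside/outside definition. The index
signal/noise is scale-invariant (multiplying the channel by k > 0
changes nothing) and ≈ 1 when the probe is spatially uniform. The
movie-level value is the mean of per-frame indices; frames with no
segmented cells are skipped. Masks come from the cell-reporter channel,
since the procedure binarizes osteoclast areas, not probe signal.

## Segmentation and tracking

Per frame: threshold (Otsu by default; a fixed threshold is available for
reproducibility experiments) → morphological opening (disk radius 1) →
8-connected components → drop regions below `min_area` (50 px) → drop
border-touching regions (their A/B/C areas would be censored) → relabel
contiguously. A constant image under Otsu yields an empty label map, not
an error. Tracking links consecutive frames by greedy maximum pixel
overlap, accepting a link only at IoU ≥ `min_iou` (0.3); ties break
toward larger intersection, then smaller label ids, so assignment is
deterministic. There is no gap closing and no watershed splitting:
osteoclasts are large, sparse and slow relative to the frame interval, so
greedy overlap matching suffices, and a cell lost for a frame starts a
new track. Fused or touching cells are treated as single regions.

## Spectral unmixing

Raw multi-detector stacks are modeled as a per-pixel linear mixture
x = S·a of nonnegative endmember abundances a through a known spectra
matrix S (detectors × endmembers, one column named `autofluorescence`).
Abundances are recovered by nonnegative least squares — the standard
reference method when the commercial implementation is unpublished —
with a vectorized unconstrained solve as the fast path and Lawson–Hanson
NNLS only for pixels where it goes negative (identical results, since
NNLS coincides with unconstrained LS whenever that solution is feasible).
Reference spectra must be supplied; blind decomposition is out of scope.
S is validated for nonnegativity and conditioning (rejected above
condition number 1e8).

## The synthetic movie generator

Cells are star-convex blobs: boundary radius r(θ) = R·(1 + Σₖ aₖcos kθ +
bₖsin kθ) with 6 harmonics, modulation clipped to ±0.7 so masks stay
simply connected. Motility is a per-frame random walk on the Fourier
coefficients (step `motility·0.5/k`) and centroid (step `motility·2` px
per axis); the random draws are motility-independent, so motility 0 gives
exactly static masks, and a common seed yields a common random path
across motility levels (which makes the monotone motility→deformation
response essentially deterministic in tests). Cells are placed with
rejection sampling at ≥ 2.6 radii separation and a border margin; failure
after the retry budget raises a placement diagnostic.

Three channels: `reporter` = background + 100·(cell mask);
`ph_probe` = background + secretion·60 inside the 1-px-eroded footprint
of resorbing cells (mirroring probe signal overlapping the cell body);
`bone` = a static smooth random texture. Additive Gaussian noise
(sd 5 = 5% of cell amplitude) is clipped at 0. `simulate_spectral`
additionally mixes the clean channels with a smooth autofluorescence
abundance map (weight `autofluorescence_weight`) through supplied
endmember spectra and returns raw, clean and ground truth so round trips
can be scored against the noiseless truth.

Defaults: 512×512 px fields at 1 µm/pixel, 1 min frame interval,
30 frames, 15 cells of radius 14 ± 2 px. Condition presets live in one
editable table (`osteodyn.simulate.CONDITIONS`); the values are free
choices constrained only by the qualitative orderings they must encode —
untreated: high secretion (1.0), high resorbing fraction (0.9), baseline
motility (0.05); every drug condition: secretion 0.20–0.25 and resorbing
fraction 0.3 at both time points; motility 0.40 (ris) > 0.22 (aln) >
0.10 (mino) at 12 h, with minodronate instead peaking at 24 h (0.30) and
risedronate/alendronate declining from their 12 h maxima. Motility values
sit in the non-saturated part of the deformation response (the index
compresses toward ~1 for large steps), so ordered parameters produce
ordered indices.

What the generator does **not** emulate: two-photon optics (PSF,
scattering, depth attenuation), photobleaching, cell fusion or division,
probe puncta substructure, and drift of the imaging field. Passing tests
therefore demonstrate correctness of the computations and the expected
qualitative drug contrasts under a clean additive-Gaussian imaging model,
not robustness to every artifact of real intravital data.

## Statistics

Groups are reported as mean ± SD (sample SD, n − 1; flagged undefined for
n = 1). Comparisons use two-tailed two-sample t tests — Welch by default,
robust to unequal variances; the pooled-variance variant is a flag —
with significance judged at α = 0.05 and reported alongside the
statistic. No multiple-testing correction is applied, matching
individual-comparison reporting. Because the sampling unit of the
original group comparisons is ambiguous (cell, field or animal), the
pipeline reports both movie-level tests (both indices) and cell-level
tests (deformation).

## Problem sizes and numerical choices

The analysis drivers, the test suite and `scripts/acceptance.py` run the
battery at a reduced geometry — 256×256 px, 8 frames (one 5-min window
per track start), 8 cells per movie, 3 movies per group — which preserves
every qualitative contrast while keeping a full run in seconds. Per-movie
seeds derive from one base seed via `numpy` seed sequences, so runs are
bit-reproducible; the end-to-end manifest records the materialized config
and a SHA-256 checksum of every output table. Degenerate inputs are
explicit errors: empty initial mask (deformation), empty cell mask or
zero noise mean (resorption), n < 2 groups (t test), rank-deficient
spectra (unmixing); a constant image under Otsu is an empty — not
failing — segmentation.
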