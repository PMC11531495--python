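# Methods

This note documents the models, algorithms, default parameters, and design
choices behind `condensig`, and what the synthetic benchmarks do and do not
establish about performance on real microscopy data.

## Puncta detection

Cells arrive as integer label masks (segmentation is an input, not a product
of this package). Detection runs independently per cell:

1. **Normalization.** Intensities are divided by the cell's median, so all
   downstream thresholds are unitless and detection is exactly invariant to
   per-cell expression level and acquisition gain. In a cell whose puncta
   occupy a small area fraction, the median is the diffuse cytoplasmic level.
2. **Enhancement.** Gaussian smoothing (`gaussian_sigma_px`, default 1.0),
   then a morphological white top-hat with a disk structuring element
   (`tophat_radius_px`, default 8) that removes background varying on scales
   larger than a punctum, then a negated Laplacian of Gaussian
   (`laplacian_scale_px`, default 2.0) so compact bright blobs become
   positive maxima. Pixels outside the cell are treated as median-level
   (1.0) background during filtering to soften border effects.
3. **Seeding.** Seeds are 8-neighborhood local maxima of the enhanced image
   with value ≥ `seed_cutoff` (default 0.2), processed in descending order.
4. **Growth.** Each unclaimed seed grows to the connected component (default
   8-connectivity) of pixels whose *normalized* value is at least
   `growth_scale × local background`, where the local background is the
   median of cell pixels not yet assigned to any punctum, recomputed after
   each accepted cluster. Clusters below `min_area_px` (default 4) are
   discarded. Growing inside the unclaimed region keeps puncta disjoint by
   construction.

`seed_cutoff` and `growth_scale` are the two user-facing sensitivity
parameters. Their defaults (0.2 and 2.0) were calibrated on the synthetic
benchmark scenes (5× intensity gain, ~2–4 px punctum radii, SNR ≈ 40) where
they give recall ≈ 1 at zero false discoveries; on real data with different
punctum scales or noise they should be re-tuned, which is why they are
parameters rather than constants. Filter sizes assume puncta of roughly 2–8
px radius at the benchmark pixel scale.

Colocalization counts a channel-A punctum as overlapping if it shares at
least `min_overlap_px` (default 1) pixels with any channel-B punctum; the
per-cell fraction is undefined (NaN, flagged) for cells without A-puncta.

## Translocation scoring

The edge ring is the set of mask pixels within `ring_width_px` (default 10)
of the mask complement, by Euclidean distance transform (Chebyshev available
via `metric="chebyshev"`); the core is the remainder, and both must be
nonempty. Membrane localization is mean(edge)/mean(core); translocation is
the post-stimulation minus pre-stimulation localization, scored by default
1.5 min after stimulation. Because absolute magnitudes vary with imaging
plane between acquisitions, the suppression summary
(`translocation_suppression`) takes paired oncogene/wild-type samples from
the same scene and reports `fraction = median(oncogene)/median(wt)` and
`suppression = 1 − fraction`, with quartiles from 1000 seeded bootstrap
resamples of both groups. Defining suppression as one minus the median
fraction is this package's convention; both quantities are always reported.

## KTR pulse calling

Traces are cytoplasmic/nuclear reporter ratios sampled uniformly (default 5
min over 22 h, 264 frames). Processing order:

1. **Expression QC.** Traces with reporter expression below `min_expression`
   (default 0.2 on the benchmark's unit-mean expression scale) are removed.
2. **Death truncation.** A dying cell's trace is cut at its death frame.
   This replaces manual outlier inspection of apoptotic-debris artifacts
   with a deterministic rule.
3. **Peak detection.** Local maxima with topographic prominence ≥
   `min_prominence` (default 0.5) separated by ≥ `min_peak_distance_frames`
   (default 3), via the standard distance-then-prominence filtering order of
   `scipy.signal.find_peaks`. An optional moving-median smoothing window is
   off by default. The prominence default is calibrated to the benchmark's
   unit pulse amplitude at 5% noise; prominence was chosen because it is
   shift-invariant and scales linearly with the trace.
4. **Division exclusion.** Pulses within `division_exclusion_frames`
   (default 10, i.e. 50 min) before a division frame are flagged
   `division_proximal` and excluded from all counts — such pulses occur
   independently of RAS/ERK signaling.
5. **Lineage deduplication.** Daughter traces carry the parent's duplicated
   history for display and tracking continuity. Each retained pulse is
   attributed to the cell physically alive at its peak frame (walking up the
   lineage while the peak precedes the cell's own birth), and unique
   (owner, frame) pairs are counted once. The fraction of pulsing cells is
   computed over owned pulses, with a Wilson 95% CI.

## Death-neighborhood enrichment

A cell is a neighbor of a death event if its centroid lies within
`radius_px` (default 100) of the dying cell in **at least one** of the
`window_frames` (default 10) frames preceding death in which both are alive
("any" rule; the stricter "all" rule is available via a flag — the inclusive
reading was chosen because cells plausibly move 2–3 cell diameters within
50 min). Controls are drawn per event, uniformly without replacement, from
cells alive throughout the window that are not neighbors (or dying cells) of
*any* event with an overlapping window, with the sample size exactly equal to
the neighbor count; events with an insufficient control pool are dropped and
logged. Pulses are counted in the same 10-frame pre-death window for both
groups, and the per-event neighbor vs control means are compared with a
paired one-sided bootstrap median test. Pooled fraction-pulsing per group is
reported over (event, cell) membership instances with Wilson CIs.

## Bootstrap median test and kinetics

The bootstrap statistic is `median(a) − median(b)`; each group is resampled
with replacement `n_boot` (default 1000) times — jointly over pairs in the
paired variant — and the one-sided p-value is the fraction of bootstrap
statistics on the null side of zero with a `+1/(n_boot+1)` continuity
correction, so p is never exactly zero. The test is mildly conservative at
small samples (empirical type-I ≈ 0.03–0.04 at n = 25–50 per group,
nominal 0.05) because ties at zero count against rejection.

Dissociation kinetics are fitted by least squares to the mean trace of an
ensemble, with model `I(t) = offset + amplitude · 2^(−t/t½)`. The offset is
free because kinase inhibition releases adapters without fully dissolving
the underlying condensates, so the condensate-localized signal plateaus
above zero. Fits are declared failures (a `FitError`, never a silent result)
when the amplitude does not stand clear of the residual noise (amplitude ≤
3×RMSE), the rate is nonpositive, or the implied half-life exceeds 50× the
observation window. The half-life standard error is a bootstrap over traces.

## Synthetic benchmarks: what they emulate

The generator produces the regimes the pipeline targets, with ground truth
known by construction and all randomness from one seed per call
(byte-identical outputs under identical configs):

- **Puncta scenes** — cells as disks on a jittered grid (geometry is not the
  subject under test); hard-disk puncta at `gain ×` background, placed fully
  inside cells with ≥2 px separation; a per-cell share `coloc_fraction`
  (rounded to the nearest count) of A-puncta co-placed in channel B, the
  remaining B-puncta placed disjoint from all A-puncta so the per-cell truth
  is exact. Additive Gaussian noise, clipped at zero. Defaults: 9 cells of
  radius 40 px in 512², 5 puncta/cell, 5× gain, background 100, noise SD 10.
- **Translocation pairs** — one disk cell whose edge ring (same definition
  as the analysis) is painted at `enrichment × base`; the noiseless
  edge/core mean ratio equals the configured enrichment exactly.
- **KTR datasets** — default 150 starting cells in a 1024-px arena, 22 h at
  5-min frames, bounded random-walk motility (2 px/frame), baseline ratio
  1.0, raised-cosine pulses of amplitude 1.0 and duration uniform in 10–20
  min, Gaussian trace noise SD 0.05. Basal pulse rate 0.15/cell/h (≈3
  pulses per cell over 22 h, matching sporadic pulsing under kinase
  inhibition); death rate 0.02/cell/h (≈90 events per ~200 cells over 22 h,
  the scale of the imaging experiments this emulates); division rate
  0.01/cell/h; neighbor pulse rate 0.75/cell/h (5× basal) applied during the
  10 frames preceding a death to cells within 100 px of the dying cell.
  Divisions end the parent track and spawn two daughters whose output traces
  duplicate the full parental history (and inherit expression); dividing
  cells receive one division-proximal artifact pulse within the 9 frames
  before division. Reporter expression is lognormal (mean 1.0, σ 0.25) with
  a 10% low/zero-expressing subpopulation below the QC cutoff.

  Two deliberate benchmark conventions make the pulse labels well-defined:
  pulse peaks are only emitted ≥2 frames inside a cell's observed span,
  because a boundary-censored peak cannot be a local maximum of any trace
  and carries no usable label; and pulses of one cell are separated by at
  least one maximal pulse duration (a refractory gap), because two 10–20-min
  bumps 10 min apart merge into a single excursion and are not distinct
  countable events.
- **Decay traces** — `offset + amplitude · 2^(−t/t½)` plus Gaussian noise,
  default 20 traces of 90 min at 5-min intervals, offset 0.2, amplitude 1.0,
  noise SD 0.05.

**Limitations.** The scenes are deliberately minimal: disk cells, hard-edged
puncta, additive Gaussian (not Poisson-Gaussian) noise, no photobleaching,
no segmentation or tracking errors, no focus drift, and pulses of a single
amplitude (the amplitude distribution of real pulses is unknown and exposed
as a parameter rather than asserted). Passing the benchmarks therefore
demonstrates the correctness of the algorithms against their specifications
and their statistical calibration — not robustness to the full failure modes
of real microscopy, where the sensitivity parameters must be re-calibrated
and segmentation quality dominates.

## Numerical and procedural choices

- Coordinates are 0-based (row, col); connectivity defaults to 8 for both
  seeding and growth; seed conflicts are resolved by descending enhanced
  intensity with (row, col) tie-breaks, and a seed inside an already-grown
  cluster is skipped.
- Peak ties on plateaus follow the `scipy.signal.find_peaks` convention;
  sampled traces with continuous noise make this a measure-zero concern.
- Degenerate inputs raise typed errors rather than returning silent values:
  dark cells (non-positive median), rings that consume the whole cell, zero
  wild-type medians, constant decay traces, cyclic lineages, non-uniform
  sampling, and impossible punctum placements (bounded retries, then a
  placement error).
- Problem sizes in the test suite and acceptance script (200 oracle images,
  3 benchmark scenes, 20 replicate KTR datasets per condition, 500 bootstrap
  calibration replicates, 20-trace decay ensembles) were chosen as the
  smallest ensembles at which the measured quantities are stable to well
  within their acceptance tolerances.
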