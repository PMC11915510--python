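# Methods

`nucleoquant` quantifies the subnuclear trafficking of a nucleolar-enriched
protein (the motivating case is the BER endonuclease APE1, endogenously
mEGFP-tagged in mouse embryonic stem cells) and the in vitro phase-separation
behaviour of the purified protein.  Five image-analysis pipelines and a set of
biophysical utilities share one raster substrate and are exercised end to end
on a bundled synthetic-scene generator with closed-form ground truth.

## Raster substrate

All images are canonicalized to a `(t, z, c, y, x)` array with singleton axes
for absent dimensions, so 2D fields, 3D confocal stacks and time-lapses run
through one code path.  Intensities are processed in floating point; the file
dtype is recorded for lossless round trips.  Flat-field correction divides by
a gain image normalized to mean 1 (mean-preserving); estimating the gain is
out of scope — it is an input, as it is an instrument property.

## Nucleus segmentation

Real deployments of these pipelines typically use trained models (Cellpose,
Ilastik) for nuclei.  Trained weights are not distributable here, so the
package provides (a) a deterministic classical segmenter — normalize, Gaussian
smooth (`smooth_sigma` = 2 px), Otsu, hole fill, distance-transform watershed
with markers at > 0.6 of each component's distance maximum, minimum size
200 px (2D) / 2000 voxels (3D) — and (b) an ingestion contract for integer
label TIFFs exported from any external model.  Normalizing first makes the
label result invariant to global intensity rescaling.  Connectivity is
4-connected in 2D and 6-connected in 3D throughout.

## DNA-damage focus counting

The focus channel of a maximum projection is filtered with a
Laplacian-of-Gaussian (sigma 3 px), thresholded at the image mean plus
1.5 standard deviations of the filtered response, binarized, opened with a
3x3 structuring element of ones, and labelled 8-connected; foci are assigned
to the nucleus containing their centroid.  Two sign conventions exist for the
LoG of a bright blob; the response is negated by default so spot cores are
positive and the mean + k*SD rule selects them (`log_sign="literal"` keeps
the raw filter).

The threshold is a *whole-image* statistic, so it adapts to image content:
in focus-dense fields the spot response dominates the image SD and the
threshold sits far above the noise floor, while in nearly empty fields it
approaches mean + 1.5 SD of pure noise and excursion blobs of a smooth noise
field will survive the 3x3 opening.  Consequences adopted here: a
zero-variance (constant) image short-circuits to zero foci with a warning,
and a per-nucleus threshold scope is available (`threshold_scope="nucleus"`)
for sparse fields.  Nuclei touching the image border are excluded from
per-nucleus statistics by default and flagged, since their focus complement
is unobservable.

## Nucleolar substructure and nascent RNA

In 3D stacks, the dense fibrillar component (DFC) is the Otsu foreground of
the fibrillarin channel computed over nuclear voxels only, refined by binary
opening (radius 1) and re-intersected with the nucleus.  Fibrillar centres
(FCs) are watershed basins on the inverted UBF channel: seeds are
difference-of-Gaussian maxima (sigmas 1 and 2 px) inside the DFC whose
response exceeds the mean + 1 SD of the DoG maxima found in the nucleoplasm
(nucleus minus DFC) — a reference distribution that suppresses background
puncta — and the flood is confined to the UBF Otsu foreground intersected
with the DFC, which acts as the spatial stop criterion and enforces the
containment chain FC ⊆ DFC ⊆ nucleus by construction.  Every surviving seed
yields exactly one basin, so the label count equals the seed count.

Nascent transcription is read out as the mean EU intensity over the union of
each cell's FC voxels; cells without FCs carry a missing value (never zero).
Group values are normalized to the control-group mean, making the readout
invariant to global intensity scale.

## Live-cell ratio tracking and onset statistics

Nucleoli are detected in nucleus-masked phase contrast as dark compact
objects: smoothed, inverted, Otsu-split per nucleus.  A bimodality gate (the
Otsu between-class/total variance ratio must exceed 0.6) prevents splitting a
unimodal noise histogram into a fictitious nucleolus; nuclei failing the gate
are recorded with missing ratios.  Dying/dividing cells are excluded by
feature rules (default of interest: frame-to-frame area collapse > 40%);
exclusion removes the whole trajectory and cannot alter other cells'
measurements.  Identity over time uses maximum mask overlap with the previous
frame, ties broken toward the larger overlap then the lower label.

The per-frame readout is mean fluorescence over the nucleolus divided by mean
fluorescence over its parent nucleoplasm (nucleus minus nucleoli) — invariant
to any linear rescaling of a frame.  Group divergence is tested with the
split-plot ANOVA (within factor: frame; between factor: treatment group;
subjects: nucleoli with complete tracks, incomplete tracks dropped and
counted) via `pingouin.mixed_anova`, with an optional Greenhouse–Geisser
correction (off by default).  Post hoc, the group contrast at each frame uses
the Tukey HSD studentized-range statistic with the family taken as *all*
frame-by-group cell means (Tukey–Kramer, pooled within-cell error).  The
family choice is load-bearing: an unadjusted 5% test per frame would flag a
pre-onset frame with probability ~1 − 0.95^36 ≈ 0.84 over 36 pre-onset
frames, making "earliest significant timepoint" meaningless; the all-cells
family controls that familywise error.  A plain per-frame Tukey HSD remains
available (`posthoc="per_frame"`).  The onset is the earliest frame whose
adjusted p-value clears alpha, reported only when the interaction or group
main effect is itself significant.  With noiseless input the F statistics are
undefined (0/0); the result is flagged degenerate rather than significant.

## Droplet assay quantification

Droplets are segmented from the protein (488) channel with an adaptive
local-mean (Bradley) threshold: foreground where intensity ≥ k times the mean
over a 99x99 mirror-padded window, with k = 2·(1 − sensitivity) so the
default sensitivity 0.4 demands 120% of the local mean.  The referenced
adaptive-threshold routine's exact formula is proprietary; this standard
published local-mean rule with one free parameter mapped onto the stated
sensitivity is used instead, and both k and the rule are configurable.
Speckles are removed symmetrically: foreground components and background
holes smaller than 5 px.  The condensed fraction is the exact pixel-count
ratio of mask to image.  Partition ratios divide each droplet's mean
intensity by the mean over all non-droplet pixels (computed once per field);
probe (647) ratios reuse the 488-derived mask.  Max-normalization of
condensed fractions across a dose series is provided as a separate,
presentation-only helper; raw values are authoritative.

Two operating limits follow from the local-mean rule and are deliberate:
objects wider than the window cannot exceed their own local mean and are
missed (droplet radii here are ≤ 25 px against a 99 px window), and
segmentation-channel noise must keep P(background > 1.2·local mean) small —
roughly sigma ≲ 0.07·background.  Measurement noise on the quantified
channel is benign by comparison (tested at contrast/sigma = 5).

## Biophysical utilities

- Chemical-shift perturbation: Δδ = sqrt(ΔδH² + (0.2·ΔδN)²).  Residues are
  flagged on binding when they lose more than 2/3 of their free-state peak
  volume, or when Δδ strictly exceeds the mean over all usable peaks; the two
  criteria are reported separately.  Zero-free-volume records are skipped
  with a warning.
- Concentration: c = n / (N_A · V), 1 μm³ = 10⁻¹⁵ L, reported in μM.
  Applied to published copy numbers (0.35–7 × 10⁶ molecules) and mammalian
  cell volumes (1198–2425 μm³) this brackets ~0.2–10 μM at one significant
  figure.
- Isoelectric point: Henderson–Hasselbalch net charge over termini and
  ionizable side chains (D, E, C, Y negative; K, R, H positive), solved by
  bisection on pH ∈ [0, 14] to |Z| < 10⁻⁴.  Two pKa sets ship (EMBOSS-style
  and Bjellqvist-style); pI values depend on the set by a few tenths of a pH
  unit, so cross-tool comparisons carry ±0.3 tolerance.
- G-quadruplex scan: exhaustive enumeration of windows matching
  G^g N* G^g N* G^g N* G^g with equal tract size g ≥ 2 (configurable), total
  length ≤ 20 nt, loop length ≥ 0.  Overlapping candidates are collapsed by a
  deterministic greedy rule — largest g, then shortest window, then smallest
  start — which approximates "highest-scoring per locus" without reproducing
  any external scoring formula (scoring is a pluggable hook).  Retained hits
  never overlap; per-region counts use the hit start against user-supplied
  half-open intervals.

## Synthetic scenes and what they do (not) show

The generator paints ellipse/ellipsoid nuclei with smooth multiplicative
texture, hard-edged subcompartments, Gaussian foci, and additive Gaussian
read noise (optional Poisson), all from one explicit seed; outputs are
byte-identical across calls.  Every expected metric is a closed-form function
of the object parameters: programmed counts, the condensed fraction
Σπr²/area, partition ratios, and the depletion law
r(t) = 1 + (r0 − 1)·e^{−(t−t0)/τ} with total nuclear intensity held exactly
constant per frame (signal redistributes rather than disappears).  Reference
conditions mirror the motivating study: nucleolar enrichment r0 = 1.4 (~40%
above nucleoplasm), 5-minute frame interval, a 40% FC-EU reduction as the
treatment effect size, and focus recovery at sigma 3 px / SNR 10.  Two
consistency rules keep truths exact: the UBF marker fills the same FC
ellipsoid that carries the programmed EU level (optical blur is applied to
marker channels only, never the EU channel), and FC ellipsoids are placed
strictly inside the DFC ellipsoid (centre norm + worst-axis extent ≤ 0.98 in
DFC-normalized coordinates) so no painted voxel is ever clipped.

What passing on these scenes does *not* show: robustness to the textures,
debris, chromatin heterogeneity and optics of real micrographs (no PSF beyond
light Gaussian blur, no camera calibration, no drift or bleaching), nor
equivalence with the trained segmentation models used on real data — the
classical nucleus/nucleolus detectors will differ from Cellpose/Ilastik
outputs on real images, which is why external-mask ingestion exists.
Acquisition noise levels of the original raw data are unpublished; synthetic
SNR ranges were chosen for test coverage, not fidelity.

## Problem sizes and numerical choices

Validation runs use 50 nuclei × 5 foci (1024² px), 20 cells per group for the
EU readout (two 12×288×384 fields per group), 1000 null replicates of
2 groups × 10 nucleoli × 8 frames for the type-I check, one 60-frame
two-group time-lapse (8 cells each, onset at frame 36, τ = 10 frames) for
onset recovery, and 10-droplet 512² fields at enrichments 2/5/10.  Ties are
broken deterministically everywhere (raster order for watershed seeds and
labels, lowest label for tracking); degenerate inputs (constant images,
zero-variance statistics, empty control groups) warn or raise rather than
propagate NaNs silently.  Bisection tolerance for pI is 10⁻⁴ charge units;
the G4 enumerator is exact, verified against an independent regex-engine
oracle.

## Known limitations

- The classical segmenters are stand-ins behind the same contract as trained
  models, not replacements for them on real data.
- The whole-image focus threshold under-performs on sparse fields (see
  above); per-nucleus scope is the mitigation, at the cost of deviating from
  the reference procedure.
- The repeated-measures ANOVA assumes complete tracks and, by default,
  sphericity; per-nucleolus entries pseudo-replicate cells unless aggregated
  (cell ids are retained for that purpose).
- G4 counts approximate, but do not guarantee, the output of score-based
  external tools: the collapse rule is a deterministic proxy for score
  ranking, and published per-region counts additionally depend on the exact
  reference sequence used.
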