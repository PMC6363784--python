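# Methods

`microtma` re-implements, as a tested pipeline, the image-quantification
workflow used for drug studies on heterotypic glioblastoma BrainSphere
(gBS) cultures arrayed in spheroid tissue microarrays (microTMAs). The
original measurements were made on confocal/whole-slide scans of
patient-derived material that is not publicly deposited, so the package
pairs the analysis code with a synthetic-image generator that emulates the
statistical structure of those images and provides exact ground truth.
Every claim the test suite makes is therefore a claim about recovery of
known truth under the generator's model, not about any particular
instrument's data.

## The measurement model

A dual-immunofluorescence spheroid section is represented as three
registered 2D channels on a common pixel grid: a nuclear counterstain
(Hoechst/DAPI), a red channel carrying the anti-GFP tumor-cell stain, and a
green channel carrying a proliferation (Ki67) or apoptosis (cleaved
caspase-3) marker. Quantification proceeds exactly as in classical
threshold-based cytometry of such sections:

1. **Nucleus detection.** The nuclear channel is band-pass filtered with a
   Difference of Gaussians, `DoG = G(σ_small) − G(σ_large)`. Cell centres
   are strict local maxima of the response above a threshold (by default a
   fraction 0.1 of the response maximum), kept greedily in decreasing
   response order subject to a minimum pairwise separation.
2. **Per-cell measurement.** Around each centre, the mean intensity of the
   red and green channels is taken over the disc of the cell radius
   (default 10 µm), clipped to the image bounds for edge cells.
3. **Classification.** A cell is *tumor* if its red disc mean is strictly
   above the red threshold, *marker-positive* if its green disc mean is
   strictly above the green threshold; ties are negative. Thresholds are
   either fixed values or Otsu's threshold computed on the distribution of
   per-cell means of that spheroid, which adapts to per-spheroid staining
   variability.
4. **Endpoints.** Per spheroid: (1) tumor cells as % of all cells,
   (2) marker-positive tumor cells as % of tumor cells, (3) marker-positive
   normal cells as % of normal cells. Percentages with a zero denominator
   are reported missing, never as 0. Because published dose–response panels
   are sometimes normalised to all cells instead of the compartment, the
   `*_of_total` variants are carried alongside; the compartment-normalised
   definitions are primary.

### Parameter choices

| parameter | default | rationale |
|---|---|---|
| `cell_radius_um` | 10 | radius of the averaged cell area |
| `dog_sigma_small_um` | `cell_radius/4` = 2.5 | matched to the rendered nuclear core (σ ≈ 2.5 µm). The band must sit at the *nucleus* scale: in confluent tissue, centres approach one nucleus radius apart, and a DoG at the cell scale (e.g. `r/√2`) low-passes the packed carpet into a near-uniform field whose ripple falls below any usable threshold — measured as a −75% count error at 1000 cells/section before this choice. |
| `dog_sigma_large_um` | `1.6·σ_small` | standard DoG bandwidth ratio |
| `min_center_distance_um` | `cell_radius/2` | one detection per nucleus without suppressing true neighbours at contact spacing (a full cell radius would) |
| `detection_threshold` | 0.1 of DoG max | above the noise floor of the smoothed background at the default noise level, below the interior-ripple amplitude of dense sections |
| threshold modes | `otsu` | the distribution of per-cell means is strongly bimodal in both channels under the rendering model |

Pixel size defaults to 0.5 µm/px (a typical 20x scan); µm quantities are
converted to pixels by division with round-half-up.

## The synthetic generator

`generate_section` emulates one gBS section:

* **Geometry.** Cells occupy a disc of 350 µm diameter. Centres are placed
  on a randomly rotated, randomly offset hexagonal lattice whose spacing
  adapts to the requested cell count, with uniform jitter bounded so the
  minimum separation of one nucleus radius (10 µm) is guaranteed. A lattice
  is used instead of dart throwing because random sequential placement
  saturates near ~55% of hexagonal capacity and cannot reach the
  near-confluent densities (up to ~1000 cells/section) the analysis must
  tolerate; confluent tissue is in fact near-packed. Requests beyond lattice
  capacity raise an error naming the capacity.
* **Labels.** Exactly `round(tumor_fraction · n)` cells are tumor, chosen as
  the cells nearest 1–3 seeded focus centres (compact foci, mirroring the
  spherical high-cellularity morphology of the tumors). Marker-positive
  cells are exactly `round(frac · compartment size)` per compartment,
  assigned as a compact cluster around a seeded anchor cell of that
  compartment. Clustering is the realistic choice — proliferation and
  apoptosis are regional — and it is also what makes disc-mean thresholding
  well-posed at contact packing, where the 10 µm measurement disc overlaps
  neighbouring cells: with independently scattered positives, bleed from
  positive neighbours into a negative cell's disc rivals a positive cell's
  own signal and no threshold separates the classes.
* **Rendering.** Nuclei are Gaussian blobs of σ = `nucleus_radius/4`
  (≈ 6 µm FWHM — the stained nucleus, not the whole cell); red and green
  stains are wider Gaussians (σ = `nucleus_radius/2`) at tumor and
  marker-positive cells respectively. Channels get a constant background
  (10), peak amplitudes of 200, additive Gaussian noise (σ = 10) and are
  clipped at zero. The noise level and intensity scale are free parameters
  of the emulation, not claims about any instrument.
* **Determinism.** All randomness flows from one `numpy` `Generator` seeded
  by `SectionParams.seed`; identical parameters give bit-identical images
  and ground truth.

`generate_tma_slide` renders each occupied grid spot as a full section
(per-spot seed derived from the slide seed and grid coordinate) pasted
centred on its node into a noisy background canvas, so a dearrayed crop is
pixel-identical to the same spheroid rendered alone. Spot pitch must exceed
the spheroid diameter; section margins are capped at the pitch cell.

`generate_spectral_stack` applies the exact linear forward model
`spectrum = E @ (abundances, AF)` per pixel, giving the unmixer a sharp
oracle. `generate_viability_plate` draws replicate resazurin readings from
`Normal(mean, sd)` per dose.

### What the generator does not emulate

No optical PSF, no 3D structure, no Poisson (shot) noise, no illumination
gradients or staining artefacts, no irregular cell shapes, no rotated or
sheared TMA grids. Passing tests show the algorithms recover truth under
this model at realistic densities and SNR; they do not certify performance
on real scanner output, where threshold choice and debris rejection are the
fragile steps.

## Spectral unmixing

Pixel spectra are decomposed against an endmember matrix (one column per
fluorophore plus one autofluorescence column named `AF`) by nonnegative
least squares — abundances are concentrations. Columns are L2-normalised
internally and abundances rescaled back, so spectra files may store
unnormalised shapes. The implementation solves the unconstrained batched
least-squares first and re-solves only the pixels whose solution goes
negative with true NNLS; on noise-free in-span stacks the fast path is
exact. The AF abundance is computed — so it absorbs the autofluorescence
signal — and then discarded. Because NNLS over a superset of columns never
fits worse, adding the AF column cannot increase any pixel's residual. The
vendor's actual unmixing algorithm is proprietary; linear NNLS is a
functional emulation, not a claim of equivalence.

## Dearraying

Spots are found on the nuclear slide channel by Gaussian smoothing
(σ = min spot diameter / 8), Otsu thresholding, and 8-connected component
analysis, keeping components whose equivalent diameter lies within
configured bounds (defaults 150–600 µm around the 350 µm spot size). The
smoothed image is capped at its 99th percentile before computing the
threshold so a small bright artefact cannot drag it above the tissue level.
Detections are assigned to the nearest expected grid node within half a
pitch — an unambiguous partition of the plane — with contention resolved in
favour of the nearer detection; unmatched nodes are reported missing, not
raised, since TMA sections routinely lose spots. Grid rotation/shear
estimation is out of scope.

## Statistics

Treatment arms of per-spheroid endpoints are summarised as box plots with
type-7 (linear interpolation) quantiles and Tukey fences at `Q ∓ 1.5·IQR`;
outliers are strictly outside the fences. Comparisons against control use
the two-sided Welch t-test (arms need not share variance), with the effect
reported as percent change of medians. Resazurin plates are normalised to
percent of the control mean, analysed by one-way ANOVA across dose groups,
and followed by pairwise Welch tests versus control with Bonferroni
adjustment (p multiplied by the number of comparisons, capped at 1). No
multiplicity correction is applied across spheroid endpoints. Degenerate
inputs have explicit conventions: identical constant groups give t = 0,
p = 1; distinct constant groups raise with a pointer to exact alternatives;
an all-identical plate gives F = 0, p = 1.

Known limitation: Otsu auto-thresholding assumes both classes are present.
A section with a truly zero marker fraction splits the negative
distribution and overcalls positives; use a fixed threshold when a channel
may be globally empty.

## Problem sizes used in the checks

The recovery harness runs at the study's design points: sections of
200–1000 cells; 8×12 slides (96 spots, one deliberately absent) at
1 µm/px; dose arms of 16 spheroids at tumor-cell factors 0.7 and 0.2 of a
200-tumor/200-normal control, five seeds; four-dose marker sweeps
(tumor 0.10→0.60, normal 0.01→0.10) with 8 spheroids per dose; 10⁴ null
simulations at n = 32/group for t-test calibration; and a full six-arm,
96-spot end-to-end run executed twice to confirm byte-identical tables.
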