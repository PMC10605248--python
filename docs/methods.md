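# Methods

This note documents the models behind `lenscope`, the parameters that
matter, the numerical choices, and what the synthetic generators do and
do not emulate.

## Optical model of the spheroid z-stack

The generator treats a transparent spheroid as a thin converging element
under a geometric defocus cone, not wave optics. Each slice at objective
position z (µm; z = 0 at the microscope focus, negative below the sample)
is a constant background `background_b` plus, inside a central disk of
radius `spheroid_radius` (px), a radially symmetric Gaussian spot

    sigma(z) = sigma0 + cone_slope_s * |z - z_f|          [px]
    A(z)     = spot_flux_F * (1 - opacity_tau) / (2 * pi * sigma(z)^2)

so the slice-integrated flux above background is conserved in z (up to
truncation at the disk edge and 16-bit quantization; tests bound this at
2%) and the peak amplitude is maximal exactly at the focal plane `z_f`.
This is the minimal model that produces the phenomenology the focal-ratio
measurement needs — one bright central spot at one z, melting away on
either side — and nothing more. Opacity enters as the multiplicative flux
attenuation (1 − τ), τ ∈ [0, 1]: the simplest monotone link between a
cataractogenic dose and lost focusing. τ = 1 transmits nothing and is
pixel-identical to a zero-flux stack.

Defaults: 256×256 px, 21 slices over z ∈ [−100, 0] µm, z_f = −50 µm,
b = 1000, F = 2·10⁶, σ₀ = 4 px, s = 0.3 px/µm, disk radius 60 px. The
acquisition step and slice count of real stacks are free parameters; the
defaults give a 5 µm step. Noise is `none`, `poisson` (per-pixel shot
noise) or `gaussian` (additive, `noise_sd`). Slices are quantized to
uint16 with clipping, matching common camera output.

Two fields exist purely for the measurement pipeline: `disk_transmittance`
(default 1.0) darkens the disk interior so that segmentation has an
object to find — the pipeline's default run uses 0.85; and the image side
may be odd, which puts a pixel exactly on the optical axis so the peak
pixel equals the closed form A(z) (used by the exactness tests; with an
even side the peak pixel sits half a pixel off-axis, a ~1.5% effect at
σ₀ = 4).

What this does **not** emulate: a real point-spread function, refraction
through a sphere, multi-spheroid fields, uneven illumination, or camera
artefacts. Passing optics tests therefore demonstrate correctness of the
measurement code under the stated model, not robustness to real-world
imaging pathology.

## Focal-ratio measurement

Per slice, R(z) = max(center ROI) / mean(background region). The ratio is
oriented max/mean — values well above 1 indicate focusing — and the
background statistic is the mean, not the median. R is invariant to
global intensity rescaling, and a constant offset moves R toward 1 but
never past it.

ROI placement: the spheroid is segmented on a reference slice by Otsu
thresholding of the |deviation from the slice median|, after a σ = 1 px
Gaussian smooth and a log1p compression (without the compression a very
bright focal spot forms its own Otsu class and the disk is lost; without
the smooth, shot noise percolates into the mask). Largest connected
component, holes filled; if nothing reaches `min_area` (64 px) the
segmentation falls back to the image centre and flags `no_object`. The
centre ROI is a square of half-side 10% of the segmented radius (original
ROI sizes are not standardized in the field; this is a package choice);
the background is a border band of the frame excluding the mask dilated
by a factor 1.2. Manual ROIs are accepted everywhere.

Summaries: peak ratio, the z attaining it (ties broken toward smallest
|z|), and a boolean `focuses_light` at threshold 1.2 (i.e. a 20% margin
over unity; configurable). Condition comparisons report **both**
aggregations — mean ± sd of per-organoid peak ratios, and the per-z
mean ± sd curve — because published dose-response figures can be read
either way; the Spearman correlation of peak ratio against numeric dose
is the trend statistic. Degenerate inputs raise: zero background mean
(measurement undefined), out-of-bounds or overlapping ROIs, empty
condition groups.

An auxiliary `grid_contrast` metric (Michelson contrast of the 5th/95th
percentiles) is provided for macroscopy images; it is a convenience
score, not one of the study readouts.

## Count model and differential expression

Counts are NB-distributed: count ~ NB(mean = s_i · q_g · 2^δ(g, group),
dispersion α), with q_g log-normal (`baseline_log_mean_mu` = 3.0,
`baseline_log_mean_sd` = 1.5, natural-log scale), s_i scaling each sample
to a target library drawn uniformly from `library_size_range`
(default 0.5–1.5 M reads), a single common dispersion α (default 0.1,
typical for bulk RNA-seq of cell-line material), and δ the planted log2
fold (0 unless the gene belongs to a planted set affecting that group).
Defaults mirror the study design this package targets: a 10,320-gene
universe, and groups 2D/3D/external/lens/WB with 3 samples and internal
with 4. `shared_enriched_fraction_rho` plants 10% of the genome as
lens-enriched and 10% as 3D-enriched with a fraction ρ shared, creating
the cross-dataset overlap signal for the sweep. A common dispersion
(rather than per-gene) is deliberate: at n = 3–4 per group, per-gene
moment estimates are too unstable to be useful, and the DE test assumes
the same structure.

The generator does not emulate: gene–gene correlation, GC/length bias
(3′-end counting is length-free by design), batch effects, outlier
samples, or per-gene dispersion trends. Calibration results below are
therefore statements about the procedure under NB sampling, not about
concordance with any particular real dataset.

The DE procedure (a self-contained stand-in for count-model packages,
with every step specified):

1. **Filter**: keep genes with mean CPM across the contrast's samples
   > 0.2. The mean over all samples is the aggregation rule (the simplest
   symmetric choice; "expressed in k of n samples" variants are not
   implemented).
2. **Normalize**: median-of-ratios size factors over genes positive in
   all samples, rescaled to geometric mean 1; fallback to library-size
   ratios when no such gene exists.
3. **Dispersion**: per gene, the pooled within-group variance v̂ (df =
   n_A + n_B − 2) and mean m̂ of normalized counts give a moment estimate
   (v̂ − m̂)/m̂²; the common α̂ is the median over genes of its positive
   part, floored at 10⁻⁸. Because a median across genes is taken, v̂ is
   first divided by the median of χ²_df/df (≈ 0.891 at df = 6): the
   pooled variance is mean-unbiased but median-biased low at small df,
   and without this factor α̂ comes out ~15% low and the Wald test runs
   visibly anticonservative (null p < 0.05 fraction ≈ 0.065 instead of
   0.050 at n = 4 vs 4). With it the estimator is median-unbiased and
   the test calibrates.
4. **Test**: W = (ln μ̂_A − ln μ̂_B)/SE, SE² = Σ_j (1/μ̂_j + α̂)/n_j,
   two-sided normal p-value; BH step-up FDR (via statsmodels, verified
   in tests against the literal step-up definition).
5. **Calls**: up_A iff FDR < 0.05 and log2FC > 1 (symmetric for up_B).
   The strict preset (FDR < 0.01) matches the tighter threshold used for
   headline DEG counts in this literature; both thresholds are recorded
   in the result object.

Conventions for degenerate genes: the fold change uses a 0.5 pseudocount
(fold change only, never the test) and is computed as a difference of
logs so swapping groups negates it bit-exactly; a gene with both group
means zero gets p = 1 and log2FC = 0; a single zero group mean is
replaced by 0.5/n_j (half a count spread over the group) so the log and
SE remain defined without breaking swap symmetry.

Measured behaviour at the design scale (recomputed by the test suite and
`scripts/acceptance.py`, never hard-coded): null fraction of p < 0.05
≈ 0.050, zero BH discoveries at FDR 0.05 on 10,320 null genes,
KS distance to uniform ≈ 0.01–0.03; sensitivity ≈ 0.97 and realized FDP
≈ 0.05 for 200 genes planted at |log2FC| = 2 with baseline CPM ≥ 5.

## Enrichment ranking and overlap sweep

Enrichment scores e_g = log₂((m_t + c)/(m_r + c)) over mean CPM with
pseudocount c = 1 CPM (configurable); rank 1 is most enriched, ties break
deterministically by gene id (stable sort). Reference scores produced
elsewhere (e.g. a curated lens-enrichment database) can be supplied as a
ranking TSV; the module treats them as given numbers.

The sweep takes K = ⌊xN⌋ (so the published "top 10% of 10,320 = 1032" is
reproduced exactly) for x on a default grid of 0.25% steps over (0, 10%],
reports O(x), E(x) = K²/N, the intersection gene list, and the exact
hypergeometric upper tail. The tail is summed in log space from the pmf
via log-gamma, exact to ~10⁻¹⁰ relative against rational-arithmetic
summation and stable at magnitudes like 10⁻²². Two conventions are
exposed because published overlap p-values use either: `greater`
(P(X > O); the default — it reproduces the published headline value at
the printed counts) and `greater_or_equal` (P(X ≥ O), a factor ~2.4
larger there). The identity P(X ≥ O) = P(X > O − 1) holds exactly by
construction. No multiple-testing correction is applied across the sweep
grid; single-x p-values are reported as in the source figures.

One statistical caveat is built into the tests rather than glossed over:
"observed ≥ expected uniformly over the grid" is only a meaningful
property where E(x) ≥ 1; below x = 1% the expectation is a fraction of a
gene while O is an integer, so the property is asserted for x ≥ 1% only.

## Regional concordance

DEGs from the internal-vs-external contrast are annotated with their
reference identity (FC, LEC, neither, or ambiguous if present in both
reference sets — ambiguous genes are dropped with a report, since the
2×2 design requires exclusive identity). The 2×2 chi-squared uses the
closed form with df = 1; continuity (Yates) correction is off by default
with a flag to enable — published chi-squared values in this literature
rarely state the choice, so neither can be assumed. Expected counts
row·col/n are carried alongside observed counts ("the value in
brackets"). A zero row or column margin is an input error (the statistic
is undefined). The overlay analysis reports every DEG's (log2FC, FDR,
identity) with mean log2FC per identity and a Mann–Whitney rank test
between FC- and LEC-labelled fold changes.

The synthetic reference sets assign each planted internal-up gene to FC
with probability `concordance_rate` (default 0.8) and to LEC otherwise,
and symmetrically for external-up genes — an imperfectly concordant
reference atlas. Real headline counts (a specific DEG total, a specific
concordant fraction, a specific p-value) require the original deposited
datasets and are out of scope; the tests instead verify null calibration
(uniform p over random assignment) and power (p < 0.01 detection of the
80% planted concordance in ≥ 99% of runs).

## Pipeline and reproducibility

`lenscope run` executes simulate-counts → simulate-stacks → optics → DE →
enrichment → overlap → concordance → report. All randomness derives from
one seed via per-stage SHA-256 children (each below 2³¹), so a fixed seed
and config give byte-identical tables; the manifest records the seed, a
config hash, and a SHA-256 digest per output. The default run uses the
full design scale (10,320 genes; 4 opacity doses × 12 stacks at 256 px)
and completes in a few seconds; the test suite uses the same scale for
acceptance-style checks and reduced sizes (≈ 2000 genes, 96 px stacks)
for orchestration tests, which is ample to exercise every code path.

## Known limitations

- The optical model is geometric; no refraction, diffraction or PSF.
  Conclusions about the measurement code do not transfer to claims about
  real organoid optics.
- The common-dispersion NB Wald test is designed for n = 3–4 per group
  with a shared dispersion; it is not a general-purpose replacement for
  mature DE frameworks on large or heterogeneous designs, and no attempt
  is made to match any specific framework's output gene-by-gene.
- Enrichment comparison across platforms (RNA-seq vs microarray
  references) assumes the supplied reference scores are comparable as
  given; no cross-platform normalization is attempted.
- Segmentation expects a single dominant object; fields with several
  comparable spheroids are out of scope.
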