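# lenscope

Quantitative analyses for lens-organoid characterization studies.

Lens organoids — self-organized 3-D cultures of lens epithelial cells — are
judged by two kinds of evidence: **physics** (do they become transparent and
focus light like a lens, and do cataractogenic treatments abolish this?) and
**transcriptomics** (does their gene expression resemble the developing lens,
and do their inner/outer regions resemble fiber versus epithelial cells?).
`lenscope` implements the four quantitative readouts used in such studies as
a tested, reusable pipeline, together with synthetic data generators that
plant known structure so every stage can be validated without any external
dataset.

## The statistics at the core

**Focal ratio.** For a z-stack of bright-field images of a spheroid, the
per-slice light-focusing statistic is

R(z) = max intensity in a central ROI / mean intensity of the field around
the spheroid.

A transparent, lens-like organoid shows R(z) ≫ 1 at some objective position
below the focus; an opaque one stays at R ≈ 1. Conditions (e.g. increasing
oxidative-stress dose) are compared by mean ± sd of the per-organoid peak
ratio, with a Spearman trend statistic against dose.

**NB differential expression.** Counts are filtered at mean CPM > 0.2,
normalized by median-of-ratios size factors, and tested per gene with a
negative-binomial Wald statistic

W = (ln μ̂_A − ln μ̂_B) / SE,  SE² = Σ_{j∈{A,B}} (1/μ̂_j + α̂)/n_j,

where α̂ is a common dispersion estimated by a median-unbiased pooled
method of moments. P-values get Benjamini–Hochberg FDR control, and genes
are called differential at FDR < 0.05 and |log₂FC| > 1 (a `--strict`
preset uses FDR < 0.01).

**Enrichment-overlap sweep.** Genes are ranked by a tissue-enrichment score
e_g = log₂((m_target + c)/(m_ref + c)) over mean CPM against a whole-body
reference. For each top fraction x, the observed overlap O(x) between two
rankings' top K = ⌊xN⌋ genes is compared with the independence expectation
E(x) = K²/N, with an exact hypergeometric upper-tail p-value
(X ~ Hypergeometric(N, K_a, K_b); both P(X > O) and P(X ≥ O) conventions are
available) summed in log space so tails of order 10⁻²² are exact.

**Regional concordance.** Region-specific DEGs (internal vs external) are
cross-tabulated against reference fiber-cell (FC) and epithelial (LEC) gene
sets in a 2×2 table and tested with Pearson's chi-squared
χ² = n(ad − bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1, expected counts
row·col/n, optional Yates correction.

## Worked example

```python
import lenscope as L

# exact overlap p-value for 198 shared genes among two 1032-gene
# top deciles of a 10,320-gene universe
p = L.hypergeom_overlap_pvalue(198, 1032, 1032, 10320, "greater")
print(f"hypergeometric upper tail P(X > 198) = {p:.2e}")

# simulate the full study design and run the analyses
sim = L.simulate_counts(L.CountsSimConfig(shared_enriched_fraction_rho=0.2, seed=42))
de = L.nb_de_test(sim.matrix, "3D", "2D")
print(f"{de.n_degs} DEGs ({len(de.genes_called('up_A'))} up in 3D, "
      f"{len(de.genes_called('up_B'))} up in 2D)")

mc = {g: L.cpm(sim.matrix.subset_groups([g])).mean(axis=1) for g in ("3D", "lens", "WB")}
sweep = L.overlap_sweep(L.enrichment_ranking(mc["3D"], mc["WB"]),
                        L.enrichment_ranking(mc["lens"], mc["WB"]),
                        x_grid=[0.01, 0.10])
print(sweep.table.to_string(index=False))

stack = L.simulate_zstack(L.StackSimConfig(seed=0))
curve = L.focal_ratio_curve(stack, L.auto_rois(stack))
s = L.focus_summary(curve)
print(f"peak ratio {s.peak_ratio:.2f} at z = {s.peak_z:.0f} um; focuses_light={s.focuses_light}")
```

prints

```
hypergeometric upper tail P(X > 198) = 8.73e-22
963 DEGs (919 up in 3D, 44 up in 2D)
   x  set_size  observed   expected      p_value
0.01       103        11   1.028004 3.663583e-10
0.10      1032       209 103.200000 3.052829e-26
peak ratio 20.59 at z = -50 um; focuses_light=True
```

The simulated 3-D organoid group carries planted lens-shared enrichment
(rho = 0.2), so the observed overlaps (11 at the top 1%, 209 at the top 10%)
sit far above the chance expectations (1.03 and 103.2) — the same qualitative
picture the sweep produces on real organoid data. The z-stack's focal curve
peaks at the planted focal plane (z = −50 µm) with a ratio of ~21, i.e. the
synthetic organoid focuses light.

## Command line

```bash
lenscope run --seed 7 --out-dir myrun          # full simulate→analyze→report
lenscope simulate-stack --config stack.yaml --out stack.tif
lenscope focal-curve --stack stack.tif --out curve.tsv
lenscope de --counts counts.tsv --meta samples.tsv --a 3D --b 2D --out de.tsv
lenscope overlap-sweep --a rank3d.tsv --b ranklens.tsv --out sweep.tsv
lenscope concordance --de de.tsv --fc fc.txt --lec lec.txt --out cont.json
```

`lenscope run` writes all tables, four report figures (focal curves, volcano,
overlap sweep, contingency table), a Markdown report and a manifest with a
SHA-256 digest of every output; the same seed reproduces every table
byte-for-byte.

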