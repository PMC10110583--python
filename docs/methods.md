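# Methods

## Admixture model and purity/ploidy adjustment

A bulk sample is modeled as a mixture of tumor cells (fraction `PT`, the
purity) and diploid normal cells. If the tumor genome averages `PL` copies
per locus (ploidy) and carries `CN_t` copies of the gene of interest, the
sequencer sees the tumor signal diluted against the normal background. The
observed log2 copy-number ratio and variant allele frequency follow the
forward model

```
CNR_obs = log2( (PT·CN_t + 2(1−PT)) / (PT·PL + 2(1−PT)) )
VAF_obs = AF_true · PT·CN_t / (PT·CN_t + 2(1−PT))
```

and the adjustment equations used by `vhlkit.genomic` are their exact
algebraic inversions:

```
CN_t    = (2^CNR · (2(1−PT) + PL·PT) − 2(1−PT)) / PT
CNR_adj = log2(CN_t / 2)
AF_adj  = VAF · (PT·CN_t + 2(1−PT)) / (PT·CN_t)
```

Assumptions: the contaminating normal compartment is diploid at the locus;
the purity estimate used (consensus by default, ABSOLUTE selectable via
`purity_source`) is unbiased; copy number is uniform within the gene
(per-gene `CN_t`, no sub-gene segmentation). `AF_adj` is the mutant
fraction of tumor-cell gene copies: 0.5 for a fully clonal heterozygous
mutation on a diploid locus at any purity, 1.0 for a clonal mutation with
loss of the other allele.

### Filters, clamping, incompatibility

* Samples: kept only with complete data, consensus purity strictly `> 0.4`
  (`min_purity`), and — when both are present — ABSOLUTE and ESTIMATE
  purity differing strictly `< 0.3` (`max_disagreement`). All threshold
  wordings ("above", "greater/less than") are implemented as strict
  inequalities; equality falls to the lower category.
* `CN_t ≤ 0` (an observed ratio below what pure normal contamination could
  produce) marks the record `removed_incompatible`; `CNR_adj` is undefined
  there.
* Raw `AF_adj` in `(1, 1.1]` is set to 1 with `clamped=True` — measurement
  noise around a truly homozygous (AF 1) mutation lands half its mass above
  1. Raw values `> 1.1` are too far outside the model's range and the
  record is removed as incompatible. The clamp acts only on the adjusted
  value; observed VAF is never modified.
* Variant annotation gates: present in COSMIC, VEP impact above LOW
  (MODERATE or HIGH), and observed VAF strictly `> 0.1`. A missing
  annotation fails its gate (conservative drop) and is logged.

### Clonality categories

`AF_adj > 0.9` → clonal with LOH; `0.4 < AF_adj ≤ 0.9` → likely clonal;
otherwise subclonal. For copy number the reference lines −1.1 (two-copy
loss) and −0.4 (one-copy loss) partition `CNR_adj`. These lines are
*empirical display references*, not derived values: under the adjustment a
fully clonal one-copy loss maps exactly to −1.0 and a clonal two-copy loss
to −∞, so the lines bracket the realistic noisy range rather than the
idealized limits. Both thresholds and lines are configurable.

### Density summaries

`cohort_density` evaluates a Gaussian kernel density explicitly as a
mixture of normals on a 512-point grid spanning the data range ± 3
bandwidths. The default bandwidth is Silverman's rule
(`0.9·min(sd, IQR/1.34)·n^(−1/5)`); an explicit bandwidth keeps the curve
defined even for all-identical inputs, where automatic rules degenerate.
The curve agrees with `scipy.stats.gaussian_kde` at matched bandwidth
(checked in the tests) and integrates to 1 by the trapezoid rule up to the
mass truncated beyond the grid (±3 bandwidths keeps this under 1e-3 for
non-degenerate cohorts). The reported peak is the grid argmax.

### Codon mapping

CDS positions are 1-based; codon index `ceil(pos/3)`, within-codon offset
`(pos−1) mod 3`. Translation uses the standard genetic code; synonymous
changes are labeled with a `=` suffix. A reference-base mismatch against
the supplied codon raises, since it signals inconsistent coordinates.

## Concordance statistic

For each feature with log2 fold changes `x₁…x_k` across `k ≥ 2`
comparisons, `SNR = mean(x)² / max(var(x, ddof=1), floor)`. "Sample
variance" is read literally (`ddof=1`; over 3 values when k=3). The
variance floor (default 1e-8) keeps zero-variance features finite and the
ordering total. Direction is reported separately as the sign of the mean,
since the SNR itself is sign-blind. Features absent from any comparison are
dropped by inner join and counted in the log. Top-k ties break by
|mean log2FC| descending, then feature id, so selections are reproducible.
The identical code path scores per-gene log2FC matrices and gene-set NES
matrices.

Display pipeline: columns are z-scaled (mean 0, sd 1; constant columns
become zeros with a warning) *before* Ward clustering — scale-then-cluster,
chosen so that comparisons with larger fold-change dynamic range do not
dominate the Euclidean distances. Leaf order comes from SciPy's Ward
linkage, which the tests check against a from-scratch minimum-variance
merge enumeration at small n.

The pre-ranked GSEA metric is `sign(log2FC)·(−log10 p)`, falling back to
the log2 fold change itself where no p-value exists (e.g. zero-count
contrasts); `p=1` maps to 0. Single-cell QC keeps cells with total counts
`> 2000`, expressed genes `> 1000`, and mitochondrial percentage `< 20`
(all strict).

The statistic has a known statistical property worth stating plainly: under
the null, `SNR = T²/k` with `T ~ Student-t(k−1)`. For k=3 this t₂ null is
heavy-tailed (survival ∝ 1/x²), so in large feature sets a tail of
null features with lucky small between-comparison variance always competes
with genuinely concordant features of moderate effect. At effect/noise
≈ 6.7 per comparison (effect 2, noise 0.3) and 10,000 features with 200
planted, top-200 selection recovers ≈ 64% of the planted set — the
statistic's honest operating point under those conditions, reported as-is
by the acceptance script. Sensitivity is monotone in effect size (a tested
invariant) and approaches 1 only for very large effects or more
comparisons.

## Spatial profiling

Inputs are classified cell centroids (µm) with boolean markers; no image
processing is performed. The workflow:

1. **Density grid** — cells binned at `cell_size` (default 100 µm), counts
   smoothed with a Gaussian of sigma `bandwidth` (default 200 µm,
   zero-padded). Raw counts conserve the positive-cell total.
2. **Boundary** — iso-contour of the smoothed density at
   `density_threshold` × max (default 0.2), extracted by marching squares
   on a zero-padded grid so all contours close; polygons below `min_area`
   (default one grid cell) are discarded and logged. HALO-style commercial
   pipelines do not disclose their boundary definitions; equivalence at the
   pixel level cannot be asserted, only the procedure's logic.
3. **Signed distance** — Euclidean distance to the nearest boundary edge,
   negative inside the marker-positive region ("toward the inside" of the
   tumor), positive outside, zero on the boundary.
4. **Infiltration profile** — equal-width distance bands spanning
   −`inner_extent` to +`outer_extent` (defaults 2000/4000 µm, 500 µm
   bands). Band areas are geometric: region polygons buffered to each band
   edge (negative offsets erode), clipped to the analysis window, and
   differenced — no raster approximation. The analysis window is the
   bounding box of all cells expanded by `outer_extent`, which makes area
   normalization computable without an external tissue mask; densities are
   counts per µm², undefined (NaN, flagged) for zero-area bands. Cells
   beyond the band span are excluded and counted, so per-band counts plus
   the out-of-band count always equal the positive total.
5. **Co-exclusion** — two phenotypes defined as marker conjunctions are
   profiled over the same bands; the overlap statistic is the Spearman rank
   correlation of the two band-density vectors (≥3 usable bands required),
   with an optional permutation null that shuffles phenotype labels among
   the pooled cells at fixed positions (999 reps by default). Strongly
   negative values mean the phenotypes occupy opposite distance ranges.
   This gives "the two populations do not co-localize" — usually shown only
   graphically — a quantitative form. A property of midrank Spearman worth
   knowing:
   when one phenotype is *exactly* absent from a block of bands, those
   exact-zero ties cap the attainable |ρ| (−0.813 for a 4-inside/8-outside
   layout, derived in closed form and pinned by a test); smoothly graded
   segregation, which is also what stained serial sections show, yields
   ρ → −1.

## Synthetic data

The generators define the study conditions; their defaults were fixed once:

* **Cohort** (`CohortSpec`): 459 samples; purity Beta(2,2) rescaled to
  [0.3, 0.9] (mid-range purities typical of resected ccRCC after the
  consensus filter); ploidy N(2.0, 0.2) clipped to [1.5, 4] (ccRCC is
  predominantly near-diploid); one clone carrying a clonal one-copy VHL
  loss with the mutation on the remaining copy (the canonical two-hit
  configuration); CNR noise sd 0.15 on the log2 scale and VAF noise sd
  0.05, representative of SNP-array/WES segment and allele-fraction
  scatter; purity-method observation scatter 0.03 around the consensus.
  Noise is additive Gaussian on observed CNR and truncated Gaussian on
  observed VAF — the simplest model supporting recovery tests; binomial
  read-depth sampling (`read_depth`) is available as an option. A single
  gene ("VHL") is simulated by default. With zero noise the adjustment is
  the exact algebraic inverse of the generator (tested to 1e-9); with
  noise, `CN_t` estimates are unbiased to within sampling error.
* **Concordance study**: planted features share a fixed signed effect
  across comparisons plus iid noise; nulls are pure noise; p-values come
  from a two-sided normal tail on |log2FC|/noise (monotone in magnitude).
* **Tissue**: inhomogeneous Poisson processes sampled by thinning a
  homogeneous envelope at `lambda_max`; intensities are functions of signed
  distance to a known region geometry. Stock tissues: a disc region with an
  exponential infiltration gradient outside (decay length τ = 1000 µm,
  chosen at the scale of a few cell layers times typical paracrine
  signaling ranges), a co-exclusion tissue with opposed exponential
  interface gradients (τ = 1000 µm), its hard step-function variant, and a
  uniform null tissue.

What the generators do *not* emulate: multi-gene linkage and segmentation
noise structure, purity-estimate biases correlated with ploidy, batch
effects or inter-comparison correlation in expression studies, cell-size
exclusion effects and staining artifacts in tissues. Passing recovery tests
therefore demonstrates correctness of the computations under the stated
models, not robustness to every failure mode of real data.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical outputs (manifest-hash tested).
* Strict inequalities at every stated threshold; equality goes to the lower
  / removed side.
* The variant adjuster joins per-sample-per-gene `CN_t` from the
  copy-number step; variants whose gene lacks a usable copy-number record
  fall back to `default_cn_t = 2` (copy-neutral) and are flagged with
  `cn_t_source = "default"`.
* Ward clustering and leaf ordering delegate to SciPy; tie-breaks follow
  its cluster-index convention.
* Problem sizes in the test suite and acceptance script (10,000 round-trip
  tuples, 459-sample cohorts, ~10⁴-cell tissues, 999 permutations) were
  chosen to make Monte-Carlo assertions stable at the stated tolerances
  while keeping a full run in well under a minute.

## Known limitations

* Per-gene copy number only; no allele-specific copy number, so `AF_adj`
  near 1 cannot distinguish copy-neutral LOH from deletion-LOH.
* Boundary inference depends on `cell_size`/`bandwidth`/threshold; for
  sparse markers the iso-contour is unstable and the estimator raises
  rather than guessing.
* The co-exclusion statistic summarizes band densities, not cell-level
  mixing; fine-grained interdigitation within a band is invisible to it.
* The concordance SNR's heavy-tailed null (see above) limits top-k
  sensitivity for moderate effects at k=3; users wanting calibrated error
  control should treat the ranking as descriptive or add more comparisons.
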