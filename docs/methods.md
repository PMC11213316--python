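# Methods

## Model and procedure

The caller tests, at every CpG probe, H₀: μ_T − μ_N = 0 on the M-value
scale (M = log₂(β/(1−β)); M-values are closer to homoscedastic Gaussian
than β-values, which ordinary linear models assume). The full procedure:

1. **Site-level statistics.** Per probe, ordinary least squares of
   M-values on an intercept, a condition indicator, optional covariates,
   and subject indicators for paired designs. Residual variances are
   shrunk by empirical Bayes: assuming σ_j² ~ s₀²·d₀/χ²_{d₀} a priori and
   s_j² | σ_j² ~ σ_j²·χ²_d/d, the hyperparameters (d₀, s₀²) are estimated
   by matching the mean and variance of log s_j² via digamma/trigamma
   identities (Newton inversion of the trigamma function), and the
   posterior variance is the df-weighted blend
   (d₀s₀² + d·s_j²)/(d₀ + d). The moderated t has ν = d + d₀ degrees of
   freedom. This reproduces the reference empirical-Bayes implementation
   (R limma) to ~1e−6 relative error on shared fixtures (see the test
   suite).
2. **Smoothing.** y_i = t_i² is smoothed per chromosome with normalized
   Gaussian-kernel weights over neighbors within a truncation window
   W = 5h: S(x_i) = y_i + Σ_{j≠i} w_j y_j with Σw_j = 1. The self-site is
   excluded from the weight sum (the j ≠ i convention); duplicate
   coordinates participate with K(0) = 1. Beyond 5 bandwidths the raw
   kernel factor is < 4·10⁻⁶, so truncation is numerically irrelevant
   while keeping the scan O(n·k).
3. **Inference.** Because ν is large after moderation, y ≈ χ²₁ under the
   null and S(x_i) is a positive linear combination of χ²₁ variables with
   mean 1 + Σw and variance 2(1 + Σw²). Satterthwaite matching gives
   p = (1+Σw²)/(1+Σw) and q = (1+Σw)²/(1+Σw²); S/p is referred to χ²_q.
   With normalized weights p·q = 2 exactly and q ∈ [2, 4): q = 2 for one
   neighbor, approaching 4 as weight spreads evenly over many neighbors.
   The χ²₁ approximation of F(1, ν) is always used; ν is carried in the
   site table so users can judge its adequacy (the Kolmogorov distance to
   χ²₁ is below 0.02 for ν ≥ 50). BH correction is applied genome-wide in
   a single family; retention requires adjusted p strictly below α (ties
   at α are removed — the conservative reading).
4. **Regions.** Retained sites chain into a region when consecutive
   same-chromosome sites are ≤ g apart; linkage is between adjacent
   member positions (chain linkage), not region envelopes. Boundaries are
   the first/last member probe positions with no padding; the
   representative p-value is the member minimum, used for ranking.

## Bandwidth policies

* **faDMR** — fixed h = 500 bp on every chromosome.
* **aaDMR** — h = median probe spacing of each chromosome (even gap
  counts: mean of the central pair). Chromosomes with fewer than two
  probes fall back to the fixed 500 bp with a warning.

## Tunable parameters

| parameter | default | units | meaning |
| --- | --- | --- | --- |
| `fixed_h` | 500 | bp | kernel bandwidth (faDMR; adaptive fallback) |
| `window_factor` | 5 | — | truncation window W = factor·h |
| `alpha` | 0.05 | — | BH-adjusted significance level |
| `g` | 1000 | bp | agglomeration distance |
| `min_probes` | 2 | probes | minimum region size (a single CpG is a DMP, not a region; set 1 to keep singletons) |
| `beta_clip` | 0.001 | — | β clipped into [clip, 1−clip] before the logit, avoiding infinite M |

## Synthetic data generator

The layout emulator reproduces the qualitative shape of array probe
spacing — a modal gap well below 200 bp and a heavy right tail — with a
two-component log-normal gap model: a fraction `island_weight` (default
0.7) of probes sit in promoter-like clusters (4–10 probes, within-cluster
gap median 80 bp), the rest are scattered open-sea singletons
(between-unit gap median 3000 bp). Clusters are annotated as candidate
regions (TSS200-like when spanning ≤ 200 bp, TSS1500-like otherwise).
Defaults were fixed once as qualitatively realistic; the emulator targets
the shape of real-array gap histograms, not their exact quantiles, since
per-chromosome spacing quantiles depend on the manifest version.

The dataset simulator draws β per probe and sample from a beta
distribution parameterized by its mode m and concentration c = a + b
(a = m(c−2)+1, b = (1−m)(c−2)+1; default c = 10). Null probes receive a
methylation status (methylated, mode 0.9 / unmethylated, mode 0.1,
equiprobably per probe; optionally constant per region) and both groups
share that distribution. In true DMRs the control group sits at the
baseline mode — unmethylated for hypermethylated regions, methylated for
hypomethylated ones — and the treatment group at baseline ± Δβ. Study
conditions default to 10 vs 10 samples, 10% of candidate regions true
(half hyper, half hypo), Δβ ∈ {0.2, 0.09}.

Because the mode, not the mean, is shifted by Δβ, the group **mean**
difference is Δβ·(c−2)/c (0.16 at Δβ = 0.2, c = 10); tests account for
this mean-vs-mode bias. What the simulator does *not* emulate: probe
chemistry (Infinium I/II) differences, batch effects, spatially
correlated residuals beyond region-constant status, cross-reactive
probes, or real-manifest spacing quantiles. Benchmarks on this generator
therefore demonstrate correctness and qualitative behavior of the caller,
not absolute performance on real arrays.

## Evaluation conventions

EO requires exact integer equality of chromosome, start and end; AO
requires ≥ 1 shared bp of the closed intervals. TP is the number of
**true regions detected** (so TP + FN equals the number of true regions —
the fixed-margin confusion-table convention; a call spanning two true
regions credits both). FP is the number of calls detecting no true
region; TN is the number of null candidate regions never matched (EO) /
intersected (AO). Region-level type-I error is FP divided by the number
of null regions. Undefined ratios (e.g. precision with zero calls) are
reported as missing and excluded from replicate summaries with a logged
count.

## Numerical choices and edge cases

* d₀ estimates are capped at 10⁹ as a stand-in for ∞ (zero log-variance
  dispersion); all-zero variance input is a degenerate-data error, and
  isolated zero variances are floored with a warning.
* Probes with any missing value are dropped (logged), not imputed.
* Zero posterior variance yields an infinite t; such probes are flagged
  and excluded from smoothing with a warning.
* Sites with no neighbor inside W keep S = y and (p, q) = (1, 1), i.e.
  the unsmoothed χ²₁ test.
* Coordinates are 1-based internally (manifest convention); BED input and
  output convert at the boundary (start+1 / start−1).
* Replicate seeds derive from the master seed via `numpy` SeedSequence
  spawning; all outputs are bitwise reproducible for a given seed.

## Problem sizes used in the shipped benchmarks

The test suite and `scripts/acceptance.py` run the study design at
reduced scale, chosen as comfortable single-CPU sizes: 15,000–50,000
probes across 2–5 chromosomes, ~1,500–5,000 candidate regions, 15–25
replicates. The full-scale design (~450K probes, 21,363 regions, 1000
replicates, real manifest annotation) is exposed through the same
`run_replicates`/`benchmark` interfaces when users supply a real probe
annotation and more compute.

## Known limitations

* The Satterthwaite scaled-χ² null for S is approximate twice over
  (F(1,ν) → χ²₁, then moment matching); raw p-values under a global null
  are calibrated to within ±0.02 of nominal at α = 0.05 in the shipped
  tests, not exactly uniform.
* Smoothing treats the y_j as independent under the null; co-methylation
  of *signals* is modeled, correlation of *noise* between neighboring
  probes is not.
* On layouts whose median spacing is well below 500 bp, the adaptive
  bandwidth pools less information than the fixed 500 bp and aaDMR can
  trail faDMR slightly in power; its advantage materializes on layouts
  whose per-chromosome median spacing exceeds the fixed bandwidth.
* No array normalization is performed; the input matrix is assumed
  preprocessed (e.g. functional normalization upstream).
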