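# Methods

## Differential methylation

Beta values (fraction of methylated signal per CpG probe, β ∈ [0,1]) are
transformed to M-values, `M = log2(β′/(1−β′))` with β′ clipped to
[1e-6, 1−1e-6]. The clip keeps M finite at β ∈ {0,1} without perturbing
interior values; M-values are approximately homoscedastic and therefore
suit linear modelling, while β is retained for effect sizes and display.

Each probe is fit by ordinary least squares against a design with an
intercept, a treated-condition indicator and donor indicator columns
(paired design; the first donor is the baseline). The tested coefficient is
the condition contrast; its unit standard error `sqrt((XᵀX)⁻¹_cc)` is shared
across probes. Probes with any missing β are dropped before modelling — no
imputation.

Residual variances are moderated by the standard empirical-Bayes scheme:
the prior `(d₀, s₀²)` is estimated by method of moments on `log s²` under
the scaled-F model `s² ~ s₀²·F(d, d₀)`, matching
`Var(log s²) = ψ′(d/2) + ψ′(d₀/2)` (trigamma inversion by bracketed root
finding) and the corresponding digamma mean identity. When the empirical
spread of `log s²` does not exceed `ψ′(d/2)` the prior is degenerate
(`d₀ = ∞`) and every probe receives the pooled variance; the moderated t is
then referred to a normal rather than a t distribution. The implementation
is validated in the test suite against Bioconductor limma on a shared
fixture (agreement to 1e-6 relative on t and p).

DMPs are probes with BH-adjusted p strictly below 0.05 and |Δβ| strictly
above 0.2, where Δβ = mean β(treated) − mean β(reference) is computed on
**raw** betas (covariate-corrected betas are for display only). Direction is
relative to the treated condition: hypo ⇔ Δβ < 0. Ties at either threshold
are excluded. No mean–variance trend is modelled on the array scale.

For display, donor contributions are removed on the M scale with
sum-to-zero donor coding (donor columns centered before subtraction, as in
limma's `removeBatchEffect`), so the overall mean is preserved and — with
donors balanced across groups — group means are too; corrected M is mapped
back to β.

## Differential expression and ranking

Counts are normalized by median-of-ratios size factors (median taken in
ratio space over genes expressed in every sample; factors scaled to
geometric mean 1). Testing uses the same moderated linear model on
`log2(normalized count + 0.5)` — a deliberate, documented divergence from
negative-binomial Wald testing: it shares machinery with the methylation
stage and its operating characteristics are validated on synthetic
negative-binomial data (sensitivity ≥ 0.9, false-discovery proportion
≤ 0.10 at the default thresholds in the acceptance checks).

Because no mean–variance trend is modelled, near-zero counts would be
over-called; genes with mean normalized count below 10 are removed before
testing (independent filtering, the standard DESeq2/edgeR-style guard).
DEGs require |log₂FC| > 1, q < 0.05 (strict) and, by default, a
protein-coding biotype.

GSEA scores are `−log10(q)·sign(log FC)`. q = 0 is floored at one tenth of
the smallest positive q so the score is defined while preserving order.
Ties are broken by larger |log₂FC| then lexicographic gene id, making the
ranking a deterministic total order. For display, `log2(normalized + 1)` is
used in place of a variance-stabilizing transformation and is labelled as
such.

## Tolerization score

On log2 expression of the four conditions of a re-stimulation experiment,

    score = (Untreated_re − Untreated) − (LPS_re − LPS),

positive = tolerized (blunted induction in the pre-exposed arm). Gene-level
constants cancel, so absolute expression does not matter; swapping the two
arms negates every score. With replicate columns the score is computed on
per-condition means. Top-N sets take the N highest and N lowest scores,
boundary ties broken by gene id; the two sets must be disjoint (2N ≤ genes).

## Preranked GSEA

The enrichment score is the weighted KS running sum: at each rank, a
set member adds `|score|^p / Σ_hits |score|^p` (p = 1 by default; p = 0
reduces to the classical KS statistic) and a non-member subtracts
`1/(N − n_hits)`; ES is the extremal deviation, and the leading edge
collects hits up to (positive ES) or after (negative ES) the extremum.
The null resamples gene labels — random same-size sets — because a
preranked list has no phenotype labels to permute. Nominal
`p = (1 + #{|null same-sign| ≥ |ES|}) / (1 + #null same-sign)` (add-one, so
p is never 0), `NES = ES / mean|same-sign null ES|`, and the
collection-level FDR uses the ratio-of-tails convention on pooled, per-set
normalized null scores, clamped to [0,1]. One generator seeded from the
user seed is consumed in set order, so results are bit-for-bit reproducible.
An exhaustive mode enumerates every same-size set (used when the
combination count is small) and reports the exact same-sign tail fraction.
Null ES values are computed by a closed form on sorted hit positions —
the running sum is piecewise linear between hits, so its extrema occur at
hits or immediately before them — which the tests verify against the full
running-sum evaluation.

## Regulatory enrichment around CpGs

Windows are ±250 bp around each 1-bp CpG (clamped at contig start). PWM
scanning scores every L-mer on both strands with
`log2((count+pc)/(column total+4·pc)) − log2(background)` per column
(pseudocount 0.25, uniform background by default); L-mers containing N are
skipped, and the hit threshold defaults to 80 % of the motif's maximum
achievable log-odds (HOMER-like behaviour, configurable as an absolute
score). A window is a hit if it contains ≥ 1 occurrence. Per motif, a 2×2
table of target versus background windows is tested with a two-sided
Fisher exact test (scipy), odds ratios take the Haldane–Anscombe +0.5
correction whenever a cell is zero, and BH runs across motifs. The
background is all annotated CpGs minus the targets, keeping the table
cells disjoint.

Tile profiles place tiles `[pos+o, pos+o+10)` for offsets o from −3000 to
+2990 (600 tiles); a CpG is a hit at an offset if that tile overlaps ≥ 1 bp
of any (merged) peak. The same 2×2 machinery gives a per-offset odds-ratio
profile. Genomic-category enrichment applies the identical test per
feature / island-context label. All overlap rules are ≥ 1 bp intersection.

## Integration

Nearest-TSS assignment minimizes |CpG − TSS| per chromosome (binary search
over sorted TSS positions); ties go to the lexicographically smaller gene
id. The signed distance is `(cpg − tss)` for + strand genes and
`(tss − cpg)` for − strand genes, so negative always means upstream.
Duplicate genes are removed by keeping the closest CpG per gene — the only
distance-principled choice. The Δβ-versus-log₂FC association uses Pearson
correlation (two-sided p via the t transform, n−2 df) on one CpG–gene pair
per gene by default; an all-pairs mode is exposed.

Time-course profiles are standardized per gene (mean 0, sd 1; constant rows
are dropped with a warning), clustered with complete linkage on Euclidean
distance, and the tree is cut into k = 3 clusters. Cluster labels C1..Ck
are ordered by the cluster mean of the standardized final timepoint,
descending, so labels are deterministic rather than dendrogram-order
dependent.

## Synthetic data

The generators are pure functions of their parameters including the seed,
and every emitted file parses back through the package's own readers.

* **Methylome** — baseline M-values from a bimodal mixture (45 % near
  unmethylated, 45 % near fully methylated, 10 % intermediate), probe-level
  donor offsets Normal(0, 0.3) on the M scale shared by both conditions of
  a donor (paired random effect), sample noise Normal(0, 0.2). Planted
  probes draw a reference β such that β + Δβ stays inside [0.05, 0.95] and
  shift the treated condition by exactly Δβ (default −0.3) before noise;
  the realized mean |Δβ| stays within 0.02 of the request. Default scale
  20,000 probes — large enough for stable FDR behaviour while keeping the
  full null calibration under seconds; full EPIC scale (~850k) is a
  parameter, not a requirement.
* **Counts** — log-normal gene means (meanlog 5, sdlog 1.5 — a typical
  bulk RNA-seq abundance spread at desk scale), negative-binomial counts
  with dispersion 0.1, log-normal library factors (sd 0.2) and per-gene
  donor factors (sd 0.1); planted genes (half up, half down) scale the
  treated mean by `2^±lfc`.
* **Tolerance time course** — per gene a baseline, an LPS-arm
  first-exposure shift and a shared re-exposure response; tolerized genes
  respond by `effect` less in the pre-exposed arm, so noise-free scores are
  exactly `effect` versus 0. Each condition carries six replicate columns
  (donor replicates, matching the paired six-donor design used elsewhere
  in the acceptance checks) with Normal(0, noise_sd) noise per entry;
  scoring averages replicates, which is what makes the planted effect
  recoverable at noise_sd = 0.5.
* **Regions** — an i.i.d. uniform-composition contig with evenly spaced,
  jittered CpG positions (an actual CG dinucleotide is written at each),
  motif consensus copies inserted within ±250 bp of target CpGs at 60 %
  and background CpGs at 5 %, peaks of ±100 bp centered near target CpGs,
  distinct genomic-feature and island-context label distributions for
  targets (mostly intergenic/intronic, open sea) versus background, and
  random stranded TSSs.

What the generators do **not** emulate: probe-type chemistry effects,
cell-composition heterogeneity, mean–variance trends on the M scale,
realistic sequence composition (CpG islands as compositional entities),
read-level noise, or correlated probes/genes. Passing tests therefore
demonstrate correctness of the statistics under the stated models and
calibrated error control under exchangeable noise — not robustness to
every artefact of real array or sequencing data.

## Numerical choices and limitations

* Trigamma inversion by `brentq` on [1e-8, 1e8]; zero residual variances
  are floored twelve orders below the smallest positive one before logs,
  and all-zero variance vectors are rejected.
* BH is the exact step-up definition (cumulative minimum over the sorted
  tail), validated exhaustively against the brute-force definition on
  small vectors.
* Fisher tests delegate to `scipy.stats.fisher_exact`, validated against
  exact hypergeometric enumeration for all small tables.
* GSEA FDR can be exactly 0 when no pooled null score reaches the observed
  NES; with finite permutation counts this means "below resolution", not
  literal zero.
* Coordinates are 0-based half-open throughout; BED is native. Probe and
  gene identifiers are case-sensitive opaque strings.
* The tile-profile runtime is linear in CpGs × offsets with a binary
  search per tile over merged peaks; the brute-force double loop is kept
  in the tests as the oracle.
* Problem sizes in the acceptance script (20k probes, 5k genes, ~1 Mb
  contigs, 1000 permutations) are desk-scale choices that keep a full run
  in well under a minute; all scale up by parameter.
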