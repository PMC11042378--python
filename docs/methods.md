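# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `methrna`, at the level of detail a maintainer or a
careful user needs. Everything stated here is computed by the test suite or
by `scripts/acceptance.py`; nothing is an external claim.

## Data model and conventions

An **AssayMatrix** is a features × samples float matrix with NaN as the
missing-value mask and a `scale` tag: `beta` (methylation fractions,
validated to [0, 1]), `counts` (validated non-negative), `log`
(ln(count + pseudocount)) or `mvalue` (log2 β/(1−β)). Keying range
validation on the scale lets the transforms produce legal outputs without
weakening the raw-input invariants.

Coordinates are 1-based inclusive internally (the GTF convention);
chromosome names are stored without the `chr` prefix, and both dialects
are accepted on input so manifest/GTF joins cannot fail on naming. BED
exports convert to 0-based half-open. The gene-level unit is the GTF
`gene` feature; its TSS is the 5′ end on the coding strand (start for `+`,
end for `−`). Transcript-isoform TSS resolution is out of scope.

**Signed TSS distance** is strand-aware: for `+` genes `pos − tss`, for
`−` genes `tss − pos`, so negative always means upstream in the gene's
reading direction. The **promoter window is [−1500, 0)**: inclusive at
1500 bp upstream, exclusive at the TSS base. Half-openness avoids counting
the TSS base as promoter; strand-awareness is what makes "upstream"
well-defined. Both choices are recorded here because reasonable
alternatives exist (closed windows, unstranded windows).

**Locus → gene assignment** is nearest-TSS, single-gene, within a radius
(default 100 kb). Ties on absolute distance prefer the gene for which the
locus is upstream, then the lexicographically smaller gene id — a
deterministic total order, checked against a brute-force all-pairs scan.
Loci with no TSS in range are reported unassigned and excluded downstream.
Multi-gene assignment is deliberately not modeled: each locus contributes
to exactly one gene's column group.

**Sample pairing** joins one methylation and one expression sample per
(patient, tissue) key. Replicates resolve to the lexicographically
smallest sample id with a warning — deterministic, though arbitrary; a
quality-based choice would need metrics the inputs do not carry.

## Preprocessing

* **Mean imputation** is per-feature (row): the feature is the biological
  unit shared across samples, and a per-sample mean would mix unrelated
  loci. Features observed in no sample are dropped (logged) by default.
  Imputation is idempotent.
* **Quantile normalization** is the classic rank-mean procedure; ties
  within a column receive the mean of the reference values their ranks
  span. It is applied within one assay at a time, never across assays.
  With ties present, a column's post-normalization multiset can differ
  from the reference at the tied entries — the invariant "all sorted
  columns identical" is exact only for tie-free data, which is what the
  invariant checks use.
* Order when both steps are on: impute, then normalize (normalization
  requires complete data).
* Expression counts are normalized on the count scale, then
  log-transformed (ln(x + 1)) where the analysis needs log expression.
  The alternative order (log then normalize) differs only by a monotone
  map of the reference distribution; the choice is recorded in
  `run_manifest.json` implicitly via the pipeline's fixed order.
* The M-value transform clips β to [ε, 1−ε] (default ε = 1e-6, required
  < 0.5) before log2 β/(1−β) so boundary betas stay finite.

## Characteristic direction

The two-group statistic solves (γS + (1−γ)I) b = μ₂ − μ₁ with S the pooled
within-group covariance of genes, then normalizes b to unit length. This
is the shrinkage-regularized LDA formulation with the identity as the
shrinkage target; no PCA pre-projection is used — the (1−γ)I term is what
keeps the system well-posed when genes outnumber samples. γ defaults to
0.5 and is exposed as a flag. At γ = 1 the system is solvable only when S
has full rank; a singular solve raises a computation error rather than
silently regularizing.

Conventions: groups are sorted lexicographically unless given explicitly;
positive components are higher in group 2; swapping the groups negates the
direction exactly. Genes with zero variance in both groups are dropped
with a warning before solving. A zero mean-difference vector (norm
< 1e-12) is an error ("no direction") rather than an arbitrary vector.

**Significance** is by label permutation (default 200 permutations,
minimum 100): per gene, p = (1 + #{|b_perm| ≥ |b_obs|}) / (n_perm + 1) —
the add-one form keeps p valid and never zero — with BH q across genes.
The gene set is fixed to the genes retained under the observed labels;
re-filtering per permutation would change the vector space between
permutations. The permutation floor 1/(n_perm+1) bounds attainable q: with
many genes and few permutations, BH q cannot reach small values even for
strong effects, so rankings (|component|) are the primary readout at
default n_perm and q is a guardrail. Permutation was chosen over the
bootstrap because it gives exact finite-sample level under
exchangeability and a directly testable calibration contract (verified:
null fraction of p ≤ 0.05 stays in 0.05 ± 0.03 at 500 genes, 20 vs 20
samples, 200 permutations).

## Promoter methylation vs. expression

Per gene and sample pair, the promoter summary is the **median** (default;
mean available) beta over the gene's promoter loci; genes with fewer than
`min_loci` (default 1) promoter loci get no summary and are reported. The
median is the default because it is robust to a single aberrant locus;
the mean is kept because both summaries are standard in the literature and
they differ for skewed promoters.

Pearson r between summary and log expression across pairs uses the exact
t-transform for p (t = r·√((n−2)/(1−r²)), two-sided, n−2 df) rather than
permutation — deterministic and cheap at genome scale. Genes need ≥ 3
complete pairs; constant inputs are unclassified with the reason recorded.
Classification: canonical if r ≤ −τ and q ≤ α; non-canonical if r ≥ τ and
q ≤ α; else unclassified. τ = 0.3 and α = 0.05 are defaults (flags): τ
filters out statistically significant but biologically negligible
correlations at large n; α is the conventional FDR level.

The per-gene linear fit is ordinary least squares of log expression on the
promoter summary (slope sign always agrees with r; R² = r² to 1e-10,
both verified). The histogram of r uses fixed bins of width 0.05 over
[−1, 1] for reproducible summaries.

**Sequence tensors** order a gene's loci by ascending TSS distance within
a window (default [−1500, 1500] bp — symmetric, wider than the promoter
window, because downstream-of-TSS methylation is informative for sequence
models even though it is not "promoter"); sequences longer than L (default
20) drop the loci farthest from the TSS first, shorter ones are
right-padded with zeros and a False mask. Real slots always precede
padding. Tensor building stops at the arrays; model training is out of
scope.

## Synthetic data generator

The generator emulates the study design the analyses expect: every
patient contributes one methylation and one expression sample per tissue,
so (patient, tissue) pairs always exist; pairing edge-cases (missing
assays, replicates) are exercised separately with hand-built metadata.

Generative model, per gene g and sample s:

* expression: count ~ NegBin(mean = exp(μ_g + 0.5·z_gs + Δ_gs),
  dispersion 0.02), μ_g ~ N(6, 1); z_gs ~ N(0,1) is the biological latent;
  Δ_gs = ±1.0 (the planted log-fold, sign randomized per gene) for DE
  genes in the second tissue, else 0.
* methylation: β = logistic(a_g + b_l + w_gs + 0.3·η_ls) for promoter
  loci (a_g ~ N(0,1) gene baseline, b_l ~ N(0, 0.3) locus offset,
  η per-locus noise); non-promoter loci are independent logit-normals.
  The gene-level latent w_gs = c·z_gs + √(1−c²)·ε_gs with c = −ρ for
  canonical genes, +ρ for non-canonical, 0 otherwise — the planted
  correlation is **exact on the logit/log-latent scale**.
* missingness: uniform i.i.d. masking at `missing_rate` (default 1%),
  realized as absent lines in per-sample files.

Noise scales (log-sd 0.5 biological expression variation, NB dispersion
0.02 at ~400-count means, logit-sd 1.0 with 0.3 per-locus noise) were
chosen once as representative of clean bulk studies; with them the
observed beta-scale correlation attenuates from |ρ| = 0.7 to ≈ 0.63
(Monte-Carlo-checked in the tests, tolerance ±0.1). Gene layout places
TSSs 200 kb apart with loci within ±20 kb, so nearest-TSS assignment
provably recovers the planted gene — the generator tests locus assignment
structurally, not statistically.

What the generator does **not** emulate: 450K probe-type (Type I/II)
chemistry, CpG-island spatial autocorrelation, library-size variation,
batch effects, or realistic repository metadata schemas. Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under the stated model, not performance on real cohort data, where
attenuation and confounding are stronger.

The structural plan (gene layout, planted classes — the truth table) and
the data noise use two independent RNG streams derived from the seed, so
the truth table is a pure function of the configuration.

## Problem sizes and determinism

The shipped checks run at: 500 genes with 20 vs 20 samples for the
differential-expression properties (200 permutations, 3 seeds), 500 genes
with 100 pairs for correlation-class recovery (3 seeds), 50 random
instances for each oracle comparison, and a 60-gene repository for the
byte-stability and round-trip checks. These sizes give stable Monte-Carlo
estimates (binomial SE < 0.02 on all reported proportions) while keeping
the whole suite fast enough to run habitually.

All outputs are deterministic given (inputs, config, seed): permutations
are the only internal randomness and are seeded; no timestamps are
written; matrix writes use shortest round-tripping float repr and reads
use exact float parsing, so write → read is bit-exact (verified at the
byte level for the full pipeline).

## Known limitations

* Correlation p-values assume bivariate normality through the t-transform;
  a permutation mode would be the robust alternative at small n.
* Pooled (cross-tissue) correlation can be confounded by tissue-level
  shifts in both assays (Simpson's-paradox patterns); within-tissue
  analysis is possible by filtering the repository query to one tissue.
* The characteristic-direction permutation test is marginal per gene, not
  joint; its q-values inherit the permutation floor discussed above.
* Quantile normalization forces a common marginal distribution and will
  partially absorb global (all-gene) shifts between groups.
* `DESeq2`-style count models and gene-set enrichment are intentionally
  not reimplemented; the `ddx` CLI points users to external tools.
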