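# Methods

## Model and procedure

The pipeline treats drug repurposing as a signature-reversal problem at the
cell-cluster level. Its inputs are (i) per-cluster differential-expression
tables comparing diseased to control cells, produced by any DE method and
imported as-is, and (ii) a drug-perturbation reference in which each treatment
instance is a total ranking of the shared gene universe by treatment response
(rank 1 = most up-regulated by the drug).

### Concordantly reversed genes

For a cluster with significantly deregulated genes (adjusted *P* < `alpha`,
default 0.05, split by the sign of logFC), each significant gene is located in
two tails: the disease tail (rank *u*; 1 = most extreme in its direction of
deregulation) and the drug's *opposing* tail (rank *v*; 1 = most extreme in
the reversing direction). Under the null that the drug is unrelated to the
disease signature, u/G and v/G are approximately independent uniforms, and the
product r = (u/G)(v/G) has exact lower-tail probability

    P(U₁U₂ ≤ r) = r (1 − ln r).

A gene is called a concordantly reversed gene (CEG) when this p-value is below
`ceg_alpha` (default 0.05). This closed form is monotone in both ranks and is
verified in the tests against a 10⁷-draw Monte-Carlo estimate.

The disease rank list orders genes by decreasing logFC, breaking ties by
increasing p and then lexicographically by symbol — a deterministic total
order. logFC is the primary key because the disease side of the comparison is
framed as a fold-change ranking; the key is configurable in principle by
re-ranking the signature before import. When the signature and reference
universes differ, both sides are restricted to the intersection and re-ranked
contiguously.

### From instances to drugs

Each instance's evidence is s = Σ −log₁₀ p over its CEGs (0 with no CEGs).
Three statistics summarize a drug:

- **Outlier sum (OS).** All instance scores are standardized as
  s̃ = (s − median)/MAD with the unscaled MAD; if the MAD is zero the mean
  absolute deviation is used, and if that is also zero every OS is 0. The
  threshold is q75(s̃) + IQR(s̃) with linear-interpolation quantiles; a drug's
  OS is the sum of its instances' s̃ above the threshold (0 if none). The OS
  is location-invariant by construction.
- **K-S significance.** A two-sample Kolmogorov–Smirnov test compares the
  drug's instance scores with all other drugs' instances, one-sided by default
  ("greater": only excess reversal evidence counts; two-sided available). The
  drug's K-S p is floored at 1e-300.
- **Single-cluster FDR.** Benjamini–Hochberg across all drugs in the cluster.

A gene counts toward the drug's reversed-gene tally when it is a CEG in at
least `majority_fraction` (default 0.5) of the drug's instances — the
multi-instance consensus is otherwise undefined for a rank-list reference.

The K-S test is reported on the distribution of instance scores, with the OS
statistic reported separately per drug; whether the outlier-threshold should
be applied before the test is a genuine modeling choice, and testing the full
instance-score distribution uses all instances of every drug rather than only
the outliers.

### Multi-cluster drug score

    score = Σ_k prop_k · (−log₁₀ FDR_k) · (reversed_k / diseased_k)

- `prop_k` = disease cells in cluster k / all disease cells in the sample.
  The denominator stays the whole sample even when scoring a cluster subset,
  so subset scores are comparable to full scores.
- FDR_k is floored at 1e-300 before the log; clusters where the drug was
  untestable (or with no diseased genes) contribute 0. Non-significant
  clusters contribute their (small) −log₁₀ FDR term literally.

The standardized score is 1 − rank/total with rank 1 for the largest score
and **average ranks for ties**, so it lies in [0, 1) and the identity
std = 1 − rank/total holds exactly (rank is therefore stored as a float).
Fisher's combined p uses t = −2 Σ ln p_k against χ²(2n) — the natural-log
form is the calibrated one (it returns p₁ exactly at n = 1); a base-10
variant (t = −2 Σ log₁₀ p_k against the same χ²) is available behind
`fisher_base="ten"` because some published pipelines print that form, but it
is not calibrated and not the default.

Default selection: significant (FDR_k < 0.05) in at least one selected
cluster AND score strictly above the 0.99 quantile of all drug scores; both
thresholds are flags.

### Drop-one-out

The contribution of a cell type is the score change when all clusters of that
type are removed from both the numerator and the denominator of the cluster
proportions (their cells leave the sample); per-cluster FDRs are unaffected,
so the delta is exactly reproducible by recomputing the score on the reduced
cell table — the tests assert this identity at 1e-12.

## Numerical and algorithmic choices

- **Exact small-sample tests.** The K-S p-value is exact by enumerating all
  C(n+m, n) label assignments of the pooled values when n+m ≤ 12 (this
  conditions on the data and is therefore tie-safe). For larger samples the
  exact distribution-free p (scipy) is used while n·m ≤ 50,000 — with few
  instances per drug against a large background the asymptotic tail is
  noticeably miscalibrated, and the exact computation is cheap — and the
  classical asymptotic tail beyond that. The built-in rank-sum DE test uses
  the same enumeration idea (total ≤ 14) and a tie-corrected normal
  approximation otherwise.
- BH adjustment delegates to statsmodels (`fdr_bh`); tests verify it against
  a literal step-up implementation.
- ROC AUC is the rank-sum (Mann–Whitney) formulation with ties counted half,
  cross-checked against exhaustive pair counting; curve points come from
  scikit-learn without intermediate-point dropping.
- Gene symbols are uppercased at ingest; no alias resolution is attempted.
- p-values and FDRs are floored at 1e-300 before any log transform.

## Synthetic study design

The generator emulates the *statistical structure* the pipeline consumes, not
raw scRNA-seq counts:

- **Cell table.** Configurable disease/control cells per cluster; defaults
  [150, 100, 50] disease and [100, 100, 100] control over 3 clusters — sizes
  typical of per-cluster cell counts in dissociated patient samples. Each
  cluster carries one cell type so majority annotation and drop-one-out are
  exercised.
- **Signatures.** 5% of 2,000 genes are truly DE per cluster
  (`de_fraction=0.05`), with |log2FC| drawn Exponential with mean
  `effect_size=1.0` and random sign — a moderate disease signature. The
  observed logFC is sign·|lfc|·`attenuation`. P-values come from a power
  model: z ~ Normal(|lfc|·√n_eff / s₀, 1) with n_eff the harmonic mean of the
  cluster's disease/control cell counts and s₀ = 2.0 playing the role of the
  per-cell log-expression noise scale, two-sided p = 2Φ(−|z|), BH within
  cluster. Smaller effects or fewer cells therefore yield fewer significant
  genes, which is what the attenuation and size robustness settings probe.
  Null genes get logFC ~ Normal(0, 0.1) and uniform p-values.
- **Reference.** 100 drugs × 3 instances of uniformly random rank
  permutations; planted drugs place each target cluster's true up-DE genes in
  their bottom tail (down-DE in the top tail) with probability
  `reversal_strength = 0.9` per gene and instance. At strength 0 a planted
  drug is exactly a background drug.
- All randomness flows from one seed through named SeedSequence streams; the
  DE gene assignment stream is keyed only by (seed, cluster) so the case
  study and the reference agree on the planted genes, and attenuation changes
  neither gene identities nor any other draw.
- A small Poisson count-level mode (`generate_counts`) feeds the built-in
  rank-sum DE test for integration testing.

What passing on this generator does **not** show: robustness to dropout and
library-size variation, ambient RNA, cluster misassignment, correlated genes,
batch effects, or the scale and redundancy of a real perturbation compendium
(hundreds of thousands of instances, dose/time structure). Results on real
data depend on the external DE method and the reference quality.

Robustness simulations regenerate the study at each level with a derived
sub-seed: `attenuation` scales true effects (0.2–1.0), `size` sets the total
cells per condition (split across clusters like the base configuration), and
`unbalance` draws 5,000 cells at a given disease proportion. Each replicate
reports the ROC AUC of the drug ranking against the planted labels; the trend
check uses a one-sided Spearman rank test of AUC against level.

The default problem sizes (100 drugs × 3 instances × 2,000 genes, 20
replicates per condition) were chosen so a complete study scores in well
under a second while leaving the planted-signal recovery and null-calibration
regimes non-trivial.

## Known limitations

- The reference format stores rank lists only; z-score matrices must be
  converted at ingest (`ranks_from_scores`), losing magnitude information.
- Instances are never collapsed per drug before testing; drugs with a single
  instance rely entirely on the K-S test's small-sample behavior.
- Fisher's combination assumes independent per-cluster p-values; clusters
  sharing cells or genes violate this mildly.
- −log₁₀ FDR is unbounded as FDR → 0; the 1e-300 floor is a numerical guard,
  and scores of extremely significant drugs are dominated by that term.
- The per-patient "overall" score is computed on the pooled cell table and
  pooled signatures; a mean-of-per-patient-scores alternative is a trivial
  wrapper left to the caller.
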