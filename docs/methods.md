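# Methods

This note documents the models, algorithms and numerical choices behind
`gwasrank`, the assumptions each one makes, and what the synthetic-data
tests do and do not demonstrate about real data.

## Genotype model and quality control

Genotypes are alternate-allele counts (0/1/2, −1 missing) for biallelic
autosomal SNPs. When a PED/MAP file carries no reference information, the
alternate allele is the minor allele observed in the data; an exact 0.5
tie is broken alphabetically (the alphabetically later allele becomes the
alternate), so reading is deterministic. Coordinates are 1-based
throughout.

The QC cascade runs, in order: marker missingness (> 0.01 removed),
sample missingness (> 0.01), minor allele frequency (< 0.05), and the
Hardy-Weinberg exact test (p < 1e-5); the whole sequence is then repeated
once, because removing samples changes marker statistics; finally markers
with differential call rates between cases and controls (two-sided Fisher
exact p below a configurable threshold, default 1e-5) are removed. The
order matters and is tested: a marker failing both MAF and HWE is
reported under MAF. Sex checks, relatedness pruning, strand fixing and
liftover are out of scope; they belong to upstream tooling.

The HWE test is the conditional exact test: given the observed allele
counts, the probabilities of all heterozygote counts of the same parity
whose conditional probability does not exceed the observed one are
summed. Weights are computed with exact integer arithmetic
(multinomial × 2^het), so the inclusion ordering is never subject to
floating-point rounding; the test suite checks agreement with an
independent rational-arithmetic enumeration oracle for every genotype
configuration with up to 50 individuals.

LD pruning is the classic sliding-window rule (window 50 SNPs, step 5,
r² > 0.2): within a window, while any retained pair exceeds the
threshold, the lower-MAF member is removed; an exact MAF tie removes the
later coordinate (a deterministic choice; any fixed rule is defensible
and this one keeps the earlier, usually better-annotated, position).
Pairs with undefined r² (monomorphic on the pairwise-complete subset) are
skipped. PCA standardizes each marker by its binomial moments (center
2p, scale √(2p(1−p))), mean-imputes missing calls (0 after centering),
and returns eigenvector × √eigenvalue sample coordinates with a
deterministic sign convention; mean imputation keeps the decomposition
well-defined at the cost of slightly shrinking loadings for
high-missingness markers.

## Association approaches

The registry enumerates 25 approaches — a (method, encoding,
implementation) triple each: logistic regression under four encodings in
two implementation variants, five basic allelic association variants
(chi-square, Fisher exact, a counts variant, and pointwise / max-T
permutation versions), six model tests (allelic, trend, genotypic,
collapsed dominant and recessive, and best-of-models with permutation),
four externally published mixed-model/liability tools as import
adapters, and three machine-learning scorers. Covariate adjustment is a
property of the approach: logistic regression and the external tools
support it; contingency-table and machine-learning approaches do not.

Logistic regression is fit by Newton/IRLS with a tolerance of 1e-8 on
the log-likelihood change and at most 25 iterations; an encoding
coefficient exceeding 15 in absolute value is treated as (quasi-)
separation. Single-column encodings use the Wald p-value; the
two-column codominant encoding uses a 2-df likelihood-ratio test against
the covariate-only null, since a single-coefficient Wald test cannot
summarize it. Failed markers (non-convergence, separation, rank
deficiency, degenerate tables) are *not* dropped: they receive the worst
ranks, after all valid markers, ordered by genomic position. This keeps
every ranking a bijection onto 1..N over a common SNP universe, which
the Canberra machinery requires.

The trend test uses the Cochran-Armitage statistic with weights
(0, 1, 2) and the binomial-variance denominator, equivalent to N·r²
for the dose/status correlation — the identity the oracle tests exploit.
The genotypic test is the 2-df Pearson chi-square; collapsed dominant/
recessive tests are 1-df chi-squares on the collapsed 2×2 table, without
continuity correction, matching the allelic test's convention. The
best-of-models permutation test takes the minimum p over the five model
tests as its statistic and estimates significance as (1 + b)/(1 + m)
over m phenotype permutations; permutation streams are seeded per marker
by hashing the marker id with the approach seed, so results are
reproducible and independent of marker order.

Ranks are dense integers 1..N: primary key ascending p (or descending
score), ties broken by (chromosome, position, marker id). Every ranking
is asserted to be a permutation at construction time.

## Machine-learning scorers

**1-way MDR.** A genotype is high-risk when its case:control ratio
strictly exceeds the training data's overall ratio (comparison done by
cross-multiplication, so zero-control cells are handled exactly). An
exact ratio tie and genotypes unseen in training are labeled low-risk:
both choices are conservative and deterministic. The score is the mean
balanced accuracy (sensitivity + specificity)/2 over 10 stratified
cross-validation folds (seeded shuffle, round-robin assignment); a fold
missing a phenotype class is skipped with a warning. With one fold the
estimator reduces to the closed-form resubstitution balanced accuracy of
the risk table, which the suite checks exhaustively on small tables.

**Entropy gain.** The plug-in mutual information H(Y) − H(Y|G) in bits,
with 0·log 0 = 0; bounded by 1 bit for a binary phenotype.

**Decision trees.** One single-feature classifier per SNP: a stratified
75/25 split, hyperparameters (criterion ∈ {gini, entropy},
min_impurity_decrease ∈ {0, 0.1, …, 0.5}) chosen by 5-fold CV on the
training part scored with r² on the 0/1 labels, and the selected tree's
held-out accuracy reported. Using r² for selection but accuracy for the
held-out report reflects a genuinely open design point: r² on class
labels is a scaled Brier improvement and discriminates between
near-equivalent trees during selection, while accuracy is the natural
end score of a classifier (and makes a root-only tree score exactly the
majority-class fraction). Splits that lose a class are re-drawn with an
incremented seed, at most five times.

MDR and entropy are invariant under relabeling genotype categories —
they see the genotype as categorical — which is exactly why they detect
heterozygote/overdominant architectures that every fixed single-column
encoding misses.

## Rank comparison and consensus

Canberra distances are summed in marker-sorted order in double
precision, so distances are bit-reproducible. Requested k values at or
beyond the universe size N are clamped to the full Canberra distance
with a warning (they are mathematically equivalent there).

Clustering is UPGMA on the distance matrix; the dendrogram's ultrametric
assigns each leaf pair the height of its first common merge. Clustering
agreement is the Pearson correlation between two ultrametrics over all
unordered leaf pairs; a constant ultrametric (all distances equal, e.g.
from identical rankings) makes the correlation undefined and raises.

The consensus of several clusterings averages their ultrametric matrices
elementwise — the closed-form least-squares aggregate — and re-clusters
the average with UPGMA. This is a deterministic approximation to
iterative least-squares consensus optimizers: the true optimizer
searches all ultrametrics, while the average-then-UPGMA surrogate stays
within the UPGMA-reachable family. For the matrices this workflow
produces the difference is immaterial, and determinism is worth more
here than the last decimal of the objective.

Trees are cut into a requested number of clusters by merge order (the
last n−1 merges are undone), so tied merge heights are broken by merge
sequence and the requested count is attained whenever possible — the
behavior of R's `cutree`. Representatives default to the cluster medoid
(minimum summed within-cluster distance, ties by name); a configuration
override can substitute any manual choice.

The k values entering the consensus are the longest ascending prefix of
the configured grid whose clusterings all agree pairwise above a
threshold (default 0.97, the level observed to mark "strong" agreement
before noise tails dominate); if not even the first two agree, the
smallest k is used alone, with a warning.

## Union statistics and haplotype blocks

Union tables are sorted by decreasing extraction number, then increasing
average position. The TSV layout encodes each approach's column as
k + 1 − rank for SNPs in that approach's top k (k best, 1 worst) and 0
otherwise. The stability percentage is 100·Σ_k/(m·k) by default — 100%
means pairwise-disjoint top-k lists; the alternative normalization
100·(Σ_k − k)/(m·k − k), which makes identical lists 0%, is available as
an option since the verbal definition of "percent of complete
instability" admits both readings.

Block inference is a deliberate simplification of confidence-interval
block callers: two-locus haplotype frequencies are estimated from
unphased genotype counts by EM (double-heterozygote phase resolved
iteratively, tolerance 1e-9), |D'| is computed from the four estimated
frequencies, and adjacent markers join a block while |D'| ≥ 0.9 against
the block's last member and the block spans ≤ 200 kb. Markers in no
multi-marker block are singletons. Externally computed block definitions
(`.blocks.det` dialect) can be loaded instead for bit-faithful
reproduction of an external caller. Within a block, the pruned union
keeps the SNP with the highest extraction number, then lowest average
position; the residual ties are broken by best single rank and then by
marker id — the first two criteria are the substantive rule, the last
two only guarantee determinism.

## Synthetic data generator

The generator emulates the statistical structure the workflow assumes,
not human genome realism. Haplotypes come from a Gaussian copula: per LD
block, a latent AR(1) normal vector (default block size 10, correlation
ρ = 0.7) is thresholded at each marker's allele-frequency quantile; two
haplotypes per individual are summed to a 0/1/2 call. This yields exact
HWE per marker, geometric within-block LD decay, and directly
controllable MAF (uniform on [0.05, 0.5] by default, respecting the QC
floor). Population structure, when enabled, shifts subpopulation allele
frequencies apart by a configured divergence. Missing calls are masked
uniformly at random (default rate 0.002, comfortably below the 0.01 QC
threshold).

The phenotype is a logistic liability: logit P(case) = α + Σ β_j·x_j +
γ·age, with β_j = ln(OR_j) under the planted effect's encoding
(heterozygote effects use the het indicator; "genotypic" effects give
the heterozygote ln(OR) and the homozygote 2·ln(OR)), age normal
(55, 10) with a default slope of 0.02 per year, and α tuned by bisection
so the expected case fraction matches the target. Cases and controls are
then ascertained from an oversampled population pool (4× by default) to
exact counts. A logistic (not probit) liability matches the analysis
models, which makes the planted odds ratios exactly the estimands of the
logistic tests. All randomness flows from one seed; outputs are
byte-reproducible.

What passing tests show — and what they do not: the generator's LD is
block-wise and stationary, its effects are single-locus, and its
structure is a clean two-population shift. Power and complementarity
results on this data demonstrate that the machinery behaves correctly
under its own assumptions (e.g. recessive loci recovered by the
recessive encoding but not the additive one; heterozygote effects
visible only to encoding-free scorers at MAF 0.5, where dosage carries
no marginal signal). They do not calibrate absolute power for real
cohorts with realistic LD, ascertainment bias or cryptic relatedness.

## Problem sizes and calibration checks

The test suite uses desk-scale datasets chosen to make the statistical
assertions sharp: 500 markers × 600 samples for null calibration, 1000
markers × 2000 samples × 20 replicates for the encoding-complementarity
experiment (10 planted recessive loci, MAF 0.25–0.35, OR 2.5), and 1000
markers × 600 samples for the end-to-end determinism run. Null p-value
uniformity is checked by Kolmogorov-Smirnov at α = 0.01, each test on
its applicability domain: recessive-type tests are evaluated on markers
with an expected homozygote-alternate count of at least 5 per class,
the standard validity condition for their asymptotics — at the MAF
floor a recessive test's null distribution is genuinely discrete, which
is a property of the test, not an implementation artifact. Fisher's
exact test is checked for validity (P(p ≤ α) ≤ α) rather than strict
uniformity, since exact conditional tests are conservative by
construction.

## Known limitations

- No BED/BIM/FAM reader: PED/MAP text is the supported input dialect.
- External mixed-model and liability methods are import adapters only;
  their statistics are never recomputed here.
- The consensus clustering is the average-ultrametric surrogate, not an
  iterative least-squares optimizer.
- Block inference is |D'|-greedy, not a confidence-interval method; use
  `load_blocks` for externally defined blocks when fidelity matters.
- Multi-locus (k-way) MDR models, dosage/imputed genotypes and the X
  chromosome are out of scope.
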