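# gwasrank

A toolkit for **multi-approach univariate GWAS analysis** of binary
(case-control) traits. Instead of committing to a single association test
and genotype encoding, `gwasrank` runs a diverse suite of per-SNP
approaches, measures how similar their ranked SNP lists are with
Canberra-based top-k distances, clusters the approaches, selects one
representative per cluster, and reports the **top-k union** of the
representatives' hits — a candidate list that keeps signals any single
approach would miss.

## Who is this for

GWAS analysts who want to probe a case-control dataset with several
modeling lenses at once: logistic regression under additive, dominant,
recessive and codominant encodings; the classic contingency-table family
(allelic, Cochran-Armitage trend, genotypic, collapsed dominant/recessive
models, and a best-of-models permutation test); and three encoding-free
machine-learning scorers (1-way MDR balanced accuracy, entropy-based
information gain, and per-SNP decision trees). Externally run mixed-model
tools plug in through a ranked-list import adapter.

The practical motivation: a truly recessive locus is often invisible to
the additive test that dominates the literature, and a heterozygote
effect is invisible to *any* fixed single-column encoding. Running the
full suite and taking a de-duplicated union recovers these architectures.

## The core machinery

**Ranked-list distance.** Every approach yields a full ranking of the N
analyzed SNPs (by increasing p-value or decreasing score). Two rankings
σ and τ are compared with the Canberra distance

    Ca(σ, τ) = Σ_SNP |τ(SNP) − σ(SNP)| / (τ(SNP) + σ(SNP))

which weights disagreements near the top of the lists most heavily. Its
top-k variant replaces every rank above k with k+1 before applying the
same formula (the *location parameter* k+1 truncation); at k = N it
reduces to the plain Canberra distance.

**Approach clustering.** Distance matrices over a grid of k values are
clustered with average linkage (UPGMA); clusterings for different k are
compared via the cophenetic correlation of their ultrametrics; the
longest prefix of k values whose clusterings all agree above a threshold
(default 0.97) enters a consensus clustering (elementwise average of the
ultrametrics, re-clustered); the consensus tree is cut into a chosen
number of clusters and each cluster contributes its medoid as a
representative.

**Union statistics.** For the m representatives, the *top-k union* is the
set of SNPs in the top k of at least one representative; its size Σ_k
(the *union number*) satisfies k ≤ Σ_k ≤ m·k, the two extremes being
complete stability and complete instability. Each union SNP carries an
*extraction number* (how many representatives rank it in the top k) and
an *average position* (its mean rank among those). Union SNPs are grouped
into haplotype blocks (|D'| threshold on EM-estimated two-locus haplotype
frequencies, or externally supplied block definitions) and each block
keeps its most stable member — the *pruned top-k union*.

Everything upstream is included: PLINK PED/MAP text I/O, the standard QC
cascade (marker/sample missingness, MAF, Hardy-Weinberg exact test —
repeated once — then a differential call-rate filter), sliding-window LD
pruning, and PCA for covariate construction. A fully seeded synthetic
data generator (HWE genotypes with block-wise LD, logistic liability with
planted additive/dominant/recessive/heterozygote/genotypic effects, an
age-like covariate, optional population structure) makes every stage
testable without controlled-access data.

## Worked example

```python
from gwasrank import (SimulationConfig, PlantedEffect, simulate_dataset,
                      apply_qc, default_registry, run_approach,
                      pairwise_distance_matrices, hclust_average, cut_tree,
                      select_representatives, union_table, stability_fraction)

config = SimulationConfig(
    n_cases=300, n_controls=300, n_markers=1000, seed=3,
    maf_range=(0.2, 0.4),
    planted_effects=[PlantedEffect(500, "recessive", 2.5)],
)
data, qc_report = apply_qc(simulate_dataset(config))

registry = {s.name: s for s in default_registry()}
names = ["plink.add", "plink.dom", "plink.rec", "plink.assoc", "entropy"]
rankings = {n: run_approach(registry[n], data, ["age"], seed=3) for n in names}
print({n: int(rl.ranking["snp00500"]) for n, rl in rankings.items()})

matrices = pairwise_distance_matrices(
    {n: rl.ranking for n, rl in rankings.items()}, [100])
dend = hclust_average(matrices[100])
reps = select_representatives(cut_tree(dend, 3), matrices[100])
table = union_table({n: rankings[n].ranking for n in reps.values()}, 100)
print(table.union_number,
      stability_fraction(table.union_number, 100, len(reps)))
```

prints

```
{'plink.add': 391, 'plink.dom': 574, 'plink.rec': 6, 'plink.assoc': 373, 'entropy': 9}
174 58.0
```

The planted recessive locus ranks **391st** for the additive logistic
test — far outside any top-100 list — but **6th** under the recessive
encoding and 9th for the encoding-free entropy scorer. The three
representative approaches (one per cluster: additive-family, recessive,
entropy) produce a top-100 union of 174 SNPs (58% of the complete-
instability maximum 300), and the planted locus is in it: the ensemble
catches what the default analysis misses.

## Command line

The same pipeline runs end-to-end from a YAML config:

```bash
gwasrank all --config workflow.yaml     # or: simulate / qc / run-approaches /
                                        #     compare / consensus / union / report
```

Each stage writes TSV/Newick/JSON artifacts (QC report, per-approach
ranked lists, per-k distance matrices and dendrograms, clustering
agreement matrix, consensus tree, representatives, union tables,
extraction-number distributions) under the configured output directory,
and reruns with the same config and seed are byte-identical. Distance
matrices contain no genotype information and can be shared across
consortium sites to agree on representative approaches without exchanging
individual-level data.

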