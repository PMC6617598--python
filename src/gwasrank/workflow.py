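"""End-to-end multi-approach GWAS workflow orchestration.

Stages: load or simulate data -> QC -> run every configured approach to a
ranked SNP list -> pairwise Canberra distance matrices over a grid of
location parameters k -> per-k average-linkage clusterings and pairwise
cophenetic agreements -> selection of the k values entering the consensus
(the largest prefix whose clusterings all agree above a threshold) ->
consensus clustering -> cut into clusters and pick representatives ->
top-k union, haplotype-block pruning, extraction-number summaries.

Every stage writes its artifacts under the configured output directory,
so later stages can be re-run from disk; given identical config and seed
the whole pipeline is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from gwasrank import association_suite as assoc
from gwasrank import genotype_io, rank_compare, synthetic_data, union_stats

log = logging.getLogger("gwasrank.workflow")

STAGES = ("data", "qc", "approaches", "compare", "consensus", "union")


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class WorkflowConfig:
    """Configuration for one end-to-end run (YAML-loadable)."""

    out_dir: str = "gwasrank_out"
    seed: int = 0
    # data: either simulation parameters or input file paths
    simulation: dict | None = None
    ped: str | None = None
    map: str | None = None
    covar: str | None = None
    # analysis
    qc_enabled: bool = True
    qc_thresholds: dict = field(default_factory=dict)
    approaches: list[str] = field(default_factory=lambda: [
        "plink.add", "plink.dom", "plink.rec",
        "plink.assoc", "plink.model.trend", "entropy",
    ])
    external_rankings: dict[str, str] = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    k_values: list[int] = field(default_factory=lambda: [100, 200, 500, 1000])
    agreement_threshold: float = 0.97
    n_clusters: int = 4
    representative_overrides: dict[int, str] = field(default_factory=dict)
    union_k: int = 100
    blocks_source: str = "infer"  # infer | file
    blocks_file: str | None = None
    dprime_threshold: float = 0.9
    max_span_kb: float = 200.0
    stability_denominator: str = "mk"

    def __post_init__(self) -> None:
        if sorted(self.k_values) != list(self.k_values):
            raise ValueError("k_values must be sorted ascending")
        n_app = len(self.approaches) + len(self.external_rankings)
        if self.n_clusters > n_app:
            raise ValueError("n_clusters exceeds the number of approaches")
        if self.blocks_source not in ("infer", "file"):
            raise ValueError("blocks_source must be 'infer' or 'file'")
        if self.blocks_source == "file" and not self.blocks_file:
            raise ValueError("blocks_source 'file' requires blocks_file")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def select_k_for_consensus(
    agreement: pd.DataFrame, k_values: list, threshold: float
) -> list:
    """Largest prefix of k_values whose clusterings all agree pairwise.

    ``agreement`` is a symmetric matrix of cophenetic correlations indexed
    by k labels. Returns the longest ascending prefix such that every pair
    within it has agreement >= threshold; if not even the first two k
    values agree, falls back to the smallest k with a warning.
    """
    best = 1
    for length in range(2, len(k_values) + 1):
        prefix = k_values[:length]
        ok = all(
            agreement.loc[a, b] >= threshold
            for i, a in enumerate(prefix) for b in prefix[i + 1:]
        )
        if ok:
            best = length
        else:
            break
    if best == 1:
        warnings.warn(
            f"no pair of clusterings reaches agreement {threshold}; "
            f"falling back to the smallest k ({k_values[0]})"
        )
    return list(k_values[:best])


def _stage(name: str):
    def wrap(fn):
        def inner(state: dict, config: WorkflowConfig):
            try:
                log.info("stage %s: start", name)
                fn(state, config)
                log.info("stage %s: done", name)
            except Exception as err:
                raise WorkflowError(f"stage {name!r} failed: {err}") from err
        return inner
    return wrap


@_stage("data")
def _run_data(state: dict, config: WorkflowConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulation is not None:
        sim = dict(config.simulation)
        sim.setdefault("seed", config.seed)
        effects = [
            synthetic_data.PlantedEffect(**e) for e in sim.pop("planted_effects", [])
        ]
        sim_config = synthetic_data.SimulationConfig(
            planted_effects=effects, **sim
        )
        gm = synthetic_data.simulate_dataset(sim_config)
        synthetic_data.write_fixture(gm, sim_config, out / "data")
        state["sim_config"] = sim_config
    else:
        if not (config.ped and config.map):
            raise ValueError("either simulation parameters or ped/map paths")
        gm = genotype_io.read_ped_map(config.ped, config.map)
        if config.covar:
            gm = genotype_io.attach_covariates(
                gm, genotype_io.read_covariates(config.covar)
            )
    state["genotypes"] = gm


@_stage("qc")
def _run_qc(state: dict, config: WorkflowConfig) -> None:
    gm = state["genotypes"]
    if not config.qc_enabled:
        state["qc_genotypes"] = gm
        return
    thresholds = genotype_io.QcThresholds(**config.qc_thresholds)
    gm2, report = genotype_io.apply_qc(gm, thresholds)
    report.write_tsv(Path(config.out_dir) / "qc_report.tsv")
    log.info("QC: %d -> %d markers, %d -> %d samples",
             gm.n_markers, gm2.n_markers, gm.n_samples, gm2.n_samples)
    state["qc_genotypes"] = gm2


@_stage("approaches")
def _run_approaches(state: dict, config: WorkflowConfig) -> None:
    gm = state["qc_genotypes"]
    registry = {s.name: s for s in assoc.default_registry()}
    ranked_dir = Path(config.out_dir) / "ranked"
    ranked_dir.mkdir(parents=True, exist_ok=True)
    rankings: dict[str, assoc.RankedList] = {}
    for name in config.approaches:
        if name not in registry:
            raise ValueError(f"unknown approach {name!r}")
        rl = assoc.run_approach(registry[name], gm, config.covariates, config.seed)
        rl.write_tsv(ranked_dir / f"{name}.tsv")
        rankings[name] = rl
    for name, path in config.external_rankings.items():
        rl = assoc.import_external_ranking(path, name, gm.markers)
        rl.write_tsv(ranked_dir / f"{name}.tsv")
        rankings[name] = rl
    state["ranked_lists"] = rankings


def _load_rankings(state: dict, config: WorkflowConfig) -> dict[str, pd.Series]:
    if "ranked_lists" not in state:
        ranked_dir = Path(config.out_dir) / "ranked"
        names = list(config.approaches) + list(config.external_rankings)
        state["ranked_lists"] = {
            name: assoc.import_external_ranking(ranked_dir / f"{name}.tsv", name)
            for name in names
        }
    return {name: rl.ranking for name, rl in state["ranked_lists"].items()}


@_stage("compare")
def _run_compare(state: dict, config: WorkflowConfig) -> None:
    rankings = _load_rankings(state, config)
    out = Path(config.out_dir)
    (out / "distances").mkdir(parents=True, exist_ok=True)
    matrices = rank_compare.pairwise_distance_matrices(rankings, config.k_values)
    dendrograms = {}
    for label, dm in matrices.items():
        dm.write_tsv(out / "distances" / f"canberra_k_{label}.tsv")
        dend = rank_compare.hclust_average(dm)
        dend.write_newick(out / "distances" / f"dendrogram_k_{label}.nwk")
        dendrograms[label] = dend
    labels = [k for k in matrices if k != "full"] + ["full"]
    agreement = pd.DataFrame(1.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            try:
                r = rank_compare.cophenetic_correlation(
                    dendrograms[a], dendrograms[b]
                )
            except ValueError:
                r = float("nan")
            agreement.loc[a, b] = agreement.loc[b, a] = r
    agreement.to_csv(out / "clustering_agreements.tsv", sep="\t",
                     index_label="k")
    state["distance_matrices"] = matrices
    state["dendrograms"] = dendrograms
    state["agreement"] = agreement


@_stage("consensus")
def _run_consensus(state: dict, config: WorkflowConfig) -> None:
    out = Path(config.out_dir)
    if "agreement" not in state:
        agr = pd.read_csv(out / "clustering_agreements.tsv", sep="\t", index_col=0)

        def _label(x):
            return int(x) if str(x).isdigit() else str(x)

        agr.index = [_label(x) for x in agr.index]
        agr.columns = [_label(x) for x in agr.columns]
        state["agreement"] = agr
        state["distance_matrices"] = {
            label: rank_compare.DistanceMatrix.read_tsv(
                out / "distances" / f"canberra_k_{label}.tsv", label
            )
            for label in list(config.k_values) + ["full"]
        }
        state["dendrograms"] = {
            label: rank_compare.hclust_average(dm)
            for label, dm in state["distance_matrices"].items()
        }
    agreement = state["agreement"]
    k_labels = [k for k in state["dendrograms"] if k != "full"]
    selected = select_k_for_consensus(agreement, k_labels, config.agreement_threshold)
    log.info("consensus built on k values %s", selected)
    dends = [state["dendrograms"][k] for k in selected]
    consensus = dends[0] if len(dends) == 1 else rank_compare.consensus_clustering(
        dends
    )
    consensus.write_newick(out / "consensus.nwk")
    labels = rank_compare.cut_tree(consensus, config.n_clusters)
    labels.to_csv(out / "clusters.tsv", sep="\t", index_label="approach")
    # medoid selection uses the smallest selected k's distances
    dist = state["distance_matrices"][selected[0]]
    reps = rank_compare.select_representatives(
        labels, dist, config.representative_overrides or None
    )
    with open(out / "representatives.json", "w") as fh:
        json.dump({str(c): n for c, n in reps.items()}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
    state["selected_k"] = selected
    state["representatives"] = reps


@_stage("union")
def _run_union(state: dict, config: WorkflowConfig) -> None:
    out = Path(config.out_dir)
    rankings = _load_rankings(state, config)
    if "representatives" not in state:
        with open(out / "representatives.json") as fh:
            state["representatives"] = {int(c): n for c, n in json.load(fh).items()}
    rep_names = sorted(set(state["representatives"].values()))
    rep_rankings = {n: rankings[n] for n in rep_names}
    table = union_stats.union_table(rep_rankings, config.union_k)
    table.write_tsv(out / f"union_top{config.union_k}.tsv")

    gm = state.get("qc_genotypes")
    if config.blocks_source == "file":
        blocks = union_stats.load_blocks(config.blocks_file, gm)
    else:
        if gm is None:
            raise ValueError("block inference needs genotypes in memory "
                             "(run the data/qc stages in the same invocation)")
        blocks = union_stats.infer_blocks(
            gm, config.dprime_threshold, config.max_span_kb
        )
    blocks.write_det(out / "blocks.det")
    pruned = union_stats.prune_union(table, blocks)
    pruned.write_tsv(out / f"pruned_union_top{config.union_k}.tsv")
    boxplot = union_stats.extraction_boxplot_data(pruned)
    boxplot.to_csv(out / "extraction_numbers.tsv", sep="\t", index=False)

    m = len(rep_names)
    summary = {
        "k": config.union_k,
        "n_representatives": m,
        "representatives": rep_names,
        "union_number": table.union_number,
        "pruned_union_number": pruned.union_number,
        "stability_percent": union_stats.stability_fraction(
            table.union_number, config.union_k, m, config.stability_denominator
        ) if m >= 2 else None,
        "selected_k": state.get("selected_k"),
    }
    with open(out / "union_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    state["union_table"] = table
    state["pruned_union"] = pruned
    state["union_summary"] = summary


_STAGE_FUNCS = {
    "data": _run_data,
    "qc": _run_qc,
    "approaches": _run_approaches,
    "compare": _run_compare,
    "consensus": _run_consensus,
    "union": _run_union,
}


def run_workflow(config: WorkflowConfig,
                 stages: list[str] | None = None) -> dict:
    """Run the pipeline (or a contiguous subset of stages) and return state.

    The returned dict holds the in-memory artifacts (genotypes, ranked
    lists, distance matrices, dendrograms, representatives, union tables,
    summary). All artifacts are also written under ``config.out_dir``.
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    state: dict = {}
    for name in STAGES:
        if name in stages:
            _STAGE_FUNCS[name](state, config)
    return state
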