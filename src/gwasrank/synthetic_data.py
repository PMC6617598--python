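"""Synthetic case-control GWAS datasets with planted architectures.

Generates biallelic autosomal SNPs in Hardy-Weinberg equilibrium with
block-wise LD (a Gaussian-copula haplotype model with AR(1) within-block
correlation), an age-like covariate, optional two-subpopulation allele
frequency divergence, and a binary phenotype from a logistic liability
model with planted additive / dominant / recessive / heterozygote /
genotypic effects. Everything is driven by a single seed and is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from gwasrank.genotype_io import (
    MISSING,
    PHENO_CASE,
    PHENO_CONTROL,
    GenotypeMatrix,
    write_ped_map,
)

EFFECT_MODELS = ("additive", "dominant", "recessive", "heterozygote", "genotypic")


@dataclass(frozen=True)
class PlantedEffect:
    """One causal marker: its index, inheritance model and odds ratio.

    For the genotypic model the scalar odds ratio applies to the
    heterozygote and its square to the homozygote alternate (separate Het
    and Hom coefficients ln(OR) and 2 ln(OR)).
    """

    marker_index: int
    model: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.model not in EFFECT_MODELS:
            raise ValueError(f"unknown effect model {self.model!r}")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")

    def linear_term(self, calls: np.ndarray) -> np.ndarray:
        """Contribution to the logit for each individual (0 where missing)."""
        g = np.where(calls == MISSING, 0, calls).astype(float)
        beta = np.log(self.odds_ratio)
        if self.model == "additive":
            return beta * g
        if self.model == "dominant":
            return beta * (g >= 1)
        if self.model == "recessive":
            return beta * (g == 2)
        if self.model == "heterozygote":
            return beta * (g == 1)
        # genotypic: separate Het/Hom coefficients
        return beta * (g == 1) + 2 * beta * (g == 2)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic case-control GWAS.

    Defaults describe a desk-scale cohort: 1000 biallelic autosomal SNPs in
    HWE with MAF uniform on [0.05, 0.5] (the post-QC floor), LD blocks of
    10 adjacent markers with latent AR(1) correlation 0.7, a Normal(55, 10)
    age covariate with a mild log-odds slope, balanced cases and controls,
    and a 0.2% missing-call rate.
    """

    n_cases: int = 300
    n_controls: int = 300
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.7
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    age_mean: float = 55.0
    age_sd: float = 10.0
    age_coefficient: float = 0.02  # log-odds per year of age
    structure_fraction: float = 0.0  # fraction of samples in subpopulation 2
    structure_divergence: float = 0.0  # allele-frequency shift between subpops
    missing_rate: float = 0.002
    markers_per_chromosome: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not 0 < low <= high <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.structure_fraction < 1:
            raise ValueError("structure_fraction must be in [0, 1)")
        idx = [e.marker_index for e in self.planted_effects]
        if len(idx) != len(set(idx)):
            raise ValueError("planted marker indices must be distinct")
        if idx and (min(idx) < 0 or max(idx) >= self.n_markers):
            raise ValueError("planted marker index out of range")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_samples


def _marker_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic marker map: ids, chromosomes, 2-kb spaced positions."""
    n = config.n_markers
    per_chrom = config.markers_per_chromosome
    chroms = [str(1 + j // per_chrom) for j in range(n)]
    pos = [100_000 + 2_000 * (j % per_chrom) for j in range(n)]
    return pd.DataFrame({
        "marker_id": [f"snp{j:05d}" for j in range(n)],
        "chromosome": chroms,
        "position_bp": pos,
        "allele_ref": "A",
        "allele_alt": "G",
    })


def _block_cholesky(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def simulate_genotypes(config: SimulationConfig,
                       n_individuals: int | None = None) -> GenotypeMatrix:
    """Draw genotypes only (phenotype column is set to missing).

    Two haplotypes per individual are generated per LD block from a latent
    AR(1) Gaussian vector thresholded at the quantile implied by each
    marker's alternate-allele frequency, then summed to a 0/1/2 call. This
    yields HWE at every marker and geometric LD decay within blocks.
    """
    n_ind = config.n_samples if n_individuals is None else n_individuals
    rng = np.random.default_rng(config.seed)
    n = config.n_markers

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    pop2 = np.zeros(n_ind, dtype=bool)
    if config.structure_fraction > 0 and config.structure_divergence > 0:
        n2 = int(round(config.structure_fraction * n_ind))
        pop2[n_ind - n2:] = True
        shift = config.structure_divergence / 2.0
        f1 = np.clip(maf - shift, 0.01, 0.99)
        f2 = np.clip(maf + shift, 0.01, 0.99)
    else:
        f1 = f2 = maf

    calls = np.empty((n, n_ind), dtype=np.int8)
    block = config.ld_block_size
    chroms = _marker_table(config)["chromosome"].to_numpy()
    start = 0
    while start < n:
        end = min(start + block, n)
        # blocks never span a chromosome boundary
        while end > start + 1 and chroms[end - 1] != chroms[start]:
            end -= 1
        size = end - start
        chol = _block_cholesky(size, config.ld_rho)
        z = rng.standard_normal((2 * n_ind, size)) @ chol.T
        thr1 = stats.norm.ppf(f1[start:end])
        thr2 = stats.norm.ppf(f2[start:end])
        thresholds = np.where(np.repeat(pop2, 2)[:, None], thr2, thr1)
        hap = (z < thresholds).astype(np.int8)
        calls[start:end] = (hap[0::2] + hap[1::2]).T
        start = end

    if config.missing_rate > 0:
        mask = rng.random((n, n_ind)) < config.missing_rate
        calls[mask] = MISSING

    samples = pd.DataFrame({
        "sample_id": [f"ind{i:05d}" for i in range(n_ind)],
        "phenotype": np.full(n_ind, -9, dtype=int),
    })
    return GenotypeMatrix(_marker_table(config), samples, calls)


def _tune_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection on alpha so that mean sigmoid(alpha + eta) == target."""
    lo, hi = -30.0, 30.0
    if not np.mean(expit(lo + eta)) <= target <= np.mean(expit(hi + eta)):
        raise ValueError("target case fraction unattainable")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.mean(expit(mid + eta)) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_phenotype(
    genotypes: GenotypeMatrix, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw case/control status and age for every individual.

    logit P(case) = alpha + sum_j beta_j x_j + gamma * age_z, with beta_j =
    ln(OR_j) under each planted effect's encoding and age_z the
    standardized age. The intercept alpha is tuned by bisection so the
    expected case fraction matches the configured n_cases / n.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n_ind = genotypes.n_samples
    age = rng.normal(config.age_mean, config.age_sd, size=n_ind)
    age_z = (age - config.age_mean) / config.age_sd
    eta = config.age_coefficient * config.age_sd * age_z
    for effect in config.planted_effects:
        eta = eta + effect.linear_term(genotypes.calls[effect.marker_index])
    alpha = _tune_intercept(eta, config.case_fraction)
    status = (rng.random(n_ind) < expit(alpha + eta)).astype(int)
    return status, age


def simulate_dataset(config: SimulationConfig,
                     oversample: float = 4.0) -> GenotypeMatrix:
    """Simulate a complete case-control dataset with exact class counts.

    A population pool ``oversample`` times the target size is generated,
    statuses are drawn from the liability model, and the first n_cases
    cases and n_controls controls are retained (case-control ascertainment
    from a larger population). Raises if the pool has too few of either
    class.
    """
    pool_n = int(np.ceil(oversample * config.n_samples))
    pool = simulate_genotypes(config, n_individuals=pool_n)
    status, age = simulate_phenotype(pool, config)

    case_idx = np.flatnonzero(status == 1)[: config.n_cases]
    ctrl_idx = np.flatnonzero(status == 0)[: config.n_controls]
    if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
        raise ValueError(
            f"pool of {pool_n} yielded {len(case_idx)} cases / "
            f"{len(ctrl_idx)} controls; increase oversample"
        )
    keep = np.sort(np.concatenate([case_idx, ctrl_idx]))
    calls = pool.calls[:, keep]
    samples = pd.DataFrame({
        "sample_id": [f"ind{i:05d}" for i in range(len(keep))],
        "phenotype": np.where(status[keep] == 1, PHENO_CASE, PHENO_CONTROL),
        "age": np.round(age[keep], 2),
    })
    return GenotypeMatrix(pool.markers.copy(), samples, calls)


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Planted-effect truth: marker_id, model, odds_ratio."""
    markers = _marker_table(config)
    rows = [{
        "marker_id": markers.iloc[e.marker_index]["marker_id"],
        "model": e.model,
        "odds_ratio": e.odds_ratio,
    } for e in config.planted_effects]
    return pd.DataFrame(rows, columns=["marker_id", "model", "odds_ratio"])


def write_fixture(gm: GenotypeMatrix, config: SimulationConfig,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write PED/MAP, covariate and truth files for a simulated dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "synthetic.ped",
        "map": out / "synthetic.map",
        "covar": out / "synthetic.covar",
        "truth": out / "synthetic.truth.tsv",
    }
    write_ped_map(gm, paths["ped"], paths["map"])
    with open(paths["covar"], "w") as fh:
        fh.write("FID IID age\n")
        for row in gm.samples.itertuples(index=False):
            fh.write(f"{row.sample_id} {row.sample_id} {row.age}\n")
    truth_table(config).to_csv(paths["truth"], sep="\t", index=False)
    return paths
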