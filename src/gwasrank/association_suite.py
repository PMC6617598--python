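"""Per-SNP association approaches and ranked-list construction.

Each *approach* is a (method, encoding, implementation-variant, options)
configuration; the default registry enumerates the 25 approaches used in the
multi-approach workflow, spanning logistic regression under four genotype
encodings (two implementation variants), the classic contingency-table
family (allelic, trend, genotypic, dominant/recessive model tests, and a
best-of-models permutation test), three machine-learning scorers, and
import adapters for externally run mixed-model tools.

Every approach yields a :class:`RankedList`: a full ranking of all analyzed
SNPs, ordered by increasing p-value or decreasing score. Markers whose test
fails (non-convergence, separation, degenerate tables) keep their place in
the universe but receive the worst ranks, so that rank-based distances stay
defined on a common SNP domain.
"""

from __future__ import annotations

import zlib
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
    _chrom_sort_key,
)

ENCODINGS = ("additive", "dominant", "recessive", "codominant", "none")
METHODS = (
    "logistic",
    "allelic_chisq",
    "allelic_fisher",
    "trend",
    "genotypic",
    "model_dom",
    "model_rec",
    "model_best_perm",
    "mdr_ba",
    "entropy",
    "dec_tree",
    "external_import",
)
_COVARIATE_CAPABLE = {"logistic", "external_import"}


@dataclass(frozen=True)
class ApproachSpec:
    """One association approach: method, encoding, implementation, options."""

    name: str
    method: str
    encoding: str = "none"
    covariate_adjustment: bool = False
    implementation: str = "gwasrank"
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.covariate_adjustment and self.method not in _COVARIATE_CAPABLE:
            raise ValueError(
                f"{self.name}: method {self.method!r} does not support covariates"
            )

    @property
    def ordering_key(self) -> str:
        if self.method in ("mdr_ba", "entropy", "dec_tree"):
            return "score_descending"
        return "p_ascending"


def default_registry() -> list[ApproachSpec]:
    """The 25-approach registry: methods x encodings x implementations.

    External mixed-model/liability tools (CARAT global and LOCO, LTMLM,
    LEAP) are import adapters: their rankings are produced by the published
    software and read in as TSV.
    """
    specs = [
        # logistic regression, two implementation variants
        ApproachSpec("plink.add", "logistic", "additive", True, "plink"),
        ApproachSpec("plink.dom", "logistic", "dominant", True, "plink"),
        ApproachSpec("plink.rec", "logistic", "recessive", True, "plink"),
        ApproachSpec("plato.add", "logistic", "additive", True, "plato"),
        ApproachSpec("plato.dom", "logistic", "dominant", True, "plato"),
        ApproachSpec("plato.rec", "logistic", "recessive", True, "plato"),
        ApproachSpec("plato.codom", "logistic", "codominant", True, "plato"),
        # basic association tests
        ApproachSpec("plink.assoc", "allelic_chisq", "none", False, "plink"),
        ApproachSpec("plink.assoc.fisher", "allelic_fisher", "none", False, "plink"),
        ApproachSpec("plink.assoc.counts", "allelic_chisq", "none", False, "plink",
                     {"variant": "counts"}),
        ApproachSpec("plink.assoc.perm", "allelic_chisq", "none", False, "plink",
                     {"permutations": 100, "correction": "pointwise"}),
        ApproachSpec("plink.assoc.mperm", "allelic_chisq", "none", False, "plink",
                     {"permutations": 100, "correction": "maxT"}),
        # model tests
        ApproachSpec("plink.model.allelic", "allelic_chisq", "none", False, "plink",
                     {"variant": "model"}),
        ApproachSpec("plink.model.trend", "trend", "none", False, "plink"),
        ApproachSpec("plink.model.geno", "genotypic", "none", False, "plink"),
        ApproachSpec("plink.model.dom", "model_dom", "dominant", False, "plink"),
        ApproachSpec("plink.model.rec", "model_rec", "recessive", False, "plink"),
        ApproachSpec("plink.model.best.perm", "model_best_perm", "none", False,
                     "plink", {"permutations": 100}),
        # externally run tools (import adapters)
        ApproachSpec("carat", "external_import", "none", True, "carat"),
        ApproachSpec("carat.loco", "external_import", "none", True, "carat"),
        ApproachSpec("ltmlm", "external_import", "none", True, "ltmlm"),
        ApproachSpec("leap", "external_import", "none", True, "leap"),
        # machine-learning scorers
        ApproachSpec("mdr.ba", "mdr_ba", "none", False, "gwasrank",
                     {"folds": 10}),
        ApproachSpec("entropy", "entropy", "none", False, "gwasrank"),
        ApproachSpec("dec.tree", "dec_tree", "none", False, "gwasrank"),
    ]
    names = [s.name for s in specs]
    assert len(names) == len(set(names))
    return specs


# ---------------------------------------------------------------------------
# Genotype encodings
# ---------------------------------------------------------------------------


@dataclass
class EncodedDesign:
    """Numeric predictor columns for one marker under a given encoding.

    ``columns`` has shape (n_samples, 1) for additive/dominant/recessive and
    (n_samples, 2) for codominant (Het, Hom dummies); missing genotypes are
    NaN in every column.
    """

    columns: np.ndarray
    encoding: str
    column_names: list[str]


def encode_genotype(calls: np.ndarray, scheme: str) -> EncodedDesign:
    """Encode 0/1/2 alternate-allele counts under the requested scheme.

    additive keeps 0/1/2; dominant maps 1,2 -> 1; recessive maps only 2 -> 1;
    codominant yields two dummies, Het (call == 1) and Hom (call == 2).
    Missing calls propagate as NaN.
    """
    calls = np.asarray(calls)
    g = calls.astype(float)
    g[calls == MISSING] = np.nan
    if scheme == "additive":
        cols, names = g[:, None], ["add"]
    elif scheme == "dominant":
        cols, names = (g >= 1).astype(float)[:, None], ["dom"]
        cols[np.isnan(g), 0] = np.nan
    elif scheme == "recessive":
        cols, names = (g == 2).astype(float)[:, None], ["rec"]
        cols[np.isnan(g), 0] = np.nan
    elif scheme == "codominant":
        het = (g == 1).astype(float)
        hom = (g == 2).astype(float)
        het[np.isnan(g)] = np.nan
        hom[np.isnan(g)] = np.nan
        cols, names = np.column_stack([het, hom]), ["het", "hom"]
    else:
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    return EncodedDesign(cols, scheme, names)


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------


@dataclass
class LogisticResult:
    betas: np.ndarray  # coefficients of the encoding column(s)
    ses: np.ndarray
    p_value: float
    n_used: int
    failed: bool = False
    reason: str | None = None


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 25
          ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton/IRLS fit; returns (beta, se, loglik, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    cov = np.full((p, p), np.nan)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        info = X.T @ (X * w[:, None])
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), -np.inf, False
        beta = beta + step
        ll = _log_likelihood(y, X @ beta)
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        converged = False
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return beta, se, ll_old, converged


def logistic_test(
    phenotype: np.ndarray,
    design: EncodedDesign,
    covariates: np.ndarray | None = None,
    max_abs_beta: float = 15.0,
) -> LogisticResult:
    """Case-control logistic regression for one marker.

    Fits intercept + encoding column(s) + covariates by IRLS on complete
    cases. The p-value is a Wald test on the single encoding coefficient for
    additive/dominant/recessive, and a 2-df likelihood-ratio test against
    the covariate-only null for codominant. Non-convergence or (quasi-)
    separation (|beta| above ``max_abs_beta``) flags the marker as failed.
    """
    pheno = np.asarray(phenotype, dtype=float)
    enc = design.columns
    n_enc = enc.shape[1]
    parts = [enc]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        parts.append(cov)
    Xfull = np.column_stack(parts)
    ok = np.isfinite(Xfull).all(axis=1) & np.isin(pheno, [PHENO_CASE, PHENO_CONTROL])
    y = pheno[ok]
    Xfull = Xfull[ok]
    n = int(ok.sum())

    def fail(reason: str) -> LogisticResult:
        return LogisticResult(np.full(n_enc, np.nan), np.full(n_enc, np.nan),
                              np.nan, n, failed=True, reason=reason)

    if n == 0 or len(np.unique(y)) < 2:
        return fail("single_class")
    X = np.column_stack([np.ones(n), Xfull])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return fail("rank_deficient")

    beta, se, ll, converged = _irls(X, y)
    if not converged:
        return fail("non_convergence")
    enc_beta = beta[1: 1 + n_enc]
    enc_se = se[1: 1 + n_enc]
    if np.any(np.abs(enc_beta) > max_abs_beta):
        return fail("separation")

    if design.encoding == "codominant":
        X0 = np.delete(X, [1, 2], axis=1)  # intercept + covariates
        _b0, _s0, ll0, conv0 = _irls(X0, y)
        if not conv0:
            return fail("null_non_convergence")
        lrt = max(0.0, 2.0 * (ll - ll0))
        p = float(stats.chi2.sf(lrt, df=2))
    else:
        z = enc_beta[0] / enc_se[0]
        p = float(2.0 * stats.norm.sf(abs(z)))
    return LogisticResult(enc_beta, enc_se, p, n)


# ---------------------------------------------------------------------------
# Contingency-table tests
# ---------------------------------------------------------------------------


class DegenerateTableError(ValueError):
    """A contingency table is too degenerate for the requested test."""


def genotype_table(calls: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """2x3 genotype counts: rows (cases, controls), columns (0, 1, 2)."""
    calls = np.asarray(calls)
    pheno = np.asarray(phenotype)
    ok = calls != MISSING
    out = np.zeros((2, 3), dtype=int)
    for row, cls in enumerate((PHENO_CASE, PHENO_CONTROL)):
        sel = ok & (pheno == cls)
        out[row] = np.bincount(calls[sel], minlength=3)[:3]
    return out


def _chi2_2x2(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError("zero margin in 2x2 table")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    return float(((table - expected) ** 2 / expected).sum())


def allelic_test(
    case_allele_counts: np.ndarray,
    control_allele_counts: np.ndarray,
    exact: bool = False,
) -> float:
    """Allelic association on a 2x2 allele-count table.

    1-df chi-square without continuity correction, or two-sided Fisher
    exact when ``exact`` is true. Zero margins raise
    :class:`DegenerateTableError` (the marker is flagged by callers).
    """
    table = np.array([case_allele_counts, control_allele_counts], dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 allele-count table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError("zero margin in allele-count table")
    if exact:
        return float(stats.fisher_exact(table.astype(int))[1])
    chi2 = _chi2_2x2(table)
    return float(stats.chi2.sf(chi2, df=1))


def allele_table_from_genotypes(table_2x3: np.ndarray) -> np.ndarray:
    """Collapse a 2x3 genotype table to a 2x2 (ref, alt) allele-count table."""
    t = np.asarray(table_2x3)
    ref = 2 * t[:, 0] + t[:, 1]
    alt = t[:, 1] + 2 * t[:, 2]
    return np.column_stack([ref, alt])


def trend_statistic(table_2x3: np.ndarray) -> float:
    """Cochran-Armitage trend chi-square statistic with weights (0, 1, 2)."""
    t = np.asarray(table_2x3, dtype=float)
    r = t[0]  # cases
    n_col = t.sum(axis=0)
    big_n = t.sum()
    big_r = r.sum()
    if big_r == 0 or big_r == big_n:
        raise DegenerateTableError("one phenotype class absent")
    w = np.array([0.0, 1.0, 2.0])
    t_num = float(w @ r - big_r / big_n * (w @ n_col))
    var = (big_r * (big_n - big_r) / big_n ** 3) * (
        big_n * (w ** 2 @ n_col) - (w @ n_col) ** 2
    )
    if var <= 0:
        raise DegenerateTableError("degenerate genotype distribution")
    return t_num ** 2 / var


def trend_test(
    genotype_counts_cases: np.ndarray, genotype_counts_controls: np.ndarray
) -> float:
    """Cochran-Armitage trend test p-value (1-df chi-square)."""
    table = np.array([genotype_counts_cases, genotype_counts_controls])
    if np.count_nonzero(table.sum(axis=0)) < 2:
        raise DegenerateTableError("only one genotype class present")
    stat = trend_statistic(table)
    return float(stats.chi2.sf(stat, df=1))


def genotypic_test(table_2x3: np.ndarray) -> float:
    """2-df Pearson chi-square on the full 2x3 genotype table."""
    t = np.asarray(table_2x3, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2:
        raise DegenerateTableError("fewer than two genotype classes")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if np.any(expected == 0):
        raise DegenerateTableError("zero expected cell")
    chi2 = float(((t - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=t.shape[1] - 1))


def model_collapsed_test(table_2x3: np.ndarray, mode: str) -> float:
    """Dominant/recessive 1-df chi-square on the collapsed genotype table."""
    t = np.asarray(table_2x3, dtype=float)
    if mode == "dom":
        collapsed = np.column_stack([t[:, 0], t[:, 1] + t[:, 2]])
    elif mode == "rec":
        collapsed = np.column_stack([t[:, 0] + t[:, 1], t[:, 2]])
    else:
        raise ValueError(f"mode must be 'dom' or 'rec', got {mode!r}")
    chi2 = _chi2_2x2(collapsed)
    return float(stats.chi2.sf(chi2, df=1))


_BEST_COMPONENTS = ("allelic", "trend", "genotypic", "dom", "rec")


def _min_p_over_models(table: np.ndarray) -> tuple[float, str]:
    ps = []
    for name in _BEST_COMPONENTS:
        try:
            if name == "allelic":
                at = allele_table_from_genotypes(table)
                p = allelic_test(at[0], at[1])
            elif name == "trend":
                p = trend_test(table[0], table[1])
            elif name == "genotypic":
                p = genotypic_test(table)
            else:
                p = model_collapsed_test(table, name)
        except DegenerateTableError:
            p = np.nan
        ps.append(p)
    ps = np.asarray(ps)
    if np.all(np.isnan(ps)):
        raise DegenerateTableError("all component model tests degenerate")
    best = int(np.nanargmin(ps))
    return float(ps[best]), _BEST_COMPONENTS[best]


def model_best_perm(
    calls: np.ndarray,
    phenotype: np.ndarray,
    permutations: int,
    seed: int,
) -> tuple[str, float]:
    """Best-of-models permutation test for one marker.

    The observed statistic is the minimum p over the allelic, trend,
    genotypic, dominant and recessive model tests. Phenotype labels are
    permuted ``permutations`` times and the empirical p-value is
    (1 + #{permuted min-p <= observed}) / (1 + permutations).
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    calls = np.asarray(calls)
    pheno = np.asarray(phenotype).copy()
    obs_p, best_label = _min_p_over_models(genotype_table(calls, pheno))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(pheno)
        try:
            perm_p, _ = _min_p_over_models(genotype_table(calls, perm))
        except DegenerateTableError:
            continue
        if perm_p <= obs_p:
            hits += 1
    return best_label, (1 + hits) / (1 + permutations)


# ---------------------------------------------------------------------------
# Ranked lists
# ---------------------------------------------------------------------------


@dataclass
class RankedList:
    """A full ranking of all analyzed SNPs for one approach.

    ``entries`` has columns marker_id, score, p_value, rank; ranks are a
    permutation of 1..N with rank 1 the most associated marker.
    """

    approach: str
    entries: pd.DataFrame
    ordering_key: str  # p_ascending | score_descending

    @property
    def ranking(self) -> pd.Series:
        return self.entries.set_index("marker_id")["rank"]

    def top_k(self, k: int) -> set[str]:
        e = self.entries
        return set(e.loc[e["rank"] <= k, "marker_id"])

    def write_tsv(self, path: str | Path) -> None:
        out = self.entries[["marker_id", "score", "p_value", "rank"]]
        out.to_csv(path, sep="\t", index=False, na_rep="")


def rank_snps(
    values: pd.DataFrame,
    ordering_key: str,
    marker_map: pd.DataFrame,
    approach: str = "",
) -> RankedList:
    """Assign dense ranks 1..N from per-marker scores or p-values.

    ``values`` needs columns marker_id plus p_value and/or score, and
    optionally a boolean ``flagged`` column. Ties are broken by genomic
    order (chromosome, position, marker_id); flagged/failed markers are
    placed after all valid markers, ordered by the same tie-break.
    """
    if ordering_key not in ("p_ascending", "score_descending"):
        raise ValueError(f"unknown ordering_key {ordering_key!r}")
    df = values.copy()
    if df["marker_id"].duplicated().any():
        dups = sorted(set(df.loc[df["marker_id"].duplicated(), "marker_id"]))
        raise ValueError(f"duplicate marker ids: {dups}")
    if "p_value" not in df:
        df["p_value"] = np.nan
    if "score" not in df:
        df["score"] = np.nan
    if "flagged" not in df:
        df["flagged"] = False

    mm = marker_map.set_index("marker_id")
    missing_map = set(df["marker_id"]) - set(mm.index)
    if missing_map:
        raise ValueError(f"markers absent from marker map: {sorted(missing_map)}")
    df["_chrom_key"] = _chrom_sort_key(
        mm.loc[df["marker_id"], "chromosome"].reset_index(drop=True)
    )
    df["_pos"] = mm.loc[df["marker_id"], "position_bp"].to_numpy()

    primary = df["p_value"] if ordering_key == "p_ascending" else -df["score"]
    primary = primary.astype(float)
    flagged = df["flagged"].astype(bool) | ~np.isfinite(primary)
    df["_flagged"] = flagged
    df["_primary"] = np.where(flagged, np.inf, primary)

    df = df.sort_values(
        by=["_flagged", "_primary", "_chrom_key", "_pos", "marker_id"],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    ranks = df["rank"].to_numpy()
    assert np.array_equal(np.sort(ranks), np.arange(1, len(df) + 1))
    entries = df[["marker_id", "score", "p_value", "rank"]]
    return RankedList(approach, entries, ordering_key)


def import_external_ranking(
    tsv_path: str | Path,
    approach_name: str,
    marker_map: pd.DataFrame | None = None,
    strict: bool = True,
) -> RankedList:
    """Read an externally produced per-SNP result table as a RankedList.

    The TSV needs a header with marker_id and at least one of p_value /
    score. When a marker map (the current dataset's markers) is supplied,
    unknown markers raise an error in strict mode or are dropped otherwise;
    no overlap at all is always an error.
    """
    df = pd.read_csv(tsv_path, sep="\t")
    if "marker_id" not in df.columns:
        raise ValueError(f"{tsv_path}: missing required column marker_id")
    if "p_value" not in df.columns and "score" not in df.columns:
        raise ValueError(f"{tsv_path}: need a p_value or score column")

    if marker_map is not None:
        known = set(marker_map["marker_id"])
        unknown = [m for m in df["marker_id"] if m not in known]
        overlap = [m for m in df["marker_id"] if m in known]
        if not overlap:
            raise ValueError(f"{tsv_path}: no overlap with dataset markers")
        if unknown:
            if strict:
                raise ValueError(
                    f"{tsv_path}: markers not in dataset: {sorted(set(unknown))}"
                )
            df = df[df["marker_id"].isin(known)].reset_index(drop=True)
        mm = marker_map
    else:
        # no map available: file order provides the genomic tie-break
        mm = pd.DataFrame(
            {"marker_id": df["marker_id"], "chromosome": "0",
             "position_bp": np.arange(len(df))}
        )
    ordering = "p_ascending" if "p_value" in df.columns and df[
        "p_value"].notna().any() else "score_descending"
    return rank_snps(df, ordering, mm, approach=approach_name)


# ---------------------------------------------------------------------------
# Approach dispatcher
# ---------------------------------------------------------------------------


def _vectorized_allelic_chi2(calls: np.ndarray, case_mask: np.ndarray
                             ) -> np.ndarray:
    """Allelic 1-df chi-square for every marker at once (no correction)."""
    ok = calls != MISSING
    alt = np.where(ok, calls, 0).astype(float)
    n_case = (ok & case_mask).sum(axis=1)
    n_ctrl = (ok & ~case_mask).sum(axis=1)
    alt_case = (alt * (ok & case_mask)).sum(axis=1)
    alt_ctrl = (alt * (ok & ~case_mask)).sum(axis=1)
    a = 2 * n_case - alt_case  # ref alleles, cases
    b = alt_case
    c = 2 * n_ctrl - alt_ctrl
    d = alt_ctrl
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, np.nan)
    return chi2


def _run_permuted_allelic(
    gm: GenotypeMatrix, permutations: int, correction: str, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical allelic p-values: pointwise or max-T family-wise."""
    pheno = gm.phenotype
    used = np.isin(pheno, [PHENO_CASE, PHENO_CONTROL])
    calls = gm.calls[:, used]
    case_mask = (pheno[used] == PHENO_CASE)[None, :]
    obs = _vectorized_allelic_chi2(calls, case_mask)
    rng = np.random.default_rng(seed)
    hits = np.zeros(gm.n_markers)
    valid = np.isfinite(obs)
    for _ in range(permutations):
        perm = rng.permutation(case_mask[0])[None, :]
        stat = _vectorized_allelic_chi2(calls, perm)
        if correction == "maxT":
            mx = np.nanmax(stat) if np.isfinite(stat).any() else -np.inf
            hits += (mx >= obs) & valid
        else:
            hits += np.where(valid & np.isfinite(stat), stat >= obs, 0)
    p = np.where(valid, (1 + hits) / (1 + permutations), np.nan)
    return obs, p


def derive_seed(global_seed: int, label: str) -> int:
    """Stable per-approach (or per-marker) seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(label.encode())) % (2 ** 31)


def run_approach(
    spec: ApproachSpec,
    gm: GenotypeMatrix,
    covariate_names: list[str] | None = None,
    seed: int = 0,
) -> RankedList:
    """Run one internal approach over every marker and return its RankedList."""
    if spec.method == "external_import":
        path = spec.options.get("path")
        if not path:
            raise ValueError(
                f"{spec.name}: external approach needs options['path'] "
                "(use import_external_ranking)"
            )
        return import_external_ranking(path, spec.name, gm.markers)

    pheno = gm.phenotype
    covars = None
    if spec.covariate_adjustment and covariate_names:
        covars = gm.covariate_matrix(covariate_names)

    n = gm.n_markers
    scores = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)

    if spec.method == "allelic_chisq" and spec.options.get("permutations"):
        obs, p = _run_permuted_allelic(
            gm, int(spec.options["permutations"]),
            spec.options.get("correction", "pointwise"),
            derive_seed(seed, spec.name),
        )
        scores, pvals = obs, p
        flagged = ~np.isfinite(p)
    elif spec.method == "logistic":
        for j in range(n):
            design = encode_genotype(gm.calls[j], spec.encoding)
            res = logistic_test(pheno, design, covars)
            if res.failed:
                flagged[j] = True
            else:
                pvals[j] = res.p_value
                scores[j] = res.betas[0]
    elif spec.method in ("allelic_chisq", "allelic_fisher", "trend", "genotypic",
                         "model_dom", "model_rec", "model_best_perm"):
        approach_seed = derive_seed(seed, spec.name)
        for j in range(n):
            table = genotype_table(gm.calls[j], pheno)
            try:
                if spec.method in ("allelic_chisq", "allelic_fisher"):
                    at = allele_table_from_genotypes(table)
                    pvals[j] = allelic_test(
                        at[0], at[1], exact=spec.method == "allelic_fisher"
                    )
                elif spec.method == "trend":
                    pvals[j] = trend_test(table[0], table[1])
                elif spec.method == "genotypic":
                    pvals[j] = genotypic_test(table)
                elif spec.method == "model_dom":
                    pvals[j] = model_collapsed_test(table, "dom")
                elif spec.method == "model_rec":
                    pvals[j] = model_collapsed_test(table, "rec")
                else:  # model_best_perm
                    _label, pvals[j] = model_best_perm(
                        gm.calls[j], pheno,
                        int(spec.options.get("permutations", 100)),
                        derive_seed(approach_seed, gm.markers.iloc[j]["marker_id"]),
                    )
            except (DegenerateTableError, ValueError):
                flagged[j] = True
    elif spec.method in ("mdr_ba", "entropy", "dec_tree"):
        from gwasrank import ml_scorers

        approach_seed = derive_seed(seed, spec.name)
        for j in range(n):
            try:
                if spec.method == "mdr_ba":
                    scores[j] = ml_scorers.mdr_1way(
                        gm.calls[j], pheno,
                        folds=int(spec.options.get("folds", 10)),
                        seed=approach_seed,
                    )
                elif spec.method == "entropy":
                    scores[j] = ml_scorers.entropy_gain(gm.calls[j], pheno)
                else:
                    scores[j] = ml_scorers.decision_tree_score(
                        gm.calls[j], pheno, seed=approach_seed
                    )
            except ValueError:
                flagged[j] = True
    else:  # pragma: no cover - registry validation prevents this
        raise ValueError(f"cannot run method {spec.method!r} internally")

    values = pd.DataFrame(
        {"marker_id": gm.marker_ids, "score": scores, "p_value": pvals,
         "flagged": flagged}
    )
    return rank_snps(values, spec.ordering_key, gm.markers, approach=spec.name)
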