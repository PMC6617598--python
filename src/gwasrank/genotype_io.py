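"""Genotype input/output, quality control, LD pruning and PCA.

Genotypes are held as a markers x samples matrix of alternate-allele counts
(0/1/2, with -1 for missing). The QC cascade mirrors the standard
case-control pipeline: marker missingness, sample missingness, minor allele
frequency, Hardy-Weinberg exact test (repeated once), then a differential
call-rate filter between cases and controls. LD pruning follows the classic
sliding-window r-squared rule (window 50 SNPs, step 5, threshold 0.2) and
principal components for covariate adjustment are computed on the pruned,
standardized matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

PHENO_CASE = 1
PHENO_CONTROL = 0
PHENO_MISSING = -9

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_ref", "allele_alt"]


class PedFormatError(ValueError):
    """A PED/MAP file violates the expected layout."""


class MultiAllelicError(ValueError):
    """A marker shows more than two distinct alleles."""


class EmptyAfterQcError(RuntimeError):
    """All markers or all samples were removed by the QC cascade."""


@dataclass(frozen=True)
class MarkerInfo:
    """One biallelic autosomal marker."""

    marker_id: str
    chromosome: str
    position_bp: int
    allele_ref: str
    allele_alt: str

    def __post_init__(self) -> None:
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"marker {self.marker_id}: ref and alt alleles are equal")
        if self.position_bp < 0:
            raise ValueError(f"marker {self.marker_id}: negative position")


@dataclass(frozen=True)
class SampleInfo:
    """One individual with phenotype and optional covariates."""

    sample_id: str
    phenotype: int  # PHENO_CASE / PHENO_CONTROL / PHENO_MISSING
    covariates: dict[str, float] = field(default_factory=dict)


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric key for autosome names '1'..'22' (non-numeric sorts last)."""
    return pd.to_numeric(chrom, errors="coerce").fillna(10**6)


@dataclass
class GenotypeMatrix:
    """Markers x samples matrix of alternate-allele counts.

    Attributes
    ----------
    markers : DataFrame with columns marker_id, chromosome, position_bp,
        allele_ref, allele_alt; rows sorted by (chromosome, position_bp).
    samples : DataFrame with columns sample_id, phenotype (1 = case,
        0 = control, -9 = missing) plus any numeric covariate columns.
    calls : int8 ndarray of shape (n_markers, n_samples); -1 = missing.
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls contain values outside {0, 1, 2, missing}")
        if self.markers["marker_id"].duplicated().any():
            dups = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids: {sorted(set(dups))}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        key = list(
            zip(_chrom_sort_key(self.markers["chromosome"]), self.markers["position_bp"])
        )
        if key != sorted(key):
            raise ValueError("markers must be sorted by (chromosome, position_bp)")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy()

    def covariate_matrix(self, names: list[str]) -> np.ndarray:
        return self.samples[names].to_numpy(dtype=float)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.markers.loc[mask].copy(), self.samples.copy(), self.calls[mask]
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.markers.copy(), self.samples.loc[mask].copy(), self.calls[:, mask]
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.markers.equals(other.markers)
            and self.samples.equals(other.samples)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# PED/MAP reading and writing
# ---------------------------------------------------------------------------

_PED_PHENO_DECODE = {"2": PHENO_CASE, "1": PHENO_CONTROL}
_PED_PHENO_ENCODE = {PHENO_CASE: "2", PHENO_CONTROL: "1", PHENO_MISSING: "0"}


def _read_map(map_path: str | Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise PedFormatError(
                    f"{map_path}:{lineno}: expected 4 fields (CHR ID cM BP), "
                    f"got {len(fields)}"
                )
            chrom, mid, _cm, bp = fields
            rows.append((mid, chrom, int(bp)))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    alt_alleles: dict[str, str] | None = None,
    drop_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    The alternate allele at each marker is the minor allele observed across
    samples (tie at 0.5 broken alphabetically: the alphabetically later
    allele becomes the alternate), unless ``alt_alleles`` maps the marker id
    to an explicit alternate allele. "0 0" allele pairs are missing calls.

    Parameters
    ----------
    drop_multiallelic : if True, markers with more than two observed alleles
        are dropped (and reported in the exception-free path); otherwise a
        :class:`MultiAllelicError` is raised.
    """
    marker_map = _read_map(map_path)
    m = len(marker_map)

    sample_rows: list[tuple[str, int]] = []
    allele_rows: list[list[str]] = []  # per sample, flat list of 2m allele tokens
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise PedFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 header + 2 alleles x {m} markers), got {len(fields)}"
                )
            _fid, iid, _pat, _mat, _sex, pheno = fields[:6]
            sample_rows.append((iid, _PED_PHENO_DECODE.get(pheno, PHENO_MISSING)))
            allele_rows.append(fields[6:])

    n = len(sample_rows)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty(
        (0, m, 2), dtype=object
    )

    calls = np.full((m, n), MISSING, dtype=np.int8)
    ref_list: list[str] = []
    alt_list: list[str] = []
    multiallelic: list[str] = []
    for j in range(m):
        a = alleles[:, j, :]  # n x 2
        present = a != "0"
        observed = sorted({tok for tok in a[present]})
        if len(observed) > 2:
            mid = marker_map.loc[j, "marker_id"]
            if drop_multiallelic:
                multiallelic.append(mid)
                ref_list.append("N")
                alt_list.append("M")
                continue
            raise MultiAllelicError(
                f"marker {mid}: {len(observed)} distinct alleles {observed}"
            )
        mid = marker_map.loc[j, "marker_id"]
        if alt_alleles is not None and mid in alt_alleles:
            alt = alt_alleles[mid]
            others = [x for x in observed if x != alt]
            ref = others[0] if others else "N"
        elif len(observed) == 0:
            ref, alt = "N", "M"  # all-missing marker; placeholder alleles
        elif len(observed) == 1:
            ref, alt = observed[0], ("N" if observed[0] != "N" else "M")
        else:
            counts = {x: int((a == x).sum()) for x in observed}
            x0, x1 = observed  # alphabetical order
            if counts[x0] < counts[x1]:
                alt, ref = x0, x1
            elif counts[x1] < counts[x0]:
                alt, ref = x1, x0
            else:
                # tie at 0.5: alphabetically later allele is the alternate
                ref, alt = x0, x1
        ref_list.append(ref)
        alt_list.append(alt)
        both_called = present.all(axis=1)
        calls[j, both_called] = (a[both_called] == alt).sum(axis=1)

    markers = marker_map.copy()
    markers["allele_ref"] = ref_list
    markers["allele_alt"] = alt_list
    markers = markers[MARKER_COLUMNS]
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "phenotype"])

    keep = ~markers["marker_id"].isin(multiallelic)
    order = np.lexsort(
        (markers["position_bp"], _chrom_sort_key(markers["chromosome"]))
    )
    order = [i for i in order if keep.iloc[i]]
    return GenotypeMatrix(markers.iloc[order], samples, calls[order])


def write_ped_map(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a PED/MAP pair; inverse of :func:`read_ped_map` for minor-alt data."""
    with open(map_path, "w") as fh:
        for row in gm.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\n")

    ref = gm.markers["allele_ref"].to_numpy()
    alt = gm.markers["allele_alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(gm.samples.itertuples(index=False)):
            fields = [srow.sample_id, srow.sample_id, "0", "0", "0",
                      _PED_PHENO_ENCODE[srow.phenotype]]
            col = gm.calls[:, i]
            for j in range(gm.n_markers):
                c = col[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [ref[j], ref[j]]
                elif c == 1:
                    fields += [ref[j], alt[j]]
                else:
                    fields += [alt[j], alt[j]]
            fh.write(" ".join(fields) + "\n")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited covariate table (header, FID IID, numerics).

    Returns a DataFrame indexed by IID with float covariate columns.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 3:
        raise PedFormatError(f"{path}: need FID IID plus at least one covariate")
    df = df.rename(columns={df.columns[0]: "FID", df.columns[1]: "IID"})
    out = df.set_index("IID").drop(columns=["FID"]).astype(float)
    return out


def attach_covariates(gm: GenotypeMatrix, covar: pd.DataFrame) -> GenotypeMatrix:
    """Join covariate columns onto the sample table by sample id."""
    samples = gm.samples.merge(
        covar, left_on="sample_id", right_index=True, how="left"
    )
    return GenotypeMatrix(gm.markers.copy(), samples, gm.calls.copy())


# ---------------------------------------------------------------------------
# Per-marker / per-sample statistics
# ---------------------------------------------------------------------------


def compute_maf(calls_for_marker: np.ndarray) -> float:
    """Minor allele frequency, folded into [0, 0.5].

    Raises ValueError on an all-missing marker (MAF undefined).
    """
    calls = np.asarray(calls_for_marker)
    ok = calls != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError("MAF undefined: all calls missing")
    p_alt = float(calls[ok].sum()) / (2.0 * n)
    return min(p_alt, 1.0 - p_alt)


def marker_missingness(calls_for_marker: np.ndarray) -> float:
    calls = np.asarray(calls_for_marker)
    if calls.size == 0:
        raise ValueError("empty marker row")
    return float((calls == MISSING).mean())


def sample_missingness(calls_for_sample: np.ndarray) -> float:
    calls = np.asarray(calls_for_sample)
    if calls.size == 0:
        raise ValueError("empty sample column")
    return float((calls == MISSING).mean())


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (of the same parity as the minor allele count)
    whose conditional probability does not exceed that of the observed
    configuration. Computed with exact integer weights, so the ordering of
    configurations is never subject to rounding.
    """
    if n_hom_ref < 0 or n_het < 0 or n_hom_alt < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)

    # weight(h) proportional to P(het = h | allele counts): multinomial x 2^h
    def weight(h: int) -> int:
        hom_rare = (rare - h) // 2
        hom_common = n - hom_rare - h
        return math.comb(n, hom_rare) * math.comb(n - hom_rare, h) * (1 << h)

    hs = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    w_obs = weights[n_het]
    p_num = sum(w for w in weights.values() if w <= w_obs)
    return p_num / total


def differential_missingness_test(
    calls_for_marker: np.ndarray, phenotypes: np.ndarray
) -> float:
    """Fisher exact p-value for unequal call rates in cases vs controls."""
    calls = np.asarray(calls_for_marker)
    pheno = np.asarray(phenotypes)
    case = pheno == PHENO_CASE
    ctrl = pheno == PHENO_CONTROL
    if not case.any() or not ctrl.any():
        raise ValueError("both phenotype classes required")
    called = calls != MISSING
    table = [
        [int((called & case).sum()), int((~called & case).sum())],
        [int((called & ctrl).sum()), int((~called & ctrl).sum())],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QcThresholds:
    marker_missingness: float = 0.01
    sample_missingness: float = 0.01
    maf: float = 0.05
    hwe_p: float = 1e-5
    diff_missingness_p: float = 1e-5


@dataclass
class QcReport:
    """Record of every QC removal: entity, step, offending value, threshold."""

    thresholds: QcThresholds
    records: list[dict] = field(default_factory=list)

    def add(self, entity_id: str, entity_type: str, step: str, value: float,
            threshold: float) -> None:
        self.records.append(
            {"entity_id": entity_id, "entity_type": entity_type, "step": step,
             "value": value, "threshold": threshold}
        )

    @property
    def removed_markers(self) -> list[tuple[str, str]]:
        return [(r["entity_id"], r["step"]) for r in self.records
                if r["entity_type"] == "marker"]

    @property
    def removed_samples(self) -> list[tuple[str, str]]:
        return [(r["entity_id"], r["step"]) for r in self.records
                if r["entity_type"] == "sample"]

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r["step"]] = out.get(r["step"], 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = ["entity_id", "entity_type", "step", "value", "threshold"]
        return pd.DataFrame(self.records, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_qc(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the QC filter cascade in its canonical order.

    Order: marker missingness, sample missingness, MAF, HWE exact test; the
    whole sequence repeated once (sample removal can change marker
    statistics); finally the differential call-rate filter between cases and
    controls. Raises :class:`EmptyAfterQcError` if nothing survives.
    """
    thresholds = thresholds or QcThresholds()
    report = QcReport(thresholds=thresholds)
    current = gm

    def drop_markers(mask_remove: np.ndarray, step: str, values: np.ndarray,
                     threshold: float) -> None:
        nonlocal current
        if mask_remove.any():
            for idx in np.flatnonzero(mask_remove):
                report.add(current.markers.iloc[idx]["marker_id"], "marker", step,
                           float(values[idx]), threshold)
            current = current.subset_markers(~mask_remove)
            if current.n_markers == 0:
                raise EmptyAfterQcError(f"no markers left after step {step}")

    def drop_samples(mask_remove: np.ndarray, step: str, values: np.ndarray,
                     threshold: float) -> None:
        nonlocal current
        if mask_remove.any():
            for idx in np.flatnonzero(mask_remove):
                report.add(current.samples.iloc[idx]["sample_id"], "sample", step,
                           float(values[idx]), threshold)
            current = current.subset_samples(~mask_remove)
            if current.n_samples == 0:
                raise EmptyAfterQcError(f"no samples left after step {step}")

    for _pass in (1, 2):
        miss_m = (current.calls == MISSING).mean(axis=1)
        drop_markers(miss_m > thresholds.marker_missingness, "marker_missingness",
                     miss_m, thresholds.marker_missingness)

        miss_s = (current.calls == MISSING).mean(axis=0)
        drop_samples(miss_s > thresholds.sample_missingness, "sample_missingness",
                     miss_s, thresholds.sample_missingness)

        ok = current.calls != MISSING
        n_ok = ok.sum(axis=1)
        alt_sum = np.where(ok, current.calls, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_alt = np.where(n_ok > 0, alt_sum / (2.0 * n_ok), 0.0)
        maf = np.minimum(p_alt, 1.0 - p_alt)
        maf = np.where(n_ok > 0, maf, 0.0)  # all-missing marker: treat as MAF 0
        drop_markers(maf < thresholds.maf, "maf", maf, thresholds.maf)

        hwe_p = np.array([
            hwe_exact_test(
                int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())
            )
            for row in current.calls
        ])
        drop_markers(hwe_p < thresholds.hwe_p, "hwe", hwe_p, thresholds.hwe_p)

    pheno = current.phenotype
    if (pheno == PHENO_CASE).any() and (pheno == PHENO_CONTROL).any():
        diff_p = np.array([
            differential_missingness_test(row, pheno) for row in current.calls
        ])
        drop_markers(diff_p < thresholds.diff_missingness_p,
                     "differential_missingness", diff_p,
                     thresholds.diff_missingness_p)

    return current, report


# ---------------------------------------------------------------------------
# LD pruning and PCA
# ---------------------------------------------------------------------------


def ld_r2(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Squared Pearson correlation of two 0/1/2 call vectors.

    Uses pairwise-complete samples; raises ValueError when either marker is
    monomorphic on the complete subset (r-squared undefined).
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise ValueError("need at least 2 pairwise-complete samples")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("r2 undefined: marker monomorphic on complete subset")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> list[str]:
    """Sliding-window LD pruning; returns retained marker ids in order.

    Within each window, while any retained pair has r2 above the threshold,
    the member with the lower MAF is removed (tie: the later coordinate).
    Pairs with undefined r2 are skipped. Windows never span chromosomes.
    """
    maf = np.empty(gm.n_markers)
    for j in range(gm.n_markers):
        try:
            maf[j] = compute_maf(gm.calls[j])
        except ValueError:
            maf[j] = -1.0  # undefined: prune-neutral, always the removal choice
    kept = np.ones(gm.n_markers, dtype=bool)

    chroms = gm.markers["chromosome"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n = len(idx)
        start = 0
        while start < n:
            window = idx[start: start + window_snps]
            removed_any = True
            while removed_any:
                removed_any = False
                active = [j for j in window if kept[j]]
                for ai in range(len(active)):
                    for bi in range(ai + 1, len(active)):
                        ja, jb = active[ai], active[bi]
                        try:
                            r2 = ld_r2(gm.calls[ja], gm.calls[jb])
                        except ValueError:
                            continue
                        if r2 > r2_threshold:
                            if maf[ja] < maf[jb]:
                                victim = ja
                            elif maf[jb] < maf[ja]:
                                victim = jb
                            else:
                                victim = jb  # tie: later coordinate
                            kept[victim] = False
                            removed_any = True
                            break
                    if removed_any:
                        break
            start += step_snps
    ids = gm.markers["marker_id"].to_numpy()
    return [str(ids[j]) for j in range(gm.n_markers) if kept[j]]


def pca_covariates(
    gm: GenotypeMatrix, n_components: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the standardized genotype matrix.

    Markers are centered by 2p and scaled by sqrt(2p(1-p)) (the usual
    variance standardization for a binomial allele count); missing calls
    become 0 after centering (mean imputation). Returns the per-sample PC
    coordinates (eigenvector x sqrt(eigenvalue)) for the top ``n_components``
    components of the sample-sample covariance, plus the full non-increasing
    eigenvalue spectrum.
    """
    if n_components > gm.n_samples:
        raise ValueError(
            f"n_components={n_components} exceeds n_samples={gm.n_samples}"
        )
    X = gm.calls.astype(float)
    X[X == MISSING] = np.nan
    p = np.nanmean(X, axis=1) / 2.0
    usable = (p > 0) & (p < 1) & np.isfinite(p)
    X = X[usable]
    p = p[usable]
    if X.shape[0] == 0:
        raise ValueError("no polymorphic markers for PCA")
    X = (X - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    X[~np.isfinite(X)] = 0.0

    m = X.shape[0]
    # sample-sample covariance C = X^T X / m; eigen via SVD of X
    _u, s, vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = (s ** 2) / m
    scores = vt * np.sqrt(eigenvalues)[:, None]  # rows = components
    # deterministic sign: largest-|.| coordinate of each component positive
    for i in range(scores.shape[0]):
        j = int(np.argmax(np.abs(scores[i])))
        if scores[i, j] < 0:
            scores[i] = -scores[i]
    cols = {f"PC{i + 1}": scores[i] for i in range(n_components)}
    out = pd.DataFrame(cols, index=gm.samples["sample_id"].to_numpy())
    out.index.name = "sample_id"
    return out, eigenvalues
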