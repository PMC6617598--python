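"""Unit and property tests for genotype I/O, QC, LD pruning and PCA."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwasrank import genotype_io as gio
from gwasrank.synthetic_data import SimulationConfig, simulate_dataset, \
    simulate_genotypes, write_fixture

from conftest import make_gm


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------


def _write(path, text):
    path.write_text(text)
    return path


class TestPedMap:
    def test_minor_allele_becomes_alt(self, tmp_path):
        ped = _write(tmp_path / "a.ped",
                     "f1 s1 0 0 0 2 A A\nf2 s2 0 0 0 1 A G\n")
        mp = _write(tmp_path / "a.map", "1 m1 0 500\n")
        gm = gio.read_ped_map(ped, mp)
        assert gm.markers.iloc[0]["allele_alt"] == "G"
        assert gm.calls.tolist() == [[0, 1]]
        assert gm.samples["phenotype"].tolist() == [1, 0]

    def test_zero_zero_is_missing(self, tmp_path):
        ped = _write(tmp_path / "a.ped",
                     "f1 s1 0 0 0 2 0 0\nf2 s2 0 0 0 1 A G\n")
        mp = _write(tmp_path / "a.map", "1 m1 0 500\n")
        gm = gio.read_ped_map(ped, mp)
        assert gm.calls[0, 0] == gio.MISSING

    def test_allele_count_mismatch_names_line(self, tmp_path):
        ped = _write(tmp_path / "a.ped", "f1 s1 0 0 0 2 A A G\n")
        mp = _write(tmp_path / "a.map", "1 m1 0 500\n")
        with pytest.raises(gio.PedFormatError, match=":1:"):
            gio.read_ped_map(ped, mp)

    def test_multiallelic_raises_or_drops(self, tmp_path):
        ped = _write(tmp_path / "a.ped",
                     "f1 s1 0 0 0 2 A A\nf2 s2 0 0 0 1 C G\n")
        mp = _write(tmp_path / "a.map", "1 m1 0 500\n")
        with pytest.raises(gio.MultiAllelicError, match="m1"):
            gio.read_ped_map(ped, mp)
        gm = gio.read_ped_map(ped, mp, drop_multiallelic=True)
        assert gm.n_markers == 0

    def test_roundtrip_on_simulated_fixture(self, tmp_path):
        config = SimulationConfig(n_cases=20, n_controls=20, n_markers=3,
                                  seed=5, missing_rate=0.1)
        gm = simulate_dataset(config)
        paths = write_fixture(gm, config, tmp_path)
        back = gio.read_ped_map(paths["ped"], paths["map"])
        again_dir = tmp_path / "again"
        again_dir.mkdir()
        gio.write_ped_map(back, again_dir / "b.ped", again_dir / "b.map")
        back2 = gio.read_ped_map(again_dir / "b.ped", again_dir / "b.map")
        assert back.equals(back2)
        assert np.array_equal(back.calls, gm.calls)

    def test_covariate_file_roundtrip(self, tmp_path):
        config = SimulationConfig(n_cases=10, n_controls=10, n_markers=2, seed=5)
        gm = simulate_dataset(config)
        paths = write_fixture(gm, config, tmp_path)
        cov = gio.read_covariates(paths["covar"])
        bare = gio.GenotypeMatrix(
            gm.markers.copy(), gm.samples[["sample_id", "phenotype"]].copy(),
            gm.calls.copy(),
        )
        merged = gio.attach_covariates(bare, cov)
        assert np.allclose(merged.samples["age"], gm.samples["age"])


# ---------------------------------------------------------------------------
# Marker statistics
# ---------------------------------------------------------------------------


class TestMaf:
    @pytest.mark.parametrize("calls,expected", [
        ([0, 1, 2, 1], 0.5),
        ([0, 0, 0, 0], 0.0),
        ([2, 2, 2, 1], 1 / 8),
    ])
    def test_examples(self, calls, expected):
        assert gio.compute_maf(np.array(calls)) == pytest.approx(expected)

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            gio.compute_maf(np.array([gio.MISSING, gio.MISSING]))

    @given(st.lists(st.sampled_from([0, 1, 2, gio.MISSING]), min_size=1,
                    max_size=40).filter(lambda c: any(x != gio.MISSING for x in c)))
    def test_folded_range(self, calls):
        maf = gio.compute_maf(np.array(calls))
        assert 0.0 <= maf <= 0.5


class TestMissingness:
    def test_examples(self):
        assert gio.marker_missingness(np.array([0, 1, gio.MISSING, 2])) == 0.25
        assert gio.marker_missingness(np.array([0, 1, 2])) == 0.0
        assert gio.sample_missingness(np.array([gio.MISSING] * 3)) == 1.0


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exhaustive rational-arithmetic HWE exact test oracle.

    Enumerates every heterozygote count compatible with the observed allele
    counts, computes each configuration's conditional probability exactly,
    and sums those not exceeding the observed configuration's.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_alt, 2 * n - n_alt)

    def prob(h: int) -> Fraction:
        hom_rare = (rare - h) // 2
        hom_common = n - hom_rare - h
        num = (Fraction(math.factorial(n),
                        math.factorial(hom_rare) * math.factorial(h)
                        * math.factorial(hom_common))
               * Fraction(math.factorial(n_alt)
                          * math.factorial(2 * n - n_alt),
                          math.factorial(2 * n)))
        return num * Fraction(2) ** h

    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs)


class TestHweExact:
    @pytest.mark.parametrize("n", [1, 5, 20])
    def test_monomorphic_is_one(self, n):
        assert gio.hwe_exact_test(n, 0, 0) == 1.0

    def test_enumeration_oracle_examples(self):
        assert gio.hwe_exact_test(5, 3, 2) == pytest.approx(
            float(hwe_oracle(5, 3, 2)), abs=1e-12)
        p = gio.hwe_exact_test(1, 0, 1)
        assert p == pytest.approx(float(hwe_oracle(1, 0, 1)), abs=1e-12)
        assert p < 1.0  # the all-het configuration is more probable

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gio.hwe_exact_test(-1, 2, 3)

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
           .filter(lambda t: sum(t) >= 1))
    @settings(max_examples=150, deadline=None)
    def test_matches_oracle(self, counts):
        a, b, c = counts
        assert gio.hwe_exact_test(a, b, c) == pytest.approx(
            float(hwe_oracle(a, b, c)), abs=1e-12)


def fisher_oracle(table) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                        math.comb(n, c1))

    obs = prob(a)
    return sum(prob(x) for x in range(0, c1 + 1) if prob(x) <= obs)


class TestDifferentialMissingness:
    def test_no_missingness_p_one(self):
        calls = np.array([0] * 20)
        pheno = np.array([1] * 10 + [0] * 10)
        assert gio.differential_missingness_test(calls, pheno) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        # cases: 8 called / 2 missing; controls: 2 called / 8 missing
        calls = np.array([0] * 8 + [gio.MISSING] * 2 + [0] * 2 + [gio.MISSING] * 8)
        pheno = np.array([1] * 10 + [0] * 10)
        p = gio.differential_missingness_test(calls, pheno)
        assert p == pytest.approx(float(fisher_oracle([[8, 2], [2, 8]])),
                                  rel=1e-9)

    def test_equal_proportions_p_one(self):
        calls = np.array([0] * 8 + [gio.MISSING] * 2 + [0] * 8 + [gio.MISSING] * 2)
        pheno = np.array([1] * 10 + [0] * 10)
        assert gio.differential_missingness_test(calls, pheno) == pytest.approx(1.0)

    def test_one_class_absent_is_error(self):
        with pytest.raises(ValueError):
            gio.differential_missingness_test(np.zeros(5, int), np.ones(5, int))


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------


class TestApplyQc:
    def test_low_maf_marker_removed_with_reason(self):
        rng = np.random.default_rng(0)
        common = rng.binomial(2, 0.4, size=(3, 100)).astype(np.int8)
        rare = np.zeros((1, 100), np.int8)
        rare[0, :8] = 1  # MAF 0.04
        gm = make_gm(np.vstack([common, rare]),
                     phenotype=[1] * 50 + [0] * 50)
        _gm2, report = gio.apply_qc(gm)
        assert ("m3", "maf") in report.removed_markers

    def test_clean_matrix_unchanged(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.4, size=(5, 200)).astype(np.int8)
        gm = make_gm(calls, phenotype=[1] * 100 + [0] * 100)
        gm2, report = gio.apply_qc(gm)
        assert gm2.equals(gm)
        assert report.records == []

    def test_high_missingness_marker_removed_at_that_step(self):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.4, size=(3, 100)).astype(np.int8)
        calls[1, :5] = gio.MISSING  # 5% missing
        gm = make_gm(calls, phenotype=[1] * 50 + [0] * 50)
        _gm2, report = gio.apply_qc(gm)
        assert ("m1", "marker_missingness") in report.removed_markers

    def test_order_maf_before_hwe(self):
        """A marker failing both MAF and HWE is reported under MAF: the
        MAF filter runs first in the cascade."""
        rng = np.random.default_rng(3)
        common = rng.binomial(2, 0.4, size=(2, 100)).astype(np.int8)
        # MAF 0.04 and total heterozygote deficiency (4 hom-alt, 0 het)
        bad = np.zeros((1, 100), np.int8)
        bad[0, :4] = 2
        assert gio.hwe_exact_test(96, 0, 4) < 1e-5
        gm = make_gm(np.vstack([common, bad]), phenotype=[1] * 50 + [0] * 50)
        _gm2, report = gio.apply_qc(gm)
        steps = dict(report.removed_markers)
        assert steps["m2"] == "maf"

    def test_empty_result_raises(self):
        calls = np.zeros((2, 50), np.int8)  # all monomorphic -> MAF 0
        gm = make_gm(calls, phenotype=[1] * 25 + [0] * 25)
        with pytest.raises(gio.EmptyAfterQcError):
            gio.apply_qc(gm)

    def test_report_tsv_layout(self, tmp_path):
        rng = np.random.default_rng(0)
        common = rng.binomial(2, 0.4, size=(2, 100)).astype(np.int8)
        rare = np.zeros((1, 100), np.int8)
        rare[0, :4] = 1
        gm = make_gm(np.vstack([common, rare]), phenotype=[1] * 50 + [0] * 50)
        _gm2, report = gio.apply_qc(gm)
        out = tmp_path / "qc.tsv"
        report.write_tsv(out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == ["entity_id", "entity_type", "step", "value", "threshold"]


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


class TestLdR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 0, 1])
        assert gio.ld_r2(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert gio.ld_r2(np.array([0, 0, 1, 1]),
                         np.array([0, 1, 0, 1])) == pytest.approx(0.0)

    def test_closed_form_oracle(self):
        a = np.array([0, 1, 2, 0], float)
        b = np.array([0, 1, 1, 1], float)
        r = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert gio.ld_r2(a.astype(int), b.astype(int)) == pytest.approx(r * r)

    def test_symmetry_and_allele_flip_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        r2 = gio.ld_r2(a, b)
        assert gio.ld_r2(b, a) == pytest.approx(r2)
        assert gio.ld_r2(2 - a, b) == pytest.approx(r2)
        assert gio.ld_r2(a, 2 - b) == pytest.approx(r2)

    def test_monomorphic_is_error(self):
        with pytest.raises(ValueError):
            gio.ld_r2(np.array([1, 1, 1, 1]), np.array([0, 1, 2, 0]))


def brute_force_prune(calls, maf, window, threshold):
    """Naive within-window pruning oracle applying the same removal rule."""
    kept = list(range(calls.shape[0]))
    removed = True
    while removed:
        removed = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept[i], kept[j]
                if b - a >= window:
                    continue
                va, vb = calls[a].astype(float), calls[b].astype(float)
                if va.std() == 0 or vb.std() == 0:
                    continue
                r2 = np.corrcoef(va, vb)[0, 1] ** 2
                if r2 > threshold:
                    victim = a if maf[a] < maf[b] else b
                    kept.remove(victim)
                    removed = True
                    break
            if removed:
                break
    return kept


class TestLdPrune:
    def test_duplicated_markers_keep_one(self):
        rng = np.random.default_rng(5)
        base = rng.binomial(2, 0.3, 50).astype(np.int8)
        gm = make_gm(np.vstack([base, base]))
        assert gio.ld_prune(gm) == ["m0"]

    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(6)
        calls = rng.binomial(2, 0.5, size=(5, 500)).astype(np.int8)
        gm = make_gm(calls)
        assert gio.ld_prune(gm) == [f"m{j}" for j in range(5)]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n = 200
        calls = rng.binomial(2, 0.4, size=(10, n)).astype(np.int8)
        # plant a high-LD triple: markers 3, 4, 5 nearly identical
        calls[4] = calls[3].copy()
        calls[5] = calls[3].copy()
        flip = rng.choice(n, 5, replace=False)
        calls[4, flip] = np.clip(calls[4, flip] + 1, 0, 2)
        gm = make_gm(calls)
        got = gio.ld_prune(gm, window_snps=10, step_snps=10, r2_threshold=0.2)
        maf = [gio.compute_maf(calls[j]) for j in range(10)]
        expect = brute_force_prune(calls, maf, 10, 0.2)
        assert got == [f"m{j}" for j in expect]


class TestPca:
    def test_separates_planted_subpopulations(self):
        config = SimulationConfig(
            n_cases=100, n_controls=100, n_markers=300, seed=9,
            structure_fraction=0.5, structure_divergence=0.3, missing_rate=0.0,
        )
        gm = simulate_genotypes(config)
        scores, _ = gio.pca_covariates(gm, 2)
        group = np.zeros(200)
        group[100:] = 1  # subpopulation 2 is the tail of the sample list
        r = np.corrcoef(scores["PC1"], group)[0, 1]
        assert abs(r) > 0.9

    def test_eigenvalue_sum_equals_total_variance(self):
        config = SimulationConfig(n_cases=30, n_controls=30, n_markers=50,
                                  seed=10, missing_rate=0.0)
        gm = simulate_genotypes(config)
        _scores, eigenvalues = gio.pca_covariates(gm, 3)
        X = gm.calls.astype(float)
        p = X.mean(axis=1) / 2
        ok = (p > 0) & (p < 1)
        X = (X[ok] - 2 * p[ok, None]) / np.sqrt(2 * p[ok] * (1 - p[ok]))[:, None]
        assert eigenvalues.sum() == pytest.approx((X ** 2).sum() / X.shape[0])
        assert np.all(np.diff(eigenvalues) <= 1e-9)

    def test_duplicating_samples_preserves_directions(self):
        config = SimulationConfig(n_cases=20, n_controls=20, n_markers=60,
                                  seed=12, missing_rate=0.0)
        gm = simulate_genotypes(config)
        scores1, _ = gio.pca_covariates(gm, 2)
        dup = make_gm(np.hstack([gm.calls, gm.calls]))
        scores2, _ = gio.pca_covariates(dup, 2)
        half = scores2.iloc[:40].to_numpy()
        for i in range(2):
            r = np.corrcoef(scores1.to_numpy()[:, i], half[:, i])[0, 1]
            assert abs(r) > 0.999

    def test_too_many_components_rejected(self):
        gm = make_gm(np.array([[0, 1, 2], [1, 0, 1]]))
        with pytest.raises(ValueError):
            gio.pca_covariates(gm, 4)
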