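"""Stratification axes, score-test scan, genomic control, PVE, annotation."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdgen.gwas import (
    GwasOptions,
    annotate_snp_feature,
    classify_significance,
    egscore_scan,
    estimate_pve,
    genomic_control,
    stratification_axes,
)
from tests.conftest import build_dataset


def random_dataset(rng, n, m, freqs=None):
    freqs = rng.uniform(0.1, 0.5, m) if freqs is None else freqs
    calls = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
    chrom = [1 + j // 1000 for j in range(m)]
    bp = [1 + (j % 1000) * 50_000 for j in range(m)]
    return build_dataset(calls, chrom=chrom, bp=bp)


class TestStratificationAxes:
    def test_orthonormal(self):
        rng = np.random.default_rng(0)
        ds = random_dataset(rng, 30, 300)
        axes = stratification_axes(ds, 3)
        np.testing.assert_allclose(axes.T @ axes, np.eye(3), atol=1e-10)

    def test_duplicated_individuals_same_scores(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.4, size=(10, 200)).astype(np.int8)
        dup = np.vstack([calls, calls[:1]])
        ds = build_dataset(dup, chrom=[1] * 200, bp=[(j + 1) * 1000 for j in range(200)])
        axes = stratification_axes(ds, 2)
        np.testing.assert_allclose(axes[0], axes[10], atol=1e-8)

    def test_separates_two_subpopulations(self):
        rng = np.random.default_rng(2)
        f1 = rng.uniform(0.1, 0.9, 600)
        f2 = np.clip(f1 + rng.normal(0, 0.3, 600), 0.02, 0.98)
        calls = np.vstack(
            [rng.binomial(2, f1, (20, 600)), rng.binomial(2, f2, (20, 600))]
        ).astype(np.int8)
        ds = build_dataset(calls, chrom=[1] * 600, bp=[(j + 1) * 1000 for j in range(600)])
        axes = stratification_axes(ds, 2)
        pop = np.r_[np.zeros(20), np.ones(20)]
        assert abs(np.corrcoef(axes[:, 0], pop)[0, 1]) > 0.9

    def test_too_many_axes_rejected(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, 10, 50)
        with pytest.raises(ValueError, match="n_axes"):
            stratification_axes(ds, 9)


class TestEgscoreScan:
    def test_reduction_to_plain_score_test(self):
        rng = np.random.default_rng(4)
        ds = random_dataset(rng, 42, 20)
        y = pd.Series(rng.normal(size=42), index=ds.samples)
        raw = egscore_scan(y, ds, None)
        n = 42
        for j in range(5):
            g = ds.calls[:, j].astype(float)
            r2 = np.corrcoef(g, y.to_numpy())[0, 1] ** 2
            assert raw["chi2"].iloc[j] == pytest.approx((n - 1) * r2, abs=1e-10)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, 42, 1000)
        y = pd.Series(rng.normal(size=42), index=ds.samples)
        axes = stratification_axes(ds, 3)
        raw = egscore_scan(y, ds, axes)
        frac = (raw["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_invariant_to_sample_reordering_and_phenotype_scale(self):
        rng = np.random.default_rng(6)
        ds = random_dataset(rng, 30, 50)
        y = pd.Series(rng.normal(size=30), index=ds.samples)
        axes = stratification_axes(ds, 2)
        raw = egscore_scan(y, ds, axes)
        perm = rng.permutation(30)
        ds_p = ds.subset(sample_idx=perm)
        axes_p = axes[perm]
        raw_p = egscore_scan(3.0 * y + 5.0, ds_p, axes_p)
        np.testing.assert_allclose(raw_p["p"], raw["p"], atol=1e-10)
        np.testing.assert_allclose(raw_p["beta"], 3.0 * raw["beta"], atol=1e-10)

    def test_monomorphic_snps_skipped(self):
        rng = np.random.default_rng(7)
        ds = random_dataset(rng, 20, 10)
        calls = ds.calls.copy()
        calls[:, 0] = 2
        ds = build_dataset(calls, chrom=[1] * 10, bp=[(j + 1) * 1000 for j in range(10)])
        y = pd.Series(rng.normal(size=20), index=ds.samples)
        with pytest.warns(UserWarning, match="monomorphic"):
            raw = egscore_scan(y, ds, None)
        assert "s0" not in set(raw["snp"])


class TestGenomicControl:
    def _null_scan(self, seed=8, n=42, m=5000):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n, m)
        y = pd.Series(rng.normal(size=n), index=ds.samples)
        axes = stratification_axes(ds, 3)
        return egscore_scan(y, ds, axes)

    def test_null_lambda_near_one(self):
        lam, _ = genomic_control(self._null_scan())
        assert 0.85 <= lam.lambda_ <= 1.15

    def test_lambda_one_leaves_p_unchanged(self):
        raw = self._null_scan(seed=9)
        raw = raw.copy()
        med = np.median(raw["chi2"])
        from scipy.stats import chi2 as chi2_dist

        raw["chi2"] = raw["chi2"] * (chi2_dist.ppf(0.5, 1) / med)  # force lambda = 1
        raw["p"] = chi2_dist.sf(raw["chi2"], 1)
        lam, adj = genomic_control(raw)
        assert lam.lambda_ == pytest.approx(1.0)
        np.testing.assert_allclose(adj["p_adjusted"], adj["p"])

    def test_median_lambda_scale_equivariant(self):
        raw = self._null_scan(seed=10)
        lam1, _ = genomic_control(raw)
        doubled = raw.copy()
        doubled["chi2"] = 2 * doubled["chi2"]
        lam2, _ = genomic_control(doubled)
        assert lam2.lambda_ == pytest.approx(2 * lam1.lambda_)

    def test_stratified_null_lambda_restored_by_axes(self):
        rng = np.random.default_rng(11)
        m = 2400
        f1 = rng.uniform(0.1, 0.9, m)
        f2 = np.clip(f1 + rng.normal(0, 0.25, m), 0.02, 0.98)
        calls = np.vstack(
            [rng.binomial(2, f1, (21, m)), rng.binomial(2, f2, (21, m))]
        ).astype(np.int8)
        chrom = [1 + j // 200 for j in range(m)]
        bp = [1 + (j % 200) * 50_000 for j in range(m)]
        ds = build_dataset(calls, chrom=chrom, bp=bp)
        pop = np.r_[np.zeros(21), np.ones(21)]
        y = pd.Series(pop * 1.5 + rng.normal(size=42), index=ds.samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam_no, _ = genomic_control(egscore_scan(y, ds, None))
            axes = stratification_axes(ds, 3)
            lam_ax, _ = genomic_control(egscore_scan(y, ds, axes))
        assert lam_no.lambda_ > lam_ax.lambda_
        assert 0.85 <= lam_ax.lambda_ <= 1.15


class TestSignificanceTiers:
    @pytest.mark.parametrize(
        "p,tier",
        [
            (9.53e-7, "genome-wide"),
            (2.72e-5, "suggestive"),
            (1.0, "none"),
            (5e-6, "suggestive"),   # boundary: strict inequality
            (5e-5, "none"),
        ],
    )
    def test_reference_classifications(self, p, tier):
        assert classify_significance(p) == tier

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(min_value=1e-12, max_value=1.0))
    def test_grid_against_bruteforce_comparator(self, p):
        opts = GwasOptions()
        expected = (
            "genome-wide" if p < 5e-6 else "suggestive" if p < 5e-5 else "none"
        )
        assert classify_significance(p, opts) == expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            classify_significance(0.0)


class TestPve:
    def test_zero_beta(self):
        assert estimate_pve(0.0, 0.3, 1.0) == 0.0

    def test_plug_in_half(self):
        assert estimate_pve(1.0, 0.5, 1.0) == pytest.approx(0.5)

    def test_engineered_pve_recovered(self):
        rng = np.random.default_rng(12)
        vals = []
        for rep in range(20):
            g = rng.binomial(2, 0.3, 200).astype(float)
            beta = np.sqrt(0.2 / g.var())
            y = beta * g + rng.normal(0, np.sqrt(0.8), 200)
            bhat = np.polyfit(g, y, 1)[0]
            vals.append(estimate_pve(bhat, g.mean() / 2, float(np.var(y, ddof=1))))
        assert 0.1 <= np.mean(vals) <= 0.3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            estimate_pve(1.0, 0.5, 0.0)


GFF = """\
##gff-version 3
1\ttest\tgene\t1000000\t1050000\t.\t+\t.\tID=gene:G1;Name=GENEA
1\ttest\texon\t1000000\t1002000\t.\t+\t.\tParent=gene:G1
1\ttest\texon\t1040000\t1050000\t.\t+\t.\tParent=gene:G1
2\ttest\tgene\t500000\t560000\t.\t-\t.\tID=gene:G2;Name=GENEB
"""


class TestAnnotation:
    @pytest.fixture
    def gff3(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text(GFF)
        return p

    def _snps(self, rows):
        return pd.DataFrame(rows, columns=["snp", "chromosome", "bp"])

    def test_intron_and_exon_variants(self, gff3):
        out = annotate_snp_feature(
            self._snps([("a", 1, 1020000), ("b", 1, 1001000)]), gff3
        )
        assert list(out["feature_type"]) == ["intron variant", "exon variant"]
        assert set(out["feature_gene"]) == {"GENEA"}

    def test_upstream_of_minus_strand_gene(self, gff3):
        # 2 kb beyond the end coordinate is 5' of a minus-strand gene
        out = annotate_snp_feature(self._snps([("c", 2, 562000)]), gff3)
        assert out["feature_type"].iloc[0] == "upstream gene variant"
        assert out["feature_gene"].iloc[0] == "GENEB"

    def test_downstream_of_minus_strand_gene_is_intergenic(self, gff3):
        out = annotate_snp_feature(self._snps([("d", 2, 498000)]), gff3)
        assert out["feature_type"].iloc[0] == "intergenic"

    def test_no_gene_in_window_intergenic(self, gff3):
        out = annotate_snp_feature(self._snps([("e", 1, 5_000_000)]), gff3)
        assert out["feature_type"].iloc[0] == "intergenic"

    def test_unmatched_chromosome_warns(self, gff3):
        with pytest.warns(UserWarning, match="absent"):
            out = annotate_snp_feature(self._snps([("f", 9, 100)]), gff3)
        assert out["feature_type"].iloc[0] == "intergenic"
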