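"""Scan orchestration, thresholds, inflation diagnostics and result I/O."""

import numpy as np
import pandas as pd
import pytest

import famscan as fs
from famscan.qc import dosages_from_calls
from famscan.scan import ScanResult

from conftest import snp_meta


@pytest.fixture(scope="module")
def scan_setup(cohort):
    ped, phi, fams = cohort
    rng = np.random.default_rng(30)
    gm, org = fs.gene_drop(ped, rng.uniform(0.1, 0.5, size=100), seed=31)
    freqs = fs.allele_freqs(gm, ped)
    dos = dosages_from_calls(gm, freqs)
    return ped, phi, fams, dos, org


class TestMGAScan:
    def test_null_scan_rejection_rate(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        y = fs.simulate_trait(
            ped, phi, fs.TraitModel(sigma2_a=0.39, sigma2_e=0.61), seed=32
        )["trait"].to_numpy()
        res = fs.run_mga_scan(y, phi, dos, families=fams)
        assert len(res.table) == 100
        n_hits = int((res.table["p_mga"] < 0.05).sum())
        # ~5 of 100 expected under the null; allow generous Monte-Carlo slack
        assert n_hits <= 15

    def test_planted_snp_is_top_hit(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        target = dos.snps["id"].iloc[7]
        d = dos.dosages[:, 7]
        maf = d.mean() / 2
        # effect sized to ~5% of residual variance
        gamma = np.sqrt(0.05 / 0.95 / (2 * maf * (1 - maf)))
        y = fs.simulate_trait(
            ped, phi,
            fs.TraitModel(snp_effect=gamma, sigma2_a=0.39, sigma2_e=0.61),
            dosages=d, seed=33,
        )["trait"].to_numpy()
        res = fs.run_mga_scan(y, phi, dos, families=fams)
        top = res.table.loc[res.table["p_mga"].idxmin(), "snp"]
        assert top == target

    def test_column_permutation_only_permutes_rows(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        y = fs.simulate_trait(
            ped, phi, fs.TraitModel(sigma2_a=0.3, sigma2_e=0.7), seed=34
        )["trait"].to_numpy()
        sub = fs.DosageMatrix(dos.dosages[:, :10], dos.imputed[:, :10],
                              list(dos.samples), dos.snps.iloc[:10].copy())
        perm = np.array([3, 1, 4, 0, 2, 9, 8, 7, 6, 5])
        shuffled = fs.DosageMatrix(dos.dosages[:, perm], dos.imputed[:, perm],
                                   list(dos.samples), dos.snps.iloc[perm].copy())
        a = fs.run_mga_scan(y, phi, sub, families=fams).table.set_index("snp")
        b = fs.run_mga_scan(y, phi, shuffled, families=fams).table.set_index("snp")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_rows_sorted_by_position(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        y = np.random.default_rng(35).standard_normal(ped.n)
        res = fs.run_mga_scan(y, phi, dos, families=fams)
        assert res.table["pos"].is_monotonic_increasing

    def test_dimension_mismatch_rejected(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        with pytest.raises(ValueError):
            fs.run_mga_scan(np.zeros(10), phi, dos, families=fams)


class TestConditionalScan:
    def test_empty_conditioning_set_is_identity(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        y = fs.simulate_trait(
            ped, phi, fs.TraitModel(sigma2_a=0.3, sigma2_e=0.7), seed=36
        )["trait"].to_numpy()
        plain = fs.run_mga_scan(y, phi, dos, families=fams)
        cond = fs.conditional_scan(y, phi, dos, [], families=fams)
        pd.testing.assert_frame_equal(plain.table, cond.table)

    def test_conditioning_on_causal_attenuates_proxy(self, cohort):
        ped, phi, fams = cohort
        gm, _ = fs.gene_drop(ped, np.full(1, 0.3), seed=37)
        causal = gm.calls[:, 0]
        rng = np.random.default_rng(38)
        # proxy: causal dosage with a little noise-flipping (high LD)
        proxy = causal.copy()
        flip = rng.random(ped.n) < 0.05
        proxy[flip] = rng.integers(0, 3, size=int(flip.sum()))
        D = np.column_stack([causal, proxy])
        dos = fs.DosageMatrix(D, np.zeros_like(D, bool), ped.ids,
                              snp_meta(["causal", "proxy"]))
        y = fs.simulate_trait(
            ped, phi, fs.TraitModel(snp_effect=0.5, sigma2_a=0.3, sigma2_e=0.7),
            dosages=causal, seed=39,
        )["trait"].to_numpy()
        plain = fs.run_mga_scan(y, phi, dos, families=fams).table.set_index("snp")
        cond = fs.conditional_scan(y, phi, dos, ["causal"], families=fams)
        assert list(cond.table["snp"]) == ["proxy"]
        assert cond.table["p_mga"].iloc[0] > plain.loc["proxy", "p_mga"]

    def test_conditioning_on_null_snp_preserves_ranking(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        y = fs.simulate_trait(
            ped, phi, fs.TraitModel(sigma2_a=0.39, sigma2_e=0.61), seed=40
        )["trait"].to_numpy()
        null_snp = dos.snps["id"].iloc[0]
        plain = fs.run_mga_scan(y, phi, dos, families=fams).table.set_index("snp")
        cond = fs.conditional_scan(y, phi, dos, [null_snp], families=fams)
        merged = cond.table.set_index("snp").join(plain, rsuffix="_plain")
        rho = merged["p_mga"].corr(merged["p_mga_plain"], method="spearman")
        assert rho > 0.95

    def test_collinear_conditioning_snp_dropped(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        D = np.column_stack([dos.dosages[:, 0], dos.dosages[:, 0], dos.dosages[:, 1]])
        dup = fs.DosageMatrix(D, np.zeros_like(D, bool), list(dos.samples),
                              snp_meta(["a", "a_copy", "b"]))
        y = np.random.default_rng(41).standard_normal(ped.n)
        with pytest.warns(UserWarning, match="collinear"):
            res = fs.conditional_scan(y, phi, dup, ["a", "a_copy"], families=fams)
        assert res.metadata["conditioned_on"] == ["a"]


class TestJLAScan:
    def test_common_causal_top_locus_concordance(self, scan_setup):
        ped, phi, fams, dos, org = scan_setup
        loci = []
        for j in [2, 5, 11, 20]:
            loci.append((dos.snps["id"].iloc[j], dos.dosages[:, j],
                         fs.true_ibd(org, j)))
        d = dos.dosages[:, 5]
        y = fs.simulate_trait(
            ped, phi,
            fs.TraitModel(snp_effect=0.5, sigma2_a=0.3, sigma2_e=0.7),
            dosages=d, seed=42,
        )["trait"].to_numpy()
        res = fs.run_jla_scan(y, phi, loci, dosages=dos, families=fams)
        t = res.table
        assert t.loc[t["p_jla"].idxmin(), "snp"] == dos.snps["id"].iloc[5]
        assert t.loc[t["p_mga"].idxmin(), "snp"] == dos.snps["id"].iloc[5]

    def test_missing_ibd_skipped_with_warning(self, scan_setup):
        ped, phi, fams, dos, org = scan_setup
        loci = [
            (dos.snps["id"].iloc[0], dos.dosages[:, 0], fs.true_ibd(org, 0)),
            (dos.snps["id"].iloc[1], dos.dosages[:, 1], None),
        ]
        y = np.random.default_rng(43).standard_normal(ped.n)
        with pytest.warns(UserWarning, match="IBD"):
            res = fs.run_jla_scan(y, phi, loci, dosages=dos, families=fams)
        assert len(res.table) == 1


class TestThresholds:
    def test_closed_form_uniform_small_panel(self):
        rng = np.random.default_rng(44)
        pvals = rng.uniform(size=(2000, 100))
        est = fs.thresholds_from_pvalues(pvals)
        sig_expected = 1 - 0.95 ** (1 / 100)  # ~5.13e-4
        assert abs(est.significant - sig_expected) / sig_expected < 0.25
        assert abs(est.suggestive - 0.01) / 0.01 < 0.15
        assert est.ci_significant[0] <= est.significant <= est.ci_significant[1]

    def test_single_test_degenerate_case(self):
        rng = np.random.default_rng(45)
        pvals = rng.uniform(size=(4000, 1))
        est = fs.thresholds_from_pvalues(pvals)
        assert est.significant == pytest.approx(0.05, rel=0.15)
        assert est.suggestive > 0.5  # at most one hit per scan is nearly always true

    def test_ordering_invariant(self):
        rng = np.random.default_rng(46)
        est = fs.thresholds_from_pvalues(rng.uniform(size=(500, 50)))
        assert 0 < est.significant <= est.suggestive <= 1

    def test_simulated_null_scans_on_panel(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        sub = fs.DosageMatrix(dos.dosages[:, :30], dos.imputed[:, :30],
                              list(dos.samples), dos.snps.iloc[:30].copy())
        with pytest.warns(UserWarning, match="noisy"):
            est = fs.empirical_thresholds(phi, sub, h2_null=0.39, n_scans=40,
                                          seed=47, families=fams)
        # 30 tests/scan: significant ~1.7e-3, suggestive ~1/30
        assert 1e-4 < est.significant < 2e-2
        assert 5e-3 < est.suggestive < 0.15

    def test_input_validation(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        with pytest.raises(ValueError):
            fs.empirical_thresholds(phi, dos, h2_null=1.2, n_scans=50, families=fams)
        with pytest.raises(ValueError):
            fs.empirical_thresholds(phi, dos, h2_null=0.3, n_scans=5, families=fams)


class TestQQLambda:
    def test_uniform_grid_lambda_one(self):
        p = (np.arange(1, 10_001) - 0.5) / 10_000
        _, lam = fs.qq_lambda(p)
        assert lam == pytest.approx(1.0, abs=0.01)

    def test_halving_pvalues_inflates(self):
        p = (np.arange(1, 2001) - 0.5) / 2000
        _, lam0 = fs.qq_lambda(p)
        _, lam1 = fs.qq_lambda(p / 2)
        assert lam1 > lam0

    def test_qq_table_shape(self):
        qq, _ = fs.qq_lambda([0.5, 0.1, 0.9])
        assert list(qq.columns) == ["expected_mlog10p", "observed_mlog10p"]
        assert qq["observed_mlog10p"].is_monotonic_decreasing
        with pytest.raises(ValueError):
            fs.qq_lambda([])


class TestEffectiveTests:
    def test_independent_snps_full_count(self):
        # orthogonal dosage columns -> identity correlation -> M_eff = K
        D = np.kron(np.eye(8), np.ones(5)).T[:, :8]
        rng = np.random.default_rng(48)
        D = rng.permutation(np.eye(40))[:, :8] * 2  # orthogonal one-hot dosages
        m_eff, alpha = fs.effective_tests(D)
        assert m_eff == pytest.approx(8.0, abs=1e-8)
        assert alpha == pytest.approx(0.05 / 8, abs=1e-10)

    def test_duplicated_snps_collapse_to_one(self):
        rng = np.random.default_rng(49)
        base = rng.integers(0, 3, size=100).astype(float)
        D = np.column_stack([base] * 6)
        m_eff, alpha = fs.effective_tests(D)
        assert m_eff == pytest.approx(1.0, abs=1e-8)
        assert alpha == pytest.approx(0.05, abs=1e-10)

    def test_intermediate_ld(self):
        rng = np.random.default_rng(50)
        a = rng.normal(size=500)
        b = 0.999 * a + 0.045 * rng.normal(size=500)  # r^2 ~ 0.998
        m_eff, _ = fs.effective_tests(np.column_stack([a, b]))
        assert 1.0 <= m_eff <= 2.0

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(51)
        D = np.column_stack([rng.normal(size=50), np.ones(50), rng.normal(size=50)])
        with pytest.warns(UserWarning, match="constant"):
            m_eff, _ = fs.effective_tests(D)
        assert m_eff <= 2.0 + 1e-9


class TestResultIO:
    def test_roundtrip_preserves_12_digits(self, tmp_path, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        y = fs.simulate_trait(
            ped, phi, fs.TraitModel(sigma2_a=0.3, sigma2_e=0.7), seed=52
        )["trait"].to_numpy()
        sub = fs.DosageMatrix(dos.dosages[:, :15], dos.imputed[:, :15],
                              list(dos.samples), dos.snps.iloc[:15].copy())
        res = fs.run_mga_scan(y, phi, sub, families=fams,
                              metadata={"trait": "sim", "seed": "52"})
        path = tmp_path / "scan.tsv"
        fs.write_results(res, path)
        back = fs.read_results(path)
        assert back.metadata["trait"] == "sim"
        for col in ["p_mga", "gamma", "maf", "lrt_mga"]:
            np.testing.assert_allclose(
                back.table[col], res.table[col], rtol=1e-11, atol=1e-300
            )

    def test_scientific_notation_roundtrip(self, tmp_path):
        t = pd.DataFrame({"snp": ["a"], "chrom": ["1"], "pos": [1],
                          "p_mga": [1.234567890123e-12]})
        path = tmp_path / "s.tsv"
        fs.write_results(ScanResult(t), path)
        assert fs.read_results(path).table["p_mga"][0] == pytest.approx(
            1.234567890123e-12, rel=1e-11
        )

    def test_empty_scan_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        fs.write_results(ScanResult(pd.DataFrame(columns=["snp"])), path)
        back = fs.read_results(path)
        assert len(back.table) == 0

    def test_malformed_metadata_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# no colon here\nsnp\tchrom\tpos\n")
        with pytest.raises(ValueError, match="malformed"):
            fs.read_results(path)


class TestOLSContrast:
    def test_ols_scan_runs_and_inflates_on_families(self, scan_setup):
        ped, phi, fams, dos, _ = scan_setup
        y = fs.simulate_trait(
            ped, phi, fs.TraitModel(sigma2_a=0.6, sigma2_e=0.4), seed=53
        )["trait"].to_numpy()
        naive = fs.run_ols_scan(y, dos)
        mixed = fs.run_mga_scan(y, phi, dos, families=fams)
        _, lam_naive = fs.qq_lambda(naive.table["p_mga"])
        _, lam_mixed = fs.qq_lambda(mixed.table["p_mga"])
        assert lam_naive > lam_mixed
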