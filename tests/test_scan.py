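import numpy as np
import pandas as pd
import pytest


from penescreen.cohort_io import GenotypeMatrix
from penescreen.kinship import fit_logistic, inflation_lambda
from penescreen.scan import (
    burden_test, gene_regions, gwas_scan, ld_confound_screen, tile_region,
)


def _gm(dosage, chrom="1", info=None, pos=None):
    n, m = dosage.shape
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "ref": "A", "alt": "G",
        "info": info if info is not None else np.ones(m),
    })
    return GenotypeMatrix(samples=[f"S{i}" for i in range(n)],
                          variants=variants, dosage=dosage.astype(float))


def _case_control(rng, n_case, n_control, mafs, case_mafs=None):
    """Genotypes under per-group allele frequencies; outcome first block."""
    n = n_case + n_control
    y = np.zeros(n)
    y[:n_case] = 1.0
    case_mafs = mafs if case_mafs is None else case_mafs
    d = np.empty((n, len(mafs)))
    d[:n_case] = rng.binomial(2, case_mafs[None, :], (n_case, len(mafs)))
    d[n_case:] = rng.binomial(2, mafs[None, :], (n_control, len(mafs)))
    ids = pd.Index([f"S{i}" for i in range(n)])
    covars = pd.DataFrame({"age": rng.uniform(20, 70, n),
                           "sex": rng.integers(0, 2, n).astype(float),
                           "PC1": rng.normal(size=n)}, index=ids)
    return _gm(d), pd.Series(y, index=ids), covars


class TestGwasScan:
    def test_group_specific_maf_filter_reason_codes(self, rng):
        # variant 0: MAF 0.08 in cases (fails carrier filter), 0.3 in controls
        gm, y, cov = _case_control(
            rng, 200, 800, mafs=np.array([0.30, 0.30, 0.02]),
            case_mafs=np.array([0.08, 0.30, 0.30]))
        # pin the filtered variants' allele counts exactly
        gm.dosage[:200, 0] = np.r_[np.ones(32), np.zeros(168)]   # case MAF 0.08
        gm.dosage[200:, 2] = np.r_[np.ones(48), np.zeros(752)]   # ctrl MAF 0.03
        scan = gwas_scan(gm, y, cov)
        assert scan.table.loc[0, "status"] == "carrier-MAF"
        assert scan.table.loc[2, "status"] == "control-MAF"
        assert scan.table.loc[1, "status"] == "tested"

    def test_info_filter(self, rng):
        gm, y, cov = _case_control(rng, 100, 400, mafs=np.full(2, 0.3))
        gm.variants.loc[1, "info"] = 0.3
        scan = gwas_scan(gm, y, cov)
        assert scan.table.loc[1, "status"] == "INFO"
        counts = scan.skip_counts()
        assert counts.get("INFO", 0) + len(scan.tested()) == 2

    def test_batch_fits_match_single_logistic(self, rng):
        gm, y, cov = _case_control(rng, 150, 600, mafs=rng.uniform(0.2, 0.4, 5))
        scan = gwas_scan(gm, y, cov)
        X = np.column_stack([np.ones(750), cov.to_numpy()])
        for j in range(5):
            single = fit_logistic(y.to_numpy(),
                                  np.column_stack([X, gm.dosage[:, j]]))
            assert scan.table.loc[j, "beta"] == pytest.approx(
                single.beta[-1], abs=1e-6)
            assert scan.table.loc[j, "se"] == pytest.approx(
                single.se[-1], abs=1e-6)

    def test_injected_causal_variant_detected(self, rng):
        maf, or_ = 0.2, 4.5
        p1 = or_ * maf / (1 - maf + or_ * maf)
        gm, y, cov = _case_control(rng, 40, 8000,
                                   mafs=np.array([maf, 0.3]),
                                   case_mafs=np.array([p1, 0.3]))
        scan = gwas_scan(gm, y, cov)
        assert scan.table.loc[0, "p"] < 5e-8
        assert scan.table.loc[0, "OR"] == pytest.approx(
            np.exp(scan.table.loc[0, "beta"]))

    def test_null_scan_lambda_near_one(self, rng):
        gm, y, cov = _case_control(rng, 100, 900,
                                   mafs=rng.uniform(0.1, 0.5, 4000))
        scan = gwas_scan(gm, y, cov)
        lam = inflation_lambda(scan.tested()["p"])
        assert 0.9 <= lam <= 1.1

    def test_invariant_to_variant_order(self, rng):
        gm, y, cov = _case_control(rng, 100, 400, mafs=rng.uniform(0.2, 0.5, 6))
        perm = rng.permutation(6)
        order = np.argsort(perm)  # keep positions increasing after shuffle
        gm2 = GenotypeMatrix(
            samples=gm.samples,
            variants=gm.variants.iloc[perm].assign(
                pos=gm.variants["pos"].to_numpy()).reset_index(drop=True),
            dosage=gm.dosage[:, perm])
        s1 = gwas_scan(gm, y, cov).table
        s2 = gwas_scan(gm2, y, cov).table
        np.testing.assert_allclose(s1["beta"].to_numpy()[perm],
                                   s2["beta"].to_numpy(), rtol=1e-9)

    def test_reason_counts_partition_variants(self, rng):
        gm, y, cov = _case_control(rng, 80, 300, mafs=rng.uniform(0.01, 0.5, 40))
        scan = gwas_scan(gm, y, cov)
        assert len(scan.tested()) + sum(scan.skip_counts().values()) == 40

    def test_too_few_cases_aborts(self, rng):
        gm, y, cov = _case_control(rng, 1, 100, mafs=np.array([0.3]))
        with pytest.raises(ValueError, match="2 cases"):
            gwas_scan(gm, y, cov)


class TestLdConfoundScreen:
    @staticmethod
    def _fixture(rng, n_ld=40, with_independent=True):
        """-log10(p) rises linearly in r² for founder-LD variants; one
        strong variant sits at r² = 0, far off the line."""
        r2 = rng.uniform(0.3, 0.95, n_ld)
        neglog = 4 + 8 * r2 + rng.normal(0, 0.3, n_ld)
        rows = [{"status": "tested", "p": 10 ** -nl, "r2_founder": r}
                for nl, r in zip(neglog, r2)]
        if with_independent:
            rows.append({"status": "tested", "p": 1e-7, "r2_founder": 0.0})
        table = pd.DataFrame(rows)
        return table

    def test_line_variants_founder_ld_outlier_independent(self, rng):
        table = self._fixture(rng)
        flags = ld_confound_screen(table)
        assert flags.iloc[-1]["flag"] == "independent_suggestive"
        assert (flags.iloc[:-1]["flag"] == "founder_LD").all()

    def test_no_variants_below_pmax_is_empty(self, rng):
        table = pd.DataFrame({"status": ["tested"] * 3,
                              "p": [0.1, 0.2, 0.3],
                              "r2_founder": [0.5, 0.1, 0.0]})
        assert len(ld_confound_screen(table)) == 0

    def test_too_few_variants_raises(self, rng):
        table = self._fixture(rng, n_ld=5, with_independent=False)
        with pytest.raises(ValueError, match=">= 10"):
            ld_confound_screen(table)

    def test_all_zero_r2_warns_and_flags_independent(self, rng):
        table = pd.DataFrame({"status": ["tested"] * 12,
                              "p": 10 ** -rng.uniform(4, 8, 12),
                              "r2_founder": np.zeros(12)})
        with pytest.warns(UserWarning, match="r2"):
            flags = ld_confound_screen(table)
        assert (flags["flag"] == "independent_suggestive").all()


class TestBurden:
    def test_extreme_separation_hits_permutation_floor(self, rng):
        n_case, n_control = 30, 400
        d = np.zeros((n_case + n_control, 6))
        d[:n_case] = rng.binomial(1, 0.5, (n_case, 6))
        d[:n_case, 0] = 1  # every case carries at least one rare allele
        gm = _gm(d)
        ids = pd.Index(gm.samples)
        y = pd.Series(np.r_[np.ones(n_case), np.zeros(n_control)], index=ids)
        cov = pd.DataFrame({"age": rng.uniform(20, 70, len(ids)),
                            "sex": rng.integers(0, 2, len(ids)).astype(float),
                            "PC1": rng.normal(size=len(ids))}, index=ids)
        res = burden_test(gm, y, cov, ("1", 1, 10_000), maf_tier=0.05,
                          n_perm=99, seed=4)
        assert res.perm_p == pytest.approx(1 / 100)

    def test_zero_qualifying_variants(self, rng):
        d = rng.binomial(2, 0.4, (100, 3))  # too common for the rare tier
        gm = _gm(d)
        ids = pd.Index(gm.samples)
        y = pd.Series(rng.integers(0, 2, 100).astype(float), index=ids)
        cov = pd.DataFrame({"age": np.ones(100)}, index=ids)
        res = burden_test(gm, y, cov, ("1", 1, 10_000), maf_tier=0.01)
        assert res.n_variants == 0 and np.isnan(res.perm_p)

    def test_subregions_tile_region_exactly(self):
        tiles = tile_region(100, 1099, 10)
        assert tiles[0][0] == 100 and tiles[-1][1] == 1099
        covered = []
        for lo, hi in tiles:
            covered.extend(range(lo, hi + 1))
        assert covered == list(range(100, 1100))  # union, pairwise disjoint

    def test_subregion_analysis_triggered_for_significant_region(self, rng):
        n_case, n_control = 40, 800
        d = np.zeros((n_case + n_control, 12))
        d[:, :] = rng.binomial(1, 0.004, d.shape)
        d[:n_case, :6] = rng.binomial(1, 0.5, (n_case, 6))
        gm = _gm(d, pos=np.arange(1, 13) * 800)
        ids = pd.Index(gm.samples)
        y = pd.Series(np.r_[np.ones(n_case), np.zeros(n_control)], index=ids)
        cov = pd.DataFrame({"age": rng.uniform(20, 70, len(ids))}, index=ids)
        res = burden_test(gm, y, cov, ("1", 1, 10_000), maf_tier=0.05,
                          n_perm=99, seed=2, subregion_threshold=2.5e-6)
        assert res.subregions is not None
        assert len(res.subregions) == 10
        assert res.subregions["n_variants"].sum() == res.n_variants

    def test_wald_p_anticonservative_under_imbalance_perm_p_not(self, rng):
        """Spot check of the imbalance rationale: on null rare-variant
        regions with 40 cases vs 4000 controls, asymptotic p-values pile up
        near zero more often than permutation p-values do."""
        n_case, n_control = 40, 4000
        wald, perm = [], []
        for seed in range(30):
            r = np.random.default_rng(seed)
            d = r.binomial(1, 0.004, (n_case + n_control, 8))
            gm = _gm(d)
            ids = pd.Index(gm.samples)
            y = pd.Series(np.r_[np.ones(n_case), np.zeros(n_control)],
                          index=ids)
            cov = pd.DataFrame({"age": r.uniform(20, 70, len(ids))},
                               index=ids)
            res = burden_test(gm, y, cov, ("1", 1, 10_000), maf_tier=0.05,
                              n_perm=99, seed=seed)
            if np.isfinite(res.wald_p):
                wald.append(res.wald_p)
            perm.append(res.perm_p)
        assert np.mean(np.array(perm) <= 0.1) <= 0.3
        # permutation p is dispersed over (0, 1], not concentrated at 0
        assert np.median(perm) > 0.2


def test_gene_regions_flanks():
    genes = pd.DataFrame({"gene": ["SLC35F1"], "chrom": ["6"],
                          "start": [118_200_000], "end": [118_600_000]})
    out = gene_regions(genes, flank=50_000)
    assert out.loc[0, "region_start"] == 118_150_000
    assert out.loc[0, "region_end"] == 118_650_000
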