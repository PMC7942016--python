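"""edQTL mapping, permutation FDR, interaction/non-linearity LRTs, LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editqtl.qtl import (
    GenotypeTable,
    cv_filter,
    effect_size_matrix,
    enzyme_correlation,
    gwas_link,
    interaction_lrt,
    ld_r2,
    map_edqtl,
    nonlinearity,
    ols_assoc,
    permutation_threshold,
)
from editqtl.synthetic import simulate_genotypes


def make_gt(dosage, positions=None, chrom="chr1"):
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    m, n = dosage.shape
    if positions is None:
        positions = 1_000_000 + 1000 * np.arange(m)
    return GenotypeTable(
        samples=[f"s{j}" for j in range(n)],
        snp_ids=np.array([f"rs{i}" for i in range(m)]),
        chrom=np.array([chrom] * m),
        pos=np.asarray(positions),
        dosage=dosage,
    )


class TestOls:
    def test_hand_computed_slope_and_intercept(self):
        phi = [0, 0.1, 0.2, 0.3, 0.4, 0.5]
        dos = [0, 0, 1, 1, 2, 2]
        slope, intercept, p, n, se = ols_assoc(phi, dos)
        assert slope == pytest.approx(0.2)
        assert intercept == pytest.approx(0.05)
        assert n == 6

    def test_constant_phi(self):
        slope, _, p, _, _ = ols_assoc([0.3] * 6, [0, 0, 1, 1, 2, 2])
        assert slope == 0.0 and p == 1.0

    def test_perfect_fit_p_zero(self):
        dos = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        slope, _, p, _, _ = ols_assoc(0.1 + 0.2 * dos, dos)
        assert slope == pytest.approx(0.2)
        # residuals at float rounding: p collapses far below any cutoff
        assert p < 1e-50

    def test_constant_dosage_flagged(self):
        slope, _, p, _, _ = ols_assoc([0.1, 0.2, 0.3, 0.4], [1, 1, 1, 1])
        assert np.isnan(slope) and np.isnan(p)

    def test_missing_dropped_pairwise(self):
        phi = [0.1, np.nan, 0.3, 0.2, 0.5]
        dos = [0, 1, 1, np.nan, 2]
        _, _, _, n, _ = ols_assoc(phi, dos)
        assert n == 3

    def test_fuzz_against_linregress(self, rng):
        """Slope/intercept/p match scipy's independent OLS on 1000 draws."""
        for _ in range(1000):
            n = rng.integers(4, 20)
            dos = rng.integers(0, 3, n).astype(float)
            if np.unique(dos).size < 2:
                continue
            phi = rng.random(n)
            slope, intercept, p, _, _ = ols_assoc(phi, dos)
            ref = stats.linregress(dos, phi)
            assert slope == pytest.approx(ref.slope, rel=1e-9, abs=1e-12)
            assert intercept == pytest.approx(ref.intercept, rel=1e-9, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)


class TestMapEdqtl:
    def test_single_snp_is_lead(self, rng):
        dos = rng.integers(0, 3, 30).astype(float)
        gt = make_gt([dos], positions=[1_000_000])
        phi = 0.2 + 0.1 * dos + rng.normal(0, 0.01, 30)
        res = map_edqtl("site", "chr1", 1_000_500, phi, gt)
        assert res.lead is not None and res.lead.snp == "rs0"

    def test_identical_columns_closest_wins(self, rng):
        dos = rng.integers(0, 3, 40).astype(float)
        site_pos = 1_000_000
        gt = make_gt([dos, dos], positions=[site_pos + 100_000, site_pos + 1_000])
        phi = 0.2 + 0.1 * dos + rng.normal(0, 0.02, 40)
        res = map_edqtl("site", "chr1", site_pos, phi, gt)
        assert res.lead.snp == "rs1"  # the 1-kb SNP

    def test_equal_distance_tie_breaks_to_lower_coordinate(self, rng):
        dos = rng.integers(0, 3, 40).astype(float)
        site_pos = 1_000_000
        gt = make_gt([dos, dos], positions=[site_pos - 5_000, site_pos + 5_000])
        phi = 0.2 + 0.1 * dos + rng.normal(0, 0.02, 40)
        res = map_edqtl("site", "chr1", site_pos, phi, gt)
        assert res.lead.snp == "rs0"

    def test_window_and_maf_filters(self, rng):
        dos_common = rng.integers(0, 3, 200).astype(float)
        dos_rare = (rng.random(200) < 0.01).astype(float)
        far = 1_000_000 + 300_000  # outside the +/-200kb window
        gt = make_gt(
            [dos_common, dos_rare, dos_common],
            positions=[far, 1_000_100, 1_050_000],
        )
        phi = 0.2 + 0.1 * dos_common + rng.normal(0, 0.02, 200)
        res = map_edqtl("site", "chr1", 1_000_000, phi, gt)
        assert set(res.assocs["snp"]) == {"rs2"}

    def test_no_testable_snps_reports_untested(self, rng):
        gt = make_gt([np.zeros(20)], positions=[1_000_000])
        res = map_edqtl("site", "chr1", 5_000_000, rng.random(20), gt)
        assert res.status == "untested" and res.lead is None

    def test_null_per_snp_type_one_error(self, rng):
        """Under the global null, ~5% of single-SNP tests reach p < 0.05."""
        n, n_tests = 50, 4000
        hits = 0
        gt = simulate_genotypes(n, n_tests, (0.2, 0.5), seed=77)
        for j in range(n_tests):
            phi = rng.random(n)
            _, _, p, _, _ = ols_assoc(phi, gt.dosage[j])
            hits += p < 0.05
        rate = hits / n_tests
        se = np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(rate - 0.05) < 3 * se


class TestPermutationThreshold:
    def _null_data(self, rng, n=40, n_sites=15, n_snps=30):
        gt = simulate_genotypes(n, n_snps, (0.2, 0.5), seed=9)
        phi = pd.DataFrame(
            rng.random((n_sites, n)),
            index=[f"site{i}" for i in range(n_sites)],
            columns=gt.samples,
        )
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.linspace(gt.pos[0], gt.pos[-1], n_sites).astype(int),
                "strand": "+",
                "gene": "g",
            },
            index=phi.index,
        )
        return gt, phi, sites

    def test_identity_permutation_gives_no_threshold(self, rng):
        gt, phi, sites = self._null_data(rng)
        thr = permutation_threshold(
            phi, sites, gt, B=1, _permutations=[np.arange(gt.n_samples)]
        )
        # FDR(t) = 1 everywhere when the permutation is the identity
        assert thr is None

    def test_global_null_excludes_everything(self, rng):
        gt, phi, sites = self._null_data(rng)
        thr = permutation_threshold(phi, sites, gt, B=5, seed=4)
        if thr is not None:
            obs_pass = 0
            from editqtl.qtl import _min_window_p

            minp = _min_window_p(phi, sites, gt, 400_000, 0.05)
            obs_pass = int(np.nansum(minp <= thr))
            assert obs_pass <= max(1, 0.1 * len(sites))

    def test_admits_true_signals(self, rng):
        """Planted strong signals survive at FDR 0.10."""
        n, n_true, n_null = 80, 15, 60
        gt = simulate_genotypes(n, 100, (0.2, 0.5), seed=21)
        rows, names = [], []
        causal = rng.choice(100, size=n_true, replace=False)
        for k in range(n_true):
            dos = gt.dosage[causal[k]]
            rows.append(0.3 + 0.15 * dos + rng.normal(0, 0.03, n))
            names.append(f"true{k}")
        for k in range(n_null):
            rows.append(rng.normal(0.4, 0.05, n))
            names.append(f"null{k}")
        phi = pd.DataFrame(rows, index=names, columns=gt.samples)
        pos_mid = int(np.median(gt.pos))
        sites = pd.DataFrame(
            {"chrom": "chr1",
             "pos": [gt.pos[causal[k]] + 7 for k in range(n_true)]
                    + [pos_mid] * n_null,
             "strand": "+", "gene": "g"},
            index=names,
        )
        thr = permutation_threshold(phi, sites, gt, B=5, seed=3)
        assert thr is not None
        from editqtl.qtl import _min_window_p

        minp = _min_window_p(phi, sites, gt, 400_000, 0.05)
        true_pass = np.nansum(minp[:n_true] <= thr)
        assert true_pass >= 0.9 * n_true


class TestInteraction:
    def test_equal_slopes_noise_free(self):
        dos = np.tile([0, 1, 2], 20).astype(float)
        tissue = np.repeat([0, 1], 30)
        phi = 0.1 + 0.2 * dos + 0.05 * tissue
        fit = interaction_lrt(phi, dos, tissue)
        assert fit.lrt == pytest.approx(0.0, abs=1e-6)
        assert fit.p == pytest.approx(1.0, abs=1e-6)

    def test_detects_muscle_style_attenuation(self, rng):
        """An 80% smaller genotype slope in one tissue is found reliably."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            dos = np.tile([0, 1, 2], 134)[:200].astype(float)
            dos = np.concatenate([dos, dos])
            tissue = np.repeat([0, 1], 200)
            slope = np.where(tissue == 0, 0.2, 0.04)
            phi = 0.1 + slope * dos + r.normal(0, 0.02, 400)
            fit = interaction_lrt(phi, dos, tissue)
            hits += fit.p < 0.05
        assert hits / n_rep >= 0.95

    def test_nesting_rss_inequality(self, rng):
        for _ in range(50):
            n = 40
            dos = rng.integers(0, 3, n).astype(float)
            tissue = rng.integers(0, 2, n)
            if len(np.unique(dos[tissue == 0])) < 2 or len(np.unique(dos[tissue == 1])) < 2:
                continue
            phi = rng.random(n)
            fit = interaction_lrt(phi, dos, tissue)
            assert fit.lrt >= 0.0

    def test_singular_design_flagged(self):
        fit = interaction_lrt([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1], [0, 0, 0, 0])
        assert fit.status == "singular"

    def test_gamma_recovers_slope_difference(self, rng):
        dos = np.tile([0.0, 1.0, 2.0], 100)
        tissue = np.repeat([0, 1], 150)
        phi = 0.1 + np.where(tissue == 0, 0.2, 0.05) * dos
        fit = interaction_lrt(phi, dos, tissue)
        assert fit.alpha == pytest.approx(0.2, abs=1e-9)
        assert fit.gamma == pytest.approx(-0.15, abs=1e-9)


class TestNonlinearity:
    def test_collinear_means_give_zero_shift(self):
        dos = np.repeat([0.0, 1.0, 2.0], 10)
        phi = 0.1 + 0.1 * dos
        res = nonlinearity(phi, dos)
        assert res.shift == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_shift(self, rng):
        """Class means (0.1, 0.28, 0.3): quadratic through the means at
        dosage 1 is 0.28, the homozygote chord gives 0.2 -> shift +0.08."""
        dos = np.repeat([0.0, 1.0, 2.0], 30)
        means = {0.0: 0.1, 1.0: 0.28, 2.0: 0.3}
        phi = np.array([means[d] for d in dos]) + rng.normal(0, 1e-6, dos.size)
        res = nonlinearity(phi, dos)
        assert res.shift == pytest.approx(0.08, abs=1e-3)
        assert res.p < 1e-6

    def test_missing_genotype_class_flagged(self):
        res = nonlinearity([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1])
        assert res.status != "ok"


class TestCrossTissue:
    def test_effect_matrix_complete_view(self):
        per_tissue = {
            "a": {"s1": 0.2, "s2": 0.1},
            "b": {"s1": 0.15},
        }
        full = effect_size_matrix(per_tissue)
        comp = effect_size_matrix(per_tissue, complete_only=True)
        assert set(full.index) == {"s1", "s2"}
        assert set(comp.index) == {"s1"}
        assert comp.loc["s1", "b"] == pytest.approx(0.15)

    def test_cv_hand_computed(self):
        mat = pd.DataFrame([[0.3, 0.0, 0.0, 0.0]], index=["s"])
        out = cv_filter(mat)
        assert out.loc["s", "cv"] == pytest.approx(2.0)
        assert bool(out.loc["s", "flagged"])

    def test_cv_constant_not_flagged(self):
        out = cv_filter(pd.DataFrame([[0.2, 0.2, 0.2]], index=["s"]))
        assert out.loc["s", "cv"] == pytest.approx(0.0)
        assert not bool(out.loc["s", "flagged"])

    def test_cv_zero_mean_undefined(self):
        out = cv_filter(pd.DataFrame([[0.1, -0.1]], index=["s"]))
        assert bool(out.loc["s", "undefined"])

    def test_enzyme_correlation_proportional(self):
        levels = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
        r2, flag = enzyme_correlation(2.0 * levels, levels)
        assert r2 == pytest.approx(1.0) and flag
        r2, flag = enzyme_correlation(-2.0 * levels, levels)
        assert r2 == pytest.approx(1.0) and flag  # sign-blind

    def test_enzyme_correlation_null_mean(self, rng):
        """For independent vectors over k tissues, E[r^2] ~ 1/(k-1)."""
        k = 49
        r2s = [
            enzyme_correlation(rng.normal(size=k), rng.normal(size=k))[0]
            for _ in range(400)
        ]
        assert np.mean(r2s) == pytest.approx(1 / (k - 1), abs=0.01)


class TestLd:
    def test_identical_and_flipped(self):
        d = np.array([0, 1, 2, 1, 0, 2, 1], dtype=float)
        assert ld_r2(d, d) == pytest.approx(1.0)
        assert ld_r2(d, 2 - d) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        ok = 0
        for rep in range(40):
            r = np.random.default_rng(rep)
            d1 = r.binomial(2, 0.5, 1000).astype(float)
            d2 = r.binomial(2, 0.5, 1000).astype(float)
            ok += ld_r2(d1, d2) < 0.02
        assert ok >= 0.85 * 40

    def test_constant_vector_undefined(self):
        assert np.isnan(ld_r2([1, 1, 1], [0, 1, 2]))

    def test_gwas_link_self_and_skip(self, rng):
        dos = rng.integers(0, 3, 50).astype(float)
        other = rng.integers(0, 3, 50).astype(float)
        gt = make_gt([dos, other])
        catalog = pd.DataFrame(
            {"snp": ["rs0", "rs_missing"], "trait": ["height", "BMI"]}
        )
        records, skipped = gwas_link({"site1": "rs0"}, catalog, gt)
        assert skipped == 1
        assert len(records) == 1
        assert records.iloc[0]["gwas_snp"] == "rs0"
        assert records.iloc[0]["r2"] == pytest.approx(1.0)

    def test_gwas_link_threshold_against_independent_r2(self, rng):
        """Only pairs whose numpy-computed r2 clears 0.8 are linked."""
        base = rng.integers(0, 3, 200).astype(float)
        high = base.copy()
        high[:6] = rng.integers(0, 3, 6)  # strongly linked
        low = base.copy()
        low[:120] = rng.integers(0, 3, 120)  # weakly linked
        gt = make_gt([base, high, low])
        catalog = pd.DataFrame({"snp": ["rs1", "rs2"], "trait": ["t1", "t2"]})
        records, _ = gwas_link({"site": "rs0"}, catalog, gt)
        expect = {
            s for s, d in (("rs1", high), ("rs2", low))
            if np.corrcoef(base, d)[0, 1] ** 2 > 0.8
        }
        assert set(records["gwas_snp"]) == expect
        assert "rs1" in expect and "rs2" not in expect
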