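"""edQTL mapping: normalization, OLS oracle, permutations, q-values."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import edscape as e
import edscape.edqtl_mapping as em


def _genotypes(calls, gene_id="g0", pos_start=100):
    calls = np.asarray(calls, dtype=float)
    n_var = calls.shape[0]
    table = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n_var)],
            "chrom": "c",
            "pos": np.arange(pos_start, pos_start + n_var),
            "gene_id": gene_id,
            "ref": "A",
            "alt": "G",
        }
    )
    strains = [f"S{i}" for i in range(calls.shape[1])]
    return em.GenotypeMatrix(table, strains, calls)


class TestNormalize:
    def test_mean_zero_sd_one(self, rng):
        y = rng.uniform(size=51)
        z = em.normalize_editing_levels(y)
        assert abs(z.mean()) < 0.02
        assert z.std(ddof=0) == pytest.approx(1.0, abs=0.05)

    def test_rank_preserving(self, rng):
        y = np.sort(rng.uniform(size=30))
        z = em.normalize_editing_levels(y)
        assert np.all(np.diff(z) >= 0)

    def test_two_values_closed_form(self):
        z = em.normalize_editing_levels(np.array([0.1, 0.9]))
        assert z[0] == pytest.approx(stats.norm.ppf(0.25), abs=1e-9)
        assert z[1] == pytest.approx(stats.norm.ppf(0.75), abs=1e-9)
        assert z[1] == pytest.approx(0.6744897, abs=1e-6)

    def test_missing_stays_missing(self, rng):
        y = rng.uniform(size=20)
        y[3] = np.nan
        z = em.normalize_editing_levels(y)
        assert np.isnan(z[3]) and not np.isnan(np.delete(z, 3)).any()

    def test_zero_variance_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert em.normalize_editing_levels(np.full(10, 0.4)) is None


class TestAssociationScan:
    def test_closed_form_example(self):
        g = np.array([[0, 0, 0, 1, 1, 1]], dtype=float)
        y = np.array([-0.2, 0.1, -0.1, 0.9, 1.1, 1.0])
        res = em.cis_association_scan("s", y, _genotypes(g), "g0", min_minor=3, min_n=6)
        assert len(res) == 1
        # brute-force oracle: statsmodels OLS
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(g[0])).fit()
        assert res[0].beta == pytest.approx(fit.params[1], abs=1e-12)
        assert res[0].p == pytest.approx(fit.pvalues[1], abs=1e-12)

    def test_rare_minor_allele_not_tested(self):
        g = np.zeros((1, 20))
        g[0, :3] = 1
        y = np.random.default_rng(0).normal(size=20)
        assert em.cis_association_scan("s", y, _genotypes(g), "g0") == []

    def test_ols_matches_oracle_many(self, rng):
        import statsmodels.api as sm

        for _ in range(200):
            n = int(rng.integers(10, 60))
            g = (rng.uniform(size=n) < 0.4).astype(float)
            if g.sum() < 2 or g.sum() > n - 2:
                continue
            y = rng.normal(size=n) + 0.3 * g
            beta, p = em._ols_slope_p(g, y)
            fit = sm.OLS(y, sm.add_constant(g)).fit()
            assert beta == pytest.approx(fit.params[1], abs=1e-10)
            assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_null_p_uniform(self, rng):
        n = 60
        ps = []
        for _ in range(500):
            g = np.zeros(n)
            g[rng.choice(n, 20, replace=False)] = 1
            y = rng.normal(size=n)
            _, p = em._ols_slope_p(g, y)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPermutationEmpiricalP:
    def test_add_one_lower_bound(self, rng):
        n = 50
        g = np.zeros((3, n))
        for i in range(3):
            g[i, rng.choice(n, 20, replace=False)] = 1
        y = 1.0 * g[0] + 0.05 * rng.normal(size=n)  # overwhelming signal
        geno = _genotypes(g)
        p_min, p_emp = em.permutation_empirical_p(
            em.normalize_editing_levels(y), geno, np.arange(3), n_perm=1000, seed=1
        )
        assert p_emp == pytest.approx(1 / 1001)

    def test_null_signal_centered(self, rng):
        n = 40
        g = np.zeros((1, n))
        g[0, :20] = 1
        y = rng.normal(size=n)
        geno = _genotypes(g)
        _, p_emp = em.permutation_empirical_p(y, geno, np.array([0]), n_perm=500, seed=2)
        assert 0.02 < p_emp <= 1.0  # no spurious certainty on null data

    def test_reproducible(self, rng):
        n = 30
        g = (rng.uniform(size=(4, n)) < 0.4).astype(float)
        y = rng.normal(size=n)
        geno = _genotypes(g)
        idx = np.arange(4)
        a = em.permutation_empirical_p(y, geno, idx, n_perm=200, seed=7)
        b = em.permutation_empirical_p(y, geno, idx, n_perm=200, seed=7)
        assert a == b

    def test_missing_genotype_path_matches_complete_path(self, rng):
        # NaN-free matrix routed through the fast path must agree with the
        # general path when a NaN elsewhere forces the slow route
        n = 30
        g = (rng.uniform(size=(2, n)) < 0.5).astype(float)
        y = rng.normal(size=n)
        geno_fast = _genotypes(g)
        g_slow = g.copy()
        g_slow = np.vstack([g_slow, np.full(n, np.nan)])
        g_slow[2, 0] = 0.0
        geno_slow = _genotypes(g_slow)
        a = em.permutation_empirical_p(y, geno_fast, np.arange(2), n_perm=300, seed=3)
        b = em.permutation_empirical_p(y, geno_slow, np.arange(2), n_perm=300, seed=3)
        assert a[0] == pytest.approx(b[0], abs=1e-12)
        assert a[1] == pytest.approx(b[1], abs=0.02)


class TestQValues:
    def test_bh_equivalence_hand_example(self):
        q = em.qvalue_fdr([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.all(em.qvalue_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        q = em.qvalue_fdr(p, pi0=1.0)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    def test_null_uniform_few_discoveries(self, rng):
        p = rng.uniform(size=10_000)
        q = em.qvalue_fdr(p)
        assert np.sum(q < 0.05) <= 5

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=100)
        q = em.qvalue_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty(self):
        assert em.qvalue_fdr([]).size == 0


class TestEffectSize:
    def test_hand_example(self):
        levels = np.array([0.40, 0.40, 0.30, 0.30])
        g = np.array([1.0, 1.0, 0.0, 0.0])
        assert em.effect_size(levels, g) == pytest.approx(0.05)

    def test_identical_means(self):
        levels = np.array([0.3, 0.3, 0.3, 0.3])
        g = np.array([0.0, 0.0, 1.0, 1.0])
        assert em.effect_size(levels, g) == 0.0

    def test_empty_class_missing(self):
        assert np.isnan(em.effect_size(np.array([0.1, 0.2]), np.array([0.0, 0.0])))


class TestSecondaryScan:
    def test_residuals_orthogonal(self, rng):
        n = 50
        g = (rng.uniform(size=n) < 0.4).astype(float)
        y = rng.normal(size=n) + 0.5 * g
        r = em.regress_out(y, g)
        assert abs(np.corrcoef(r, g)[0, 1]) < 1e-12

    def test_pure_primary_leaves_no_secondary(self):
        # phenotype exactly linear in the primary genotype: residuals ~ 0
        g = np.array([0.0, 0, 0, 1, 1, 1, 0, 1])
        y = 2.0 * g + 1.0
        r = em.regress_out(y, g)
        assert np.allclose(r, 0.0, atol=1e-12)

    def test_two_planted_variants_both_recovered(self):
        cfg = e.SimulationConfig(
            n_strains=80,
            n_sites=3,
            n_variants_per_gene=6,
            effect_sizes=(-0.15,),
            noise_sd=0.03,
            maf_range=(0.3, 0.5),
            seed=21,
        )
        ds = e.simulate_dataset(cfg)
        # plant a second, independent variant effect on site s000
        geno = ds.genotypes
        second = "g000_v02"
        ds.truth.qtl_assignments[second] = ("s000", 0.12)
        levels = e.generate_editing_levels(geno, ds.truth, cfg)
        res = em.map_edqtls(levels, geno, n_perm=300, seed=5, fdr=0.10)
        hits = {(q.site_id, q.rank) for q in res.edqtls}
        assert ("s000", "primary") in hits and ("s000", "secondary") in hits
        found = {q.variant_id for q in res.edqtls if q.site_id == "s000"}
        assert found == {"g000_v00", "g000_v02"}


class TestSharedSiteAssociation:
    def test_shared_driver_and_scope(self):
        cfg = e.SimulationConfig(
            n_strains=60,
            n_sites=2,
            n_variants_per_gene=4,
            effect_sizes=(-0.15,),
            noise_sd=0.03,
            seed=31,
        )
        ds = e.simulate_dataset(cfg)
        # second site in gene g000, driven by the same variant
        extra = e.EditingSite("chrS", ds.sites[0].pos + 500, "+", "g000", "sX")
        ds.truth.sites.append(extra)
        ds.truth.qtl_assignments["g000_v00"] = ("s000", -0.15)
        ds.truth.qtl_assignments = dict(ds.truth.qtl_assignments)
        by_var = dict(ds.truth.qtl_assignments)
        by_var["g000_v00"] = ("s000", -0.15)
        # plant the same effect on the extra site via a second assignment map
        truth2 = e.PlantedTruth(
            {**by_var, "g000_v01": ("sX", 0.0)},
            ds.truth.duplex_specs,
            ds.truth.disrupting_variants,
            ds.truth.sites,
        )
        levels = e.generate_editing_levels(ds.genotypes, truth2, cfg)
        # manually add the shared effect on sX
        gv = ds.genotypes.row("g000_v00")
        i = levels.site_index("sX")
        levels.level[i] = np.clip(levels.level[i] - 0.3 * gv, 0, 1)
        qtl = e.EdQTL("s000", "g000_v00", 1e-6, 1e-4, 0.01, "primary", 0.15)
        out = em.shared_site_association([qtl], levels, ds.genotypes)
        row = out[out["other_site"] == "sX"]
        assert len(row) == 1
        assert row["p"].iloc[0] < 1e-4
        assert row["distance_bin"].iloc[0] == "<1kb"
        # sites in other genes are not tested
        assert set(out["other_site"]) == {"sX"}
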