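"""Structural edQTL interpretation: classification, LD, exact tests, stems."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import edscape as e
import edscape.qtl_structure as qs
from edscape.ecs_prediction import EcsPrediction, predict_proximal_ecs
from edscape.editing_quant import EditingSite
from edscape.synthetic_data import DuplexSpec, generate_duplex_locus


def _site(pos0, chrom="chrS", strand="+", site_id="s0", gene="g0"):
    return EditingSite(chrom, pos0 + 1, strand, gene, site_id)


def _prediction(edit_iv, ecs_iv, site_pos0, pairs=None, strand="+"):
    from edscape.structure_engine import Stem

    stem = Stem(
        pairs=[(0, 1)],
        left=(0, 1),
        right=(1, 2),
        n_pairs=25,
        max_bulge=0,
        max_bulge_left=0,
        max_bulge_right=0,
        contains=0,
    )
    return EcsPrediction(
        site=_site(site_pos0, strand=strand),
        approach="proximal",
        stem=stem,
        ecs_interval=ecs_iv,
        edit_interval=edit_iv,
        distance=None,
        accepted=True,
        pairs_genomic=pairs or [],
    )


class TestClassification:
    def test_inside_ecs(self):
        pred = _prediction((100, 125), (160, 185), 112)
        assert qs.classify_variant_location(171, pred) == qs.WITHIN_DUPLEX

    def test_inside_edit_side(self):
        pred = _prediction((100, 125), (160, 185), 112)
        assert qs.classify_variant_location(105, pred) == qs.WITHIN_DUPLEX

    def test_distal(self):
        pred = _prediction((100, 125), (160, 185), 112)
        assert qs.classify_variant_location(3000, pred) == qs.DISTAL

    def test_unresolved_without_prediction(self):
        assert qs.classify_variant_location(105, None) == qs.UNRESOLVED


class TestLdR2:
    def test_identical(self):
        g = np.array([0.0, 1, 0, 1, 1, 0, 0, 1])
        assert qs.ld_r2(g, g) == pytest.approx(1.0)

    def test_orthogonal(self):
        a = np.array([0.0, 0, 1, 1] * 2)
        b = np.array([0.0, 1, 0, 1] * 2)
        assert qs.ld_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        for _ in range(200):
            a = (rng.uniform(size=30) < 0.4).astype(float)
            b = (rng.uniform(size=30) < 0.4).astype(float)
            if a.std() == 0 or b.std() == 0:
                continue
            cov = np.mean(a * b) - a.mean() * b.mean()
            want = cov**2 / (np.var(a) * np.var(b))
            assert qs.ld_r2(a, b) == pytest.approx(want, abs=1e-12)

    def test_constant_missing(self):
        assert math.isnan(qs.ld_r2(np.zeros(10), np.ones(10)))


class TestControlSelection:
    def _setup(self, rng, n_extra=0):
        n = 40
        calls = [(rng.uniform(size=n) < 0.4).astype(float) for _ in range(4 + n_extra)]
        table = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(len(calls))],
                "chrom": "chrS",
                "pos": [105, 170, 172, 3000] + [174] * (len(calls) - 4),
                "gene_id": "g0",
                "ref": "A",
                "alt": "G",
            }
        )
        geno = e.GenotypeMatrix(table, [f"S{i}" for i in range(n)], np.vstack(calls))
        pred = _prediction((100, 125), (160, 185), 112)
        qtl = e.EdQTL("s0", "v0", 1e-6, 1e-4, 0.01, "primary", 0.1)
        return geno, [qtl], {"s0": pred}

    def test_linked_candidate_excluded_unlinked_included(self, rng):
        geno, qtls, preds = self._setup(rng, n_extra=1)
        # v4 identical to the edQTL -> r^2 = 1 -> excluded
        geno.calls[4] = geno.calls[0]
        out = qs.select_control_variants(geno, qtls, preds, mode="duplex")
        assert "v4" not in out
        # v1/v2 inside the duplex, independent draws -> typically unlinked
        assert set(out) <= {"v1", "v2"}

    def test_inclusive_boundary(self, rng):
        # a candidate at exactly the threshold passes (r^2 <= 0.05)
        geno, qtls, preds = self._setup(rng, n_extra=1)
        geno.calls[4] = geno.calls[1]
        r2 = qs.ld_r2(geno.calls[4], geno.calls[0])
        out = qs.select_control_variants(geno, qtls, preds, mode="duplex", r2_max=r2)
        assert "v4" in out  # its own r2 equals the (inclusive) threshold

    def test_distal_matched_excludes_duplex(self, rng):
        geno, qtls, preds = self._setup(rng)
        qtls[0].variant_id = "v3"  # the distal variant is the edQTL
        out = qs.select_control_variants(geno, qtls, preds, mode="distal-matched")
        # candidates inside the primary duplex are excluded
        assert set(out) <= {"v0"}  # v0 at pos 105 is inside -> actually excluded
        assert "v1" not in out and "v2" not in out


class TestFisher:
    def test_hand_table_matches_scipy(self):
        _, p = qs.fisher_exact_2x2([[3, 1], [1, 3]])
        assert p == pytest.approx(stats.fisher_exact([[3, 1], [1, 3]])[1], abs=1e-12)

    def test_balanced_symmetric_table(self):
        _, p = qs.fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_matches_scipy_randomly(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            odds, p = qs.fisher_exact_2x2([[a, b], [c, d]])
            so, sp = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(sp, abs=1e-9)

    def test_planted_difference_detected(self, rng):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            q = r.uniform(size=30) < 0.9
            c = r.uniform(size=100) < 0.3
            _, p = qs.pairing_enrichment_test(q, c)
            hits += p < 0.01
        assert hits >= 38  # >= 95% of seeds

    def test_empty_margin_missing(self):
        odds, p = qs.fisher_exact_2x2([[0, 0], [3, 4]])
        assert math.isnan(p)


class TestMannWhitney:
    def test_closed_case(self):
        u, p = qs.mannwhitney_u([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0
        assert p == pytest.approx(1 / 20)

    def test_identical_samples(self):
        _, p = qs.mannwhitney_u([1, 2, 3], [1, 2, 3], alternative="less")
        assert p >= 0.5

    def test_matches_scipy_exact(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(3, 9)))
            y = rng.normal(size=int(rng.integers(3, 9)))
            _, p = qs.mannwhitney_u(x, y, alternative="less")
            sp = stats.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
            assert p == pytest.approx(sp, abs=1e-9)

    def test_normal_approx_close_to_exact_at_boundary(self, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10) + 0.5
            _, p_exact = qs.mannwhitney_u(x, y, alternative="less", exact_max_n=10)
            _, p_approx = qs.mannwhitney_u(x, y, alternative="less", exact_max_n=5)
            assert p_approx == pytest.approx(p_exact, rel=0.05, abs=0.005)

    def test_ties_handled(self):
        _, p = qs.mannwhitney_u([1, 1, 2], [2, 3, 3], alternative="less")
        assert 0 < p < 1


class TestSignedPosition:
    def _pred(self):
        # stem pairs: edit side 100..109 pairs ECS 209..200; site at 105
        pairs = [(100 + k, 209 - k) for k in range(10)]
        return _prediction((100, 110), (200, 210), 105, pairs=pairs)

    def test_at_site_zero(self):
        assert qs.signed_position(106, self._pred()) == 0

    def test_downstream_positive(self):
        assert qs.signed_position(106 + 3, self._pred()) == 3

    def test_ecs_inherits_paired_sign(self):
        # ECS base paired with edit-side position 100 (5 pairs upstream)
        assert qs.signed_position(210, self._pred()) == -5

    def test_minus_strand_flips(self):
        pairs = [(100 + k, 209 - k) for k in range(10)]
        pred = _prediction((100, 110), (200, 210), 105, pairs=pairs, strand="-")
        assert qs.signed_position(106 + 3, pred) == -3


class TestCompareAlleles:
    def _planted_case(self, seed, effect=-0.1, noise=0.0):
        cfg = e.SimulationConfig(
            n_strains=30,
            n_sites=1,
            n_variants_per_gene=4,
            effect_sizes=(effect,),
            noise_sd=noise,
            maf_range=(0.4, 0.5),
            baseline_editing_range=(0.5, 0.7),
            seed=seed,
        )
        ds = e.simulate_dataset(cfg)
        seq = e.synthetic_data.chromosome_sequence(ds.loci)
        pred = predict_proximal_ecs(ds.sites[0], seq)
        var = next(iter(ds.truth.disrupting_variants))
        return ds, seq, pred, var

    def test_disrupting_variant_direction(self):
        ds, seq, pred, var = self._planted_case(71)
        comp = qs.compare_alleles(
            var, ds.genotypes, pred, seq, ds.levels.level[0]
        )
        # intact (reference) allele edits more and is more stable
        assert comp.allele_high == ds.genotypes.variants.set_index("variant_id").loc[var, "ref"]
        assert comp.delta_g < 0
        assert comp.is_base_paired is True
        assert comp.location_class == qs.WITHIN_DUPLEX

    def test_small_effect_gated_but_reported(self):
        ds, seq, pred, var = self._planted_case(72, effect=-0.01)
        comp = qs.compare_alleles(var, ds.genotypes, pred, seq, ds.levels.level[0])
        assert comp.effect_size == pytest.approx(0.01, abs=1e-9)
        assert not comp.passes_effect_gate

    def test_degenerate_identical_alleles(self):
        # ref == alt construct (variant outside both intervals): delta_g = 0
        ds, seq, pred, var = self._planted_case(73)
        vt = ds.genotypes.variants
        flank_var = next(
            vt["variant_id"].iloc[i]
            for i in range(len(vt))
            if qs.classify_variant_location(int(vt["pos"].iloc[i]), pred) == qs.DISTAL
        )
        comp = qs.compare_alleles(
            flank_var, ds.genotypes, pred, seq, ds.levels.level[0]
        )
        assert comp.delta_g == 0.0
        assert comp.location_class == qs.DISTAL


class TestDistalStems:
    def test_planted_stem_found(self):
        spec = DuplexSpec(stem_length=24, ecs_offset=38)
        seq, truth = generate_duplex_locus(spec, seed=81)
        var_pos0 = truth.pairs[5][0]  # inside the stem
        out = qs.find_distal_stems("v", var_pos0 + 1, seq)
        assert len(out) == 1
        assert out[0].n_pairs >= 24

    def test_19bp_stem_not_reported(self):
        spec = DuplexSpec(stem_length=19, ecs_offset=32)
        seq, truth = generate_duplex_locus(spec, seed=82)
        out = qs.find_distal_stems("v", truth.pairs[5][0] + 1, seq)
        assert out == []

    def test_unstructured_mostly_empty(self):
        found = 0
        for seed in range(20):
            r = np.random.default_rng(seed + 500)
            seq = "".join(r.choice(list("ACGT"), size=401))
            found += bool(qs.find_distal_stems("v", 201, seq))
        assert found <= 1

    def test_primary_duplex_excluded(self):
        spec = DuplexSpec(stem_length=24, ecs_offset=38)
        seq, truth = generate_duplex_locus(spec, seed=83)
        var_pos0 = truth.pairs[5][0]
        out = qs.find_distal_stems(
            "v",
            var_pos0 + 1,
            seq,
            exclude_intervals=[truth.edit_interval, truth.ecs_interval],
        )
        assert out == []


class TestWindowFrequency:
    def test_counts_and_monotonicity(self):
        variants = pd.DataFrame(
            [{"variant_id": "v", "chrom": "c", "pos": 1000}]
        )
        sites = [_site(949, chrom="c", site_id="a"), _site(1049, chrom="c", site_id="b")]
        out = qs.editing_site_window_frequency(variants, sites, (100, 200, 400))
        assert out.loc[0, "w100"] == 2  # sites at +/- 50 within window 100? no:
        # |950-1000| = 50 <= 50 and |1050-1000| = 50 <= 50
        assert out.loc[0, "w200"] == 2
        assert out.loc[0, "w400"] == 2

    def test_empty_window(self):
        variants = pd.DataFrame([{"variant_id": "v", "chrom": "c", "pos": 10}])
        out = qs.editing_site_window_frequency(variants, [], (200,))
        assert out.loc[0, "w200"] == 0
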