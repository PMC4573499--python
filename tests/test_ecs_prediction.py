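"""ECS prediction: proximal/distal recovery, conservation smoothing, enrichment."""

import math

import numpy as np
import pytest

import edscape.ecs_prediction as ep
from edscape.editing_quant import EditingSite
from edscape.synthetic_data import (
    DuplexSpec,
    generate_distal_locus,
    generate_duplex_locus,
    revcomp,
)


def _site(pos0: int, chrom="chrS", strand="+", site_id="s0", gene="g0") -> EditingSite:
    return EditingSite(chrom, pos0 + 1, strand, gene, site_id)


class TestProximal:
    def test_planted_stem_recovered_with_interval(self):
        spec = DuplexSpec(stem_length=25, bulges=(), ecs_offset=40)
        seq, truth = generate_duplex_locus(spec, seed=101)
        pred = ep.predict_proximal_ecs(_site(truth.site_index), seq)
        assert pred is not None and pred.accepted
        assert pred.n_pairs >= 25
        assert abs(pred.ecs_interval[0] - truth.ecs_interval[0]) <= 2
        assert abs(pred.ecs_interval[1] - truth.ecs_interval[1]) <= 2
        # the site's partner sits (stem_length - 1 - site_index_in_arm) nt
        # into the ECS arm, which itself starts ecs_offset nt downstream
        expected = spec.ecs_offset + (spec.stem_length - 1 - spec.site_index_in_arm)
        assert pred.distance == pytest.approx(expected, abs=1)

    def test_19bp_stem_rejected(self):
        spec = DuplexSpec(stem_length=19, ecs_offset=30)
        seq, truth = generate_duplex_locus(spec, seed=102)
        pred = ep.predict_proximal_ecs(_site(truth.site_index), seq)
        assert pred is None or not pred.accepted

    def test_unstructured_locus_mostly_rejected(self, rng):
        accepted = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            seq = "".join(r.choice(list("ACGT"), size=401))
            pred = ep.predict_proximal_ecs(_site(200), seq)
            accepted += bool(pred and pred.accepted)
        assert accepted <= 1  # >= 95% negative-control rejection

    def test_minus_strand_mirror(self):
        spec = DuplexSpec(stem_length=24, ecs_offset=38)
        seq, truth = generate_duplex_locus(spec, seed=103)
        plus = ep.predict_proximal_ecs(_site(truth.site_index), seq)
        rc = revcomp(seq)
        n = len(seq)
        site_rc = _site(n - 1 - truth.site_index, strand="-")
        minus = ep.predict_proximal_ecs(site_rc, rc)
        assert minus is not None and minus.accepted
        # mirrored coordinates: intervals map onto each other
        assert minus.ecs_interval == (
            n - plus.ecs_interval[1],
            n - plus.ecs_interval[0],
        )

    def test_window_truncated_at_contig_edge(self):
        spec = DuplexSpec(stem_length=22, ecs_offset=35)
        seq, truth = generate_duplex_locus(spec, seed=104, flank=30)
        pred = ep.predict_proximal_ecs(_site(truth.site_index), seq)
        assert pred is not None and pred.accepted


class TestSmoothing:
    def test_constant_track(self):
        out = ep.smooth_conservation(np.ones(200))
        assert np.allclose(out, 1.0)

    def test_single_spike(self):
        track = np.zeros(201)
        track[100] = 1.0
        out = ep.smooth_conservation(track)
        assert out[100] == pytest.approx(1 / 51)

    def test_step_crosses_half_at_midpoint(self):
        track = np.concatenate([np.zeros(100), np.ones(100)])
        out = ep.smooth_conservation(track)
        assert out[99] < 0.5 <= out[100]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ep.smooth_conservation(np.ones(10), window=50)

    def test_truncated_ends(self):
        out = ep.smooth_conservation(np.ones(100))
        assert out[0] == pytest.approx(1.0)  # truncated window, still mean of ones


class TestCandidateRegions:
    def _smoothed(self, runs, n=6000):
        arr = np.zeros(n)
        for s, e_, v in runs:
            arr[s:e_] = v
        return arr

    def test_short_run_rejected(self):
        sm = self._smoothed([(1000, 1019, 0.95)])
        assert ep.candidate_conserved_regions(sm, 500) == []

    def test_far_run_rejected(self):
        sm = self._smoothed([(3200, 3260, 0.95)])
        assert ep.candidate_conserved_regions(sm, 500) == []
        assert len(ep.candidate_conserved_regions(sm, 800)) == 1

    def test_low_score_rejected(self):
        sm = self._smoothed([(1000, 1060, 0.89)])
        assert ep.candidate_conserved_regions(sm, 500) == []

    def test_intronic_filter(self):
        sm = self._smoothed([(1000, 1060, 0.95)])
        assert ep.candidate_conserved_regions(sm, 500, introns=[(0, 900)]) == []
        assert len(ep.candidate_conserved_regions(sm, 500, introns=[(900, 2000)])) == 1


class TestDistal:
    def test_assembled_length_arithmetic(self):
        # a 40-nt candidate: (2*60+1) + 100 + (40+2*30) = 321 assembled nt
        seq, truth, cons = generate_distal_locus(
            DuplexSpec(stem_length=25, ecs_offset=40), distance=800, seed=7
        )
        site = _site(truth.site_index)
        cand = ep.ConservedRegion(600, 640, 0.95, 500)
        preds = ep.predict_distal_ecs(site, [cand], seq)
        assert preds and preds[0].structure.n == 321

    def test_planted_distal_recovered(self):
        spec = DuplexSpec(stem_length=26, ecs_offset=40)
        seq, truth, cons = generate_distal_locus(spec, distance=1500, seed=8)
        site = _site(truth.site_index)
        smoothed = ep.smooth_conservation(cons)
        cands = ep.candidate_conserved_regions(smoothed, truth.site_index)
        assert cands, "planted conserved region must qualify"
        preds = ep.predict_distal_ecs(site, cands, seq)
        acc = [p for p in preds if p.accepted]
        assert acc
        assert acc[0].ecs_interval[0] <= truth.ecs_interval[0] + 2
        assert acc[0].ecs_interval[1] >= truth.ecs_interval[1] - 2

    def test_site_flank_pairing_rejected(self):
        # proximal hairpin near the site, conserved candidate far away and
        # unstructured: any stem found pairs flank-to-flank -> not accepted
        spec = DuplexSpec(stem_length=22, ecs_offset=35)
        seq, truth = generate_duplex_locus(spec, seed=9, flank=1200)
        site = _site(truth.site_index)
        cand = ep.ConservedRegion(
            truth.site_index + 900, truth.site_index + 950, 0.95, 900
        )
        preds = ep.predict_distal_ecs(site, [cand], seq)
        assert all(not p.accepted for p in preds)
        assert any(
            p.reject_reason and "site flank" in p.reject_reason for p in preds
        ) or preds == []

    def test_overlap_falls_back_to_proximal(self):
        spec = DuplexSpec(stem_length=25, ecs_offset=40)
        seq, truth = generate_duplex_locus(spec, seed=10)
        site = _site(truth.site_index)
        cand = ep.ConservedRegion(truth.site_index + 30, truth.site_index + 60, 0.95, 30)
        with pytest.warns(UserWarning, match="proximal"):
            preds = ep.predict_distal_ecs(site, [cand], seq)
        assert preds and preds[0].approach == "proximal"


def _fake_prediction(chrom, ecs_start, ecs_end, site_pos0):
    return ep.EcsPrediction(
        site=_site(site_pos0, chrom=chrom),
        approach="proximal",
        stem=None,
        ecs_interval=(ecs_start, ecs_end),
        edit_interval=None,
        distance=None,
        accepted=True,
    )


class TestEnrichmentScore:
    def test_hand_counts(self):
        # 50 sites in one 1000-nt ECS, 20 in its two 1000-nt flanks -> 5.0
        preds = [_fake_prediction("c", 2000, 3000, 10)]
        sites = [_site(p, chrom="c", site_id=f"e{p}") for p in range(2000, 3000, 20)]
        sites += [_site(p, chrom="c", site_id=f"f{p}") for p in range(1000, 2000, 100)]
        sites += [_site(p, chrom="c", site_id=f"g{p}") for p in range(3000, 4000, 100)]
        score, table = ep.enrichment_score(preds, sites, {"c": 10_000})
        assert score == pytest.approx(50 / (20 / 2))
        assert table["n_sites_ecs"].sum() == 50

    def test_uniform_placement_near_one(self, rng):
        preds = []
        sites = []
        for i in range(200):
            chrom = f"L{i}"
            preds.append(_fake_prediction(chrom, 400, 430, 10))
            pos = rng.integers(0, 1000, size=30)
            sites.extend(
                _site(int(p), chrom=chrom, site_id=f"{chrom}_{k}")
                for k, p in enumerate(pos)
            )
        score, _ = ep.enrichment_score(preds, sites, {f"L{i}": 1000 for i in range(200)})
        assert 0.8 <= score <= 1.2

    def test_zero_flank_sites_missing(self):
        preds = [_fake_prediction("c", 2000, 3000, 10)]
        sites = [_site(2500, chrom="c", site_id="x")]
        score, table = ep.enrichment_score(preds, sites, {"c": 10_000})
        assert math.isnan(score)
        assert len(table) == 1


class TestSubstrateProperties:
    def test_perfect_helix_all_paired(self):
        spec = DuplexSpec(stem_length=30, ecs_offset=45)
        seq, truth = generate_duplex_locus(spec, seed=55)
        pred = ep.predict_proximal_ecs(_site(truth.site_index), seq)
        props = ep.substrate_properties([pred])
        frac = props["pairing_fraction"]
        offsets = props["pairing_offsets"]
        assert frac[offsets == 0][0] == 1.0
        assert all(frac[np.abs(offsets) <= 5] == 1.0)

    def test_single_distance_mass(self):
        spec = DuplexSpec(stem_length=25, ecs_offset=40)
        seq, truth = generate_duplex_locus(spec, seed=56)
        pred = ep.predict_proximal_ecs(_site(truth.site_index), seq)
        props = ep.substrate_properties([pred])
        assert props["distances"] == [pred.distance]
        assert props["stem_lengths"] == [pred.n_pairs]

    def test_requires_accepted(self):
        with pytest.raises(ValueError):
            ep.substrate_properties([])
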