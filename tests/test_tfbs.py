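"""TFBS selection, coverage profiling and footprint features."""

import numpy as np
import pytest

from cfpipe.genome import TfbsCatalog, TfbsSite
from cfpipe.simulate import CohortSpec, expected_central_flank_ratio, simulate_subject
from cfpipe.tfbs import (
    TfbsProfile,
    coverage_profile,
    normalize_profile,
    select_tfs,
    select_top_sites,
    tfbs_features,
)

from conftest import make_frags


def sites_at(peaks, chrom="chr1", support=1):
    return [TfbsSite(chrom, p - 100, p + 100, p, support) for p in peaks]


class TestSelectTfs:
    @pytest.mark.parametrize("n_sites,kept", [(1000, False), (1001, True)])
    def test_strictly_more_than_threshold(self, n_sites, kept):
        catalog = TfbsCatalog(
            {"TFA": sites_at(range(1000, 1000 + 300 * n_sites, 300))[:n_sites]}
        )
        if kept:
            assert "TFA" in select_tfs(catalog, min_sites=1000).sites
        else:
            with pytest.raises(ValueError, match="lower min_sites"):
                select_tfs(catalog, min_sites=1000)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            select_tfs(TfbsCatalog(), min_sites=10)


class TestSelectTopSites:
    def test_small_list_fully_kept_sorted(self):
        sites = [TfbsSite("chr1", i * 1000, i * 1000 + 100, i * 1000 + 50, s)
                 for i, s in enumerate([3, 9, 1, 7, 5])]
        top = select_top_sites(sites, k=1000)
        assert [s.support_score for s in top] == [9, 7, 5, 3, 1]

    def test_ties_break_by_genome_order(self):
        sites = [
            TfbsSite("chr1", 5000, 5100, 5050, 9),
            TfbsSite("chr1", 1000, 1100, 1050, 9),
            TfbsSite("chr1", 3000, 3100, 3050, 3),
        ]
        top = select_top_sites(sites, k=3)
        assert [s.peak_point for s in top] == [1050, 5050, 3050]

    def test_matches_bruteforce_sort_on_random_sites(self):
        rng = np.random.default_rng(6)
        sites = [
            TfbsSite("chr%d" % rng.integers(1, 3), int(p), int(p) + 100, int(p) + 50,
                     int(rng.integers(0, 50)))
            for p in rng.integers(0, 10_000_000, 10_000)
        ]
        top = select_top_sites(sites, k=1000)
        oracle = sorted(sites, key=lambda s: (-s.support_score, s.chrom, s.peak_point))[:1000]
        assert top == oracle


class TestCoverageProfile:
    def test_no_fragments_all_zero(self):
        frags = make_frags("chr1", [], [])
        prof, n = coverage_profile(frags, sites_at([50_000]), flank=1000)
        assert prof.shape == (2001,)
        assert np.all(prof == 0)

    def test_single_fragment_interval_overlap(self):
        peak = 50_000
        frags = make_frags("chr1", [peak - 10], [peak + 10])
        prof, _ = coverage_profile(frags, sites_at([peak]), flank=1000)
        p = np.arange(-1000, 1001)
        expected = ((p >= -10) & (p <= 9)).astype(float)
        np.testing.assert_array_equal(prof, expected)

    def test_matches_bruteforce_on_random_instance(self):
        rng = np.random.default_rng(12)
        starts = rng.integers(0, 100_000, 2000)
        lens = rng.integers(60, 350, 2000)
        frags = make_frags("chr1", starts.tolist(), (starts + lens).tolist())
        sites = sites_at(rng.integers(3000, 97_000, 9).tolist())
        prof, _ = coverage_profile(frags, sites, flank=500)
        oracle = np.zeros(1001)
        for s in sites:
            for j, p in enumerate(range(s.peak_point - 500, s.peak_point + 501)):
                oracle[j] += ((starts <= p) & (starts + lens > p)).sum()
        np.testing.assert_allclose(prof, oracle / len(sites))

    def test_invariant_to_site_order(self):
        rng = np.random.default_rng(14)
        starts = rng.integers(0, 100_000, 1000)
        frags = make_frags("chr1", starts.tolist(), (starts + 160).tolist())
        sites = sites_at(rng.integers(3000, 97_000, 8).tolist())
        a, _ = coverage_profile(frags, sites, flank=300)
        b, _ = coverage_profile(frags, sites[::-1], flank=300)
        np.testing.assert_array_equal(a, b)

    def test_mirrored_fragments_reverse_profile(self):
        rng = np.random.default_rng(15)
        total = 200_000
        starts = rng.integers(0, total - 400, 1500)
        lens = rng.integers(60, 350, 1500)
        frags = make_frags("chr1", starts.tolist(), (starts + lens).tolist())
        peaks = rng.integers(3000, total - 3000, 6).tolist()
        # covered position x maps to total - 1 - x under reflection
        mirrored_starts = total - (starts + lens)
        mirrored = make_frags("chr1", mirrored_starts.tolist(), (total - starts).tolist())
        mirrored_sites = sites_at([total - 1 - p for p in peaks])
        a, _ = coverage_profile(frags, sites_at(peaks), flank=400)
        b, _ = coverage_profile(mirrored, mirrored_sites, flank=400)
        np.testing.assert_allclose(a, b[::-1])

    def test_chromosome_edge_truncation(self):
        # site peak 200 bp from the chromosome start: positions < -200 undefined
        frags = make_frags("chr1", [0], [400])
        prof, _ = coverage_profile(
            frags, sites_at([200]), flank=1000, chrom_sizes={"chr1": 100_000}
        )
        p = np.arange(-1000, 1001)
        assert np.all(prof[p < -200] == 0)
        np.testing.assert_array_equal(prof[(p >= -200) & (p < 200)], 1.0)

    def test_uniform_simulation_is_flat(self, small_genome):
        spec = CohortSpec(label="h", n_subjects=1, fragments_per_subject=400_000)
        frags = simulate_subject(small_genome, spec, 0, seed=31)
        sites = select_top_sites(small_genome.tfbs_catalog.sites["TF1"], k=60)
        prof, _ = coverage_profile(frags, sites, flank=1000, chrom_sizes=small_genome.sizes())
        mean_len = float((frags["end"] - frags["start"]).mean())
        expected = len(frags) * mean_len / small_genome.total_length()
        # per-position mean over n sites: roughly Poisson(n*expected)/n
        se = np.sqrt(expected / len(sites))
        assert np.abs(prof - expected).max() < 4.5 * se


class TestNormalizationAndFeatures:
    def test_flat_profile_gives_unit_ratio(self):
        prof = TfbsProfile("TFX", np.arange(-1000, 1001), np.ones(2001), 10)
        feats = tfbs_features(prof)
        assert feats["TFX_central_flank_ratio"] == pytest.approx(1.0)

    def test_half_depth_center(self):
        p = np.arange(-1000, 1001)
        depth = np.where(np.abs(p) <= 150, 0.5, 1.0)
        prof = TfbsProfile("TFX", p, depth, 10)
        feats = tfbs_features(prof)
        assert feats["TFX_central_mean"] == pytest.approx(0.5)
        assert feats["TFX_flank_mean"] == pytest.approx(1.0)
        assert feats["TFX_central_flank_ratio"] == pytest.approx(0.5)

    def test_normalization_scale_contract(self):
        raw = np.full(2001, 0.25)
        a = normalize_profile(raw, "TFX", 5, mean_depth=0.25)
        b = normalize_profile(raw * 2, "TFX", 5, mean_depth=0.5)
        np.testing.assert_allclose(a.depth, b.depth, atol=1e-12)
        np.testing.assert_allclose(a.depth, 1.0)

    def test_neutral_subject_normalizes_to_one(self, small_genome):
        spec = CohortSpec(label="h", n_subjects=1, fragments_per_subject=400_000)
        frags = simulate_subject(small_genome, spec, 0, seed=33)
        sites = select_top_sites(small_genome.tfbs_catalog.sites["TF2"], k=60)
        raw, n = coverage_profile(frags, sites, flank=1000, chrom_sizes=small_genome.sizes())
        depth = float((frags["end"] - frags["start"]).sum() / small_genome.total_length())
        prof = normalize_profile(raw, "TF2", n, depth)
        assert prof.depth.mean() == pytest.approx(1.0, abs=0.05)


class TestDipRecovery:
    def test_simulated_dip_matches_kernel_integral(self):
        """Central/flank ratio at dip 0.5 agrees with the numerical kernel
        prediction within 3 SE over replicate subjects."""
        from cfpipe.genome import MiniGenome

        peaks = list(range(20_000, 2_000_000, 40_000))
        genome = MiniGenome(
            chromosomes=[("chr1", 2_000_000)],
            gc_window=50_000,
            gc_track={"chr1": np.full(40, 0.5)},
            blacklist=[],
            tfbs_catalog=TfbsCatalog({"TFD": sites_at(peaks)}),
        )
        dip = 0.5
        spec = CohortSpec(label="npc", n_subjects=8, fragments_per_subject=120_000,
                          tfbs_dip=dip)
        ratios = []
        for i in range(spec.n_subjects):
            frags = simulate_subject(genome, spec, i, seed=37)
            raw, n = coverage_profile(
                frags, genome.tfbs_catalog.sites["TFD"], flank=1000,
                chrom_sizes=genome.sizes(),
            )
            prof = TfbsProfile("TFD", np.arange(-1000, 1001), raw, n)
            feats = tfbs_features(prof)
            ratios.append(feats["TFD_central_flank_ratio"])
        ratios = np.asarray(ratios)
        predicted = expected_central_flank_ratio(dip, spec.length_params)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - predicted) < 3 * se
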