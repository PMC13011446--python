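"""Generator behavior: Poisson landscapes, rearranged anchor tables,
two-population genotypes, determinism, validation."""

import numpy as np
import pytest
from scipy import stats

from karyoshift import simdata
from karyoshift.simdata import (
    ConservedTract, Fusion, PlantedInversion, PopGenConfig, SimConfig,
    TEFamily, Translocation, simulate_anchor_table, simulate_genotypes,
    simulate_landscape,
)


def landscape_config(seed=1, rate=2e-4, lam=1.0, inversions=None, L=10_000_000):
    return SimConfig(
        seed=seed, chromosomes=[("chr1", L)],
        te_families=[TEFamily("DNA/h", "DNA", rate)],
        inversions=inversions if inversions is not None else [],
    )


class TestLandscape:
    def test_zero_rate_empty_annotation(self):
        cfg = SimConfig(seed=1, chromosomes=[("c", 1_000_000)],
                        te_families=[TEFamily("DNA/h", "DNA", 0.0)])
        _, feats, _ = simulate_landscape(cfg)
        assert feats == []

    def test_zero_background_enriched_flanks_contain_everything(self):
        cfg = SimConfig(
            seed=2, chromosomes=[("c", 10_000_000)],
            te_families=[TEFamily("DNA/h", "DNA", 1e-3)],
            inversions=[PlantedInversion("c", 2_000_000, 7_000_000,
                                         enrichment=0.0)])
        # complementary construction: lambda=0 removes everything inside the
        # flanks, so flanks and background partition the output
        _, feats, truth = simulate_landscape(cfg)
        flanks = [(1_950_000, 2_050_000), (6_950_000, 7_050_000)]
        for f in feats:
            assert not any(lo <= f.start < hi for lo, hi in flanks)

    def test_enriched_only_landscape_containment(self):
        """With zero background but a positive flank rate, every repeat
        starts within ±50 kb of a planted breakpoint."""
        cfg = SimConfig(
            seed=3, chromosomes=[("c", 10_000_000)],
            te_families=[TEFamily("DNA/h", "DNA", 1e-9)],  # ~0 background
            inversions=[PlantedInversion("c", 2_000_000, 7_000_000,
                                         enrichment=50_000.0)])
        _, feats, _ = simulate_landscape(cfg)
        assert len(feats) > 0
        flanks = [(1_950_000, 2_050_000), (6_950_000, 7_050_000)]
        stray = [f for f in feats
                 if not any(lo <= f.start < hi for lo, hi in flanks)]
        # background expectation is rate*L = 0.01 repeats; allow none
        assert len(stray) <= 1

    def test_poisson_count_three_sigma_over_seeds(self):
        """λ=1: per-seed repeat counts stay within ±3·sqrt(rL) of rL for at
        least 97% of 200 seeds (the 3σ band holds ~99.7%)."""
        rate, L = 2e-4, 10_000_000
        mean = rate * L
        within = 0
        counts = []
        for seed in range(200):
            _, feats, _ = simulate_landscape(landscape_config(seed=seed, rate=rate))
            counts.append(len(feats))
            within += abs(len(feats) - mean) <= 3 * np.sqrt(mean)
        assert within >= 0.97 * 200
        # dispersion consistent with Poisson: chi-square goodness of fit
        chi2 = sum((k - mean) ** 2 / mean for k in counts)
        p = stats.chi2.sf(chi2, 200)
        assert p > 0.01 and stats.chi2.cdf(chi2, 200) > 0.01

    def test_seed_determinism_byte_identical(self, tmp_path):
        from karyoshift.genome_io import write_repeat_bed
        cfg = landscape_config(seed=11, inversions=[
            PlantedInversion("chr1", 1_000_000, 4_000_000, enrichment=3.0)])
        out = []
        for name in ("a.bed", "b.bed"):
            _, feats, _ = simulate_landscape(cfg)
            write_repeat_bed(feats, tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            TEFamily("DNA/h", "DNA", -1e-4)

    def test_overlapping_inversions_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            SimConfig(seed=1, chromosomes=[("c", 10_000_000)],
                      inversions=[PlantedInversion("c", 1_000_000, 3_000_000),
                                  PlantedInversion("c", 2_500_000, 5_000_000)])

    def test_inversion_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, chromosomes=[("c", 1_000_000)],
                      inversions=[PlantedInversion("c", 500_000, 2_000_000)])


class TestAnchorTable:
    def test_no_rearrangements_monotone_per_chromosome(self):
        cfg = SimConfig(seed=1, chromosomes=[("a", 5_000_000), ("b", 3_000_000)])
        anchors, _ = simulate_anchor_table(cfg)
        for chrom, grp in anchors.groupby("qchrom"):
            grp = grp.sort_values("qstart")
            assert (grp["rchrom"] == chrom).all()
            assert grp["rstart"].is_monotonic_increasing

    def test_fusion_concatenation_arithmetic(self):
        cfg = SimConfig(seed=1, chromosomes=[("chrA", 10_000_000), ("chrB", 8_000_000)],
                        fusions=[Fusion(("chrA", "chrB"))])
        anchors, truth = simulate_anchor_table(cfg)
        assert truth.derived_genome["chrA+chrB"] == 18_000_000
        fused = anchors[anchors["qchrom"] == "chrA+chrB"].sort_values("qstart")
        # chrA anchors come first, then chrB
        switch = fused["rchrom"].tolist()
        assert switch == sorted(switch, key=lambda c: c != "chrA")
        b_rows = fused[fused["rchrom"] == "chrB"]
        np.testing.assert_array_equal(b_rows["qstart"], b_rows["rstart"] + 10_000_000)

    def test_inversion_reverses_contained_rank_run(self):
        cfg = SimConfig(seed=1, chromosomes=[("c", 10_000_000)],
                        genes_per_mb=10.0,
                        inversions=[PlantedInversion("c", 2_000_000, 4_000_000)])
        anchors, _ = simulate_anchor_table(cfg)
        a = anchors.sort_values("qstart").reset_index(drop=True)
        rranks = a["rrank"].tolist()
        inside = a[(a["qstart"] >= 2_000_000) & (a["qend"] <= 4_000_000)]
        run = inside["rrank"].tolist()
        assert run == sorted(run, reverse=True) and len(run) >= 10
        outside = a[~a.index.isin(inside.index)]
        assert outside["rrank"].is_monotonic_increasing

    def test_rearrangement_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, chromosomes=[("c", 1_000_000)],
                      translocations=[Translocation("c", 0, 100, "c", 2_000_000)])


class TestGenotypes:
    def test_all_rates_zero_everyone_identical(self):
        cfg = SimConfig(seed=1, chromosomes=[("a", 1000)],
                        popgen=PopGenConfig(n_sites=500, d=0.0, pi_x=0.0, pi_y=0.0))
        gt, _ = simulate_genotypes(cfg)
        assert all(all(a == 0 for a in row) for row in gt.alleles)

    def test_fixed_difference_count_binomial(self):
        """d=0.01 over 100,000 sites: fixed-difference count within 3σ of
        1,000 (σ = sqrt(n d (1-d)))."""
        cfg = SimConfig(seed=7, chromosomes=[("a", 1000)],
                        popgen=PopGenConfig(n_sites=100_000, d=0.01,
                                            pi_x=0.0, pi_y=0.0))
        gt, _ = simulate_genotypes(cfg)
        n = cfg.popgen.n_haplotypes_per_pop
        fixed = sum(1 for row in gt.alleles
                    if all(a == 0 for a in row[:n]) and all(a == 1 for a in row[n:]))
        sigma = np.sqrt(100_000 * 0.01 * 0.99)
        assert abs(fixed - 1000) <= 3 * sigma

    def test_conserved_tract_with_zero_rate_has_no_fixed_differences(self):
        cfg = SimConfig(seed=3, chromosomes=[("a", 1000)],
                        popgen=PopGenConfig(
                            n_sites=50_000, d=0.02, pi_x=0.0, pi_y=0.0,
                            conserved_tracts=(ConservedTract(10_000, 20_000, 0.0),)))
        gt, _ = simulate_genotypes(cfg)
        n = cfg.popgen.n_haplotypes_per_pop
        for site in range(10_000, 20_000):
            row = gt.alleles[site]
            assert not (all(a == 0 for a in row[:n]) and all(a == 1 for a in row[n:])
                        and any(a == 1 for a in row))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            PopGenConfig(n_sites=10, d=1.5)

    def test_determinism(self):
        cfg = SimConfig(seed=5, chromosomes=[("a", 1000)],
                        popgen=PopGenConfig(n_sites=5000, d=0.01,
                                            pi_x=0.003, pi_y=0.001,
                                            missing_rate=0.02))
        g1, _ = simulate_genotypes(cfg)
        g2, _ = simulate_genotypes(cfg)
        assert g1.alleles == g2.alleles


class TestRecovery:
    """Noise-free planted features are recovered by the downstream
    detectors across many random configurations."""

    def test_fusion_and_tract_and_enrichment_recovery(self, rng):
        from karyoshift import synteny as syn
        from karyoshift import popgen as pg
        from karyoshift.popgen import SiteCounts
        from karyoshift.genome_io import GenomeIndex
        from karyoshift.enrichment import PermutationConfig, permutation_test

        for trial in range(20):
            seed = int(rng.integers(0, 2**31 - 1))
            lens = [int(rng.integers(8, 20)) * 1_000_000 for _ in range(3)]
            tract_start = int(rng.integers(2, 6)) * 10_000
            cfg = SimConfig(
                seed=seed,
                chromosomes=[("a1", lens[0]), ("a2", lens[1]), ("a3", lens[2])],
                te_families=[TEFamily("DNA/h", "DNA", 3e-4)],
                fusions=[Fusion(("a1", "a2"), "fused")],
                inversions=[PlantedInversion(
                    "a3", lens[2] // 4, lens[2] // 2, enrichment=12.0)],
                popgen=PopGenConfig(
                    n_sites=100_000, d=0.01, pi_x=0.001, pi_y=0.001,
                    conserved_tracts=(ConservedTract(tract_start,
                                                     tract_start + 30_000, 0.0),)),
            )
            anchors, truth = simulate_anchor_table(cfg)
            blocks = syn.chain_blocks(syn.rank_anchors(anchors))
            calls = syn.detect_fusions(blocks)
            assert len(calls) == 1
            assert {p[0] for p in calls[0].partners} == {"a1", "a2"}

            genome, repeats, _ = simulate_landscape(cfg)
            res = permutation_test(repeats, truth.inversions[0], genome,
                                   PermutationConfig(n_replicates=500, seed=seed))
            assert res.significant

            gt, _ = simulate_genotypes(cfg)
            sc = SiteCounts.from_genotypes(gt, {s: s[0] for s in gt.samples})
            gi = GenomeIndex([("pg1", 100_000)])
            fst = pg.windowed_fst(sc, "X", "Y", gi, w=10_000)
            tracts = pg.scan_conserved_tracts(fst, 0.5)
            assert any(t.start <= tract_start and t.end >= tract_start + 30_000
                       for t in tracts)
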