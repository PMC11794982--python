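"""Synthetic-data generator: determinism, ground-truth invariants,
capture-chemistry geometry and the DV200 metric."""

import numpy as np
import pandas as pd
import pytest

from utarscan.simulate import (
    SimConfig,
    SimulationSizingError,
    dv200,
    fragment_and_place_reads,
    make_databases,
    make_genome,
    simulate_counts,
    simulate_spots,
)


class TestMakeGenome:
    def test_same_seed_is_reproducible(self, small_sim_config):
        _, a = make_genome(small_sim_config)
        _, b = make_genome(small_sim_config)
        pd.testing.assert_frame_equal(a, b)

    def test_no_lnc_means_all_annotated(self):
        cfg = SimConfig(seed=1, n_contigs=2, contig_length=120_000,
                        n_genes=6, n_lnc=0, n_spots=10)
        _, loci = make_genome(cfg)
        assert loci["annotated"].all()

    def test_pairwise_gaps_respect_min_gap(self):
        genome, loci = make_genome(SimConfig(seed=3))
        # exhaustive pairwise scan (same-strand invariant, checked on all
        # pairs since placement is strand-blind here)
        rows = list(loci.itertuples(index=False))
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                if a.contig != b.contig:
                    continue
                gap = max(a.start, b.start) - min(a.end, b.end)
                assert gap >= 2_000, f"{a.id} vs {b.id}: gap {gap}"
        for r in rows:
            assert 0 <= r.start < r.end <= genome.lengths[r.contig]

    def test_too_small_genome_raises_sizing_error(self):
        cfg = SimConfig(seed=0, n_contigs=1, contig_length=20_000,
                        n_genes=10, n_lnc=10, n_spots=10)
        with pytest.raises(SimulationSizingError):
            make_genome(cfg)

    def test_marker_genes_carry_the_planted_fold(self):
        _, loci = make_genome(SimConfig(seed=5))
        markers = loci[loci["id"].isin(["KRT5", "KRT1", "KRT10", "DSP", "LOR"])]
        assert len(markers) == 5
        assert (markers["celltype_effect"] == 8.0).all()
        assert markers["annotated"].all()


class TestMakeDatabases:
    def test_zero_fractions_leave_databases_empty(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.to_dict(),
                           "db1_frac": 0.0, "db2_frac": 0.0})
        _, loci = make_genome(cfg)
        db1, db2 = make_databases(loci, cfg)
        assert len(db1) == 0 and len(db2) == 0
        assert not loci["in_db1"].any() and not loci["in_db2"].any()

    def test_full_fractions_cover_every_lnc(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.to_dict(),
                           "db1_frac": 1.0, "db2_frac": 1.0})
        _, loci = make_genome(cfg)
        db1, db2 = make_databases(loci, cfg)
        n_lnc = (~loci["annotated"]).sum()
        assert len(db1) == n_lnc == len(db2)
        assert loci.loc[~loci["annotated"], ["in_db1", "in_db2"]].all().all()

    def test_sizes_match_fractions_and_flags(self):
        cfg = SimConfig(seed=9, db1_frac=0.6, n_lnc=20)
        _, loci = make_genome(cfg)
        db1, db2 = make_databases(loci, cfg)
        assert len(db1) == 12  # 0.6 * 20
        assert loci["in_db1"].sum() == 12
        assert len(db2) == loci["in_db2"].sum() == 10
        # database intervals are the exact planted intervals, stranded
        merged = db1.merge(loci, left_on="name", right_on="id",
                           suffixes=("", "_t"))
        assert (merged["start"] == merged["start_t"]).all()
        assert (merged["end"] == merged["end_t"]).all()
        assert (merged["strand"] == merged["strand_t"]).all()


class TestSimulateSpots:
    def test_grid_is_unique_and_complete(self):
        spots = simulate_spots(SimConfig(seed=2, n_spots=200))
        assert len(spots) == 200
        assert spots["barcode"].is_unique
        assert not spots[["x", "y"]].duplicated().any()
        assert spots["x"].max() == 19 and spots["y"].max() == 9  # 10 x 20

    def test_zero_noise_is_exact_half_plane(self):
        cfg = SimConfig(seed=4, n_spots=200, flip_rate=0.0)
        spots = simulate_spots(cfg)
        boundary = (1 - cfg.domain_frac) * 20
        expect = np.where(spots["x"] >= boundary, "keratinocyte", "other")
        assert (spots["domain"].to_numpy() == expect).all()

    def test_flip_fraction_is_binomial(self):
        cfg = SimConfig(seed=6, n_spots=10_000, flip_rate=0.05)
        noisy = simulate_spots(cfg)
        clean = simulate_spots(
            SimConfig(**{**cfg.to_dict(), "flip_rate": 0.0})
        )
        flipped = (noisy["domain"] != clean["domain"]).mean()
        sd = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(flipped - 0.05) < 3 * sd


class TestSimulateCounts:
    def test_zero_mean_gives_zero_counts(self, small_sim_config):
        _, loci = make_genome(small_sim_config)
        loci["base_mean"] = 0.0
        spots = simulate_spots(small_sim_config)
        counts = simulate_counts(loci, spots, small_sim_config)
        assert (counts.to_numpy() == 0).all()

    def test_sample_mean_matches_nb_mean(self):
        cfg = SimConfig(seed=8, n_spots=10_000, base_mean=2.0, dispersion=2.0)
        loci = pd.DataFrame(
            {"id": ["x"], "base_mean": [2.0], "dispersion": [2.0],
             "celltype_effect": [1.0]}
        )
        spots = simulate_spots(cfg)
        counts = simulate_counts(loci, spots, cfg).to_numpy().ravel()
        se = np.sqrt((2.0 + 2.0**2 / 2.0) / 10_000)  # var = mu + mu^2/size
        assert abs(counts.mean() - 2.0) < 3 * se

    def test_effect_multiplies_domain_mean(self):
        cfg = SimConfig(seed=12, n_spots=10_000, flip_rate=0.0,
                        domain_frac=0.5)
        loci = pd.DataFrame(
            {"id": ["x"], "base_mean": [2.0], "dispersion": [5.0],
             "celltype_effect": [8.0]}
        )
        spots = simulate_spots(cfg)
        counts = simulate_counts(loci, spots, cfg).to_numpy().ravel()
        kera = spots["domain"].to_numpy() == "keratinocyte"
        assert counts[kera].mean() == pytest.approx(16.0, rel=0.1)
        assert counts[~kera].mean() == pytest.approx(2.0, rel=0.1)


@pytest.fixture(scope="module", params=["probe", "polyA"])
def bundle(request, small_sim_config):
    cfg = SimConfig(**{**small_sim_config.to_dict(),
                       "capture_mode": request.param})
    _, loci = make_genome(cfg)
    spots = simulate_spots(cfg)
    counts = simulate_counts(loci, spots, cfg)
    reads = fragment_and_place_reads(counts, loci, cfg)
    return cfg, loci, counts, reads


class TestReads:
    def test_read_count_conservation(self, bundle):
        cfg, _, counts, reads = bundle
        assert len(reads) == cfg.reads_per_count * counts.to_numpy().sum()

    def test_reads_stay_within_origin_locus(self, bundle):
        _, loci, _, reads = bundle
        merged = reads.merge(loci, left_on="origin", right_on="id",
                             suffixes=("", "_l"))
        assert (merged["start"] >= merged["start_l"]).all()
        assert (merged["start"] + merged["length"] <= merged["end"]).all()
        assert (merged["strand"] == merged["strand_l"]).all()
        assert (merged["fragment_length"] >= merged["length"]).all()

    def test_reads_per_count_multiplies_reads(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.to_dict(),
                           "reads_per_count": 3})
        _, loci = make_genome(cfg)
        spots = simulate_spots(cfg)
        counts = simulate_counts(loci, spots, cfg)
        reads = fragment_and_place_reads(counts, loci, cfg)
        assert len(reads) == 3 * counts.to_numpy().sum()

    def test_polya_three_prime_bias_scales_with_degradation(self):
        dists = {}
        for deg in (200.0, 2_000.0):
            cfg = SimConfig(seed=21, n_contigs=1, contig_length=100_000,
                            n_genes=0, n_lnc=5, n_marker_genes=0,
                            n_spots=100, capture_mode="polyA",
                            degradation=deg, base_mean=5.0)
            _, loci = make_genome(cfg)
            spots = simulate_spots(cfg)
            counts = simulate_counts(loci, spots, cfg)
            reads = fragment_and_place_reads(counts, loci, cfg)
            m = reads.merge(loci, left_on="origin", right_on="id",
                            suffixes=("", "_l"))
            three_prime = np.where(
                m["strand"] == "+", m["start"] + m["length"] - 1, m["start"]
            )
            locus_3p = np.where(m["strand"] == "+", m["end"] - 1, m["start_l"])
            dists[deg] = np.abs(three_prime - locus_3p).mean()
        assert dists[200.0] < dists[2_000.0]


class TestDV200:
    def test_hand_cases(self):
        assert dv200([500] * 10) == 100.0
        assert dv200([100, 150, 250, 300]) == 50.0
        assert dv200([200]) == 0.0  # strictly greater than 200

    def test_closed_form_for_exponential_fragments(self):
        rng = np.random.default_rng(123)
        draws = rng.exponential(scale=200.0, size=100_000)
        expected = 100.0 * np.exp(-1.0)  # P(L > 200) = e^(-200/200)
        mc_sd = 100.0 * np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / 100_000)
        assert abs(dv200(draws) - expected) < 4 * mc_sd

    def test_monotone_in_degradation(self):
        # seed-averaged over a degradation grid, DV200 never decreases
        rng = np.random.default_rng(99)
        grid = [100.0, 200.0, 500.0, 1_000.0, 3_000.0]
        vals = [
            np.mean([dv200(rng.exponential(m, 20_000)) for _ in range(3)])
            for m in grid
        ]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            dv200([])
        with pytest.raises(ValueError):
            dv200([100, -5])
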