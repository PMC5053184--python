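"""Simulator tests: genome generation, MspI digestion, landscape sampling,
read emission chemistry and expression coupling."""

import numpy as np
import pandas as pd
import pytest

from rrbskit import simdata, profiles
from rrbskit.config import GenomeParams, SimulationConfig
from rrbskit.types import GenomeAnnotation


def naive_ccgg_count(seq: str) -> int:
    return sum(1 for i in range(len(seq) - 3) if seq[i:i + 4] == "CCGG")


class TestGenerateGenome:
    def test_deterministic_for_seed(self, small_config, small_genome):
        again = simdata.generate_genome(small_config)
        assert again.chromosomes == small_genome.chromosomes
        assert again.genes == small_genome.genes
        assert again.cg_islands == small_genome.cg_islands

    def test_ccgg_density_supports_fragments(self, small_config, small_genome):
        frags = simdata.mspi_digest(small_genome, small_config.size_range)
        assert len(frags) >= 100

    def test_ccgg_count_matches_string_scan(self, small_genome):
        seq = small_genome.chromosomes["chr1"]
        found = seq.count("CCGG")  # CCGG cannot overlap itself
        assert found == naive_ccgg_count(seq)
        assert found > 0

    def test_zero_cgi_config_valid(self):
        cfg = SimulationConfig(seed=5, genome=GenomeParams(
            n_chromosomes=1, chromosome_bp=100_000, cgi_per_mb=0,
            promoter_cgi_fraction=0.0, genes_per_mb=10))
        g = simdata.generate_genome(cfg)
        assert g.cg_islands == []
        g.validate()

    def test_rejects_hopeless_config(self):
        cfg = SimulationConfig(seed=1, genome=GenomeParams(
            n_chromosomes=1, chromosome_bp=50, spike_in_bp=40))
        with pytest.raises(ValueError):
            simdata.generate_genome(cfg)

    def test_spike_in_unannotated(self, small_genome):
        s = small_genome.spike_in
        assert s in small_genome.chromosomes
        assert all(g.chrom != s for g in small_genome.genes)
        assert all(r.chrom != s for r in small_genome.cg_islands)


class TestMspiDigest:
    def test_toy_string_cut_position(self):
        g = GenomeAnnotation(chromosomes={"c": "AACCGGTT"})
        frags = simdata.digest_fragments_prefilter(g)["c"]
        assert [(f.start, f.end) for f in frags] == [(0, 3), (3, 8)]

    def test_no_site_outside_range_yields_nothing(self):
        g = GenomeAnnotation(chromosomes={"c": "ATATATAT"})
        assert simdata.mspi_digest(g, (150, 400)) == []

    def test_prefilter_partition_reconstructs_chromosome(self, small_genome):
        for chrom, seq in small_genome.chromosomes.items():
            frags = simdata.digest_fragments_prefilter(small_genome)[chrom]
            assert frags[0].start == 0 and frags[-1].end == len(seq)
            rebuilt = "".join(seq[f.start:f.end] for f in frags)
            assert rebuilt == seq
            # every internal boundary is a C | CGG cut
            for f in frags[1:]:
                assert seq[f.start:f.start + 3] == "CGG"
                assert seq[f.start - 1] == "C"

    def test_size_selection_inclusive(self, small_genome, small_config):
        lo, hi = small_config.size_range
        for f in simdata.mspi_digest(small_genome, small_config.size_range):
            assert lo <= len(f) <= hi


class TestLandscape:
    def test_spike_probabilities_zero(self, small_genome, small_landscape):
        spike = (small_landscape.sites["chrom"] == small_genome.spike_in).to_numpy()
        assert spike.any()
        assert (small_landscape.base_prob[spike] == 0).all()

    def test_every_cytosine_has_one_entry(self, small_genome, small_landscape):
        seq = small_genome.chromosomes["chr1"]
        sub = small_landscape.sites[small_landscape.sites["chrom"] == "chr1"]
        n_c = seq.count("C")
        n_g = seq.count("G")
        assert len(sub) == n_c + n_g
        assert not sub.duplicated(["pos", "strand"]).any()

    def test_context_consistent_with_sequence(self, small_genome, small_landscape):
        from rrbskit.bsalign import classify_context

        sub = small_landscape.sites[small_landscape.sites["chrom"] == "chr1"]
        sample = sub.sample(200, random_state=0)
        for row in sample.itertuples(index=False):
            assert classify_context(small_genome, "chr1", row.pos, row.strand) == row.context

    def test_cgi_sites_hypomethylated_vs_background(self, small_genome, small_landscape):
        df = small_landscape.frame_for()
        cg = df[(df["context"] == "CG") & (df["chrom"] == "chr1")]
        in_cgi = np.zeros(len(cg), dtype=bool)
        pos = cg["pos"].to_numpy()
        for r in small_genome.cg_islands:
            in_cgi |= (pos >= r.start) & (pos < r.end)
        assert cg.loc[in_cgi, "true_prob"].mean() < cg.loc[~in_cgi, "true_prob"].mean() - 0.2

    def test_rejects_invalid_compartment_means(self, small_genome, small_config):
        import dataclasses

        bad = dataclasses.replace(small_config.landscape, cg_high_mean=1.5)
        cfg = dataclasses.replace(small_config, landscape=bad)
        with pytest.raises(ValueError):
            simdata.sample_landscape(small_genome, cfg)

    def test_oocyte_mode_couples_noncg_to_cg(self):
        """1-Mb-window CG vs non-CG correlation: ~0 when independent, >0.5
        in oocyte mode (window shrunk to the toy genome scale)."""
        import dataclasses

        base = SimulationConfig(seed=9, samples=("A",), genome=GenomeParams(
            n_chromosomes=1, chromosome_bp=400_000))
        g = simdata.generate_genome(base)
        rs = {}
        for oocyte in (False, True):
            lp = dataclasses.replace(base.landscape, oocyte_mode=oocyte,
                                     oocyte_coupling=0.35)
            cfg = dataclasses.replace(base, landscape=lp)
            land = simdata.sample_landscape(g, cfg)
            df = land.frame_for()
            df = df[df["chrom"] == "chr1"].rename(columns={"true_prob": "level"})
            rs[oocyte] = profiles.window_correlation_cg_noncg(df, window_bp=10_000)
        assert abs(rs[False]) < 0.2
        assert rs[True] > 0.5


class TestSimulateReads:
    @pytest.mark.parametrize("p_m,expect_c", [(0.0, False), (1.0, True)])
    def test_forced_conversion_extremes(self, small_config, small_genome,
                                        small_fragments, small_landscape, p_m, expect_c):
        import dataclasses

        land = dataclasses.replace(
            small_landscape, base_prob=np.full_like(small_landscape.base_prob, p_m),
            sample_shifts={})
        cfg = dataclasses.replace(small_config, conversion_rate=1.0, depth=2.0)
        reads, side = simdata.simulate_reads(
            small_fragments[:20], land, cfg, "A", small_genome)
        seq = small_genome.chromosomes["chr1"]
        checked = 0
        for (rid, read), row in zip(reads, side.itertuples(index=False)):
            window = seq[row.read_start:row.read_start + row.read_len]
            if row.strand_class == "OT":
                for off, base in enumerate(window):
                    if base == "C":
                        assert (read[off] == "C") == expect_c
                        checked += 1
        assert checked > 50

    def test_incomplete_conversion_rate(self, small_config, small_genome,
                                        small_fragments, small_landscape):
        """With p_m = 0 and conversion 0.99, the fraction of Cs read as C is
        within 3 binomial SD of 0.01."""
        import dataclasses

        land = dataclasses.replace(
            small_landscape, base_prob=np.zeros_like(small_landscape.base_prob),
            sample_shifts={})
        cfg = dataclasses.replace(small_config, conversion_rate=0.99, depth=6.0)
        reads, side = simdata.simulate_reads(
            small_fragments, land, cfg, "A", small_genome)
        n_c = n_tot = 0
        seqs = small_genome.chromosomes
        for (rid, read), row in zip(reads, side.itertuples(index=False)):
            window = seqs[row.chrom][row.read_start:row.read_start + row.read_len]
            target = "C" if row.strand_class == "OT" else "G"
            fwd = read if row.strand_class == "OT" else read.translate(
                str.maketrans("ACGT", "TGCA"))[::-1]
            for off, base in enumerate(window):
                if base == target:
                    n_tot += 1
                    n_c += fwd[off] == target
        assert n_tot > 10_000
        sd = np.sqrt(0.01 * 0.99 / n_tot)
        assert abs(n_c / n_tot - 0.01) < 3 * sd

    def test_deterministic_per_seed(self, small_config, small_genome,
                                    small_fragments, small_landscape):
        r1, s1 = simdata.simulate_reads(
            small_fragments[:30], small_landscape, small_config, "B", small_genome)
        r2, s2 = simdata.simulate_reads(
            small_fragments[:30], small_landscape, small_config, "B", small_genome)
        assert r1 == r2
        pd.testing.assert_frame_equal(s1, s2)

    def test_reads_only_from_retained_fragments(self, small_reads, small_fragments):
        retained = {(f.chrom, f.start, f.end) for f in small_fragments}
        side = small_reads["A"][1]
        origins = set(zip(side["chrom"], side["frag_start"], side["frag_end"]))
        assert origins <= retained


class TestSimulateExpression:
    def test_deterministic(self, small_genome, small_landscape, small_config):
        e1, _ = simdata.simulate_expression(small_genome, small_landscape, small_config)
        e2, _ = simdata.simulate_expression(small_genome, small_landscape, small_config)
        pd.testing.assert_frame_equal(e1, e2)
        assert (e1.to_numpy() >= 0).all()

    def test_coupling_produces_negative_correlation(self, small_genome,
                                                    small_landscape, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config,
            samples=tuple(f"S{i}" for i in range(8)),
            landscape=dataclasses.replace(small_config.landscape,
                                          n_tissue_regions=6,
                                          tissue_promoter_fraction=1.0),
            expression=dataclasses.replace(small_config.expression,
                                           coupling=8.0, noise_sd=0.05),
        )
        land = simdata.sample_landscape(small_genome, cfg)
        expr, meta = simdata.simulate_expression(small_genome, land, cfg)
        shifted_samples = set(land.sample_shifts)
        sites = land.sites
        neg = tot = 0
        for gene in small_genome.genes:
            prom = gene.promoter(1500)
            sel = ((sites["context"] == "CG") & (sites["chrom"] == prom.chrom)
                   & (sites["pos"] >= prom.start) & (sites["pos"] < prom.end))
            if not sel.any():
                continue
            meth = np.array([land.prob_for(s)[sel.to_numpy()].mean()
                             for s in cfg.samples])
            if meth.std() < 0.01:
                continue
            r = np.corrcoef(meth, np.log2(expr.loc[gene.name] + 1))[0, 1]
            tot += 1
            neg += r < 0
        assert tot >= 3
        assert neg == tot  # strong coupling, tiny noise: all negative

    def test_null_coupling_uncorrelated(self, small_genome, small_landscape,
                                        small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config,
            expression=dataclasses.replace(small_config.expression, coupling=0.0),
        )
        expr, meta = simdata.simulate_expression(small_genome, small_landscape, cfg)
        # with zero coupling all genes share the same baseline distribution
        assert expr.shape == (len(small_genome.genes), len(cfg.samples))
        flagged = meta[meta["n_promoter_cg"] == 0]
        assert (meta["n_promoter_cg"] >= 0).all()
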