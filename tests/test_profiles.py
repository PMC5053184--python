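"""Profile analytics: global levels, density windows, metagene/CGI shapes,
compartments, window correlation, chromosome windows, autocorrelation and
sample similarity."""

import numpy as np
import pandas as pd
import pytest

from rrbskit import filtering, profiles
from rrbskit.types import GeneModel, GenomeAnnotation, Region, make_report
from conftest import synthetic_report


class TestGlobalLevel:
    def test_unweighted_mean(self):
        rep = synthetic_report([1, 5], [0.2, 0.8], coverage=10)
        # unweighted even if coverages differ
        rep.loc[0, ["count_meth", "count_unmeth"]] = [20, 80]
        rep["level"] = rep["count_meth"] / (rep["count_meth"] + rep["count_unmeth"])
        assert profiles.global_level(rep, "CG") == pytest.approx(0.5)

    def test_all_zero(self):
        rep = synthetic_report([1, 5], [0.0, 0.0])
        assert profiles.global_level(rep, "CG") == 0.0

    def test_missing_context_raises(self):
        rep = synthetic_report([1], [0.5], context="CHH")
        with pytest.raises(ValueError):
            profiles.global_level(rep, "CG")

    def test_recovers_truth_within_3se(self, small_config, small_landscape,
                                       filtered_reports):
        """Sample estimate matches the truth restricted to covered sites.

        Comparison target includes the incomplete-conversion floor:
        E[level] = p + (1-p)(1-c) at conversion rate c.
        """
        rep = filtered_reports["A"]
        rep = rep[rep["chrom"] != "spike"]
        truth = small_landscape.frame_for("A")
        m = rep[rep["context"] == "CG"].merge(truth, on=["chrom", "pos", "strand"])
        c = small_config.conversion_rate
        expect = m["true_prob"] + (1 - m["true_prob"]) * (1 - c)
        n = (m["count_meth"] + m["count_unmeth"]).to_numpy()
        se = np.sqrt((expect * (1 - expect) / n).sum()) / len(m)
        est = profiles.global_level(rep, "CG")
        # restrict truth mean to the same covered sites
        assert abs(est - expect.mean()) < 3 * se + 1e-9


class TestDensityWindows:
    def test_empty_report_zero_counts(self):
        from rrbskit.types import empty_report

        out = profiles.density_windows(empty_report(), 20000, {"chr1": 50000})
        assert list(out["n_sites"]) == [0, 0, 0]

    def test_all_sites_first_window(self):
        rep = synthetic_report([10, 100, 5000, 19999, 15000], [0.5] * 5)
        out = profiles.density_windows(rep, 20000, {"chr1": 60000})
        assert list(out["n_sites"]) == [5, 0, 0]

    def test_matches_floor_division_oracle(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(100_000, 500, replace=False))
        rep = synthetic_report(pos, rng.random(500))
        out = profiles.density_windows(rep, 7000)
        manual = pd.Series(pos // 7000).value_counts()
        for row in out.itertuples(index=False):
            assert row.n_sites == manual.get(row.window_start // 7000, 0)

    def test_rejects_nonpositive_window(self):
        with pytest.raises(ValueError):
            profiles.density_windows(synthetic_report([1], [0.5]), 0)


def _uniform_report(n=4000, level=0.5, spacing=7, context="CG"):
    return synthetic_report(np.arange(n) * spacing, np.full(n, level),
                            coverage=100, context=context)


class TestMetagene:
    GENES = [GeneModel("g1", "chr1", "+", 8000, 12000),
             GeneModel("g2", "chr1", "-", 16000, 21000)]

    def test_uniform_landscape_flat(self):
        rep = _uniform_report()
        prof = profiles.metagene_profile(rep, self.GENES, 2000, 10, 8)
        seen = prof.mean_level[prof.site_count > 0]
        assert np.allclose(seen, 0.5)

    def test_site_counts_conserve_assignments(self):
        rep = _uniform_report()
        prof = profiles.metagene_profile(rep, self.GENES, 2000, 10, 8)
        manual = 0
        for g in self.GENES:
            pos = rep["pos"].to_numpy()
            manual += ((pos >= g.start - 2000) & (pos < g.end + 2000)).sum()
        assert prof.site_count.sum() == manual

    def test_strand_symmetry(self):
        """A minus-strand gene with mirrored landscape gives the identical
        profile as its plus-strand twin."""
        n = 3000
        rng = np.random.default_rng(8)
        levels = rng.random(300)
        pos_f = np.arange(300) * 10
        rep_f = synthetic_report(pos_f, levels)
        gene_f = [GeneModel("f", "chr1", "+", 1000, 2000)]
        # mirror the chromosome: position p -> L - 1 - p
        L = n * 10
        mirrored = L - 1 - pos_f
        order = np.argsort(mirrored)
        rep_r = synthetic_report(mirrored[order], levels[order])
        gene_r = [GeneModel("r", "chr1", "-", L - 2000, L - 1000)]
        pf = profiles.metagene_profile(rep_f, gene_f, 1000, 5, 4)
        pr = profiles.metagene_profile(rep_r, gene_r, 1000, 5, 4)
        np.testing.assert_allclose(pf.mean_level, pr.mean_level)
        np.testing.assert_array_equal(pf.site_count, pr.site_count)

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(30000, 400, replace=False))
        lv = rng.random(400)
        rep = synthetic_report(pos, lv)
        rep_shift = synthetic_report(pos + 5000, lv)
        g = [GeneModel("g", "chr1", "+", 9000, 14000)]
        g_shift = [GeneModel("g", "chr1", "+", 14000, 19000)]
        p1 = profiles.metagene_profile(rep, g, 2000, 10, 8)
        p2 = profiles.metagene_profile(rep_shift, g_shift, 2000, 10, 8)
        np.testing.assert_allclose(p1.mean_level, p2.mean_level)

    def test_short_gene_flagged(self):
        rep = _uniform_report()
        short = [GeneModel("s", "chr1", "+", 1000, 1020)]
        with pytest.warns(UserWarning, match="shorter than body"):
            profiles.metagene_profile(rep, short, 2000, 10, 40)


class TestCgiProfile:
    def test_island_dip(self):
        pos = np.arange(3000) * 5
        levels = np.where((pos >= 6000) & (pos < 8000), 0.1, 0.8)
        rep = synthetic_report(pos, levels)
        prof = profiles.cgi_profile(rep, [Region("chr1", 6000, 8000)], 2000, 10, 8)
        body = prof.mean_level[10:18]
        flank = np.concatenate([prof.mean_level[:10], prof.mean_level[18:]])
        assert np.nanmax(body) < np.nanmin(flank)


class TestCompartments:
    def _setup(self):
        genome = GenomeAnnotation(
            chromosomes={"chr1": "A" * 40000},
            cg_islands=[Region("chr1", 10000, 12000)],
        )
        pos = np.arange(0, 40000, 20)
        lv = np.full(len(pos), 0.7)
        lv[(pos >= 10000) & (pos < 12000)] = 0.2
        lv[((pos >= 8000) & (pos < 10000)) | ((pos >= 12000) & (pos < 14000))] = 0.5
        return genome, synthetic_report(pos, lv, coverage=1000)

    def test_exact_recovery_at_fixed_levels(self):
        genome, rep = self._setup()
        summ = profiles.compartment_summary(rep, genome)
        part = summ[summ["category"] == "cgi_partition"].set_index("name")
        assert part.loc["CGI", "mean_level"] == pytest.approx(0.2)
        assert part.loc["shore", "mean_level"] == pytest.approx(0.5)
        assert part.loc["non_CGI", "mean_level"] == pytest.approx(0.7)

    def test_repeat_and_island_both_counted(self):
        genome, rep = self._setup()
        from rrbskit.types import RepeatRegion

        genome.repeats = [RepeatRegion(Region("chr1", 11000, 11500), "LINE")]
        summ = profiles.compartment_summary(rep, genome)
        rep_rows = summ[summ["category"] == "repeat"]
        assert len(rep_rows) == 1
        assert rep_rows.iloc[0]["mean_level"] == pytest.approx(0.2)  # inside CGI
        # CGI partition unchanged by the repeat overlap
        part = summ[summ["category"] == "cgi_partition"].set_index("name")
        assert part.loc["CGI", "mean_level"] == pytest.approx(0.2)

    def test_no_repeats_no_rows(self):
        genome, rep = self._setup()
        summ = profiles.compartment_summary(rep, genome)
        assert (summ["category"] != "repeat").all()


class TestWindowCorrelation:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(10)
        n = 3000
        pos = np.arange(n) * 10
        ctx = np.where(np.arange(n) % 2 == 0, "CG", "CHH")
        lv = rng.random(n)
        rep = make_report(pd.DataFrame({
            "chrom": "chr1", "pos": pos, "strand": "+", "context": ctx,
            "count_meth": np.rint(lv * 100).astype(int),
            "count_unmeth": 100 - np.rint(lv * 100).astype(int)}))
        r = profiles.window_correlation_cg_noncg(rep, window_bp=3000)
        df = rep.assign(w=rep["pos"] // 3000, cg=rep["context"] == "CG")
        tab = df.groupby(["w", "cg"])["level"].mean().unstack()
        x, y = tab[True].to_numpy(), tab[False].to_numpy()
        manual = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_error(self):
        n = 300
        pos = np.arange(n) * 10
        ctx = np.where(np.arange(n) % 2 == 0, "CG", "CHH")
        lv = np.where(ctx == "CG", np.linspace(0, 1, n), 0.25)
        rep = make_report(pd.DataFrame({
            "chrom": "chr1", "pos": pos, "strand": "+", "context": ctx,
            "count_meth": np.rint(lv * 100).astype(int),
            "count_unmeth": 100 - np.rint(lv * 100).astype(int)}))
        with pytest.raises(ValueError, match="zero variance"):
            profiles.window_correlation_cg_noncg(rep, window_bp=1000)


class TestCgiChromosomeWindows:
    def test_uniform_flat(self):
        islands = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(10) * 1000,
            "end": np.arange(10) * 1000 + 500, "mean_level": 0.3})
        out = profiles.cgi_chromosome_windows(islands, {"chr1": 10000}, 10)
        assert np.allclose(out["mean_level"].dropna(), 0.3)

    def test_terminal_elevation_detected(self):
        starts = np.arange(20) * 500
        lv = np.where((starts < 1000) | (starts >= 9000), 0.9, 0.3)
        islands = pd.DataFrame({"chrom": "chr1", "start": starts,
                                "end": starts + 100, "mean_level": lv})
        out = profiles.cgi_chromosome_windows(islands, {"chr1": 10000}, 10)
        m = out["mean_level"].to_numpy()
        assert m[0] > np.nanmax(m[1:-1]) and m[-1] > np.nanmax(m[1:-1])

    def test_midpoint_boundary_goes_right(self):
        islands = pd.DataFrame({"chrom": "chr1", "start": [900], "end": [1100],
                                "mean_level": [0.5]})  # midpoint 1000 = boundary
        out = profiles.cgi_chromosome_windows(islands, {"chr1": 10000}, 10)
        assert out.loc[1, "n_islands"] == 1
        assert out.loc[0, "n_islands"] == 0


class TestAutocorrelation:
    def test_dyad_symmetric_opposite_strand_r1(self):
        """CG dyads with equal levels on both strands: opposite-strand r at
        d = 1 is exactly 1."""
        rng = np.random.default_rng(11)
        n = 200
        pos_plus = np.arange(n) * 50
        lv = rng.random(n)
        plus = synthetic_report(pos_plus, lv, coverage=1000, strand="+")
        minus = synthetic_report(pos_plus + 1, lv, coverage=1000, strand="-")
        rep = make_report(pd.concat([plus, minus], ignore_index=True))
        curve = profiles.autocorrelation(rep, ("CG", "CG"), "opposite", 5,
                                         min_pairs=10)
        assert curve.r[0] == pytest.approx(1.0)

    def test_block_structure_decays(self):
        rng = np.random.default_rng(12)
        blocks = rng.random(500)
        pos, lv = [], []
        for b in range(500):
            offs = np.arange(0, 20)
            pos.extend(b * 200 + offs)
            lv.extend(np.clip(blocks[b] + rng.normal(0, 0.01, 20), 0, 1))
        rep = synthetic_report(np.array(pos), np.array(lv), coverage=1000)
        curve = profiles.autocorrelation(rep, ("CG", "CG"), "same", 19,
                                         min_pairs=50)
        assert (curve.r[:10] > 0.9).all()
        far = profiles.autocorrelation(rep, ("CG", "CG"), "same", 200,
                                       min_pairs=50)
        cross = far.r[(far.distances >= 181) & (far.distances <= 199)]
        assert np.nanmean(np.abs(cross)) < 0.2

    def test_iid_levels_uncorrelated(self):
        rng = np.random.default_rng(13)
        rep = synthetic_report(np.arange(5000), rng.random(5000), coverage=1000)
        curve = profiles.autocorrelation(rep, ("CG", "CG"), "same", 20,
                                         min_pairs=1000)
        assert np.nanmax(np.abs(curve.r)) < 0.05

    def test_min_pair_suppression(self):
        rep = synthetic_report([0, 3], [0.2, 0.8], coverage=10)
        curve = profiles.autocorrelation(rep, ("CG", "CG"), "same", 5,
                                         min_pairs=50)
        assert np.isnan(curve.r).all()


class TestSampleSimilarity:
    def _matrix(self, levels, samples):
        levels = np.asarray(levels, dtype=float)
        sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(len(levels)),
                              "strand": "+", "context": "CG"})
        return filtering.MultiSampleMatrix(
            sites=sites, samples=samples, levels=levels,
            coverages=np.full_like(levels, 10.0))

    def test_duplicate_sample_joined_first(self):
        rng = np.random.default_rng(14)
        a = rng.random(50)
        b = rng.random(50)
        m = self._matrix(np.column_stack([a, a, b]), ["a1", "a2", "b"])
        corr, linkage, newick = profiles.sample_similarity(m)
        assert corr.loc["a1", "a2"] == pytest.approx(1.0)
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 1}

    def test_symmetric_unit_diagonal(self, filtered_reports):
        matrix = filtering.build_matrix(filtered_reports)
        corr, _, _ = profiles.sample_similarity(matrix)
        v = corr.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)

    def test_cogeneated_samples_are_siblings(self, filtered_reports,
                                             small_config, small_genome,
                                             small_fragments, small_index):
        """Two samples from one landscape cluster together against a sample
        from a shifted landscape."""
        import dataclasses
        from rrbskit import bsalign, simdata

        shifted = dataclasses.replace(
            small_config, seed=small_config.seed + 1,
            landscape=dataclasses.replace(small_config.landscape,
                                          p_high_background=0.35))
        land2 = simdata.sample_landscape(small_genome, shifted)
        reads, _ = simdata.simulate_reads(small_fragments, land2, shifted, "Z",
                                          small_genome)
        alns, _ = bsalign.map_reads(reads, small_index)
        rep_z = filtering.filter_coverage(
            bsalign.call_cytosines(alns, reads, small_genome), 8)
        m = filtering.build_matrix({"A": filtered_reports["A"],
                                    "B": filtered_reports["B"], "Z": rep_z})
        _, linkage, _ = profiles.sample_similarity(m)
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 1}

    def test_zero_variance_sample_error(self):
        m = self._matrix(np.column_stack([np.full(10, 0.5), np.arange(10) / 10]),
                         ["flat", "var"])
        m.levels[:, 0] = 0.5
        sites = 10
        with pytest.raises(ValueError):
            profiles.sample_similarity(m)
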