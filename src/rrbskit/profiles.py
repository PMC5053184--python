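"""Descriptive methylome analytics.

Global per-context levels, site-density windows, metagene and CG-island
profiles with scaled bodies and fixed flanks, compartment summaries
(island / shore / non-island, repeat classes, per contig), CG vs non-CG
window correlation, chromosome-window island means, adjacent-cytosine
autocorrelation and sample similarity clustering.

Every mean here is the unweighted mean of per-site levels (not a pooled
count ratio), matching the definition of a feature's methylation level as
the average over its annotated cytosines.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import cluster
from .types import AutocorrelationCurve, GenomeAnnotation, MultiSampleMatrix, Profile


def global_level(report: pd.DataFrame, context: str) -> float:
    """Unweighted mean methylation level of all sites in one context."""
    if context == "non-CG":
        sel = report[report["context"] != "CG"]
    else:
        sel = report[report["context"] == context]
    if sel.empty:
        raise ValueError(f"no sites in context {context!r}")
    return float(sel["level"].mean())


def density_windows(report: pd.DataFrame, window_bp: int = 20000,
                    chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Detected-site counts in non-overlapping windows tiled from position 0.

    The last partial window is included.  With ``chrom_lengths`` given, empty
    windows are reported as zero counts over the full chromosome extent.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    chroms = (chrom_lengths.keys() if chrom_lengths
              else report["chrom"].unique())
    grouped = dict(tuple(report.groupby("chrom")))
    for chrom in chroms:
        sub = grouped.get(chrom)
        if chrom_lengths:
            n_win = max(1, -(-chrom_lengths[chrom] // window_bp))
        elif sub is not None and len(sub):
            n_win = int(sub["pos"].max() // window_bp) + 1
        else:
            continue
        counts = np.zeros(n_win, dtype=np.int64)
        if sub is not None and len(sub):
            idx = (sub["pos"].to_numpy() // window_bp).astype(int)
            np.add.at(counts, idx, 1)
        for w in range(n_win):
            rows.append({"chrom": chrom, "window_start": w * window_bp,
                         "n_sites": int(counts[w])})
    return pd.DataFrame(rows, columns=["chrom", "window_start", "n_sites"])


def _by_chrom_positions(report: pd.DataFrame):
    out = {}
    for chrom, sub in report.groupby("chrom"):
        sub = sub.sort_values("pos")
        out[chrom] = (sub["pos"].to_numpy(), sub["level"].to_numpy())
    return out


def _feature_profile(report, features, flank_bp, flank_bins, body_bins):
    """Shared flank/body binning engine.

    ``features``: iterable of (chrom, start, end, strand).  Bodies are scaled
    to ``body_bins`` relative bins (fractional positions handle bodies
    shorter than the bin count); flanks use fixed-width bins; minus-strand
    features are flipped so bins always read 5'->3'.
    """
    if flank_bp % flank_bins:
        raise ValueError("flank_bp must be divisible by flank_bins")
    bin_bp = flank_bp // flank_bins
    n_bins = 2 * flank_bins + body_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    sites = _by_chrom_positions(report)
    short_flagged = False
    for chrom, start, end, strand in features:
        if chrom not in sites:
            continue
        pos, lvl = sites[chrom]
        if end - start < body_bins:
            short_flagged = True
        lo = np.searchsorted(pos, start - flank_bp)
        hi = np.searchsorted(pos, end + flank_bp)
        p = pos[lo:hi]
        v = lvl[lo:hi]
        # assign each site to a 5'->3' bin index
        upstream = p < start
        body = (p >= start) & (p < end)
        downstream = p >= end
        idx = np.empty(len(p), dtype=np.int64)
        idx[upstream] = (p[upstream] - (start - flank_bp)) // bin_bp
        rel = (p[body] - start) / (end - start)
        idx[body] = flank_bins + np.minimum(
            (rel * body_bins).astype(np.int64), body_bins - 1
        )
        idx[downstream] = (
            flank_bins + body_bins + (p[downstream] - end) // bin_bp
        )
        if strand == "-":
            idx = n_bins - 1 - idx
        np.add.at(sums, idx, v)
        np.add.at(counts, idx, 1)
    if short_flagged:
        warnings.warn("feature(s) shorter than body bin count; fractional binning used")
    labels = (
        [f"up_{i:03d}" for i in range(flank_bins)]
        + [f"body_{i:03d}" for i in range(body_bins)]
        + [f"down_{i:03d}" for i in range(flank_bins)]
    )
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Profile(bin_labels=labels, mean_level=means, site_count=counts,
                   n_flank_bins=flank_bins, n_body_bins=body_bins)


def metagene_profile(report: pd.DataFrame, genes, flank_bp: int = 10000,
                     flank_bins: int = 50, body_bins: int = 40) -> Profile:
    """Mean methylation across scaled gene bodies with +/- ``flank_bp`` flanks."""
    if not genes:
        raise ValueError("no genes provided")
    feats = [(g.chrom, g.start, g.end, g.strand) for g in genes]
    return _feature_profile(report, feats, flank_bp, flank_bins, body_bins)


def cgi_profile(report: pd.DataFrame, cg_islands, flank_bp: int = 10000,
                flank_bins: int = 50, body_bins: int = 40) -> Profile:
    """As ``metagene_profile`` with CG islands as unstranded bodies."""
    if not cg_islands:
        raise ValueError("no islands provided")
    feats = [(r.chrom, r.start, r.end, "+") for r in cg_islands]
    return _feature_profile(report, feats, flank_bp, flank_bins, body_bins)


def compartment_summary(report: pd.DataFrame, annotation: GenomeAnnotation,
                        shore_bp: int = 2000) -> pd.DataFrame:
    """Mean level by compartment and context.

    The island partition assigns each site one of CGI > shore > non-CGI (in
    that precedence); repeat-class and per-contig means are computed
    independently of that partition, so a site inside both a repeat and an
    island contributes to both tables.  Empty compartments are absent, not
    zero.  The spike-in contig is excluded from the island partition.
    """
    rows = []
    chrom_arr = report["chrom"].to_numpy()
    pos_arr = report["pos"].to_numpy()
    compartment = np.full(len(report), "non_CGI", dtype=object)
    shore_mask = np.zeros(len(report), dtype=bool)
    for r in annotation.cg_islands:
        on = chrom_arr == r.chrom
        shore_mask |= on & (
            ((pos_arr >= r.start - shore_bp) & (pos_arr < r.start))
            | ((pos_arr >= r.end) & (pos_arr < r.end + shore_bp))
        )
    compartment[shore_mask] = "shore"
    for r in annotation.cg_islands:
        inside = (chrom_arr == r.chrom) & (pos_arr >= r.start) & (pos_arr < r.end)
        compartment[inside] = "CGI"
    not_spike = chrom_arr != (annotation.spike_in or "")
    part = report.loc[not_spike].assign(compartment=compartment[not_spike])
    for (comp, ctx), sub in part.groupby(["compartment", "context"]):
        rows.append({"category": "cgi_partition", "name": comp, "context": ctx,
                     "mean_level": sub["level"].mean(), "n_sites": len(sub)})

    for fam in sorted({r.family for r in annotation.repeats}):
        mask = np.zeros(len(report), dtype=bool)
        for r in annotation.repeats:
            if r.family != fam:
                continue
            mask |= ((chrom_arr == r.region.chrom)
                     & (pos_arr >= r.region.start) & (pos_arr < r.region.end))
        sub = report.loc[mask]
        for ctx, ss in sub.groupby("context"):
            rows.append({"category": "repeat", "name": fam, "context": ctx,
                         "mean_level": ss["level"].mean(), "n_sites": len(ss)})

    for chrom, sub in report.groupby("chrom"):
        for ctx, ss in sub.groupby("context"):
            rows.append({"category": "contig", "name": chrom, "context": ctx,
                         "mean_level": ss["level"].mean(), "n_sites": len(ss)})
    return pd.DataFrame(rows, columns=["category", "name", "context",
                                       "mean_level", "n_sites"])


def window_correlation_cg_noncg(report: pd.DataFrame,
                                window_bp: int = 1_000_000) -> float:
    """Pearson r between per-window mean CG and mean non-CG levels.

    Windows lacking either context are dropped; fewer than 3 usable windows
    or zero variance in either vector raises.
    """
    df = report.assign(window=report["pos"] // window_bp,
                       is_cg=report["context"] == "CG")
    means = (
        df.groupby(["chrom", "window", "is_cg"])["level"].mean().unstack("is_cg")
    )
    if True not in means.columns or False not in means.columns:
        raise ValueError("need both CG and non-CG sites")
    means = means.dropna()
    if len(means) < 3:
        raise ValueError("fewer than 3 windows with both contexts")
    cg = means[True].to_numpy()
    noncg = means[False].to_numpy()
    if cg.std() == 0 or noncg.std() == 0:
        raise ValueError("zero variance in window means; correlation undefined")
    return float(np.corrcoef(cg, noncg)[0, 1])


def cgi_chromosome_windows(island_means: pd.DataFrame, chrom_lengths: dict,
                           n_windows: int = 10) -> pd.DataFrame:
    """Mean island methylation in equal-length chromosome windows.

    ``island_means`` needs columns chrom/start/end/mean_level (one row per
    stable island).  Each chromosome is split into ``n_windows`` equal
    windows; an island is assigned by midpoint (a midpoint exactly on a
    boundary goes to the right window); window means are aggregated across
    chromosomes.  Windows with no islands carry NaN.
    """
    sums = np.zeros(n_windows)
    counts = np.zeros(n_windows, dtype=np.int64)
    for row in island_means.itertuples(index=False):
        length = chrom_lengths[row.chrom]
        size = length / n_windows
        mid = (row.start + row.end) // 2
        w = min(int(mid // size), n_windows - 1)
        sums[w] += row.mean_level
        counts[w] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"window": np.arange(n_windows), "mean_level": mean,
                         "n_islands": counts})


def autocorrelation(report: pd.DataFrame, context_pair=("CG", "CG"),
                    strand_mode: str = "same", max_distance_bp: int = 50,
                    min_pairs: int = 50) -> AutocorrelationCurve:
    """Pearson correlation of levels at site pairs separated by exact lags.

    For each distance d in 1..max, all pairs of sites of the two contexts
    whose reference positions differ by exactly d are collected, restricted
    to same-strand or opposite-strand pairs; distances with fewer than
    ``min_pairs`` pairs are suppressed (NaN r).
    """
    if strand_mode not in ("same", "opposite"):
        raise ValueError("strand_mode must be 'same' or 'opposite'")
    ctx_a, ctx_b = context_pair
    series: dict = {}
    for (chrom, strand, ctx), sub in report.groupby(["chrom", "strand", "context"]):
        series[(chrom, strand, ctx)] = pd.Series(
            sub["level"].to_numpy(), index=sub["pos"].to_numpy()
        ).sort_index()

    chroms = sorted({k[0] for k in series})
    distances = np.arange(1, max_distance_bp + 1)
    r_out = np.full(len(distances), np.nan)
    n_out = np.zeros(len(distances), dtype=np.int64)
    for di, d in enumerate(distances):
        xs, ys = [], []
        for chrom in chroms:
            if strand_mode == "same":
                combos = [(("+", ctx_a), ("+", ctx_b)), (("-", ctx_a), ("-", ctx_b))]
            else:
                combos = [(("+", ctx_a), ("-", ctx_b)), (("-", ctx_a), ("+", ctx_b))]
            if ctx_a != ctx_b:
                # unordered cross-context pairs: also sweep with B 5' of A
                combos = combos + [((s2, ctx_b), (s1, ctx_a)) for (s1, _), (s2, _) in combos]
            for (s1, c1), (s2, c2) in combos:
                a = series.get((chrom, s1, c1))
                b = series.get((chrom, s2, c2))
                if a is None or b is None:
                    continue
                pos_a = a.index.to_numpy()
                shifted = pos_a + d
                hit = np.isin(shifted, b.index.to_numpy())
                if not hit.any():
                    continue
                xs.append(a.to_numpy()[hit])
                ys.append(b.loc[shifted[hit]].to_numpy())
        if not xs:
            continue
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        n_out[di] = len(x)
        if len(x) >= min_pairs and x.std() > 0 and y.std() > 0:
            r_out[di] = np.corrcoef(x, y)[0, 1]
    return AutocorrelationCurve(
        context_a=ctx_a, context_b=ctx_b, strand_mode=strand_mode,
        distances=distances, r=r_out, n_pairs=n_out,
    )


def sample_similarity(matrix: MultiSampleMatrix):
    """Pairwise Pearson correlation and average-linkage dendrogram of samples.

    Uses common shared sites only.  Returns (correlation DataFrame, linkage,
    newick string).
    """
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples")
    shared = matrix.levels[matrix.shared_mask()]
    if shared.shape[0] < 3:
        raise ValueError("need >= 3 common shared sites")
    r = cluster.correlation_matrix(shared)
    linkage = cluster.linkage_from_levels(shared)
    corr = pd.DataFrame(r, index=matrix.samples, columns=matrix.samples)
    return corr, linkage, cluster.to_newick(linkage, matrix.samples)
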