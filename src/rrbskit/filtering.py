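"""Coverage filtering, stable-site selection and the cluster-stability
procedure for choosing the minimum coverage threshold.

The threshold scan reproduces the study's selection logic: filter every
sample's report at each candidate coverage threshold, restrict to sites
shared by all samples, keep sites whose across-sample standard deviation is
below 0.2, cluster the samples (average linkage on 1 - Pearson) and report
the smallest threshold from which the tree topology no longer changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster
from .types import MultiSampleMatrix


def filter_coverage(report: pd.DataFrame, min_cov: int = 8) -> pd.DataFrame:
    """Keep cytosines covered by at least ``min_cov`` reads, order preserved."""
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    keep = (report["count_meth"] + report["count_unmeth"]) >= min_cov
    return report.loc[keep].reset_index(drop=True)


def build_matrix(reports: dict) -> MultiSampleMatrix:
    """Stack per-sample reports into a site x sample matrix (NaN = missing)."""
    samples = list(reports)
    pieces = []
    for s in samples:
        df = reports[s][["chrom", "pos", "strand", "context",
                         "count_meth", "count_unmeth", "level"]].copy()
        df["sample"] = s
        df["coverage"] = df["count_meth"] + df["count_unmeth"]
        pieces.append(df)
    stacked = pd.concat(pieces, ignore_index=True)
    lv = stacked.pivot_table(index=["chrom", "pos", "strand", "context"],
                             columns="sample", values="level", aggfunc="first")
    cov = stacked.pivot_table(index=["chrom", "pos", "strand", "context"],
                              columns="sample", values="coverage", aggfunc="first")
    lv = lv.sort_index()
    cov = cov.reindex(lv.index)
    sites = lv.index.to_frame(index=False)
    return MultiSampleMatrix(
        sites=sites,
        samples=samples,
        levels=lv[samples].to_numpy(dtype=float),
        coverages=cov[samples].to_numpy(dtype=float),
    )


def select_stable_sites(matrix: MultiSampleMatrix, sd_threshold: float = 0.2) -> MultiSampleMatrix:
    """Common-shared sites whose across-sample level SD (ddof=1) is < threshold."""
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples for stable-site selection")
    if matrix.n_sites == 0:
        warnings.warn("empty matrix; stable-site selection returns empty result")
        return matrix
    shared = matrix.shared_mask()
    sd = np.full(matrix.n_sites, np.inf)
    sd[shared] = matrix.levels[shared].std(axis=1, ddof=1)
    return matrix.subset(shared & (sd < sd_threshold))


def concordance_rate(report_a: pd.DataFrame, report_b: pd.DataFrame,
                     tolerance: float = 0.2) -> float:
    """Fraction of shared sites whose levels differ by less than ``tolerance``.

    This is the validation "success rate" used when comparing RRBS levels
    against an independent assay of the same cytosines.
    """
    merged = report_a.merge(
        report_b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("no shared sites between the two reports")
    return float((np.abs(merged["level_a"] - merged["level_b"]) < tolerance).mean())


@dataclass
class ThresholdScanResult:
    thresholds: list
    usable: dict  # threshold -> bool
    linkages: dict  # threshold -> linkage matrix (usable thresholds only)
    n_sites: dict  # threshold -> stable common site count
    stability: dict = field(default_factory=dict)  # t -> stability vs previous usable t
    recommended: int | None = None
    samples: list = field(default_factory=list)

    def newick(self, threshold: int) -> str:
        return cluster.to_newick(self.linkages[threshold], self.samples)


def threshold_stability_scan(reports: dict, thresholds=range(3, 11),
                             sd_threshold: float = 0.2,
                             min_sites: int = 3) -> ThresholdScanResult:
    """Scan coverage thresholds for cluster stability.

    For each threshold: coverage-filter, restrict to common shared sites,
    apply the stable-site rule, cluster the samples.  Stability between
    consecutive usable thresholds is 1.0 for identical tree topologies
    (Robinson-Foulds distance 0), else the cophenetic correlation.  The
    recommended threshold is the smallest one from which every later
    topology is identical.
    """
    samples = list(reports)
    if len(samples) < 3:
        raise ValueError("threshold scan needs >= 3 samples")
    thresholds = list(thresholds)
    result = ThresholdScanResult(
        thresholds=thresholds, usable={}, linkages={}, n_sites={}, samples=samples
    )
    for t in thresholds:
        filtered = {s: filter_coverage(reports[s], t) for s in samples}
        matrix = select_stable_sites(build_matrix(filtered), sd_threshold)
        result.n_sites[t] = matrix.n_sites
        if matrix.n_sites < min_sites:
            result.usable[t] = False
            continue
        try:
            linkage = cluster.linkage_from_levels(matrix.levels)
        except ValueError:
            result.usable[t] = False
            continue
        result.usable[t] = True
        result.linkages[t] = linkage

    usable_ts = [t for t in thresholds if result.usable.get(t)]
    for prev, cur in zip(usable_ts, usable_ts[1:]):
        if cluster.same_topology(result.linkages[prev], result.linkages[cur], samples):
            result.stability[cur] = 1.0
        else:
            result.stability[cur] = cluster.cophenetic_correlation(
                result.linkages[prev], result.linkages[cur]
            )

    for i, t in enumerate(usable_ts):
        later = usable_ts[i:]
        if all(
            cluster.same_topology(result.linkages[t], result.linkages[u], samples)
            for u in later
        ):
            result.recommended = t
            break
    return result


def select_stable_islands(island_levels: pd.DataFrame, sd_threshold: float = 0.2) -> pd.DataFrame:
    """Stable CG islands: across-sample SD of island mean level < threshold.

    ``island_levels`` is indexed by island with one column per sample; rows
    with missing samples are dropped before the SD rule.
    """
    shared = island_levels.dropna()
    sd = shared.std(axis=1, ddof=1)
    return shared.loc[sd < sd_threshold]
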