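"""Differential methylation calling at cytosines and CG islands.

With one library per tissue the per-site test is the two-sided Fisher exact
test on the 2x2 table of (methylated, unmethylated) read counts, implemented
here by direct hypergeometric enumeration.  q-values are Benjamini-Hochberg
within each sample-pair test family; a call requires both q below the cutoff
and an absolute methylation-level difference of at least ``diff_cutoff``
(default 25 % / q < 0.01).  A cytosine (island) is a DMC (DMI) if it is
significant in at least one sample pair; tissue-specific calls additionally
require consistent, exclusive significance against every other sample.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import DMRecord, IslandMethylation

_REL_TIE = 1e-12
_lgamma = math.lgamma


def _log_comb(n: int, k: int) -> float:
    return _lgamma(n + 1) - _lgamma(k + 1) - _lgamma(n - k + 1)


def fisher_dm_test(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int,
                   _cache: dict = {}) -> float:
    """Two-sided Fisher exact p for the 2x2 table (meth_a, unmeth_a / meth_b, unmeth_b).

    Sums hypergeometric probabilities, at fixed margins, of every table at
    most as probable as the observed one (ties within 1e-12 relative
    included).  A zero row or column margin returns p = 1.
    """
    if min(meth_a, unmeth_a, meth_b, unmeth_b) < 0:
        raise ValueError("counts must be non-negative")
    key = (meth_a, unmeth_a, meth_b, unmeth_b)
    hit = _cache.get(key)
    if hit is not None:
        return hit
    row_a = meth_a + unmeth_a
    row_b = meth_b + unmeth_b
    col_m = meth_a + meth_b
    n = row_a + row_b
    if row_a == 0 or row_b == 0 or col_m == 0 or col_m == n:
        _cache[key] = 1.0
        return 1.0
    denom = _log_comb(n, col_m)
    k_lo = max(0, col_m - row_b)
    k_hi = min(row_a, col_m)
    logp_obs = _log_comb(row_a, meth_a) + _log_comb(row_b, col_m - meth_a) - denom
    total = 0.0
    cutoff = logp_obs + math.log1p(_REL_TIE)
    for k in range(k_lo, k_hi + 1):
        logp = _log_comb(row_a, k) + _log_comb(row_b, col_m - k) - denom
        if logp <= cutoff:
            total += math.exp(logp)
    # if no table is excluded the sum is 1 up to float error; any genuinely
    # excluded table contributes at least the modal probability (>> 1e-9)
    p = 1.0 if total >= 1.0 - 1e-9 else total
    _cache[key] = p
    return p


def _fisher_vector(ma, ua, mb, ub) -> np.ndarray:
    return np.array([
        fisher_dm_test(int(a), int(b), int(c), int(d))
        for a, b, c, d in zip(ma, ua, mb, ub)
    ])


def call_dmcs(reports: dict, diff_cutoff: float = 0.25, q_cutoff: float = 0.01,
              min_cov: int = 8) -> list:
    """Differentially methylated cytosines over every unordered sample pair.

    For each pair, sites covered >= ``min_cov`` in both samples are tested;
    BH correction is applied within the pair's test family.  All contexts
    (CG and non-CG) are eligible.  Returns the significant DMRecords; a site
    is a DMC if it appears in at least one record.
    """
    from .filtering import filter_coverage

    samples = list(reports)
    filtered = {s: filter_coverage(reports[s], min_cov) for s in samples}
    records: list = []
    for a, b in combinations(samples, 2):
        merged = filtered[a].merge(
            filtered[b], on=["chrom", "pos", "strand", "context"],
            suffixes=("_a", "_b"),
        )
        if merged.empty:
            continue
        p = _fisher_vector(
            merged["count_meth_a"], merged["count_unmeth_a"],
            merged["count_meth_b"], merged["count_unmeth_b"],
        )
        q = multipletests(p, method="fdr_bh")[1]
        diff = (merged["level_a"] - merged["level_b"]).to_numpy()
        sig = (q < q_cutoff) & (np.abs(diff) >= diff_cutoff)
        for i in np.flatnonzero(sig):
            row = merged.iloc[i]
            records.append(DMRecord(
                kind="cytosine", chrom=row["chrom"], start=int(row["pos"]),
                end=int(row["pos"]) + 1, strand=row["strand"], context=row["context"],
                sample_a=a, sample_b=b,
                level_a=float(row["level_a"]), level_b=float(row["level_b"]),
                p_value=float(p[i]), q_value=float(q[i]), significant=True,
            ))
    return records


def summarize_islands(report: pd.DataFrame, cg_islands, sample: str = "",
                      min_cg: int = 5) -> list:
    """Per-island methylation from a coverage-filtered report.

    Islands with at least ``min_cg`` detected CG sites (both strands counted
    separately) are summarised by the unweighted mean of their sites' levels
    plus pooled counts.
    """
    cg = report[report["context"] == "CG"]
    chrom_arr = cg["chrom"].to_numpy()
    pos_arr = cg["pos"].to_numpy()
    out = []
    for r in cg_islands:
        mask = (chrom_arr == r.chrom) & (pos_arr >= r.start) & (pos_arr < r.end)
        n = int(mask.sum())
        if n < min_cg:
            continue
        sub = cg.loc[mask]
        out.append(IslandMethylation(
            region=r, sample=sample, n_detected_cg=n,
            mean_level=float(sub["level"].mean()),
            count_meth=int(sub["count_meth"].sum()),
            count_unmeth=int(sub["count_unmeth"].sum()),
        ))
    return out


def call_dmis(island_summaries: dict, diff_cutoff: float = 0.25,
              q_cutoff: float = 0.01) -> list:
    """Differentially methylated islands over every unordered sample pair.

    ``island_summaries`` maps sample -> list[IslandMethylation].  The p-value
    comes from the Fisher test on pooled island counts; the difference cutoff
    applies to the mean-of-site-levels difference.
    """
    samples = list(island_summaries)
    by_sample = {
        s: {(im.region.chrom, im.region.start, im.region.end): im
            for im in island_summaries[s]}
        for s in samples
    }
    records = []
    for a, b in combinations(samples, 2):
        shared = sorted(set(by_sample[a]) & set(by_sample[b]))
        if not shared:
            continue
        ia = [by_sample[a][k] for k in shared]
        ib = [by_sample[b][k] for k in shared]
        p = np.array([
            fisher_dm_test(x.count_meth, x.count_unmeth, y.count_meth, y.count_unmeth)
            for x, y in zip(ia, ib)
        ])
        q = multipletests(p, method="fdr_bh")[1]
        for i, key in enumerate(shared):
            diff = ia[i].mean_level - ib[i].mean_level
            if q[i] < q_cutoff and abs(diff) >= diff_cutoff:
                records.append(DMRecord(
                    kind="island", chrom=key[0], start=key[1], end=key[2],
                    strand=".", context=".", sample_a=a, sample_b=b,
                    level_a=ia[i].mean_level, level_b=ib[i].mean_level,
                    p_value=float(p[i]), q_value=float(q[i]), significant=True,
                ))
    return records


def dm_feature_set(records) -> set:
    """Distinct differential features (significant in >= 1 pair)."""
    return {(r.kind, r.chrom, r.start, r.end, r.strand, r.context) for r in records}


def tissue_specific(records, samples) -> dict:
    """One-vs-all calls: feature -> the sample it is specific to.

    A feature is specific to sample s iff it is significant in all n-1 pairs
    involving s, with a consistent sign of (level_s - level_other), and in no
    pair not involving s.
    """
    samples = list(samples)
    n = len(samples)
    by_feature: dict = {}
    for r in records:
        key = (r.kind, r.chrom, r.start, r.end, r.strand, r.context)
        by_feature.setdefault(key, []).append(r)
    out = {}
    for key, recs in by_feature.items():
        for s in samples:
            involving = [r for r in recs if s in (r.sample_a, r.sample_b)]
            others = [r for r in recs if s not in (r.sample_a, r.sample_b)]
            if others or len(involving) != n - 1:
                continue
            partners = {r.sample_b if r.sample_a == s else r.sample_a
                        for r in involving}
            if len(partners) != n - 1:
                continue
            signs = {
                np.sign((r.level_a - r.level_b) if r.sample_a == s
                        else (r.level_b - r.level_a))
                for r in involving
            }
            if len(signs) == 1 and 0 not in signs:
                out[key] = s
                break
    return out


def records_to_frame(records) -> pd.DataFrame:
    rows = [{
        "kind": r.kind, "chrom": r.chrom, "start": r.start, "end": r.end,
        "strand": r.strand, "context": r.context,
        "sample_a": r.sample_a, "sample_b": r.sample_b,
        "level_a": r.level_a, "level_b": r.level_b,
        "difference": r.difference, "p_value": r.p_value, "q_value": r.q_value,
    } for r in records]
    cols = ["kind", "chrom", "start", "end", "strand", "context", "sample_a",
            "sample_b", "level_a", "level_b", "difference", "p_value", "q_value"]
    return pd.DataFrame(rows, columns=cols)
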