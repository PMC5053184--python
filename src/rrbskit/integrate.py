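"""Methylation-expression integration.

Differential features are assigned to genes (1500 bp promoter upstream of
the TSS, or gene body), their methylation levels are correlated with
log2(expression + 1) across samples (Pearson, two-sided t-test p), and BH
FDR is applied jointly over all tested (feature, gene) pairs at q < 0.05.
Promoter methylation is expected to anticorrelate with expression; gene-body
methylation shows no preferred sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CorrelationResult


def assign_region(feature, genes, promoter_bp: int = 1500) -> list:
    """Assign a feature to (gene, region class) pairs.

    ``feature`` is ``(kind, chrom, start, end)`` with kind 'cytosine'
    (matched by position) or 'island' (matched by >= 1 bp overlap).  The
    promoter is the ``promoter_bp`` window upstream of the TSS on the gene's
    strand; the gene body spans TSS to gene end.  A feature may map to
    several genes; within one gene, promoter takes precedence over body.
    """
    kind, chrom, start, end = feature[:4]
    out = []
    for g in genes:
        if g.chrom != chrom:
            continue
        prom = g.promoter(promoter_bp)
        body = (g.start, g.end)
        if kind == "cytosine":
            in_prom = prom.start <= start < prom.end
            in_body = body[0] <= start < body[1]
        else:
            in_prom = start < prom.end and prom.start < end
            in_body = start < body[1] and body[0] < end
        if in_prom:
            out.append((g.name, "promoter"))
        elif in_body:
            out.append((g.name, "gene_body"))
    return out


def correlate_expression(feature_levels: pd.DataFrame, assignments,
                         expression: pd.DataFrame, q_cutoff: float = 0.05,
                         min_samples: int = 3, log_transform: bool = True):
    """Pearson correlation of feature methylation with gene expression.

    ``feature_levels``: one row per feature id, one column per sample;
    ``assignments``: iterable of (feature_id, gene, region_class);
    ``expression``: gene-indexed table with sample columns.  Expression is
    log2(x + 1)-transformed before correlating.  Pairs with fewer than
    ``min_samples`` complete samples or zero variance in either vector are
    skipped.  Returns a list of CorrelationResult with joint-BH q-values.
    """
    expr = np.log2(expression + 1.0) if log_transform else expression
    tested = []
    for feature_id, gene, region_class in assignments:
        if feature_id not in feature_levels.index or gene not in expr.index:
            continue
        meth = feature_levels.loc[feature_id]
        ex = expr.loc[gene]
        shared = [s for s in feature_levels.columns
                  if s in expr.columns
                  and np.isfinite(meth[s]) and np.isfinite(ex[s])]
        if len(shared) < min_samples:
            continue
        x = meth[shared].to_numpy(dtype=float)
        y = ex[shared].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"zero-variance pair skipped: {feature_id} / {gene}")
            continue
        r, p = stats.pearsonr(x, y)
        tested.append((feature_id, gene, region_class, len(shared), float(r), float(p)))
    if not tested:
        return []
    q = multipletests([t[5] for t in tested], method="fdr_bh")[1]
    return [
        CorrelationResult(
            feature_id=f, gene=g, region_class=rc, n=n, r=r, p_value=p,
            q_value=float(qv), significant=bool(qv < q_cutoff),
        )
        for (f, g, rc, n, r, p), qv in zip(tested, q)
    ]


def sign_by_region(results) -> pd.DataFrame:
    """Region class x correlation sign counts among significant results."""
    sig = [r for r in results if r.significant]
    if not sig:
        warnings.warn("no significant correlations; sign table is empty")
    rows = []
    for region in ("promoter", "gene_body"):
        neg = sum(1 for r in sig if r.region_class == region and r.r < 0)
        pos = sum(1 for r in sig if r.region_class == region and r.r > 0)
        total = neg + pos
        rows.append({
            "region_class": region, "negative": neg, "positive": pos,
            "fraction_negative": neg / total if total else np.nan,
        })
    return pd.DataFrame(rows)


def results_to_frame(results) -> pd.DataFrame:
    cols = ["feature_id", "gene", "region_class", "n", "r", "p_value",
            "q_value", "significant"]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols
    )
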