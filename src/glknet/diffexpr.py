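"""Differential expression between two accession groups.

Per-gene Welch two-sample t-tests on normalized log2 expression with
Benjamini-Hochberg adjustment across all tested genes. The fold change is the
difference of group means on the log2 scale, and significance is the strict
conjunction q < fdr_threshold AND |log2FC| > lfc_threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_adjust, welch_ttest
from .clustering import AccessionGrouping
from .errors import GlknetError

__all__ = ["differential_expression", "bh_adjust"]


def differential_expression(expr, groups: AccessionGrouping, group_a, group_b,
                            fdr_threshold: float = 0.01,
                            lfc_threshold: float = 2.0) -> pd.DataFrame:
    """Contrast group_a vs group_b per gene.

    Returns a DataFrame indexed by gene with columns mean_a, mean_b, log2fc
    (mean_a - mean_b), t_stat, p_value, q_value, significant.
    """
    if expr.scale != "normalized":
        raise GlknetError("differential expression expects normalized (not relative) expression")
    acc_a = [a for a in expr.accession_ids if groups.labels.get(a) == group_a]
    acc_b = [a for a in expr.accession_ids if groups.labels.get(a) == group_b]
    if len(acc_a) < 2 or len(acc_b) < 2:
        raise GlknetError(
            f"both groups need >=2 accessions (got {len(acc_a)} and {len(acc_b)})"
        )
    a = expr.values[acc_a].to_numpy(dtype=float)
    b = expr.values[acc_b].to_numpy(dtype=float)
    t, p, _, ma, mb = welch_ttest(a, b, axis=1)
    q = bh_adjust(p)
    lfc = ma - mb
    res = pd.DataFrame(
        {
            "mean_a": ma,
            "mean_b": mb,
            "log2fc": lfc,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "significant": (q < fdr_threshold) & (np.abs(lfc) > lfc_threshold),
        },
        index=expr.values.index,
    )
    res.index.name = "gene_id"
    return res
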