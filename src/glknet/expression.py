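"""Raw-count processing: library filtering, per-accession aggregation,
normalization, and relative (row-centered) expression.

Normalization follows the median-of-ratios size-factor scheme with a shifted
log2 transform: size factors are estimated from genes with no zero counts
(their per-gene geometric mean across accessions is the reference), and the
normalized value is log2(count / size_factor + 1). This is a deliberate
lightweight stand-in for a full variance-stabilizing transform: downstream
stages (clustering, group contrasts, partial correlations) operate on the
log scale and do not depend on the exact form of the variance stabilization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GlknetError
from .targets import GenomeAnnotation

log = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Integer counts, genes x libraries, with a library -> accession map."""

    values: pd.DataFrame  # index: gene ids, columns: library ids
    library_to_accession: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise GlknetError("counts must be non-negative")
        missing = [c for c in self.values.columns if c not in self.library_to_accession]
        if missing:
            raise GlknetError(f"libraries without accession mapping: {missing[:5]}")

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def library_ids(self):
        return list(self.values.columns)

    @property
    def accession_ids(self):
        seen = dict.fromkeys(self.library_to_accession[c] for c in self.values.columns)
        return list(seen)


@dataclass
class ExpressionMatrix:
    """Real-valued expression, genes x accessions; ``scale`` is 'normalized' or 'relative'."""

    values: pd.DataFrame  # index: gene ids, columns: accession ids
    scale: str = "normalized"

    def __post_init__(self):
        if self.scale not in ("normalized", "relative"):
            raise GlknetError(f"unknown expression scale {self.scale!r}")
        if self.scale == "relative":
            row_means = self.values.mean(axis=1).abs()
            if (row_means > 1e-9).any():
                raise GlknetError("relative expression rows must have mean 0")

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def accession_ids(self):
        return list(self.values.columns)


def filter_libraries(counts: CountMatrix, min_reads: int = 1_000_000) -> CountMatrix:
    """Drop libraries with total counts strictly below ``min_reads``."""
    if min_reads < 0:
        raise GlknetError("min_reads must be >= 0")
    totals = counts.values.sum(axis=0)
    keep = totals[totals >= min_reads].index
    dropped = [c for c in counts.values.columns if c not in set(keep)]
    if len(keep) == 0:
        raise GlknetError("all libraries fall below the read-count threshold")
    if dropped:
        log.info("filter_libraries: removed %d/%d libraries below %g reads",
                 len(dropped), counts.values.shape[1], min_reads)
    sub = counts.values[list(keep)]
    mapping = {c: counts.library_to_accession[c] for c in sub.columns}
    return CountMatrix(sub, mapping)


def filter_genes(counts: CountMatrix, annotation: GenomeAnnotation) -> CountMatrix:
    """Keep only nuclear protein-coding genes, in the original row order."""
    unknown = [g for g in counts.values.index if g not in annotation]
    if unknown:
        raise GlknetError(f"genes absent from annotation: {unknown[:10]}")
    keep = [g for g in counts.values.index if annotation[g].is_nuclear_coding]
    return CountMatrix(counts.values.loc[keep], dict(counts.library_to_accession))


def merge_by_accession(counts: CountMatrix) -> CountMatrix:
    """Sum library columns per accession (integer addition)."""
    acc_of = counts.library_to_accession
    merged = counts.values.T.groupby(lambda lib: acc_of[lib], sort=False).sum().T
    mapping = {a: a for a in merged.columns}
    return CountMatrix(merged, mapping)


def normalize(counts: CountMatrix, pseudo_reference: bool = False) -> ExpressionMatrix:
    """Median-of-ratios size factors followed by log2(count/sf + 1).

    Size-factor reference genes are those with all-positive counts; with
    ``pseudo_reference`` the geometric mean ignores zeros instead (fallback
    for sparse matrices).
    """
    mat = counts.values.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise GlknetError("normalize needs >=2 accessions")
    all_positive = (mat > 0).all(axis=1)
    if all_positive.any():
        ref_rows = mat[all_positive]
        geomean = np.exp(np.log(ref_rows).mean(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = ref_rows / geomean[:, None]
    elif pseudo_reference:
        ref = np.where(mat > 0, mat, np.nan)
        with np.errstate(invalid="ignore"):
            geomean = np.exp(np.nanmean(np.log(ref), axis=1))
        use = np.isfinite(geomean) & (geomean > 0)
        if not use.any():
            raise GlknetError("pseudo-reference failed: no expressed gene")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = mat[use] / geomean[use][:, None]
    else:
        raise GlknetError(
            "no gene has all-positive counts; re-run with pseudo_reference=True"
        )
    size_factors = np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)
    if np.any(size_factors <= 0):
        raise GlknetError("non-positive size factor estimated")
    norm = np.log2(mat / size_factors[None, :] + 1.0)
    df = pd.DataFrame(norm, index=counts.values.index,
                      columns=[counts.library_to_accession[c] for c in counts.values.columns])
    return ExpressionMatrix(df, scale="normalized")


def relative_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene on its mean across accessions."""
    if expr.scale == "relative":
        raise GlknetError("expression is already relative (double-centering guard)")
    centered = expr.values.sub(expr.values.mean(axis=1), axis=0)
    return ExpressionMatrix(centered, scale="relative")
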