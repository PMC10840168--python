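"""Candidate direct-target definition from ranked transcription-factor binding sites.

A gene is called a candidate direct target of the focal transcription factor
when one of the top-ranked binding sites (ranked by site FDR) overlaps a
window extending a fixed distance beyond both gene ends ("1 kb upstream,
inside, and 1 kb downstream"). Only nuclear protein-coding genes are
eligible. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import GlknetError


@dataclass(frozen=True)
class Gene:
    """One annotated gene. ``cds_segments`` are (start, end, phase) tuples."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    compartment: str = "nuclear"  # nuclear | organellar
    cds_segments: tuple = ()

    def __post_init__(self):
        if not self.start < self.end:
            raise GlknetError(f"gene {self.gene_id}: start must be < end")
        for s, e, _ in self.cds_segments:
            if not (self.start <= s < e <= self.end):
                raise GlknetError(f"gene {self.gene_id}: CDS segment outside gene interval")

    @property
    def is_nuclear_coding(self) -> bool:
        return self.biotype == "protein_coding" and self.compartment == "nuclear"


@dataclass
class GenomeAnnotation:
    """Gene models plus (optionally) the chromosome sequences they live on."""

    genes: list
    sequences: dict = field(default_factory=dict)

    def __post_init__(self):
        self._by_id = {g.gene_id: g for g in self.genes}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def chroms(self):
        return {g.chrom for g in self.genes}

    def nuclear_coding_ids(self):
        return [g.gene_id for g in self.genes if g.is_nuclear_coding]


@dataclass(frozen=True)
class BindingSite:
    """A scored binding event; 0-based half-open, ``fdr`` in [0, 1]."""

    chrom: str
    start: int
    end: int
    score: float
    fdr: float
    name: str = "."

    def __post_init__(self):
        if not self.start < self.end:
            raise GlknetError(f"binding site {self.chrom}:{self.start}: start must be < end")
        if not 0.0 <= self.fdr <= 1.0:
            raise GlknetError(f"binding site {self.chrom}:{self.start}: fdr outside [0, 1]")


def select_top_sites(sites, n: int, max_fdr: float | None = None):
    """Return the ``n`` most significant sites.

    Sites are sorted by ascending FDR, ties broken by descending score and
    then by (chrom, start). When ``max_fdr`` is given, sites with
    ``fdr >= max_fdr`` are removed first (strict bound, matching the
    "FDR < threshold" convention).
    """
    if not sites:
        raise GlknetError("select_top_sites: empty site list")
    if n < 1:
        raise GlknetError("select_top_sites: n must be >= 1")
    pool = list(sites)
    if max_fdr is not None:
        pool = [s for s in pool if s.fdr < max_fdr]
    pool.sort(key=lambda s: (s.fdr, -s.score, s.chrom, s.start))
    return pool[:n]


def assign_sites_to_genes(sites, annotation: GenomeAnnotation,
                          upstream: int = 1000, downstream: int = 1000):
    """Map binding sites to candidate target genes.

    A nuclear protein-coding gene is a candidate iff any site overlaps
    (>=1 bp) the half-open window [gene.start - upstream, gene.end + downstream).
    The window is symmetric in genomic coordinates regardless of strand.
    Returns a sorted, deduplicated list of gene ids.
    """
    if upstream < 0 or downstream < 0:
        raise GlknetError("assign_sites_to_genes: window extents must be >= 0")
    known = annotation.chroms
    by_chrom: dict[str, list] = {}
    for g in annotation.genes:
        if g.is_nuclear_coding:
            by_chrom.setdefault(g.chrom, []).append(g)
    hits = set()
    skipped = set()
    for site in sites:
        if site.chrom not in known:
            skipped.add(site.chrom)
            continue
        for g in by_chrom.get(site.chrom, ()):
            w_start = g.start - upstream
            w_end = g.end + downstream
            if site.start < w_end and w_start < site.end:
                hits.add(g.gene_id)
    if skipped:
        warnings.warn(
            f"sites on chromosomes absent from annotation were skipped: {sorted(skipped)}",
            stacklevel=2,
        )
    return sorted(hits)
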