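"""Allelic chi-square association between accession groups, with
allele-frequency, localization and predicted-consequence filters.

The association test is the classical 2x2 allele-count Pearson chi-square
(no continuity correction): each accession contributes two alleles, a
heterozygote one of each; missing genotypes are excluded. The consequence
caller is a minimal codon-level predictor for SNVs on a genome whose CDS
coordinates and sequence are both known: it splices the CDS (strand-aware),
substitutes the alternate base and translates the affected codon with the
standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .clustering import AccessionGrouping
from .errors import DataIntegrityError, GlknetError
from .targets import GenomeAnnotation

IMPACT_OF = {
    "stop_gained": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW",
    "noncoding": "MODIFIER",
    "other": "MODIFIER",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GenotypeMatrix:
    """Biallelic variants x accessions allele dosages (0/1/2, NaN = missing).

    ``variants`` is a DataFrame with columns chrom, pos (1-based, VCF
    convention), ref, alt.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    accessions: list = field(default_factory=list)

    def __post_init__(self):
        if self.dosages.shape != (len(self.variants), len(self.accessions)):
            raise GlknetError("dosage matrix shape disagrees with variants/accessions")
        if (self.variants["ref"] == self.variants["alt"]).any():
            raise GlknetError("ref and alt alleles must differ")
        vals = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise GlknetError("dosages must be 0, 1, 2 or missing")

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def _group_columns(gm: GenotypeMatrix, groups: AccessionGrouping, group_id) -> np.ndarray:
    idx = [i for i, a in enumerate(gm.accessions) if groups.labels.get(a) == group_id]
    if not idx:
        raise GlknetError(f"group {group_id!r} has no accessions in the genotype matrix")
    return np.asarray(idx)


def _allele_counts(dos: np.ndarray):
    """(alt count, ref count) per variant from a dosage submatrix."""
    alt = np.nansum(dos, axis=1)
    n_called = np.sum(~np.isnan(dos), axis=1)
    return alt, 2.0 * n_called - alt


def group_allele_frequency(gm: GenotypeMatrix, groups: AccessionGrouping, group_id) -> np.ndarray:
    """Alternate-allele frequency per variant within one group (missing excluded)."""
    dos = gm.dosages[:, _group_columns(gm, groups, group_id)]
    alt, ref = _allele_counts(dos)
    total = alt + ref
    with np.errstate(invalid="ignore"):
        return np.where(total > 0, alt / np.maximum(total, 1), np.nan)


def allelic_chisq(gm: GenotypeMatrix, groups: AccessionGrouping,
                  group_a, group_b) -> pd.DataFrame:
    """Per-variant 2x2 allele-count Pearson chi-square (1 df), group_a vs group_b.

    Monomorphic variants get chi2=0, p=1; variants with no called genotype in
    either group get missing p.
    """
    dos_a = gm.dosages[:, _group_columns(gm, groups, group_a)]
    dos_b = gm.dosages[:, _group_columns(gm, groups, group_b)]
    alt_a, ref_a = _allele_counts(dos_a)
    alt_b, ref_b = _allele_counts(dos_b)
    n = alt_a + ref_a + alt_b + ref_b
    row_a = alt_a + ref_a
    row_b = alt_b + ref_b
    col_alt = alt_a + alt_b
    col_ref = ref_a + ref_b
    denom = row_a * row_b * col_alt * col_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (alt_a * ref_b - ref_a * alt_b) ** 2 / np.maximum(denom, 1), 0.0)
    p = stats.chi2.sf(chi2, df=1)
    # monomorphic in the pooled sample: no association information
    mono = (col_alt == 0) | (col_ref == 0)
    chi2 = np.where(mono, 0.0, chi2)
    p = np.where(mono, 1.0, p)
    uncallable = (row_a == 0) | (row_b == 0)
    p = np.where(uncallable, np.nan, p)
    chi2 = np.where(uncallable, np.nan, chi2)
    out = gm.variants.copy()
    out["chi2"] = chi2
    out["p_value"] = p
    out["freq_a"] = group_allele_frequency(gm, groups, group_a)
    out["freq_b"] = group_allele_frequency(gm, groups, group_b)
    return out


def _spliced_cds(gene, sequences) -> str:
    seq = sequences[gene.chrom]
    parts = [seq[s:e] for s, e, _ in sorted(gene.cds_segments)]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    return cds


def _cds_offset(gene, pos0: int) -> int | None:
    """Offset of genomic position ``pos0`` within the spliced, stranded CDS."""
    segs = sorted(gene.cds_segments)
    total = sum(e - s for s, e, _ in segs)
    off = 0
    for s, e, _ in segs:
        if s <= pos0 < e:
            plus_off = off + (pos0 - s)
            return plus_off if gene.strand == "+" else total - 1 - plus_off
        off += e - s
    return None


def predict_consequence(variant, annotation: GenomeAnnotation):
    """Predict (consequence, impact) for a single-nucleotide variant.

    ``variant`` is (chrom, pos, ref, alt) with a 1-based position. Positions
    in no gene are noncoding/MODIFIER; genic positions outside any CDS are
    other/MODIFIER; CDS positions are classified by translating the affected
    codon (standard genetic code). Loss of a reference stop codon falls
    outside the supported categories and is reported as other/HIGH.
    """
    chrom, pos, ref, alt = variant
    if len(ref) != 1 or len(alt) != 1:
        return "other", "MODIFIER"  # indels: association-only, no codon call
    pos0 = int(pos) - 1
    if chrom in annotation.sequences:
        actual = annotation.sequences[chrom][pos0]
        if actual.upper() != ref.upper():
            raise DataIntegrityError(
                f"{chrom}:{pos} ref allele {ref} disagrees with genome sequence {actual}"
            )
    hit_genes = [g for g in annotation.genes if g.chrom == chrom and g.start <= pos0 < g.end]
    if not hit_genes:
        return "noncoding", "MODIFIER"
    for gene in hit_genes:
        off = _cds_offset(gene, pos0) if gene.cds_segments else None
        if off is None:
            continue
        cds = _spliced_cds(gene, annotation.sequences)
        base = alt.upper() if gene.strand == "+" else alt.upper().translate(_COMPLEMENT)
        codon_i = off // 3
        codon = cds[3 * codon_i: 3 * codon_i + 3]
        if len(codon) < 3:
            continue  # trailing partial codon in a toy model
        new_codon = codon[: off % 3] + base + codon[off % 3 + 1:]
        old_aa = str(Seq(codon).translate())
        new_aa = str(Seq(new_codon).translate())
        if new_aa == old_aa:
            return "synonymous", "LOW"
        if new_aa == "*":
            return "stop_gained", "HIGH"
        if old_aa == "*":
            return "other", "HIGH"  # stop lost
        return "missense", "MODERATE"
    return "other", "MODIFIER"


def annotate_consequences(assoc: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Add consequence, impact and in_exon columns to an association table.

    ``in_exon`` marks positions inside any annotated gene's exon span (the
    toy gene models are single-exon, so the gene interval is the exon span).
    """
    out = assoc.copy()
    cons, imp, in_exon = [], [], []
    for chrom, pos, ref, alt in out[["chrom", "pos", "ref", "alt"]].itertuples(index=False):
        c, i = predict_consequence((chrom, pos, ref, alt), annotation)
        cons.append(c)
        imp.append(i)
        pos0 = int(pos) - 1
        in_exon.append(any(g.chrom == chrom and g.start <= pos0 < g.end
                           for g in annotation.genes))
    out["consequence"] = cons
    out["impact"] = imp
    out["in_exon"] = in_exon
    return out


def filter_variants(assoc: pd.DataFrame, p_threshold: float = 1e-10,
                    freq_min: float = 0.25, impact_in=("HIGH",),
                    minor_allele: bool = False):
    """Apply the association filter cascade and restrict to an impact class.

    All bounds are strict: p strictly below ``p_threshold``; frequency
    strictly above ``freq_min`` in at least one group (alt-allele frequency
    by default, minor-allele with ``minor_allele=True``). Returns
    ``(candidates, cascade)`` where ``cascade`` reports the count surviving
    each successive filter; the candidates table carries a ``passes_filters``
    column (true for every row, by construction).
    """
    fa, fb = assoc["freq_a"], assoc["freq_b"]
    if minor_allele:
        fa, fb = np.minimum(fa, 1 - fa), np.minimum(fb, 1 - fb)
    pass_p = assoc["p_value"] < p_threshold
    pass_freq = pass_p & ((fa > freq_min) | (fb > freq_min))
    pass_exon = pass_freq & assoc["in_exon"]
    out = assoc.copy()
    out["passes_filters"] = pass_exon
    selected = out[pass_exon & out["impact"].isin(set(impact_in))]
    cascade = {
        "n_variants": int(len(assoc)),
        "n_p": int(pass_p.sum()),
        "n_p_freq": int(pass_freq.sum()),
        "n_p_freq_exon": int(pass_exon.sum()),
        "n_impact_selected": int(len(selected)),
        "n_stop_gained": int((selected["consequence"] == "stop_gained").sum()),
    }
    return selected, cascade
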