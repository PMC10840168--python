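"""Allelic association, frequencies, the codon-level consequence caller, and
the filter cascade."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from glknet import (DataIntegrityError, GenotypeMatrix, GlknetError, Labeling,
                    allelic_chisq, filter_variants, generate_dataset,
                    group_allele_frequency, predict_consequence)
from glknet.gwas import annotate_consequences

from conftest import make_toy_gene, small_config


def gm_from_dosages(dosages, accessions=None):
    dosages = np.asarray(dosages, dtype=float)
    accessions = accessions or [f"s{i}" for i in range(dosages.shape[1])]
    variants = pd.DataFrame(
        [("Chr1", 100 + i, "A", "T") for i in range(dosages.shape[0])],
        columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(variants, dosages, accessions)


def two_groups(n_a, n_b):
    labels = {f"s{i}": (1 if i < n_a else 2) for i in range(n_a + n_b)}
    return Labeling(labels, 2)


class TestAllelicChisq:
    def test_closed_form_2x2_example(self):
        # group A: 40 alt / 60 ref alleles; group B: 70 alt / 30 ref
        dos_a = [2] * 20 + [0] * 30      # 50 accessions -> 100 alleles
        dos_b = [2] * 35 + [0] * 15
        gm = gm_from_dosages([dos_a + dos_b])
        res = allelic_chisq(gm, two_groups(50, 50), 1, 2)
        expect = 200 * (40 * 30 - 60 * 70) ** 2 / (100 * 100 * 110 * 90)
        assert res["chi2"].iloc[0] == pytest.approx(expect, abs=1e-10)
        assert res["p_value"].iloc[0] == pytest.approx(2.03e-5, rel=0.02)

    def test_equal_frequencies_give_null(self):
        gm = gm_from_dosages([[2, 0, 1, 1, 2, 0, 1, 1]])
        res = allelic_chisq(gm, two_groups(4, 4), 1, 2)
        assert res["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_variant(self):
        gm = gm_from_dosages([[0, 0, 0, 0, 0, 0]])
        res = allelic_chisq(gm, two_groups(3, 3), 1, 2)
        assert res["chi2"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == 1.0

    def test_all_missing_flagged(self):
        gm = gm_from_dosages([[np.nan] * 6])
        res = allelic_chisq(gm, two_groups(3, 3), 1, 2)
        assert np.isnan(res["p_value"].iloc[0])

    def test_matches_brute_force_contingency_chi2(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(7)
        dosages = rng.integers(0, 3, size=(100, 40)).astype(float)
        dosages[rng.random(dosages.shape) < 0.05] = np.nan
        gm = gm_from_dosages(dosages)
        groups = two_groups(18, 22)
        res = allelic_chisq(gm, groups, 1, 2)
        for i in range(100):
            row = dosages[i]
            a, b = row[:18], row[18:]
            table = np.array([
                [np.nansum(a), 2 * np.sum(~np.isnan(a)) - np.nansum(a)],
                [np.nansum(b), 2 * np.sum(~np.isnan(b)) - np.nansum(b)],
            ])
            if table.sum(axis=0).min() == 0:
                expect = 0.0
            else:
                expect = chi2_contingency(table, correction=False).statistic
            assert res["chi2"].iloc[i] == pytest.approx(expect, abs=1e-10)


class TestGroupAlleleFrequency:
    def test_simple_dosages(self):
        gm = gm_from_dosages([[0, 1, 2]])
        f = group_allele_frequency(gm, Labeling({"s0": 1, "s1": 1, "s2": 1}, 1), 1)
        assert f[0] == pytest.approx(0.5)

    def test_all_reference(self):
        gm = gm_from_dosages([[0, 0, 0]])
        f = group_allele_frequency(gm, Labeling({"s0": 1, "s1": 1, "s2": 1}, 1), 1)
        assert f[0] == 0.0

    def test_missing_excluded_from_denominator(self):
        gm = gm_from_dosages([[0, 1, np.nan]])
        f = group_allele_frequency(gm, Labeling({"s0": 1, "s1": 1, "s2": 1}, 1), 1)
        assert f[0] == pytest.approx(0.25)

    def test_empty_group_raises(self):
        gm = gm_from_dosages([[0, 1]])
        with pytest.raises(GlknetError):
            group_allele_frequency(gm, two_groups(2, 0), 2)


class TestPredictConsequence:
    # CDS: ATG GAT CTT CAG TAA (Met Asp Leu Gln stop)
    CDS = "ATGGATCTTCAGTAA"

    def _variant_at(self, ann, gene, cds_offset, new_base):
        """Genomic (chrom,pos,ref,alt) that changes CDS position ``cds_offset``
        to ``new_base`` (bases given in coding-strand orientation)."""
        comp = str.maketrans("ACGT", "TGCA")
        s, e, _ = gene.cds_segments[0]
        if gene.strand == "+":
            pos0 = s + cds_offset
            ref = ann.sequences[gene.chrom][pos0]
            alt = new_base
        else:
            pos0 = e - 1 - cds_offset
            ref = ann.sequences[gene.chrom][pos0]
            alt = new_base.translate(comp)
        return (gene.chrom, pos0 + 1, ref, alt)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_stop_gain_missense_synonymous(self, strand):
        ann, gene = make_toy_gene(strand, self.CDS)
        # CAG -> TAG (codon 3, position 0): stop gained
        v = self._variant_at(ann, gene, 9, "T")
        assert predict_consequence(v, ann) == ("stop_gained", "HIGH")
        # CTT -> CTC (codon 2, position 2): synonymous
        v = self._variant_at(ann, gene, 8, "C")
        assert predict_consequence(v, ann) == ("synonymous", "LOW")
        # GAT -> GCT (codon 1, position 1): missense
        v = self._variant_at(ann, gene, 4, "C")
        assert predict_consequence(v, ann) == ("missense", "MODERATE")

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_enumeration_matches_whole_protein_oracle(self, strand):
        """Every possible substitution at every CDS position agrees with an
        oracle that mutates the full CDS and translates both proteins."""
        ann, gene = make_toy_gene(strand, self.CDS)
        for off in range(len(self.CDS)):
            old_base = self.CDS[off]
            for new_base in "ACGT":
                if new_base == old_base:
                    continue
                mutated = self.CDS[:off] + new_base + self.CDS[off + 1:]
                old_aa = str(Seq(self.CDS).translate())
                new_aa = str(Seq(mutated).translate())
                i = off // 3
                if new_aa[i] == old_aa[i]:
                    expect = ("synonymous", "LOW")
                elif new_aa[i] == "*":
                    expect = ("stop_gained", "HIGH")
                elif old_aa[i] == "*":
                    expect = ("other", "HIGH")  # stop lost
                else:
                    expect = ("missense", "MODERATE")
                v = self._variant_at(ann, gene, off, new_base)
                assert predict_consequence(v, ann) == expect, (strand, off, new_base)

    def test_positions_outside_genes_and_cds(self):
        ann, gene = make_toy_gene("+", self.CDS)
        # inside gene, outside CDS (the 10 bp UTR before the CDS)
        pos0 = gene.cds_segments[0][0] - 5
        ref = ann.sequences[gene.chrom][pos0]
        alt = "A" if ref != "A" else "C"
        assert predict_consequence((gene.chrom, pos0 + 1, ref, alt), ann) == \
            ("other", "MODIFIER")
        # outside any gene
        ref = ann.sequences[gene.chrom][2]
        alt = "A" if ref != "A" else "C"
        assert predict_consequence((gene.chrom, 3, ref, alt), ann) == \
            ("noncoding", "MODIFIER")

    def test_reference_mismatch_raises(self):
        ann, gene = make_toy_gene("+", self.CDS)
        pos0 = gene.cds_segments[0][0]
        ref = ann.sequences[gene.chrom][pos0]
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(DataIntegrityError):
            predict_consequence((gene.chrom, pos0 + 1, wrong, "G"), ann)


class TestFilterVariants:
    def _assoc(self, p, fa, fb, in_exon=True, impact="HIGH", consequence="stop_gained"):
        return pd.DataFrame([{
            "chrom": "Chr1", "pos": 1, "ref": "A", "alt": "T",
            "chi2": 50.0, "p_value": p, "freq_a": fa, "freq_b": fb,
            "in_exon": in_exon, "impact": impact, "consequence": consequence,
        }])

    def test_p_boundary_is_strict(self):
        sel, _ = filter_variants(self._assoc(1e-10, 0.9, 0.1))
        assert len(sel) == 0
        sel, _ = filter_variants(self._assoc(0.9e-10, 0.9, 0.1))
        assert len(sel) == 1

    def test_frequency_boundary_is_strict(self):
        sel, _ = filter_variants(self._assoc(1e-12, 0.25, 0.10))
        assert len(sel) == 0
        sel, _ = filter_variants(self._assoc(1e-12, 0.26, 0.10))
        assert len(sel) == 1

    def test_exon_requirement(self):
        sel, _ = filter_variants(self._assoc(1e-12, 0.9, 0.1, in_exon=False))
        assert len(sel) == 0

    def test_cascade_counts_are_monotone(self):
        rows = pd.concat([
            self._assoc(1e-12, 0.9, 0.1),
            self._assoc(1e-12, 0.9, 0.1, impact="MODERATE", consequence="missense"),
            self._assoc(1e-12, 0.1, 0.1),
            self._assoc(0.5, 0.9, 0.1),
        ], ignore_index=True)
        sel, cascade = filter_variants(rows)
        vals = [cascade["n_variants"], cascade["n_p"], cascade["n_p_freq"],
                cascade["n_p_freq_exon"], cascade["n_impact_selected"],
                cascade["n_stop_gained"]]
        assert vals == sorted(vals, reverse=True)
        assert len(sel) == 1

    def test_planted_stop_gain_snps_are_exactly_the_high_candidates(self, default_bundle):
        # full-size cohort: the 1e-10 association bound needs ~200 accessions
        bundle = default_bundle
        groups = Labeling(bundle.truth.accession_groups, 2)
        assoc = allelic_chisq(bundle.genotypes, groups, 1, 2)
        assoc = annotate_consequences(assoc, bundle.annotation)
        sel, cascade = filter_variants(assoc)
        got = set(map(tuple, sel[["chrom", "pos", "ref", "alt"]].values))
        planted = {tuple(v) for v in bundle.truth.stop_gain_variants}
        assert got == planted
        assert cascade["n_stop_gained"] == len(planted)
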