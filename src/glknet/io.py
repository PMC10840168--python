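"""Readers and writers for the pipeline's on-disk formats.

Every stage boundary is file-based so real data (counts, peaks, VCF, climate
tables) can be substituted for any synthetic input: GFF3 + FASTA for the
annotation, BED6+fdr for binding sites, TSV for count/expression matrices and
label tables, VCF 4.2 for genotypes, CSV for climate and photosynthesis,
SIF for networks, JSON for the truth record and run report.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .clustering import Labeling
from .errors import GlknetError
from .expression import CountMatrix, ExpressionMatrix
from .gwas import GenotypeMatrix
from .synthetic_data import SyntheticBundle, TruthRecord
from .targets import BindingSite, Gene, GenomeAnnotation

FLOAT_FMT = "%.10g"
#: full-precision format for bundle files that must round-trip losslessly
RT_FMT = "%.17g"


# --- annotation ---------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
        attrs = f"ID={g.gene_id};biotype={g.biotype};compartment={g.compartment}"
        lines.append("\t".join([g.chrom, "glknet", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]))
        for s, e, phase in g.cds_segments:
            lines.append("\t".join([g.chrom, "glknet", "CDS", str(s + 1), str(e),
                                    ".", g.strand, str(phase),
                                    f"ID=cds-{g.gene_id};Parent={g.gene_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path, fasta_path=None) -> GenomeAnnotation:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        cds = tuple(sorted(
            (c.start - 1, c.end, int(c.frame) if c.frame not in (None, ".") else 0)
            for c in db.children(f, featuretype="CDS")))
        genes.append(Gene(
            gene_id=f.attributes["ID"][0], chrom=f.seqid, start=f.start - 1,
            end=f.end, strand=f.strand,
            biotype=f.attributes.get("biotype", ["protein_coding"])[0],
            compartment=f.attributes.get("compartment", ["nuclear"])[0],
            cds_segments=cds))
    sequences = {}
    if fasta_path is not None:
        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    return GenomeAnnotation(genes, sequences)


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


# --- binding sites ------------------------------------------------------------

def write_bed(sites, path) -> None:
    rows = [(s.chrom, s.start, s.end, s.name, RT_FMT % s.score, ".",
             RT_FMT % s.fdr) for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path):
    df = pd.read_csv(path, sep="\t", header=None, float_precision="round_trip",
                     names=["chrom", "start", "end", "name", "score", "strand", "fdr"])
    return [BindingSite(r.chrom, int(r.start), int(r.end), float(r.score),
                        float(r.fdr), str(r.name)) for r in df.itertuples(index=False)]


# --- counts and expression ----------------------------------------------------

def write_counts(counts: CountMatrix, counts_path, library_map_path) -> None:
    counts.values.to_csv(counts_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        [(lib, acc) for lib, acc in counts.library_to_accession.items()],
        columns=["library_id", "accession_id"],
    ).to_csv(library_map_path, sep="\t", index=False)


def read_counts(counts_path, library_map_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    lib_map = pd.read_csv(library_map_path, sep="\t")
    mapping = dict(zip(lib_map["library_id"].astype(str), lib_map["accession_id"].astype(str)))
    return CountMatrix(df, mapping)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def read_expression(path, scale: str) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col="gene_id"), scale=scale)


# --- cluster labels -----------------------------------------------------------

def write_labels(labeling: Labeling, path, item_col: str = "item_id") -> None:
    pd.DataFrame(sorted(labeling.labels.items()),
                 columns=[item_col, "cluster"]).to_csv(path, sep="\t", index=False)


def read_labels(path, item_col: str = "item_id") -> Labeling:
    df = pd.read_csv(path, sep="\t")
    labels = dict(zip(df[item_col].astype(str), df["cluster"].astype(int)))
    return Labeling(labels, k=int(df["cluster"].max()))


# --- genotypes ----------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    header = [
        "##fileformat=VCFv4.2",
        "##source=glknet-synthetic",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted(genotypes.variants["chrom"].unique()):
        header.append(f"##contig=<ID={chrom}>")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT",
            *genotypes.accessions]
    cols[7:7] = ["INFO"]
    lines = header + ["\t".join(cols)]
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for i, row in enumerate(genotypes.variants.itertuples(index=False)):
        gts = [gt_of.get(d, "./.") if not np.isnan(d) else "./."
               for d in genotypes.dosages[i]]
        lines.append("\t".join([row.chrom, str(row.pos), f"var{i + 1:05d}",
                                row.ref, row.alt, ".", "PASS", ".", "GT", *gts]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    vcf = VCF(str(path), gts012=True)
    accessions = list(vcf.samples)
    rows, dosages = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GlknetError(f"non-biallelic record at {rec.CHROM}:{rec.POS}")
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        gt = rec.gt_types.astype(float)  # 0/1/2 dosage, 3 = missing
        gt[gt == 3] = np.nan
        dosages.append(gt)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    mat = np.vstack(dosages) if dosages else np.zeros((0, len(accessions)))
    return GenotypeMatrix(variants, mat, accessions)


# --- climate / photosynthesis -------------------------------------------------

def write_climate(climate: pd.DataFrame, path) -> None:
    climate.to_csv(path, index=False, float_format=RT_FMT)


def read_climate(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_photosynthesis(photo: pd.DataFrame, path) -> None:
    photo.to_csv(path, index=False, float_format=RT_FMT)


def read_photosynthesis(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# --- truth record -------------------------------------------------------------

def write_truth(truth: TruthRecord, path) -> None:
    payload = {
        "accession_groups": truth.accession_groups,
        "de_genes": truth.de_genes,
        "causal_snps": truth.causal_snps,
        "planted_edges_per_group": {
            str(g): [[a, b, pc] for a, b, pc in edges]
            for g, edges in truth.planted_edges_per_group.items()
        },
        "differential_edges": [[a, b, d] for a, b, d in truth.differential_edges],
        "stop_gain_variants": [list(v) for v in truth.stop_gain_variants],
        "target_genes": truth.target_genes,
        "network_genes": truth.network_genes,
        "focal_gene": truth.focal_gene,
        "low_depth_libraries": truth.low_depth_libraries,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path) -> TruthRecord:
    d = json.loads(Path(path).read_text())
    return TruthRecord(
        accession_groups={k: int(v) for k, v in d["accession_groups"].items()},
        de_genes={k: float(v) for k, v in d["de_genes"].items()},
        causal_snps=d["causal_snps"],
        planted_edges_per_group={
            int(g): [(a, b, float(pc)) for a, b, pc in edges]
            for g, edges in d["planted_edges_per_group"].items()
        },
        differential_edges=[(a, b, float(x)) for a, b, x in d["differential_edges"]],
        stop_gain_variants=[tuple(v) for v in d["stop_gain_variants"]],
        target_genes=list(d["target_genes"]),
        network_genes=list(d["network_genes"]),
        focal_gene=d["focal_gene"],
        low_depth_libraries=list(d["low_depth_libraries"]),
    )


# --- networks -----------------------------------------------------------------

def write_sif(edges: pd.DataFrame, path, interaction: str = "pcor") -> None:
    """Cytoscape-loadable SIF: gene_i <interaction> gene_j."""
    lines = [f"{r.gene_i}\t{interaction}\t{r.gene_j}"
             for r in edges.itertuples(index=False)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_table(df: pd.DataFrame, path, index: bool = False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FMT)


# --- whole bundle -------------------------------------------------------------

BUNDLE_FILES = {
    "annotation": "annotation.gff3",
    "genome": "genome.fa",
    "sites": "sites.bed",
    "counts": "counts.tsv",
    "library_map": "library_map.tsv",
    "vcf": "genotypes.vcf",
    "climate": "climate.csv",
    "photosynthesis": "photosynthesis.csv",
    "truth": "truth.json",
    "panel": "network_panel.tsv",
}


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write every member table of a synthetic bundle; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in BUNDLE_FILES.items()}
    write_gff3(bundle.annotation, paths["annotation"])
    write_fasta(bundle.annotation.sequences, paths["genome"])
    write_bed(bundle.sites, paths["sites"])
    write_counts(bundle.counts, paths["counts"], paths["library_map"])
    write_vcf(bundle.genotypes, paths["vcf"])
    write_climate(bundle.climate, paths["climate"])
    write_photosynthesis(bundle.photosynthesis, paths["photosynthesis"])
    write_truth(bundle.truth, paths["truth"])
    pd.DataFrame({"gene_id": bundle.truth.network_genes}).to_csv(
        paths["panel"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def read_gene_list(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return list(df[df.columns[0]].astype(str))
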