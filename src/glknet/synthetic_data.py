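"""Synthetic study generator with planted ground truth.

Emulates the full input shape of the accession-stratified analysis: a toy
two-chromosome genome with annotated single-exon genes, scored binding sites
for a focal transcription factor, an RNA-seq count matrix over multiple
libraries per accession, a biallelic genotype matrix, per-accession monthly
climate tables, and per-accession photosynthesis parameters measured under
two light regimes. Every planted effect (accession groups, differentially
expressed genes, group-differentiated variants including stop-gain alleles,
group-specific network edges, a group x condition photosynthesis shift) is
recorded in a :class:`TruthRecord` for recovery testing.

Planted structure, by domain:

* **Counts** — per-gene log-normal baselines; negative-binomial sampling with
  a common dispersion; library size factors spanning a >=4-fold range; a
  configurable fraction of deliberately shallow libraries. Differential
  genes are shifted by ``de_log2fc`` (random sign per gene) in group 2.
* **Network genes** — latent expression drawn from a multivariate normal
  whose precision matrix realizes the planted group-specific partial
  correlations; counts for these genes are a deterministic transform of the
  latent value so the planted partial correlations survive normalization.
* **Genotypes** — Hardy-Weinberg sampling; causal variants receive allele
  frequencies differing between the two largest groups by a wide margin
  (empirical gap kept >= 0.45 by rejection), a subset placed inside CDS such
  that the alternate allele creates a stop codon; the rest of the causal
  variants are planted as missense.
* **Climate** — seasonal sinusoid per variable; the solar-radiation
  amplitude (hence its across-month SD) is scaled by ``srad_sd_ratio`` in
  group 2; all other variables are group-neutral.
* **Photosynthesis** — NPQ_Lss gains ``photo_interaction`` only in
  (group 2, inland/high-light); QY parameters are group-neutral.

One RNG stream per data domain, all derived from the master seed, so that
changing one domain's parameters does not reshuffle the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleEdgeSetError
from .expression import CountMatrix
from .gwas import GenotypeMatrix
from .targets import BindingSite, Gene, GenomeAnnotation

GENE_LEN = 900
CDS_OFFSET = 300
CDS_LEN = 300
GENE_SPACING = 2000
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: codon templates used when planting coding variants:
#: (reference codon, position within codon, alternate base, resulting class)
STOP_TEMPLATE = ("CAA", 0, "T", "stop_gained")   # CAA (Gln) -> TAA (stop)
MISSENSE_TEMPLATE = ("GCT", 1, "A", "missense")  # GCT (Ala) -> GAT (Asp)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset. Defaults are the desk-scale
    analogue of the real cohort: 200 accessions in two groups, 300 genes, a
    50-gene target panel, a 20-gene network panel and 500 variants."""

    n_accessions: int = 200
    group_sizes: tuple = (80, 120)
    n_genes: int = 300
    n_target_genes: int = 50
    n_network_genes: int = 20
    n_snps: int = 500
    n_causal_snps: int = 20
    de_log2fc: float = 3.0
    network_pcor: float = 0.5
    n_diff_edges: int = 3
    diff_edge_delta: float = 0.8
    nb_dispersion: float = 0.1
    libs_per_accession: int = 2
    low_depth_fraction: float = 0.1
    months: int = 12
    srad_sd_ratio: float = 2.0
    photo_interaction: float = 0.5
    seed: int = 0
    # secondary knobs (variance structure and toy-genome composition)
    n_stop_gain_causal: int = 5
    expr_noise_sd: float = 0.5
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    network_log2_mean: float = 9.0
    network_latent_sd: float = 1.0
    low_depth_scale: float = 0.005
    genotype_missing_rate: float = 0.02
    n_noncoding_genes: int = 5
    n_organellar_genes: int = 5
    n_decoy_sites: int = 50
    min_reads_hint: int = 5000

    def validate(self) -> None:
        def bad(name, why):
            raise ConfigurationError(f"{name}: {why}")

        positive = ["n_accessions", "n_genes", "n_target_genes", "n_network_genes",
                    "n_snps", "libs_per_accession", "months"]
        for name in positive:
            if getattr(self, name) < 1:
                bad(name, "must be a positive count")
        if sum(self.group_sizes) != self.n_accessions:
            bad("group_sizes", f"must sum to n_accessions={self.n_accessions}")
        if any(g < 1 for g in self.group_sizes):
            bad("group_sizes", "all group sizes must be positive")
        if len(self.group_sizes) < 2:
            bad("group_sizes", "need at least two groups")
        if self.n_causal_snps < 0 or self.n_causal_snps > self.n_snps:
            bad("n_causal_snps", "must lie in [0, n_snps]")
        if self.n_stop_gain_causal < 0 or self.n_stop_gain_causal > self.n_causal_snps:
            bad("n_stop_gain_causal", "must lie in [0, n_causal_snps]")
        n_coding = self.n_genes - self.n_noncoding_genes - self.n_organellar_genes
        if self.n_target_genes + self.n_network_genes > n_coding:
            bad("n_target_genes", "target + network panels exceed nuclear coding genes")
        if not 0.0 < abs(self.network_pcor) < 1.0 and self.network_pcor != 0.0:
            bad("network_pcor", "must satisfy |pcor| < 1")
        if not 0.0 <= self.diff_edge_delta < 1.0:
            bad("diff_edge_delta", "must lie in [0, 1)")
        if self.n_diff_edges < 0 or 2 * self.n_diff_edges > self.n_network_genes:
            bad("n_diff_edges", "needs 2 network genes per differential edge")
        if self.nb_dispersion <= 0:
            bad("nb_dispersion", "must be > 0")
        if not 0.0 <= self.low_depth_fraction <= 1.0:
            bad("low_depth_fraction", "must lie in [0, 1]")
        if self.low_depth_fraction > 0 and self.libs_per_accession < 2:
            bad("libs_per_accession", "must be >=2 when low_depth_fraction > 0 "
                "(every accession keeps one adequate library)")
        if self.srad_sd_ratio < 1.0:
            bad("srad_sd_ratio", "must be >= 1")
        if not 0.0 <= self.genotype_missing_rate < 0.5:
            bad("genotype_missing_rate", "must lie in [0, 0.5)")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class TruthRecord:
    """Planted parameters of one synthetic dataset."""

    accession_groups: dict
    de_genes: dict                 # gene -> signed log2FC (group 2 minus group 1)
    causal_snps: list              # dicts: chrom,pos,ref,alt,freqs per group
    planted_edges_per_group: dict  # group label -> [(gene_i, gene_j, pcor), ...]
    differential_edges: list       # [(gene_i, gene_j, delta), ...]
    stop_gain_variants: list       # [(chrom,pos,ref,alt), ...]
    target_genes: list
    network_genes: list
    focal_gene: str
    low_depth_libraries: list


@dataclass
class SyntheticBundle:
    annotation: GenomeAnnotation
    sites: list
    counts: CountMatrix
    genotypes: GenotypeMatrix
    climate: pd.DataFrame
    photosynthesis: pd.DataFrame
    truth: TruthRecord
    meta: dict = field(default_factory=dict)


def precision_matrix_from_edges(genes, edges) -> np.ndarray:
    """Precision matrix whose implied partial correlations equal the requested
    edge values (exactly, for a feasible edge set).

    The unit-diagonal matrix with -pcor off-diagonals is the canonical
    parameterization: any diagonal inflation followed by re-standardization
    would shrink the implied partial correlations, so an edge set whose
    canonical matrix is not positive definite is reported as infeasible.
    """
    index = {g: i for i, g in enumerate(genes)}
    p = len(genes)
    omega = np.eye(p)
    for gi, gj, pc in edges:
        if gi not in index or gj not in index:
            raise ConfigurationError(f"edge gene {gi!r}/{gj!r} not in panel")
        if not abs(pc) < 1:
            raise ConfigurationError(f"edge ({gi},{gj}): |pcor| must be < 1")
        i, j = index[gi], index[gj]
        omega[i, j] = omega[j, i] = -pc
    eigmin = float(np.linalg.eigvalsh(omega)[0])
    if eigmin <= 1e-10:
        raise InfeasibleEdgeSetError(
            f"requested edge set admits no positive-definite precision matrix "
            f"(min eigenvalue {eigmin:.3g})"
        )
    return omega


def _latent_covariance(omega: np.ndarray) -> np.ndarray:
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _plant_codon_variant(gene: Gene, sequences: dict, codon_index: int,
                         template) -> tuple:
    """Overwrite the reference so a chosen CDS codon matches ``template`` and
    return the (chrom, pos1, ref, alt) of the planted variant in VCF terms."""
    ref_codon, codon_pos, alt_base, _ = template
    cds_start = gene.cds_segments[0][0]
    cds_end = gene.cds_segments[0][1]
    seq = list(sequences[gene.chrom])
    for k, base in enumerate(ref_codon):
        off = 3 * codon_index + k
        if gene.strand == "+":
            gpos = cds_start + off
            seq[gpos] = base
        else:
            gpos = cds_end - 1 - off
            seq[gpos] = base.translate(_COMPLEMENT)
    sequences[gene.chrom] = "".join(seq)
    off = 3 * codon_index + codon_pos
    if gene.strand == "+":
        gpos = cds_start + off
        ref, alt = ref_codon[codon_pos], alt_base
    else:
        gpos = cds_end - 1 - off
        ref = ref_codon[codon_pos].translate(_COMPLEMENT)
        alt = alt_base.translate(_COMPLEMENT)
    return gene.chrom, gpos + 1, ref, alt


def _build_genome(cfg: GeneratorConfig, rng: np.random.Generator):
    """Toy genome: nuclear genes on Chr1/Chr2 at fixed spacing, organellar
    genes on ChrC; 0-based half-open coordinates."""
    n_nuclear = cfg.n_genes - cfg.n_organellar_genes
    genes = []
    per_chrom = {"Chr1": (n_nuclear + 1) // 2, "Chr2": n_nuclear // 2,
                 "ChrC": cfg.n_organellar_genes}
    gid = 0
    noncoding_ids = set(rng.choice(n_nuclear, size=cfg.n_noncoding_genes, replace=False)) \
        if cfg.n_noncoding_genes else set()
    sequences = {}
    nuc_index = 0
    for chrom, n_on in per_chrom.items():
        pos = 1000
        for k in range(n_on):
            gid += 1
            start, end = pos, pos + GENE_LEN
            strand = "+" if k % 2 == 0 else "-"
            if chrom == "ChrC":
                biotype, compartment, cds = "protein_coding", "organellar", ()
            else:
                noncoding = nuc_index in noncoding_ids
                nuc_index += 1
                biotype = "ncRNA" if noncoding else "protein_coding"
                compartment = "nuclear"
                cds = () if noncoding else (
                    (start + CDS_OFFSET, start + CDS_OFFSET + CDS_LEN, 0),)
            genes.append(Gene(f"G{gid:04d}", chrom, start, end, strand,
                              biotype, compartment, cds))
            pos = end + GENE_SPACING
        length = pos + 1000
        sequences[chrom] = "".join(rng.choice(list(_BASES), size=length))
    return GenomeAnnotation(genes, sequences)


def _plant_edges(cfg: GeneratorConfig, network_genes, rng: np.random.Generator):
    """Disjoint gene pairs: base edges shared by all groups, plus differential
    edges present only in the largest (reference-like) group."""
    order = [str(g) for g in rng.permutation(network_genes)]
    n_pairs = len(order) // 2
    n_base = n_pairs - cfg.n_diff_edges
    pairs = [tuple(sorted((order[2 * i], order[2 * i + 1]))) for i in range(n_pairs)]
    base_pairs, diff_pairs = pairs[:n_base], pairs[n_base:]
    k = len(cfg.group_sizes)
    sizes = list(cfg.group_sizes)
    ref_group = 1 + sizes.index(max(sizes))
    edges_per_group = {}
    for g in range(1, k + 1):
        edges = [(a, b, cfg.network_pcor) for a, b in base_pairs
                 if cfg.network_pcor != 0.0]
        if g == ref_group and cfg.diff_edge_delta > 0:
            edges += [(a, b, cfg.diff_edge_delta) for a, b in diff_pairs]
        edges_per_group[g] = edges
    differential = ([(a, b, cfg.diff_edge_delta) for a, b in diff_pairs]
                    if cfg.diff_edge_delta > 0 else [])
    focal = base_pairs[0][0] if base_pairs else network_genes[0]
    return edges_per_group, differential, ref_group, focal


def _sample_genotype(rng, freqs_per_acc, missing_rate):
    dos = rng.binomial(2, freqs_per_acc).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    return dos


def _empirical_gap(dos, idx_a, idx_b):
    def freq(idx):
        sub = dos[idx]
        called = ~np.isnan(sub)
        if called.sum() == 0:
            return np.nan
        return np.nansum(sub) / (2 * called.sum())

    fa, fb = freq(idx_a), freq(idx_b)
    if np.isnan(fa) or np.isnan(fb):
        return np.nan
    return abs(fa - fb)


def generate_dataset(config: GeneratorConfig) -> SyntheticBundle:
    """Generate one complete synthetic study; deterministic given the seed."""
    cfg = config
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_genome, rng_counts, rng_geno, rng_climate, rng_photo, rng_sites = (
        np.random.default_rng(s) for s in streams)

    annotation = _build_genome(cfg, rng_genome)
    coding = [g for g in annotation.genes if g.is_nuclear_coding]
    coding_ids = [g.gene_id for g in coding]
    picks = rng_genome.choice(len(coding_ids),
                              size=cfg.n_target_genes + cfg.n_network_genes,
                              replace=False)
    target_genes = sorted(coding_ids[i] for i in picks[: cfg.n_target_genes])
    network_genes = sorted(coding_ids[i] for i in picks[cfg.n_target_genes:])

    # --- accessions and groups -------------------------------------------------
    accessions = [f"acc{i + 1:04d}" for i in range(cfg.n_accessions)]
    groups = {}
    cursor = 0
    for g, size in enumerate(cfg.group_sizes, start=1):
        for a in accessions[cursor: cursor + size]:
            groups[a] = g
        cursor += size
    group_of = np.array([groups[a] for a in accessions])

    # --- planted network -------------------------------------------------------
    edges_per_group, differential_edges, ref_group, focal = _plant_edges(
        cfg, network_genes, rng_genome)
    latent = {}
    for g, edges in edges_per_group.items():
        omega = precision_matrix_from_edges(network_genes, edges)
        cov = _latent_covariance(omega)
        chol = np.linalg.cholesky(cov)
        n_g = int(np.sum(group_of == g))
        z = rng_counts.standard_normal((n_g, len(network_genes))) @ chol.T
        latent[g] = z * cfg.network_latent_sd

    # --- counts ----------------------------------------------------------------
    all_gene_ids = [g.gene_id for g in annotation.genes]
    n_genes_total = len(all_gene_ids)
    is_network = np.array([gid in set(network_genes) for gid in all_gene_ids])
    baseline = rng_counts.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                                 size=n_genes_total)
    baseline = np.clip(baseline, 2.0, None)
    baseline[is_network] = cfg.network_log2_mean + rng_counts.normal(
        0.0, 0.3, size=int(is_network.sum()))

    de_signs = {}
    if cfg.de_log2fc != 0:
        signs = rng_counts.choice([1.0, -1.0], size=len(target_genes))
        de_signs = dict(zip(target_genes, signs))
    de_genes = {g: float(s * cfg.de_log2fc) for g, s in de_signs.items()}

    shift = np.zeros((n_genes_total, cfg.n_accessions))
    gene_pos = {gid: i for i, gid in enumerate(all_gene_ids)}
    for gid, lfc in de_genes.items():
        shift[gene_pos[gid], group_of == 2] = lfc

    log2_mean = baseline[:, None] + shift
    noise = rng_counts.normal(0.0, cfg.expr_noise_sd,
                              size=(n_genes_total, cfg.n_accessions))
    noise[is_network] = 0.0
    log2_mean = log2_mean + noise
    group_counters = {g: 0 for g in edges_per_group}
    net_rows = np.where(is_network)[0]
    for j, a in enumerate(accessions):
        g = groups[a]
        z = latent[g][group_counters[g]]
        group_counters[g] += 1
        log2_mean[net_rows, j] = baseline[net_rows] + z

    lib_ids, lib_acc, lib_sf = [], {}, []
    for a in accessions:
        for l in range(cfg.libs_per_accession):
            lib = f"{a}_L{l + 1}"
            lib_ids.append(lib)
            lib_acc[lib] = a
            lib_sf.append(2.0 ** rng_counts.uniform(-1.0, 1.0))
    lib_sf = np.array(lib_sf)
    n_libs = len(lib_ids)
    n_low = int(round(cfg.low_depth_fraction * n_libs))
    candidates = [i for i, lib in enumerate(lib_ids) if not lib.endswith("_L1")]
    low_idx = sorted(rng_counts.choice(candidates, size=n_low, replace=False)) \
        if n_low else []
    lib_sf[low_idx] *= cfg.low_depth_scale
    low_depth_libraries = [lib_ids[i] for i in low_idx]

    acc_col = np.array([accessions.index(lib_acc[lib]) for lib in lib_ids])
    mu = lib_sf[None, :] * (2.0 ** log2_mean[:, acc_col])
    counts = np.zeros((n_genes_total, n_libs), dtype=np.int64)
    r = 1.0 / cfg.nb_dispersion
    nb_rows = ~is_network
    p_nb = r / (r + mu[nb_rows])
    counts[nb_rows] = rng_counts.negative_binomial(r, p_nb)
    # network genes: deterministic transform so the planted partial
    # correlations survive normalization (log2(count/sf + 1) ~ baseline + z)
    counts[is_network] = np.rint(
        lib_sf[None, :] * (2.0 ** log2_mean[is_network][:, acc_col] - 1.0)
    ).astype(np.int64)
    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=all_gene_ids, columns=lib_ids), dict(lib_acc))

    # --- genotypes -------------------------------------------------------------
    sizes = list(cfg.group_sizes)
    two_largest = sorted(range(1, len(sizes) + 1),
                         key=lambda g: (-sizes[g - 1], g))[:2]
    gA, gB = two_largest
    idx_a = np.where(group_of == gA)[0]
    idx_b = np.where(group_of == gB)[0]
    variants, dosages = [], []
    causal_records, stop_gain_variants = [], []
    used_positions = set()

    n_missense = cfg.n_causal_snps - cfg.n_stop_gain_causal
    host_pool = [g for g in coding if g.gene_id not in set(network_genes)]
    hosts = rng_geno.choice(len(host_pool), size=cfg.n_causal_snps, replace=False) \
        if cfg.n_causal_snps else []
    for k, host_i in enumerate(hosts):
        gene = host_pool[int(host_i)]
        template = STOP_TEMPLATE if k < cfg.n_stop_gain_causal else MISSENSE_TEMPLATE
        codon_index = int(rng_geno.integers(10, CDS_LEN // 3 - 10))
        chrom, pos1, ref, alt = _plant_codon_variant(
            gene, annotation.sequences, codon_index, template)
        used_positions.add((chrom, pos1))
        p_lo = rng_geno.uniform(0.05, 0.2)
        gap = rng_geno.uniform(0.5, 0.65)
        fa, fb = (p_lo, min(p_lo + gap, 0.92))
        if rng_geno.random() < 0.5:
            fa, fb = fb, fa
        freqs = np.where(group_of == gA, fa,
                         np.where(group_of == gB, fb, (fa + fb) / 2.0))
        for _ in range(200):
            dos = _sample_genotype(rng_geno, freqs, cfg.genotype_missing_rate)
            if _empirical_gap(dos, idx_a, idx_b) >= 0.45:
                break
        else:
            raise ConfigurationError("n_causal_snps: failed to realize allele-frequency gap")
        variants.append((chrom, pos1, ref, alt))
        dosages.append(dos)
        causal_records.append({"chrom": chrom, "pos": pos1, "ref": ref, "alt": alt,
                               "freq_by_group": {str(gA): float(fa), str(gB): float(fb)},
                               "consequence_class": template[3]})
        if template is STOP_TEMPLATE:
            stop_gain_variants.append((chrom, pos1, ref, alt))

    nuclear_chroms = [c for c in annotation.sequences if c != "ChrC"]
    n_null = cfg.n_snps - cfg.n_causal_snps
    made = 0
    while made < n_null:
        chrom = nuclear_chroms[int(rng_geno.integers(len(nuclear_chroms)))]
        pos1 = int(rng_geno.integers(1, len(annotation.sequences[chrom]) + 1))
        if (chrom, pos1) in used_positions:
            continue
        ref = annotation.sequences[chrom][pos1 - 1]
        alt = _BASES[int(rng_geno.integers(4))]
        if alt == ref:
            continue
        p0 = rng_geno.uniform(0.05, 0.5)
        freqs = np.full(cfg.n_accessions, p0)
        for _ in range(200):
            dos = _sample_genotype(rng_geno, freqs, cfg.genotype_missing_rate)
            if _empirical_gap(dos, idx_a, idx_b) < 0.35:
                break
        else:
            continue
        used_positions.add((chrom, pos1))
        variants.append((chrom, pos1, ref, alt))
        dosages.append(dos)
        made += 1

    var_df = pd.DataFrame(variants, columns=["chrom", "pos", "ref", "alt"])
    order = np.lexsort((var_df["pos"].to_numpy(), var_df["chrom"].to_numpy()))
    var_df = var_df.iloc[order].reset_index(drop=True)
    dosage_mat = np.vstack([dosages[i] for i in order]) if dosages else \
        np.zeros((0, cfg.n_accessions))
    genotypes = GenotypeMatrix(var_df, dosage_mat, list(accessions))

    # --- binding sites ---------------------------------------------------------
    sites = []
    for k, gid in enumerate(target_genes):
        gene = annotation[gid]
        start = gene.start + 150
        sites.append(BindingSite(gene.chrom, start, start + 60,
                                 score=float(rng_sites.uniform(50, 100)),
                                 fdr=float(10.0 ** rng_sites.uniform(-20, -12)),
                                 name=f"peak_{k + 1:03d}"))
    decoy_hosts = rng_sites.choice(len(coding), size=cfg.n_decoy_sites, replace=True) \
        if cfg.n_decoy_sites else []
    for k, host_i in enumerate(decoy_hosts):
        gene = coding[int(host_i)]
        start = gene.end + 500
        sites.append(BindingSite(gene.chrom, start, start + 60,
                                 score=float(rng_sites.uniform(5, 40)),
                                 fdr=float(10.0 ** rng_sites.uniform(-8, -3)),
                                 name=f"decoy_{k + 1:03d}"))

    # --- climate ---------------------------------------------------------------
    months = np.arange(cfg.months)
    shape = np.sin(2 * np.pi * months / cfg.months)
    specs = {  # variable -> (level, amplitude, within-accession noise sd)
        "srad": (15000.0, 3000.0, 200.0),
        "tavg": (10.0, 8.0, 1.0),
        "prec": (60.0, 20.0, 10.0),
        "wind": (4.0, 1.0, 0.5),
    }
    climate_rows = []
    for a in accessions:
        g = groups[a]
        for var, (level, amp, noise_sd) in specs.items():
            amp_a = amp
            if var == "srad" and g == 2:
                amp_a = amp * cfg.srad_sd_ratio
            amp_a = abs(rng_climate.normal(amp_a, 0.1 * amp_a))
            vals = level + amp_a * shape + rng_climate.normal(0, noise_sd, cfg.months)
            climate_rows.append({"accession": a, "variable": var,
                                 **{f"month_{m + 1:02d}": float(v)
                                    for m, v in enumerate(vals)}})
    climate = pd.DataFrame(climate_rows)

    # --- photosynthesis --------------------------------------------------------
    photo_base = {"QY_max": (0.80, 0.02), "NPQ_Lss": (1.2, 0.15), "QY_Lss": (0.55, 0.05)}
    photo_rows = []
    for a in accessions:
        g = groups[a]
        for cond in ("coastal", "inland"):
            for param, (mu0, sd0) in photo_base.items():
                val = rng_photo.normal(mu0, sd0)
                if param == "NPQ_Lss" and g == 2 and cond == "inland":
                    val += cfg.photo_interaction
                if param.startswith("QY"):
                    val = float(np.clip(val, 0.0, 1.0))
                else:
                    val = float(max(val, 0.0))
                photo_rows.append({"accession": a, "condition": cond,
                                   "parameter": param, "value": val})
    photosynthesis = pd.DataFrame(photo_rows)

    truth = TruthRecord(
        accession_groups=dict(groups),
        de_genes=de_genes,
        causal_snps=causal_records,
        planted_edges_per_group={g: list(e) for g, e in edges_per_group.items()},
        differential_edges=differential_edges,
        stop_gain_variants=stop_gain_variants,
        target_genes=list(target_genes),
        network_genes=list(network_genes),
        focal_gene=focal,
        low_depth_libraries=low_depth_libraries,
    )
    meta = {"suggested_min_reads": cfg.min_reads_hint,
            "reference_group": ref_group,
            "config": cfg.to_dict()}
    return SyntheticBundle(annotation, sites, count_matrix, genotypes,
                           climate, photosynthesis, truth, meta)
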