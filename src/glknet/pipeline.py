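"""End-to-end orchestration of the accession-stratified analysis.

Stage order mirrors the study design: candidate targets from binding sites,
count processing and normalization, biclustering into accession groups,
differential expression between the two largest groups, climate contrasts,
allelic GWAS with consequence filtering, per-group graphical Gaussian
networks over a user-supplied gene panel, differential edge comparison
around the focal gene, and photosynthesis group x condition contrasts.
Every stage reads/writes standard text formats so real data can replace any
synthetic input.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, diffexpr, expression, ggm, groupstats, gwas, io, netcompare, targets
from .errors import GlknetError, PipelineError


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run. Threshold defaults follow the
    published analysis; input paths must exist."""

    sites_path: str = ""
    gff_path: str = ""
    fasta_path: str = ""
    counts_path: str = ""
    library_map_path: str = ""
    vcf_path: str = ""
    climate_path: str = ""
    photosynthesis_path: str = ""
    panel_path: str = ""
    out_dir: str = "results"

    top_n_sites: int = 100
    site_fdr: float = 7.2e-11
    window_up: int = 1000
    window_down: int = 1000
    min_library_reads: int = 1_000_000
    k_gene_clusters: int = 3
    k_accession_clusters: int = 3
    de_fdr: float = 0.01
    de_lfc: float = 2.0
    gwas_p: float = 1e-10
    gwas_freq: float = 0.25
    edge_alpha: float = 0.05
    neighborhood_alpha: float = 0.01
    neighborhood_steps: int = 5
    edge_delta: float = 0.2
    months: int = 12
    focal_gene: str = "GLK1"
    reference_group: int = 1   # cluster ids are size-ordered; 1 = largest (A2-like)
    alternate_group: int = 2
    seed: int = 0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise GlknetError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _Report:
    def __init__(self, cfg: PipelineConfig):
        self.stages = []
        self.cfg = cfg

    def add(self, name: str, wall_time: float, **info):
        self.stages.append({"stage": name, "wall_time_s": round(wall_time, 4), **info})

    def payload(self) -> dict:
        return {"config": self.cfg.to_dict(), "config_hash": _config_hash(self.cfg),
                "seed": self.cfg.seed, "stages": self.stages}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the run report (also written as JSON)."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.write_text("run in progress\n")
    report = _Report(cfg)
    current = "setup"
    try:
        # --- targets ---------------------------------------------------------
        current = "targets"
        t0 = time.perf_counter()
        annotation = io.read_gff3(cfg.gff_path, cfg.fasta_path or None)
        sites = io.read_bed(cfg.sites_path)
        top = targets.select_top_sites(sites, cfg.top_n_sites, max_fdr=cfg.site_fdr)
        target_ids = targets.assign_sites_to_genes(
            top, annotation, cfg.window_up, cfg.window_down)
        pd.DataFrame({"gene_id": target_ids}).to_csv(
            out / "targets.tsv", sep="\t", index=False)
        report.add("targets", time.perf_counter() - t0,
                   n_sites=len(sites), n_top_sites=len(top),
                   n_target_genes=len(target_ids))

        # --- expression ------------------------------------------------------
        current = "expression"
        t0 = time.perf_counter()
        counts = io.read_counts(cfg.counts_path, cfg.library_map_path)
        n_libs0 = len(counts.library_ids)
        counts = expression.filter_genes(counts, annotation)
        n_genes_kept = len(counts.gene_ids)
        counts = expression.filter_libraries(counts, cfg.min_library_reads)
        n_libs1 = len(counts.library_ids)
        counts = expression.merge_by_accession(counts)
        norm = expression.normalize(counts)
        rel = expression.relative_expression(norm)
        io.write_expression(norm, out / "expression_normalized.tsv")
        io.write_expression(rel, out / "expression_relative.tsv")
        report.add("expression", time.perf_counter() - t0,
                   n_libraries_in=n_libs0, n_libraries_kept=n_libs1,
                   n_genes_kept=n_genes_kept, n_accessions=len(norm.accession_ids))

        # --- clustering ------------------------------------------------------
        current = "clustering"
        t0 = time.perf_counter()
        panel_targets = [g for g in target_ids if g in set(rel.gene_ids)]
        rel_targets = expression.ExpressionMatrix(
            rel.values.loc[panel_targets], scale="relative")
        gene_clusters, acc_groups, Zg, Za = clustering.hierarchical_bicluster(
            rel_targets, cfg.k_gene_clusters, cfg.k_accession_clusters,
            return_linkage=True)
        io.write_labels(gene_clusters, out / "gene_clusters.tsv", "gene_id")
        io.write_labels(acc_groups, out / "accession_groups.tsv", "accession_id")
        (out / "gene_dendrogram.nwk").write_text(
            clustering.linkage_to_newick(Zg, rel_targets.gene_ids) + "\n")
        (out / "accession_dendrogram.nwk").write_text(
            clustering.linkage_to_newick(Za, rel_targets.accession_ids) + "\n")
        report.add("clustering", time.perf_counter() - t0,
                   n_panel_genes=len(panel_targets),
                   gene_cluster_sizes=gene_clusters.sizes(),
                   accession_group_sizes=acc_groups.sizes())
        for gid in (cfg.reference_group, cfg.alternate_group):
            if gid not in acc_groups.sizes() or acc_groups.sizes()[gid] == 0:
                raise GlknetError(f"accession group {gid} absent from clustering output")

        # --- differential expression ----------------------------------------
        current = "diffexpr"
        t0 = time.perf_counter()
        de = diffexpr.differential_expression(
            norm, acc_groups, cfg.alternate_group, cfg.reference_group,
            fdr_threshold=cfg.de_fdr, lfc_threshold=cfg.de_lfc)
        io.write_table(de, out / "differential_expression.tsv",
                       index=True, index_label="gene_id")
        n_sig = int(de["significant"].sum())
        report.add("diffexpr", time.perf_counter() - t0, n_genes=len(de),
                   n_significant=n_sig,
                   n_up_in_alternate=int((de["significant"] & (de["log2fc"] > 0)).sum()),
                   n_up_in_reference=int((de["significant"] & (de["log2fc"] < 0)).sum()))

        # --- climate ---------------------------------------------------------
        current = "climate"
        t0 = time.perf_counter()
        climate = io.read_climate(cfg.climate_path)
        clim = groupstats.climate_group_tests(
            climate, acc_groups, cfg.alternate_group, cfg.reference_group,
            months=cfg.months)
        io.write_table(clim, out / "climate_tests.tsv")
        report.add("climate", time.perf_counter() - t0,
                   n_variables=int(clim["variable"].nunique()),
                   top_variable=f"{clim.iloc[0]['variable']}:{clim.iloc[0]['stat']}")

        # --- gwas ------------------------------------------------------------
        current = "gwas"
        t0 = time.perf_counter()
        genotypes = io.read_vcf(cfg.vcf_path)
        assoc = gwas.allelic_chisq(genotypes, acc_groups,
                                   cfg.alternate_group, cfg.reference_group)
        assoc = gwas.annotate_consequences(assoc, annotation)
        candidates, cascade = gwas.filter_variants(
            assoc, p_threshold=cfg.gwas_p, freq_min=cfg.gwas_freq)
        io.write_table(assoc, out / "gwas_association.tsv")
        io.write_table(candidates, out / "gwas_candidates.tsv")
        report.add("gwas", time.perf_counter() - t0, **cascade)

        # --- ggm per group ---------------------------------------------------
        current = "ggm"
        t0 = time.perf_counter()
        panel = io.read_gene_list(cfg.panel_path)
        networks = {}
        for gid in (cfg.reference_group, cfg.alternate_group):
            members = acc_groups.members(gid)
            sub = expression.ExpressionMatrix(
                norm.values.loc[panel, members], scale="normalized")
            net = ggm.build_network(sub, panel=panel, alpha=cfg.edge_alpha)
            networks[gid] = net
            io.write_table(net.edges, out / f"network_group{gid}_edges.tsv")
            io.write_sif(net.edges, out / f"network_group{gid}.sif")
        ref_net = networks[cfg.reference_group]
        report.add("ggm", time.perf_counter() - t0, n_panel=len(panel),
                   shrinkage={str(g): round(n.shrinkage, 6) for g, n in networks.items()},
                   kappa={str(g): round(n.kappa, 3) for g, n in networks.items()},
                   n_edges={str(g): int(len(n.edges)) for g, n in networks.items()})

        # --- netcompare ------------------------------------------------------
        current = "netcompare"
        t0 = time.perf_counter()
        if cfg.focal_gene not in ref_net.genes:
            raise GlknetError(f"focal gene {cfg.focal_gene!r} not in network panel")
        neighborhood = netcompare.extract_neighborhood(
            ref_net, cfg.focal_gene, alpha=cfg.neighborhood_alpha,
            steps=cfg.neighborhood_steps)
        diff_edges = netcompare.compare_edge_strengths(
            ref_net, networks[cfg.alternate_group], ref_net.genes,
            alpha=cfg.neighborhood_alpha, delta_threshold=cfg.edge_delta)
        pd.DataFrame({"gene_id": sorted(neighborhood)}).to_csv(
            out / "neighborhood.tsv", sep="\t", index=False)
        io.write_table(diff_edges, out / "differential_edges.tsv")
        sub = diff_edges[diff_edges["gene_i"].isin(neighborhood)
                         & diff_edges["gene_j"].isin(neighborhood)]
        io.write_sif(sub, out / "neighborhood.sif")
        report.add("netcompare", time.perf_counter() - t0,
                   n_neighborhood=len(neighborhood),
                   n_compared_edges=len(diff_edges),
                   n_flagged=int(diff_edges["flagged"].sum()))

        # --- photosynthesis --------------------------------------------------
        current = "photosynthesis"
        t0 = time.perf_counter()
        photo = io.read_photosynthesis(cfg.photosynthesis_path)
        photo_tests = groupstats.photosynthesis_group_tests(
            photo, acc_groups, (cfg.alternate_group, cfg.reference_group))
        io.write_table(photo_tests, out / "photosynthesis_tests.tsv")
        report.add("photosynthesis", time.perf_counter() - t0,
                   n_tests=len(photo_tests))
    except GlknetError as exc:
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    payload = report.payload()
    (out / "run_report.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    marker.unlink()
    return payload


def run_synthetic_study(gen_config, workdir, **overrides) -> dict:
    """Generate a synthetic bundle, write it to disk, and run the pipeline on
    the written files with thresholds adapted to the synthetic scale."""
    from .synthetic_data import generate_dataset

    workdir = Path(workdir)
    bundle = generate_dataset(gen_config)
    paths = io.write_bundle(bundle, workdir / "inputs")
    k = len(gen_config.group_sizes)
    defaults = dict(
        sites_path=paths["sites"], gff_path=paths["annotation"],
        fasta_path=paths["genome"], counts_path=paths["counts"],
        library_map_path=paths["library_map"], vcf_path=paths["vcf"],
        climate_path=paths["climate"], photosynthesis_path=paths["photosynthesis"],
        panel_path=paths["panel"], out_dir=str(workdir / "results"),
        min_library_reads=bundle.meta["suggested_min_reads"],
        k_gene_clusters=min(2, gen_config.n_target_genes),
        k_accession_clusters=k,
        focal_gene=bundle.truth.focal_gene,
        seed=gen_config.seed,
    )
    defaults.update(overrides)
    cfg = PipelineConfig(**defaults)
    return run_pipeline(cfg)
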