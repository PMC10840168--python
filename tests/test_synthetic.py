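"""Generator: determinism, planted structure, precision-matrix construction,
and lossless round-trips through the file formats."""

import numpy as np
import pytest

from glknet import (ConfigurationError, GeneratorConfig, InfeasibleEdgeSetError,
                    generate_dataset, precision_matrix_from_edges)
from glknet import io
from glknet.synthetic_data import _latent_covariance

from conftest import small_config


def _implied_pcor(omega):
    d = np.sqrt(np.diag(omega))
    p = -omega / np.outer(d, d)
    np.fill_diagonal(p, 1.0)
    return p


class TestPrecisionMatrix:
    def test_empty_edge_set_gives_identity(self):
        assert np.array_equal(precision_matrix_from_edges(["a", "b", "c"], []), np.eye(3))

    def test_single_edge_implied_pcor(self):
        omega = precision_matrix_from_edges(["a", "b", "c"], [("a", "b", 0.5)])
        # independent oracle: invert the covariance and re-standardize
        sigma = np.linalg.inv(omega)
        omega_back = np.linalg.inv(sigma)
        pc = _implied_pcor(omega_back)
        assert pc[0, 1] == pytest.approx(0.5, abs=1e-6)
        assert pc[0, 2] == pytest.approx(0.0, abs=1e-6)
        assert pc[1, 2] == pytest.approx(0.0, abs=1e-6)

    def test_strong_chain_is_infeasible_never_non_pd(self):
        genes = list("abcd")
        edges = [("a", "b", 0.99), ("b", "c", 0.99), ("c", "d", 0.99)]
        try:
            omega = precision_matrix_from_edges(genes, edges)
        except InfeasibleEdgeSetError:
            return
        assert np.linalg.eigvalsh(omega)[0] > 0

    def test_rejects_pcor_at_one(self):
        with pytest.raises(ConfigurationError):
            precision_matrix_from_edges(["a", "b"], [("a", "b", 1.0)])

    def test_sampled_data_recovers_planted_pcor(self):
        """MVN samples from the implied covariance re-estimate the planted
        partial correlations within 0.05 mean absolute error at n=2000."""
        from glknet.ggm import build_network

        genes = [f"g{i}" for i in range(8)]
        edges = [("g0", "g1", 0.5), ("g2", "g3", -0.4)]
        cov = _latent_covariance(precision_matrix_from_edges(genes, edges))
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(42 + seed)
            x = rng.multivariate_normal(np.zeros(8), cov, size=2000, method="cholesky")
            net = build_network(x, panel=genes)
            errs.append(abs(net.pcor_of("g0", "g1") - 0.5))
            errs.append(abs(net.pcor_of("g2", "g3") - (-0.4)))
        assert np.mean(errs) <= 0.05


class TestGenerator:
    def test_seeded_determinism_is_byte_identical(self, tmp_path):
        cfg = small_config(seed=3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        io.write_bundle(generate_dataset(cfg), d1)
        io.write_bundle(generate_dataset(small_config(seed=3)), d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes(), f1.name

    def test_null_planting_empties_truth(self):
        bundle = generate_dataset(small_config(
            de_log2fc=0.0, diff_edge_delta=0.0, srad_sd_ratio=1.0))
        assert bundle.truth.de_genes == {}
        assert bundle.truth.differential_edges == []

    def test_causal_variants_have_planted_frequency_gap(self):
        """Exactly the causal variants show an empirical allele-frequency gap
        >= 0.4 between the two groups (recomputed from the emitted matrix)."""
        cfg = GeneratorConfig(n_accessions=200, group_sizes=(80, 120),
                              n_snps=500, n_causal_snps=20, seed=5)
        bundle = generate_dataset(cfg)
        gm = bundle.genotypes
        groups = bundle.truth.accession_groups
        idx1 = [i for i, a in enumerate(gm.accessions) if groups[a] == 1]
        idx2 = [i for i, a in enumerate(gm.accessions) if groups[a] == 2]

        def freq(row, idx):
            sub = gm.dosages[row][idx]
            called = ~np.isnan(sub)
            return np.nansum(sub) / (2 * called.sum())

        gaps = np.array([abs(freq(i, idx1) - freq(i, idx2))
                         for i in range(gm.n_variants)])
        assert gm.dosages.shape == (500, 200)
        wide = set(map(tuple, gm.variants.loc[gaps >= 0.4, ["chrom", "pos"]].values))
        causal = {(c["chrom"], c["pos"]) for c in bundle.truth.causal_snps}
        assert wide == causal
        assert len(causal) == 20

    def test_counts_are_nonnegative_integers_with_consistent_accessions(self, small_bundle):
        b = small_bundle
        assert (b.counts.values.to_numpy() >= 0).all()
        assert b.counts.values.to_numpy().dtype.kind == "i"
        accs = set(b.truth.accession_groups)
        assert set(b.counts.accession_ids) == accs
        assert set(b.genotypes.accessions) == accs
        assert set(b.climate["accession"]) == accs
        assert set(b.photosynthesis["accession"]) == accs

    def test_planted_edges_reference_panel_and_deltas(self, small_bundle):
        truth = small_bundle.truth
        panel = set(truth.network_genes)
        for edges in truth.planted_edges_per_group.values():
            for gi, gj, _ in edges:
                assert gi in panel and gj in panel
        delta = small_bundle.meta["config"]["diff_edge_delta"]
        for _, _, d in truth.differential_edges:
            assert abs(d) >= delta

    @pytest.mark.parametrize("overrides, field", [
        (dict(group_sizes=(10, 10)), "group_sizes"),
        (dict(n_causal_snps=999), "n_causal_snps"),
        (dict(nb_dispersion=0.0), "nb_dispersion"),
        (dict(low_depth_fraction=0.1, libs_per_accession=1), "libs_per_accession"),
        (dict(srad_sd_ratio=0.5), "srad_sd_ratio"),
    ])
    def test_invalid_config_names_offending_field(self, overrides, field):
        with pytest.raises(ConfigurationError, match=field):
            generate_dataset(small_config(**overrides))


class TestRoundTrip:
    def test_bundle_round_trips_losslessly(self, small_bundle, tmp_path):
        b = small_bundle
        paths = io.write_bundle(b, tmp_path)
        ann = io.read_gff3(paths["annotation"], paths["genome"])
        assert ann.genes == b.annotation.genes
        assert ann.sequences == b.annotation.sequences
        assert io.read_bed(paths["sites"]) == b.sites
        counts = io.read_counts(paths["counts"], paths["library_map"])
        assert counts.values.equals(b.counts.values)
        assert counts.library_to_accession == b.counts.library_to_accession
        gm = io.read_vcf(paths["vcf"])
        assert gm.variants.equals(b.genotypes.variants)
        assert np.array_equal(gm.dosages, b.genotypes.dosages, equal_nan=True)
        assert gm.accessions == b.genotypes.accessions
        clim = io.read_climate(paths["climate"])
        np.testing.assert_allclose(
            clim.select_dtypes("number").to_numpy(),
            b.climate.select_dtypes("number").to_numpy(), rtol=1e-9)
        truth = io.read_truth(paths["truth"])
        assert truth.accession_groups == b.truth.accession_groups
        assert truth.de_genes == b.truth.de_genes
        assert truth.differential_edges == b.truth.differential_edges
        assert truth.stop_gain_variants == b.truth.stop_gain_variants
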