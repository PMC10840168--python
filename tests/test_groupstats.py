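"""Climate summaries, Welch group tests, over-representation."""

import numpy as np
import pandas as pd
import pytest

from glknet import (GlknetError, Labeling, generate_dataset, group_ttest,
                    monthly_summary, overrepresentation)
from glknet.groupstats import climate_group_tests, photosynthesis_group_tests

from conftest import small_config


def climate_row(accession, variable, values):
    return {"accession": accession, "variable": variable,
            **{f"month_{m + 1:02d}": v for m, v in enumerate(values)}}


class TestMonthlySummary:
    def test_constant_months_have_zero_sd(self):
        df = pd.DataFrame([climate_row("a1", "tavg", [5.0] * 12)])
        out = monthly_summary(df)
        assert out["sd"].iloc[0] == 0.0
        assert out["mean"].iloc[0] == 5.0

    def test_one_to_twelve(self):
        df = pd.DataFrame([climate_row("a1", "srad", list(range(1, 13)))])
        out = monthly_summary(df)
        assert out["mean"].iloc[0] == pytest.approx(6.5)
        assert out["sd"].iloc[0] == pytest.approx(np.sqrt(13))

    def test_wrong_month_count_raises(self):
        df = pd.DataFrame([climate_row("a1", "srad", list(range(1, 13)))])
        with pytest.raises(GlknetError):
            monthly_summary(df, months=6)

    def test_sd_translation_invariant_and_scale_linear(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 3, 12)
        base = monthly_summary(pd.DataFrame([climate_row("a", "v", vals)]))
        shifted = monthly_summary(pd.DataFrame([climate_row("a", "v", vals + 100)]))
        scaled = monthly_summary(pd.DataFrame([climate_row("a", "v", vals * 2.5)]))
        assert shifted["sd"].iloc[0] == pytest.approx(base["sd"].iloc[0])
        assert scaled["sd"].iloc[0] == pytest.approx(2.5 * base["sd"].iloc[0])


def welch_oracle(a, b):
    """Brute-force Welch test straight from the formulas."""
    from scipy.stats import t as tdist

    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * tdist.sf(abs(t), df)


class TestGroupTTest:
    def _groups(self, n_a, n_b):
        labels = {f"x{i}": 1 for i in range(n_a)}
        labels |= {f"y{i}": 2 for i in range(n_b)}
        return Labeling(labels, 2)

    def test_identical_groups_are_null(self):
        vals = {"x0": 1.0, "x1": 2.0, "x2": 3.0, "y0": 1.0, "y1": 2.0, "y2": 3.0}
        res = group_ttest(vals, self._groups(3, 3), 1, 2)
        assert res["t_stat"] == 0.0
        assert res["p_value"] == 1.0

    def test_perfect_separation_is_degenerate_small_p(self):
        vals = {f"x{i}": 0.0 for i in range(4)} | {f"y{i}": 10.0 for i in range(4)}
        res = group_ttest(vals, self._groups(4, 4), 1, 2)
        assert res["p_value"] < 1e-12

    def test_matches_brute_force_welch(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(3, 15))
            b = rng.normal(0.5, 2, rng.integers(3, 15))
            vals = {f"x{i}": v for i, v in enumerate(a)}
            vals |= {f"y{i}": v for i, v in enumerate(b)}
            res = group_ttest(vals, self._groups(len(a), len(b)), 1, 2)
            t, p = welch_oracle(a, b)
            assert res["t_stat"] == pytest.approx(t, abs=1e-12)
            assert res["p_value"] == pytest.approx(p, abs=1e-12)

    def test_accessions_without_values_are_dropped(self):
        vals = {"x0": 1.0, "x1": 2.0, "y0": 3.0, "y1": 4.0}
        groups = self._groups(3, 2)  # x2 has no value
        res = group_ttest(vals, groups, 1, 2)
        assert res["n_a"] == 2 and res["n_b"] == 2


class TestClimateRanking:
    def test_solar_radiation_sd_ranks_first_across_seeds(self):
        hits = 0
        for seed in range(10):
            bundle = generate_dataset(small_config(seed=700 + seed, n_genes=40,
                                                   n_target_genes=5,
                                                   n_network_genes=6,
                                                   n_snps=10, n_causal_snps=2,
                                                   n_stop_gain_causal=1,
                                                   n_noncoding_genes=2,
                                                   n_organellar_genes=2))
            groups = Labeling(bundle.truth.accession_groups, 2)
            out = climate_group_tests(bundle.climate, groups, 1, 2)
            if (out.iloc[0]["variable"], out.iloc[0]["stat"]) == ("srad", "sd"):
                hits += 1
        assert hits >= 9


class TestPhotosynthesis:
    def test_planted_interaction_only_in_group_two(self):
        bundle = generate_dataset(small_config(seed=61, n_accessions=120,
                                               group_sizes=(50, 70)))
        groups = Labeling(bundle.truth.accession_groups, 2)
        out = photosynthesis_group_tests(bundle.photosynthesis, groups, (1, 2))
        npq = out[out["parameter"] == "NPQ_Lss"].set_index("group")
        assert npq.loc[2, "p_value"] < 1e-4
        assert npq.loc[1, "p_value"] > 0.01
        qy = out[out["parameter"] == "QY_max"].set_index("group")
        assert (qy["p_value"] > 0.01).all()

    def test_paired_mode_runs(self):
        bundle = generate_dataset(small_config(seed=62))
        groups = Labeling(bundle.truth.accession_groups, 2)
        out = photosynthesis_group_tests(bundle.photosynthesis, groups, (2,),
                                         paired=True)
        assert len(out) == 3


class TestOverrepresentation:
    def test_exact_hypergeometric_five_of_five(self):
        universe = [f"i{k}" for k in range(10)]
        cats = {i: ("L" if k < 5 else "M") for k, i in enumerate(universe)}
        out = overrepresentation(universe[:5], universe, cats)
        row = out.set_index("label").loc["L"]
        assert row["p_hypergeom"] == pytest.approx(1 / 252)

    def test_selected_equals_universe_gives_p_one(self):
        universe = [f"i{k}" for k in range(8)]
        cats = {i: "L" for i in universe[:3]}
        out = overrepresentation(universe, universe, cats)
        np.testing.assert_allclose(out["p_hypergeom"], 1.0)

    def test_empty_selection_raises(self):
        with pytest.raises(GlknetError):
            overrepresentation([], {"a"}, {})

    def test_stray_selection_raises(self):
        with pytest.raises(GlknetError):
            overrepresentation({"q"}, {"a"}, {})
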