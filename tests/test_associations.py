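"""Correlation tables, deviation fractions, codon association, importance."""

import numpy as np
import pytest
from scipy import stats

import wcvr
from wcvr.associations import AssociationError, fisher_z_ci

from conftest import kendall_tau_b_oracle, make_panel


@pytest.fixture(scope="module")
def small_harmonized():
    cfg = wcvr.SimulationConfig(n_cohorts=2, n_controls=4, n_cases=20,
                                n_replicates=2, seed=6)
    panel = wcvr.generate_cohorts(cfg)
    return panel, wcvr.harmonize(panel, rescale=False)


class TestCorrelations:
    def test_affine_peptide_gives_perfect_correlations(self):
        rows = []
        for i in range(6):
            rows.append({"sample_id": f"c{i}", "group": "control",
                         "values": [1, 1, 1, 1, 1]})
        for i in range(8):
            aao = 40.0 + 2 * i
            rows.append({"sample_id": f"x{i}", "group": "case", "aao": aao,
                         "values": [1 + 0.01 * aao, 1, 1, 1, 1]})
        table = wcvr.peptide_aao_correlations(make_panel(rows))
        row = table[(table["scope"] == "c0") & (table["peptide"] == "Ab37")]
        # Ab37 rises affinely with AAO before normalization; after dividing
        # by the total it is still strictly increasing in AAO
        assert row["kendall_tau"].iloc[0] == pytest.approx(1.0)
        assert row["pearson_rho"].iloc[0] > 0.99

    def test_reversed_ranking_gives_tau_minus_one(self):
        rows = [{"sample_id": f"c{i}", "group": "control",
                 "values": [1, 1, 1, 1, 1]} for i in range(3)]
        for i in range(6):
            rows.append({"sample_id": f"x{i}", "group": "case",
                         "aao": 60.0 - i,
                         "values": [1 + 0.1 * i, 1, 1, 1, 1]})
        table = wcvr.peptide_aao_correlations(make_panel(rows))
        row = table[(table["scope"] == "c0") & (table["peptide"] == "Ab37")]
        assert row["kendall_tau"].iloc[0] == pytest.approx(-1.0)

    def test_kendall_matches_pair_counting_oracle(self, small_harmonized):
        panel, harmonized = small_harmonized
        table = wcvr.peptide_aao_correlations(panel)
        carriers = harmonized.carriers()
        for p in wcvr.PEPTIDES:
            ours = table[(table["scope"] == "all")
                         & (table["peptide"] == p)]["kendall_tau"].iloc[0]
            oracle = kendall_tau_b_oracle(
                carriers[p].to_numpy(), carriers["aao_years"].to_numpy())
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_fisher_ci_brackets_rho_and_clamps(self):
        lo, hi = fisher_z_ci(0.5, 30)
        assert lo < 0.5 < hi
        assert fisher_z_ci(1.0, 30) == (1.0, 1.0)
        lo, hi = fisher_z_ci(-0.999, 1000)
        assert -1 <= lo < -0.99


class TestDeviationProportions:
    def test_fractions_sum_to_one(self, small_harmonized):
        _, harmonized = small_harmonized
        table = wcvr.deviation_proportions(harmonized)
        np.testing.assert_allclose(
            table[["below", "above", "at"]].sum(axis=1), 1.0, atol=1e-12)

    def test_all_below(self):
        rows = [{"sample_id": "c", "group": "control", "values": [1] * 5},
                {"sample_id": "x", "group": "case", "aao": 50.0,
                 "values": [0.5, 0.5, 0.5, 2.0, 2.0]}]
        h = wcvr.HarmonizedPanel(make_panel(rows).data)
        table = wcvr.deviation_proportions(h).set_index("peptide")
        assert table.loc["Ab37", "below"] == 1.0
        assert table.loc["Ab42", "above"] == 1.0

    def test_exactly_one_counts_as_neither(self):
        rows = [{"sample_id": "c", "group": "control", "values": [1] * 5},
                {"sample_id": "x", "group": "case", "aao": 50.0,
                 "values": [1.0, 0.5, 0.5, 2.0, 2.0]}]
        h = wcvr.HarmonizedPanel(make_panel(rows).data)
        table = wcvr.deviation_proportions(h).set_index("peptide")
        assert table.loc["Ab37", "below"] == 0.0
        assert table.loc["Ab37", "above"] == 0.0
        assert table.loc["Ab37", "at"] == 1.0

    def test_no_cases_is_error(self):
        rows = [{"sample_id": "c", "group": "control", "values": [1] * 5}]
        with pytest.raises(AssociationError):
            wcvr.deviation_proportions(wcvr.HarmonizedPanel(make_panel(rows).data))


class TestMutationPosition:
    def test_monotone_codon_aao_map_gives_tau_one(self):
        rows = [{"sample_id": "c", "group": "control", "values": [1] * 5}]
        for i in range(6):
            rows.append({"sample_id": f"x{i}", "group": "case",
                         "codon": 100 + 10 * i, "aao": 40.0 + i,
                         "values": [1, 1, 1, 1 + 0.1 * i, 1]})
        out = wcvr.mutation_position_association(
            wcvr.HarmonizedPanel(make_panel(rows).data))
        assert out["aao"].kendall_tau == pytest.approx(1.0)
        assert out["aao"].df == 4

    def test_constant_codon_is_degenerate(self):
        rows = [{"sample_id": "c", "group": "control", "values": [1] * 5}]
        for i in range(5):
            rows.append({"sample_id": f"x{i}", "group": "case", "codon": 150,
                         "aao": 40.0 + i, "values": [1, 1, 1, 1, 1]})
        with pytest.raises(AssociationError):
            wcvr.mutation_position_association(
                wcvr.HarmonizedPanel(make_panel(rows).data))

    def test_null_codon_gives_small_tau(self):
        cfg = wcvr.SimulationConfig(n_cohorts=1, n_controls=3, n_cases=100,
                                    n_replicates=1, seed=0)
        h = wcvr.harmonize(wcvr.generate_cohorts(cfg), rescale=False)
        out = wcvr.mutation_position_association(h)
        assert abs(out["aao"].kendall_tau) < 0.2


class TestWeightDistribution:
    def test_single_replicate_reduces_to_search(self, small_harmonized):
        _, harmonized = small_harmonized
        rescaled = wcvr.rescale_to_reference(harmonized)
        cfg = wcvr.SearchConfig(objective="R", population_size=20,
                                generations=15, n_restarts=1, seed=0,
                                polish=False)
        dist = wcvr.bootstrap_weight_distribution(rescaled, cfg, n_boot=2,
                                                  restarts=1, seed=1)
        assert dist.n_replicates == 2
        assert set(dist.weights.columns) == set(wcvr.PEPTIDES)
        for _, row in dist.weights.iterrows():
            assert (row > 0).any() and (row < 0).any()

    def test_sign_consistency_on_planted_data(self, noise_free_planted):
        _, h = noise_free_planted
        cfg = wcvr.SearchConfig(objective="R", population_size=30,
                                generations=25, n_restarts=1, seed=0)
        dist = wcvr.bootstrap_weight_distribution(h, cfg, n_boot=8,
                                                  restarts=1, seed=2)
        cons = dist.sign_consistency()
        assert cons["Ab42"] >= 0.95
        sides = np.sign(dist.weights["Ab42"].to_numpy())
        assert (sides[sides != 0] < 0).all()


class TestGridSearch:
    def test_zero_weights_reduce_to_baseline(self, small_harmonized):
        _, harmonized = small_harmonized
        rescaled = wcvr.rescale_to_reference(harmonized)
        table = wcvr.grid_search_weights(rescaled, objective="R", step=0.5)
        base_spec = wcvr.RatioSpec("b", numerator={"Ab40": 1.0},
                                   denominator={"Ab42": 1.0})
        carriers = rescaled.is_case & np.isfinite(rescaled.aao)
        scores = wcvr.compute_ratio(base_spec, rescaled).scores
        expected = wcvr.pearson_r2_vs_aao(scores[carriers],
                                          rescaled.aao[carriers])
        zero_rows = table[table["weight"] == 0.0]
        np.testing.assert_allclose(zero_rows["value"], expected, atol=1e-12)

    def test_axis_has_51_points_at_default_step(self, small_harmonized):
        _, harmonized = small_harmonized
        rescaled = wcvr.rescale_to_reference(harmonized)
        table = wcvr.grid_search_weights(rescaled, objective="P", step=0.02)
        sub = table[(table["peptide"] == "Ab38") & (table["side"] == "num")]
        assert len(sub) == 51

    def test_invalid_step_rejected(self, small_harmonized):
        _, harmonized = small_harmonized
        with pytest.raises(AssociationError):
            wcvr.grid_search_weights(harmonized, step=0.0)


class TestPermutationImportance:
    def test_zero_weight_peptides_have_zero_importance(self, small_harmonized):
        _, harmonized = small_harmonized
        spec = wcvr.RatioSpec("Ab42/40", numerator={"Ab42": 1.0},
                              denominator={"Ab40": 1.0})
        table = wcvr.permutation_importance(spec, harmonized, n_perm=5,
                                            seed=0).set_index("peptide")
        for p in ("Ab37", "Ab38", "Ab43"):
            assert (table.loc[p] == 0.0).all()
        assert np.isfinite(table.to_numpy()).all()

    def test_signal_carrying_peptide_dominates(self):
        """When only Ab42 separates cases from controls, permuting it hurts
        the most."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(10):
            rows.append({"sample_id": f"c{i}", "group": "control",
                         "values": np.abs(rng.normal(1, 0.05, 5))})
        for i in range(30):
            v = np.abs(rng.normal(1, 0.05, 5))
            v[3] = rng.normal(3, 0.1)  # Ab42 strongly shifted
            rows.append({"sample_id": f"x{i}", "group": "case",
                         "aao": rng.uniform(40, 60), "values": v})
        h = wcvr.HarmonizedPanel(make_panel(rows).data)
        spec = wcvr.short_long_spec()
        table = wcvr.permutation_importance(
            spec, h, metrics=("roc_auc",), n_perm=30, seed=1
        ).set_index("peptide")
        assert table.loc["Ab42", "roc_auc"] == table["roc_auc"].max()
        assert table.loc["Ab42", "roc_auc"] > 0
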