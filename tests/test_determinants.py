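"""Covariate assembly, correlations, group tests and mixed models."""

import numpy as np
import pandas as pd
import pytest

from strainmatch import (
    MixedModelSpec,
    alpha_threshold_summary,
    bray_curtis,
    build_covariate_table,
    category_difference_covariates,
    correlation_with_fit,
    fit_mixed_models,
    full_model_spec,
    group_tests,
    per_category_difference_model,
    reduced_model_spec,
    shannon_index,
    wilcoxon_rank_sum,
)


def simulate_pairings(
    n_donors=10,
    n_recipients=15,
    b_pb=0.0,
    donor_sd=2.0,
    noise_sd=1.0,
    seed=0,
):
    """Covariate table with a known efficiency-generating process."""
    rng = np.random.default_rng(seed)
    donors = [f"D{i}" for i in range(n_donors)]
    recipients = [f"R{i}" for i in range(n_recipients)]
    donor_eff = rng.normal(0, donor_sd, n_donors)
    rows = []
    for j, r in enumerate(recipients):
        for i, d in enumerate(donors):
            pb = rng.uniform(0.1, 3.0)
            rows.append(
                {
                    "donor_id": d,
                    "recipient_id": r,
                    "donor_pb_mean": pb,
                    "recipient_pb": rng.uniform(0.1, 3.0),
                    "donor_alpha_mean": rng.uniform(1.5, 3.5),
                    "recipient_alpha_baseline": rng.uniform(1.0, 3.0),
                    "bc_species_mean": rng.uniform(0.2, 0.9),
                    "jaccard_species_mean": rng.uniform(0.3, 0.95),
                    "bc_functional_mean": rng.uniform(0.01, 0.2),
                    "batch_size": 4,
                    "efficiency": 10.0
                    + b_pb * pb
                    + donor_eff[i]
                    + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


class TestCovariateTable:
    def _fixture(self):
        roster = pd.DataFrame(
            {
                "sample_id": ["D1_S1", "D1_S2", "R1_BL", "R1_W8"],
                "subject_id": ["D1", "D1", "R1", "R1"],
                "role": ["donor", "donor", "fmt_recipient", "fmt_recipient"],
                "timepoint": ["donation", "donation", "baseline", "post"],
                "read_count": 1,
            }
        )
        abundance = pd.DataFrame(
            {
                "Prevotella_a": [0.2, 0.1, 0.05],
                "Bacteroides_b": [0.1, 0.2, 0.25],
                "Genus_c": [0.5, 0.5, 0.5],
                "UNKNOWN": [0.2, 0.2, 0.2],
            },
            index=pd.Index(["D1_S1", "D1_S2", "R1_BL"], name="sample_id"),
        )
        eff = pd.DataFrame(
            [{"donor": "D1", "recipient": "R1", "efficiency": 25.0}]
        )
        return roster, abundance, eff

    def test_donor_means_and_pairwise_dissimilarity(self):
        roster, abundance, eff = self._fixture()
        table = build_covariate_table(
            eff, abundance, None, roster, {"R1": {"D1"}}
        )
        assert len(table) == 1
        row = table.iloc[0]
        species = ["Prevotella_a", "Bacteroides_b", "Genus_c"]
        expected_alpha = np.mean(
            [
                shannon_index(abundance.loc[s, species].to_numpy())
                for s in ["D1_S1", "D1_S2"]
            ]
        )
        assert row["donor_alpha_mean"] == pytest.approx(expected_alpha)
        # dissimilarities averaged per donor sample, not on mean profiles
        expected_bc = np.mean(
            [
                bray_curtis(
                    abundance.loc[s, species].to_numpy(),
                    abundance.loc["R1_BL", species].to_numpy(),
                )
                for s in ["D1_S1", "D1_S2"]
            ]
        )
        assert row["bc_species_mean"] == pytest.approx(expected_bc)
        assert row["donor_pb_mean"] == pytest.approx(np.mean([2.0, 0.5]))
        assert row["recipient_pb"] == pytest.approx(0.2)
        assert row["efficiency"] == 25.0
        assert row["batch_size"] == 1

    def test_row_order_invariance(self):
        roster, abundance, eff = self._fixture()
        a = build_covariate_table(eff, abundance, None, roster, {"R1": {"D1"}})
        b = build_covariate_table(
            eff.iloc[::-1],
            abundance.iloc[::-1],
            None,
            roster.iloc[::-1],
            {"R1": {"D1"}},
        )
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_pairing_sample_raises(self):
        roster, abundance, eff = self._fixture()
        with pytest.raises(ValueError):
            build_covariate_table(
                eff, abundance, None, roster, {"R9": {"D1"}}
            )

    def test_cohort_batch_sizes_match_pools(self, clean_cohort):
        eff = pd.DataFrame(
            [
                {"donor": d, "recipient": r, "efficiency": 0.0}
                for r, ds in clean_cohort.truth.true_pairings.items()
                for d in ds
            ]
        )
        table = build_covariate_table(
            eff,
            clean_cohort.abundance,
            None,
            clean_cohort.roster,
            clean_cohort.truth.true_pairings,
        )
        pools = clean_cohort.truth.true_pairings
        for _, row in table.iterrows():
            assert row["batch_size"] == len(pools[row["recipient_id"]])


class TestCorrelation:
    def test_exact_linear_relation(self):
        res = correlation_with_fit([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_three_point_hand_value(self):
        res = correlation_with_fit([0, 1, 2], [0, 1, 4])
        assert res.r == pytest.approx(0.9608, abs=5e-5)
        assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)

    def test_independent_large_sample_near_zero(self):
        rng = np.random.default_rng(3)
        res = correlation_with_fit(
            rng.normal(size=1000), rng.normal(size=1000)
        )
        assert abs(res.r) < 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlation_with_fit([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            correlation_with_fit([1, 2], [1, 2])


class TestGroupTests:
    def test_wilcoxon_exact_small_sample(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [101, 102, 103], method="exact")
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("method", ["kruskal", "anova"])
    def test_shifted_group_flagged_in_posthoc(self, method):
        rng = np.random.default_rng(4)
        groups = {g: rng.normal(0, 1, 12) for g in "abc"}
        groups["d"] = rng.normal(10, 1, 12)
        res = group_tests(groups, method=method)
        assert res.p_value < 0.001
        flagged = res.posthoc[res.posthoc["p_adjusted"] < 0.05]
        pairs = set(map(frozenset, zip(flagged["group_a"], flagged["group_b"])))
        expected = {frozenset({g, "d"}) for g in "abc"}
        assert pairs == expected

    def test_validation(self):
        with pytest.raises(ValueError):
            group_tests({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            group_tests({"a": [1.0], "b": []})


class TestMixedModels:
    def test_reduced_equal_full_gives_lrt_one(self):
        table = simulate_pairings(seed=1)
        spec = reduced_model_spec()
        _, _, lrt_p = fit_mixed_models(table, spec, spec)
        assert lrt_p == 1.0

    def test_interaction_members_validated(self):
        with pytest.raises(ValueError, match="interaction"):
            MixedModelSpec(fixed_effects=["a"], interactions=[("a", "b")])

    def test_known_effect_recovered_single_seed(self):
        table = simulate_pairings(b_pb=5.0, seed=2)
        spec = MixedModelSpec(fixed_effects=["donor_pb_mean"])
        null = MixedModelSpec(fixed_effects=[])
        full, _, lrt_p = fit_mixed_models(table, spec, null)
        row = full.effects.set_index("effect").loc["donor_pb_mean"]
        assert row["ci_low"] <= 5.0 <= row["ci_high"]
        assert row["p_value"] < 1e-6 and lrt_p < 1e-6

    def test_full_and_reduced_specs_run_on_simulated_table(self):
        table = simulate_pairings(seed=3)
        full, red, lrt_p = fit_mixed_models(
            table, full_model_spec(False), reduced_model_spec(False)
        )
        assert 0.0 < lrt_p <= 1.0
        assert len(full.effects) == len(red.effects) + 2
        assert (full.effects["ci_low"] <= full.effects["estimate"]).all()
        assert (full.effects["estimate"] <= full.effects["ci_high"]).all()

    def test_nonfinite_covariates_dropped(self):
        table = simulate_pairings(seed=4)
        table.loc[0, "donor_pb_mean"] = np.inf
        spec = MixedModelSpec(fixed_effects=["donor_pb_mean"])
        full, _, _ = fit_mixed_models(table, spec, MixedModelSpec([]))
        assert full.n_obs == len(table) - 1


class TestCategoryDifferences:
    def _setup(self, shift=0.0):
        roster = pd.DataFrame(
            {
                "sample_id": ["D1_S1", "R1_BL", "R1_W8"],
                "subject_id": ["D1", "R1", "R1"],
                "role": ["donor", "fmt_recipient", "fmt_recipient"],
                "timepoint": ["donation", "baseline", "post"],
                "read_count": 1,
            }
        )
        functional = pd.DataFrame(
            {
                "C": [0.5 + shift, 0.5],
                "E": [0.5 - shift, 0.5],
            },
            index=pd.Index(["D1_S1", "R1_BL"], name="sample_id"),
        )
        table = pd.DataFrame(
            [
                {
                    "donor_id": "D1",
                    "recipient_id": "R1",
                    "efficiency": 10.0,
                }
            ]
        )
        return table, functional, roster

    def test_identical_profiles_zero_differences(self):
        table, functional, roster = self._setup(shift=0.0)
        cov = category_difference_covariates(table, functional, roster)
        assert cov["cat_C"].iloc[0] == pytest.approx(0.0)
        assert cov["cat_E"].iloc[0] == pytest.approx(0.0)

    def test_single_category_shift_isolated(self):
        table, functional, roster = self._setup(shift=0.1)
        cov = category_difference_covariates(table, functional, roster)
        assert cov["cat_C"].iloc[0] == pytest.approx(0.1)
        assert cov["cat_E"].iloc[0] == pytest.approx(-0.1)

    def test_simulated_category_effect_recovered(self):
        rng = np.random.default_rng(5)
        donors = [f"D{i}" for i in range(8)]
        recipients = [f"R{i}" for i in range(12)]
        rows, froster, fprof = [], [], {}
        for d in donors:
            fprof[f"{d}_S1"] = rng.dirichlet(np.ones(3))
            froster.append((f"{d}_S1", d, "donor", "donation"))
        for r in recipients:
            fprof[f"{r}_BL"] = rng.dirichlet(np.ones(3))
            froster.append((f"{r}_BL", r, "fmt_recipient", "baseline"))
        roster = pd.DataFrame(
            froster, columns=["sample_id", "subject_id", "role", "timepoint"]
        )
        roster["read_count"] = 1
        functional = pd.DataFrame.from_dict(
            fprof, orient="index", columns=["C", "E", "F"]
        )
        table_rows = []
        for r in recipients:
            for d in donors:
                diff_c = fprof[f"{d}_S1"][0] - fprof[f"{r}_BL"][0]
                table_rows.append(
                    {
                        "donor_id": d,
                        "recipient_id": r,
                        "efficiency": 5.0
                        + 20.0 * diff_c
                        + rng.normal(0, 0.5),
                    }
                )
        fit = per_category_difference_model(
            pd.DataFrame(table_rows), functional, roster
        )
        row = fit.effects.set_index("effect").loc["cat_C"]
        assert row["ci_low"] <= 20.0 <= row["ci_high"]


class TestAlphaThreshold:
    def test_fractions(self):
        table = pd.DataFrame(
            {
                "donor_alpha_mean": [1.0, 2.0, 3.0, 4.0],
                "efficiency": [0.0, 0.0, 5.0, 8.0],
            }
        )
        res = alpha_threshold_summary(table, cut=2.5)
        assert res.frac_zero_below == 1.0
        assert res.frac_zero_above == 0.0
        assert (res.n_below, res.n_above) == (2, 2)

    def test_all_positive_efficiency(self):
        table = pd.DataFrame(
            {"donor_alpha_mean": [1.0, 3.0], "efficiency": [2.0, 4.0]}
        )
        res = alpha_threshold_summary(table, cut=2.5)
        assert res.frac_zero_below == res.frac_zero_above == 0.0
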