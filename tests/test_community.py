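"""Relative abundance, rarefaction, diversity, and the sensitivity
statistic."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_confrontation_table
from t6sscomp import (
    CountTable,
    SimulationConfig,
    alpha_diversity,
    cfu_detection_filter,
    prevalence_filter,
    rarefy,
    run_confrontation_experiment,
    sensitivity_score,
    sensitivity_table,
    to_relative_abundance,
)
from t6sscomp.community import ARM_DHCP, ARM_WT


def simple_table(rows, strains, meta=None):
    counts = pd.DataFrame(rows, columns=strains,
                          index=[f"s{i}" for i in range(len(rows))])
    if meta is None:
        meta = pd.DataFrame(index=counts.index)
    return CountTable(counts, meta)


class TestRelativeAbundance:
    def test_no_pseudocount_is_plain_normalization(self):
        ra = to_relative_abundance(simple_table([[2, 3, 5]], list("abc")),
                                   pseudocount=0)
        assert list(ra.counts.iloc[0]) == pytest.approx([0.2, 0.3, 0.5])

    def test_pseudocount_applied_to_expected_strains(self):
        ra = to_relative_abundance(simple_table([[0, 10]], list("ab")),
                                   pseudocount=0.5)
        assert list(ra.counts.iloc[0]) == pytest.approx([0.5 / 11, 10.5 / 11])

    def test_unexpected_strains_get_no_pseudocount(self):
        table = simple_table([[0, 10]], list("ab"))
        expected = pd.DataFrame([[False, True]], index=table.counts.index,
                                columns=list("ab"))
        ra = to_relative_abundance(table, pseudocount=0.5, expected=expected)
        assert ra.counts.iloc[0, 0] == 0.0
        assert ra.counts.iloc[0, 1] == 1.0

    def test_rows_sum_to_one(self, rng):
        table = simple_table(rng.integers(0, 100, size=(8, 5)),
                             [f"t{i}" for i in range(5)])
        ra = to_relative_abundance(table)
        assert np.allclose(ra.counts.sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_sample_named(self):
        table = simple_table([[0, 0]], list("ab"))
        with pytest.raises(ValueError, match="s0"):
            to_relative_abundance(table, pseudocount=0)


class TestRarefy:
    def test_depth_equal_to_total_keeps_counts(self):
        table = simple_table([[60, 40]], list("ab"))
        out = rarefy(table, depth=100, seed=1)
        assert list(out.counts.iloc[0]) == [60, 40]

    def test_shallow_sample_dropped_with_warning(self):
        table = simple_table([[60, 40], [10, 5]], list("ab"))
        with pytest.warns(UserWarning, match="s1"):
            out = rarefy(table, depth=100, seed=1)
        assert list(out.counts.index) == ["s0"]

    def test_rarefied_sums_exact(self, rng):
        table = simple_table(rng.integers(50, 200, size=(6, 4)),
                             [f"t{i}" for i in range(4)])
        out = rarefy(table, depth=100, seed=3)
        assert (out.counts.sum(axis=1) == 100).all()

    def test_preserves_expected_proportions(self):
        # over many seeds the mean rarefied proportion tracks the original
        table = simple_table([[500, 300, 200]], list("abc"))
        depth = 100
        props = np.array([
            rarefy(table, depth, seed=s).counts.iloc[0].to_numpy() / depth
            for s in range(200)
        ])
        p = np.array([0.5, 0.3, 0.2])
        # hypergeometric sd of the mean over 200 draws
        sd = np.sqrt(p * (1 - p) * (1000 - depth) / (999 * depth) / 200)
        assert (np.abs(props.mean(axis=0) - p) < 2 * sd + 1e-9).all()


class TestAlphaDiversity:
    def test_uniform_counts_closed_form(self):
        table = simple_table([[5, 5, 5, 5]], list("abcd"))
        assert alpha_diversity(table, "shannon").iloc[0] == \
            pytest.approx(np.log(4))
        assert alpha_diversity(table, "pielou").iloc[0] == pytest.approx(1.0)
        assert alpha_diversity(table, "richness").iloc[0] == 4

    def test_single_strain_sample(self):
        table = simple_table([[9, 0]], list("ab"))
        assert alpha_diversity(table, "richness").iloc[0] == 1
        assert alpha_diversity(table, "shannon").iloc[0] == 0.0
        assert np.isnan(alpha_diversity(table, "pielou").iloc[0])

    def test_direct_summation_oracle(self):
        counts = [1, 1, 2]
        table = simple_table([counts], list("abc"))
        p = np.array(counts) / 4
        expected = -(p * np.log(p)).sum()
        assert alpha_diversity(table, "shannon").iloc[0] == \
            pytest.approx(expected, rel=1e-12)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            alpha_diversity(simple_table([[1]], ["a"]), "simpson")


class TestPrevalenceFilter:
    def test_threshold_boundary(self):
        rows = np.zeros((10, 2), dtype=int)
        rows[0, 0] = 5                  # strain a: 1/10 samples
        rows[0, 1] = 5
        rows[1, 1] = 5                  # strain b: 2/10 samples
        table = simple_table(rows, list("ab"))
        out = prevalence_filter(table, min_prevalence=0.2)
        assert list(out.counts.columns) == ["b"]  # >= rule keeps the boundary

    def test_minimum_threshold_keeps_observed_strains(self):
        rows = [[1, 0, 0], [0, 2, 0], [0, 0, 0], [0, 0, 0]]
        table = simple_table(rows, list("abc"))
        out = prevalence_filter(table, min_prevalence=1 / 4)
        assert list(out.counts.columns) == ["a", "b"]

    def test_empty_result_allowed(self):
        table = simple_table([[0, 0], [0, 0]], list("ab"))
        out = prevalence_filter(table, 0.5)
        assert out.counts.shape[1] == 0


class TestSensitivityScore:
    def make_ra(self, wt6_x=0.05):
        values = {
            (ARM_WT, 0.0): {"X": [0.10] * 3, "Y": [0.90] * 3},
            (ARM_WT, 6.0): {"X": [wt6_x] * 3, "Y": [1 - wt6_x] * 3},
            (ARM_DHCP, 0.0): {"X": [0.10] * 3, "Y": [0.90] * 3},
            (ARM_DHCP, 6.0): {"X": [0.20] * 3, "Y": [0.80] * 3},
        }
        return make_confrontation_table(values)

    def test_worked_example_is_minus_two(self):
        score = sensitivity_score(self.make_ra(), "X", n_boot=200, seed=0)
        # log2[(0.05/0.10) / (0.20/0.10)] = log2(1/4)
        assert score.s == pytest.approx(-2.0)

    def test_identical_arms_give_exact_zero(self):
        values = {
            (arm, t): {"X": [0.3, 0.4], "Y": [0.7, 0.6]}
            for arm in (ARM_WT, ARM_DHCP) for t in (0.0, 6.0)
        }
        ra = make_confrontation_table(values)
        for strain in ("X", "Y"):
            assert sensitivity_score(ra, strain, n_boot=100, seed=1).s == 0.0

    def test_arm_swap_negates_s(self):
        ra = self.make_ra()
        swapped = ra.copy()
        swapped.meta["arm"] = swapped.meta["arm"].map(
            {ARM_WT: ARM_DHCP, ARM_DHCP: ARM_WT})
        s = sensitivity_score(ra, "X", n_boot=100, seed=0).s
        s_swapped = sensitivity_score(swapped, "X", n_boot=100, seed=0).s
        assert s_swapped == pytest.approx(-s, abs=1e-12)

    def test_invariant_under_replicate_reordering(self):
        values = {
            (ARM_WT, 0.0): {"X": [0.10, 0.12, 0.08], "Y": [0.9, 0.88, 0.92]},
            (ARM_WT, 6.0): {"X": [0.05, 0.06, 0.04], "Y": [0.95, 0.94, 0.96]},
            (ARM_DHCP, 0.0): {"X": [0.11, 0.09, 0.10], "Y": [0.89, 0.91, 0.9]},
            (ARM_DHCP, 6.0): {"X": [0.21, 0.19, 0.20], "Y": [0.79, 0.81, 0.8]},
        }
        ra = make_confrontation_table(values)
        shuffled = CountTable(ra.counts.iloc[::-1], ra.meta.iloc[::-1])
        assert sensitivity_score(shuffled, "X", n_boot=50, seed=2).s == \
            pytest.approx(sensitivity_score(ra, "X", n_boot=50, seed=2).s)

    def test_absent_strain_is_undefined(self):
        values = {
            (ARM_WT, 0.0): {"X": [0.0] * 2, "Y": [1.0] * 2},
            (ARM_WT, 6.0): {"X": [0.1] * 2, "Y": [0.9] * 2},
            (ARM_DHCP, 0.0): {"X": [0.1] * 2, "Y": [0.9] * 2},
            (ARM_DHCP, 6.0): {"X": [0.1] * 2, "Y": [0.9] * 2},
        }
        score = sensitivity_score(make_confrontation_table(values), "X",
                                  n_boot=50, seed=0)
        assert score.status == "undefined"
        assert np.isnan(score.s)

    def test_missing_cell_is_an_error(self):
        values = {
            (ARM_WT, 0.0): {"X": [0.5], "Y": [0.5]},
            (ARM_WT, 6.0): {"X": [0.5], "Y": [0.5]},
            (ARM_DHCP, 0.0): {"X": [0.5], "Y": [0.5]},
        }
        with pytest.raises(ValueError, match="both arms"):
            sensitivity_score(make_confrontation_table(values), "X", n_boot=10)

    def test_planted_killing_called_sensitive(self):
        # a heavily-killed strain gets S < 0 with CI below zero in nearly
        # every simulated experiment
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            k = np.zeros(6)
            k[3] = 1.5
            cfg = SimulationConfig(n_strains=6, killing_coeffs=k, seed=seed,
                                   seq_depth=20_000)
            table = run_confrontation_experiment(cfg)
            ra = to_relative_abundance(table)
            score = sensitivity_score(ra, cfg.strain_names[3], n_boot=200,
                                      seed=seed)
            if score.status == "sensitive":
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_ci_brackets_point_estimate(self):
        table = self.make_ra()
        score = sensitivity_score(table, "X", n_boot=500, seed=5)
        assert score.ci_low <= score.s <= score.ci_high


class TestSensitivityMonotonicity:
    def test_s_non_increasing_in_k(self):
        # deterministic dynamics (no noise): larger killing coefficient
        # never increases the sensitivity statistic
        s_values = []
        for k_val in np.linspace(0, 1.2, 7):
            k = np.full(4, 0.2)
            k[1] = k_val
            cfg = SimulationConfig(n_strains=4, killing_coeffs=k,
                                   replicate_noise_sd=0.0, n_replicates=1,
                                   seed=0)
            from t6sscomp import simulate_confrontation
            traj = simulate_confrontation(cfg)
            ra_cells = []
            for arm in (ARM_WT, ARM_DHCP):
                for t in (0.0, 6.0):
                    row = traj.at(arm, t)[0]
                    ra_cells.append(row[2] / row.sum())  # strain index 2
            wt0, wt6, dh0, dh6 = ra_cells
            s_values.append(np.log2((wt6 / wt0) / (dh6 / dh0)))
        assert all(b <= a + 1e-12 for a, b in zip(s_values, s_values[1:]))


class TestSensitivityTable:
    def test_excludes_focal_and_reports_all(self):
        cfg = SimulationConfig(n_strains=4, seed=3, seq_depth=5000)
        table = run_confrontation_experiment(cfg)
        ra = to_relative_abundance(table)
        scores = sensitivity_table(ra, n_boot=50, seed=0, focal="focal")
        assert list(scores.index) == list(cfg.strain_names)
        assert {"S", "ci_low", "ci_high", "status"} <= set(scores.columns)


class TestCfuDetectionFilter:
    def test_boundary_kept_and_below_removed(self):
        cfu = pd.DataFrame({"strain": list("abc"), "cfu": [1e2, 1e3, 5e4]})
        out = cfu_detection_filter(cfu, limit=1e3)
        assert list(out["strain"]) == ["b", "c"]

    def test_empty_input_passes_through(self):
        out = cfu_detection_filter(pd.DataFrame({"cfu": []}), limit=1e3)
        assert len(out) == 0
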