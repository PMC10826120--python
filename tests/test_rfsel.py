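"""Two-step random-forest selection: tuning, importance p-values, recovery.

The heavier simulations here run at reduced forest sizes and permutation
counts so the whole suite stays within a desktop budget; the configurations
were fixed from pilot runs before asserting.
"""

import numpy as np
import pytest

from epitrio import (
    RFConfig,
    SimulationSpec,
    auto_mtry_grid,
    importance_pvalues,
    make_parity_penetrance,
    simulate_cohort,
    tune_rf,
    two_step_select,
)


class TestAutoMtryGrid:
    def test_single_feature(self):
        assert auto_mtry_grid(1) == [1]

    def test_contains_sqrt_and_stays_in_range(self):
        grid = auto_mtry_grid(100)
        assert 10 in grid
        assert all(1 <= m <= 100 for m in grid)

    def test_large_panel_contains_sqrt_and_folds(self):
        grid = auto_mtry_grid(3767)
        assert 61 in grid  # round(sqrt(3767))
        assert all(m <= 3767 for m in grid)
        assert grid == sorted(set(grid))
        # halvings and doublings of sqrt are present
        assert {15, 31, 123, 246} <= set(grid)


def _noise_cohort(n, p, seed):
    spec = SimulationSpec(
        n_cases=n // 2, n_controls=n // 2, n_background_snps=p, seed=seed
    )
    g, labels, _ = simulate_cohort(spec)
    return g, labels


class TestTuneRF:
    def test_single_grid_point_returned(self, toy_cohort):
        g, labels = toy_cohort
        cfg = RFConfig(ntree_grid=(25,), mtry_grid=(3,), seed=1)
        mtry, ntree, err = tune_rf(g, labels, cfg)
        assert (mtry, ntree) == (3, 25)
        assert 0 <= err <= 1

    def test_noise_cv_error_near_majority_rate(self):
        errs = []
        for s in range(3):
            g, labels = _noise_cohort(200, 10, 70 + s)
            cfg = RFConfig(ntree_grid=(50,), mtry_grid=(3,), seed=s)
            errs.append(tune_rf(g, labels, cfg)[2])
        assert abs(np.mean(errs) - 0.5) < 0.1

    def test_separable_marginal_snp_learns(self):
        spec = SimulationSpec(
            n_cases=200,
            n_controls=200,
            n_background_snps=5,
            marginal_effects=[(0.3, (1.0, 10.0, 100.0))],
            seed=71,
        )
        g, labels, _ = simulate_cohort(spec)
        cfg = RFConfig(ntree_grid=(100,), mtry_grid=(3,), seed=2)
        _, _, err = tune_rf(g, labels, cfg)
        assert err < 0.35

    def test_single_class_rejected(self, toy_cohort):
        g, labels = toy_cohort
        from epitrio import CaseControlLabels

        all_ctrl = CaseControlLabels(np.zeros(g.n_individuals, dtype=np.int8))
        with pytest.raises(ValueError, match="class"):
            tune_rf(g, all_ctrl, RFConfig(ntree_grid=(10,), mtry_grid=(2,)))


class TestImportancePvalues:
    def test_add_one_formula_with_single_permutation(self):
        # feature 0 encodes the label exactly: observed importance tops any null
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 25)
        X = np.column_stack([y, rng.integers(0, 3, 50), rng.integers(0, 3, 50)])
        obs, p = importance_pvalues(
            X, y, best_mtry=1, best_ntree=30, n_perm=1, seed=3, measure="gini"
        )
        assert p[0] == pytest.approx(0.5)  # (1+0)/(1+1)
        assert np.all((p > 0) & (p <= 1))

    def test_nperm_below_one_rejected(self):
        X = np.zeros((10, 3))
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="n_perm"):
            importance_pvalues(X, y, 1, 10, n_perm=0)

    def test_type_one_calibration_on_noise(self):
        """Null SNPs: selection at 0.05 stays near its nominal rate."""
        g, labels = _noise_cohort(150, 100, 72)
        _, p = importance_pvalues(
            g, labels, best_mtry=10, best_ntree=50, n_perm=40, seed=4, measure="gini"
        )
        assert (p < 0.05).mean() <= 0.15
        assert 0.35 < p.mean() < 0.65


class TestTwoStepSelect:
    FAST = dict(ntree_grid=(25,), mtry_grid=(3,), importance_permutations=5,
                importance_measure="gini")

    def test_determinism(self, toy_cohort):
        g, labels = toy_cohort
        cfg = RFConfig(seed=5, stage1_alpha=0.9, stage2_alpha=0.9, **self.FAST)
        a = two_step_select(g, labels, cfg)
        b = two_step_select(g, labels, cfg)
        assert a.selected_ids == b.selected_ids
        np.testing.assert_array_equal(a.importance_p, b.importance_p)

    def test_stage1_alpha_one_passes_everything_to_stage2(self, toy_cohort):
        g, labels = toy_cohort
        cfg = RFConfig(seed=6, stage1_alpha=1.0, stage2_alpha=1.0, **self.FAST)
        res = two_step_select(g, labels, cfg)
        assert res.stage2 is not None
        assert res.stage1.selected_ids == g.snp_ids

    def test_sparse_stage1_skips_stage2_with_warning(self, toy_cohort):
        g, labels = toy_cohort
        cfg = RFConfig(seed=7, stage1_alpha=0.001, **self.FAST)
        with pytest.warns(UserWarning, match="stage 2 skipped"):
            res = two_step_select(g, labels, cfg)
        assert res.stage2_skipped and res.stage2 is None

    def test_fewer_than_three_snps_rejected(self, toy_cohort):
        from epitrio import subset_snps

        g, labels = toy_cohort
        with pytest.raises(ValueError, match="3"):
            two_step_select(subset_snps(g, g.snp_ids[:2]), labels, RFConfig())

    def test_recovers_planted_interaction_snps_on_small_panel(self):
        """A strong purely third-order triplet among 7 noise SNPs is selected.

        Random forests only detect pure epistasis on small panels (the
        greedy split criterion sees no first- or second-order gain), so
        this exercises the regime where the mechanism demonstrably works.
        """
        cfg = RFConfig(
            ntree_grid=(200,),
            mtry_grid=(3,),
            importance_permutations=25,
            importance_measure="permutation",
            holdout_fraction=0.3,
            seed=17,
        )
        full_recoveries = 0
        noise_picked = 0
        for s in range(3):
            spec = SimulationSpec(
                n_cases=1000,
                n_controls=1000,
                n_background_snps=7,
                planted_triplets=[make_parity_penetrance(base=0.25, effect=0.2)],
                baseline_prevalence=0.25,
                seed=900 + s,
            )
            g, labels, truth = simulate_cohort(spec)
            planted = set(truth["planted_triplets"][0])
            res = two_step_select(g, labels, cfg)
            full_recoveries += planted <= set(res.selected_ids)
            noise_picked += len(set(res.selected_ids) - planted)
        assert full_recoveries >= 2
        assert noise_picked <= 2
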