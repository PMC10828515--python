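"""Loss balancing, CAGrad, decoy negatives, splitting, and the training loop."""

import numpy as np
import pytest

from mhcgate.model import GatedMultiTaskModel, ModelConfig
from mhcgate.synthetic import SyntheticDatasetSpec, generate_dataset
from mhcgate.training import (BA, MS, LossState, TrainingConfig,
                              TrainingError, TrainingExample,
                              cagrad_direction, fit, freeze_ba_branch,
                              sample_synthetic_negatives, split_train_val,
                              uncertainty_weighted_loss)


def brute_force_cagrad(g_np, g_ba, c, n_grid=1001):
    """Independent oracle: grid search over the mixture weight, refined once
    around the coarse optimum so the oracle itself is accurate to ~1e-9."""
    g0 = 0.5 * (g_np + g_ba)
    norm_g0 = np.linalg.norm(g0)
    if c == 0 or norm_g0 == 0:
        return g0

    def objective(w):
        gw = w * g_np + (1 - w) * g_ba
        return gw @ g0 + c * norm_g0 * np.linalg.norm(gw)

    grid = np.linspace(0.0, 1.0, n_grid)
    w_best = min(grid, key=objective)
    step = 1.0 / (n_grid - 1)
    fine = np.linspace(max(0.0, w_best - step), min(1.0, w_best + step),
                       n_grid)
    w_best = min(fine, key=objective)
    best = w_best * g_np + (1 - w_best) * g_ba
    n = np.linalg.norm(best)
    return g0 if n == 0 else g0 + c * norm_g0 * best / n


class TestUncertaintyWeighting:
    def test_zero_log_variances_reduce_to_plain_sum(self):
        assert uncertainty_weighted_loss(0.7, 1.3, LossState()) == \
            pytest.approx(2.0)

    def test_monotone_in_each_task_loss(self):
        state = LossState(s_np=0.4, s_ba=-0.3)
        lo = uncertainty_weighted_loss(0.5, 1.0, state)
        hi = uncertainty_weighted_loss(0.5, 1.5, state)
        assert hi > lo

    @pytest.mark.parametrize("L", [0.1, 0.5, 2.0, 7.0])
    def test_optimal_log_variance_is_log_loss(self, L):
        """min_s exp(-s) L + s is attained at s = log L (grid-search oracle)."""
        grid = np.linspace(-6, 6, 20001)
        values = np.exp(-grid) * L + grid
        assert grid[np.argmin(values)] == pytest.approx(np.log(L), abs=1e-3)

    def test_non_finite_loss_rejected(self):
        with pytest.raises(TrainingError):
            uncertainty_weighted_loss(np.nan, 1.0, LossState())


class TestCAGrad:
    def test_c_zero_returns_mean_gradient_exactly(self, rng):
        g1, g2 = rng.normal(size=8), rng.normal(size=8)
        np.testing.assert_array_equal(cagrad_direction(g1, g2, 0.0),
                                      0.5 * (g1 + g2))

    def test_agreeing_tasks_scale_up_along_common_direction(self, rng):
        g = rng.normal(size=6)
        d = cagrad_direction(g, g, 0.5)
        np.testing.assert_allclose(d, 1.5 * g, rtol=1e-9)

    def test_zero_mean_gradient_degenerate_case(self):
        g = np.array([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(cagrad_direction(g, -g, 0.5),
                                      np.zeros(3))

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(20):
            dim = int(rng.integers(2, 6))
            g1, g2 = rng.normal(size=dim), rng.normal(size=dim)
            d = cagrad_direction(g1, g2, 0.5)
            oracle = brute_force_cagrad(g1, g2, 0.5)
            np.testing.assert_allclose(d, oracle, rtol=1e-4, atol=1e-6)

    def test_ball_constraint_and_worst_case_descent(self, rng):
        for c in (0.0, 0.25, 0.5):
            for _ in range(30):
                g1, g2 = rng.normal(size=7), rng.normal(size=7)
                g0 = 0.5 * (g1 + g2)
                d = cagrad_direction(g1, g2, c)
                assert np.linalg.norm(d - g0) <= c * np.linalg.norm(g0) + 1e-6
                assert min(g1 @ d, g2 @ d) >= min(g1 @ g0, g2 @ g0) - 1e-6

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            cagrad_direction(np.zeros(3), np.zeros(4), 0.5)


@pytest.fixture(scope="module")
def positives():
    gen = np.random.default_rng(9)
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    # biased composition so the frequency check is informative
    p = np.ones(20)
    p[:5] = 5.0
    p /= p.sum()
    return [
        TrainingExample("".join(gen.choice(residues, size=9, p=p)),
                        f"HLA-A*0{1 + i % 3}:01", MS, label=1)
        for i in range(300)
    ]


class TestSyntheticNegatives:
    def test_contract_label_task_length(self, positives, rng):
        negs = sample_synthetic_negatives(positives, 500, rng)
        assert len(negs) == 500
        assert all(n.label == 0 and n.task == MS for n in negs)
        assert all(8 <= len(n.peptide) <= 15 for n in negs)
        alleles = {p.allele for p in positives}
        assert all(n.allele in alleles for n in negs)

    def test_residue_frequencies_match_positive_pool(self, positives):
        rng = np.random.default_rng(1)
        negs = sample_synthetic_negatives(positives, 10_000, rng)
        pool = "".join(p.peptide for p in positives)
        sample = "".join(n.peptide for n in negs)
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            expected = pool.count(aa) / len(pool)
            observed = sample.count(aa) / len(sample)
            assert observed == pytest.approx(expected, abs=0.01)

    def test_seeded_determinism(self, positives):
        a = sample_synthetic_negatives(positives, 50, np.random.default_rng(5))
        b = sample_synthetic_negatives(positives, 50, np.random.default_rng(5))
        c = sample_synthetic_negatives(positives, 50, np.random.default_rng(6))
        assert [x.peptide for x in a] == [x.peptide for x in b]
        assert [x.peptide for x in a] != [x.peptide for x in c]

    def test_nonpositive_count_gives_empty_list(self, positives, rng):
        assert sample_synthetic_negatives(positives, 0, rng) == []


@pytest.fixture(scope="module")
def mixed_data():
    data = [TrainingExample(f"AAAAAAA{aa}", "HLA-A*01:01", MS, label=i % 2)
            for i, aa in enumerate("ACDEFGHIKL" * 90)]
    data += [TrainingExample(f"CCCCCCC{aa}", "HLA-A*01:01", BA,
                             measurement_nM=100.0)
             for aa in "ACDEFGHIKL" * 10]
    return data


class TestSplit:
    def test_90_10_split_sizes(self, mixed_data, rng):
        train, val = split_train_val(mixed_data, 0.9, rng)
        assert len(train) == 900
        assert len(val) == 100

    def test_partition_is_disjoint_and_complete(self, mixed_data, rng):
        train, val = split_train_val(mixed_data, 0.9, rng)
        ids = sorted(id(x) for x in train + val)
        assert ids == sorted(id(x) for x in mixed_data)

    def test_stratified_by_task(self, mixed_data, rng):
        train, val = split_train_val(mixed_data, 0.9, rng)
        assert sum(1 for x in val if x.task == BA) == 10

    def test_same_seed_reproduces_split(self, mixed_data):
        t1, v1 = split_train_val(mixed_data, 0.9, np.random.default_rng(3))
        t2, v2 = split_train_val(mixed_data, 0.9, np.random.default_rng(3))
        assert [x.peptide for x in v1] == [x.peptide for x in v2]

    def test_single_example_task_rejected(self):
        data = [TrainingExample("AAAAAAAA", "HLA-A*01:01", MS, label=1)] * 5
        data += [TrainingExample("CCCCCCCC", "HLA-A*01:01", BA,
                                 measurement_nM=10.0)]
        with pytest.raises(TrainingError, match="stratify"):
            split_train_val(data, 0.9, np.random.default_rng(0))


@pytest.fixture(scope="module")
def tiny_dataset():
    spec = SyntheticDatasetSpec(n_alleles=2, n_pos_per_allele=150, seed=5)
    return generate_dataset(spec, with_benchmark=False)


class TestFit:
    def test_validation_loss_improves_and_history_capped(self, tiny_dataset):
        cfg = TrainingConfig(batch_size=64, lr=5e-3, epochs=8, seed=2,
                             patience=8)
        model = GatedMultiTaskModel(ModelConfig(seed=2))
        model, hist = fit(tiny_dataset.training, model, cfg,
                          tiny_dataset.table)
        assert len(hist) <= cfg.epochs
        assert hist.val_np[-1] < hist.val_np[0]

    def test_same_seed_reproduces_losses(self, tiny_dataset):
        cfg = TrainingConfig(batch_size=64, lr=5e-3, epochs=2, seed=7)
        runs = []
        for _ in range(2):
            model = GatedMultiTaskModel(ModelConfig(seed=7))
            _, hist = fit(tiny_dataset.training, model, cfg,
                          tiny_dataset.table)
            runs.append(hist.val_total)
        assert runs[0] == runs[1]

    def test_ms_only_data_requires_frozen_ba_branch(self, tiny_dataset):
        ms_only = [ex for ex in tiny_dataset.training if ex.task == MS]
        cfg = TrainingConfig(batch_size=64, epochs=1, seed=0)
        with pytest.raises(TrainingError, match="freeze"):
            fit(ms_only, GatedMultiTaskModel(ModelConfig(seed=0)), cfg,
                tiny_dataset.table)


class TestFreezeBA:
    def test_ba_branch_bitwise_frozen_while_np_trains(self, tiny_dataset):
        model = freeze_ba_branch(GatedMultiTaskModel(ModelConfig(seed=4)))
        before = {k: v.copy() for k, v in model.parameters().items()}
        cfg = TrainingConfig(batch_size=64, lr=5e-3, epochs=2, seed=4)
        model, _ = fit(tiny_dataset.training, model, cfg, tiny_dataset.table)
        after = model.parameters()
        ba_names = model.ba_branch_parameter_names()
        assert ba_names
        for name in ba_names:
            np.testing.assert_array_equal(before[name], after[name])
        assert any(not np.array_equal(before[n], after[n])
                   for n in model.shared_parameter_names())
        # the frozen BA tower still produces valid predictions
        pep = np.zeros((2, 45, 21))
        alle = np.zeros((2, 37, 21))
        _, ba_out, _, _, _ = model.forward_batch(pep, alle)
        assert np.all((ba_out >= 0) & (ba_out <= 1))
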