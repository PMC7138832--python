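"""Feature selection, grid search, and the two-level network."""

import numpy as np
import pytest

from methylsite.datasets import build_instances
from methylsite.network import (
    DEFAULT_WINDOWS,
    TrainConfig,
    load_network,
    predict,
    save_network,
    scan_window_sizes,
    train_two_level,
)
from methylsite.selection import (
    StepwiseSubtypeSelector,
    SubtypeSvmClassifier,
    grid_search_svm,
    pearson_cc,
    rank_by_pcc,
)
from methylsite.synthetic import SynthConfig, gen_sequence_dataset


class TestPearson:
    def test_identical_vectors(self):
        assert pearson_cc([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_constant_vector_convention(self):
        assert pearson_cc([3, 3, 3, 3], [0, 1, 0, 1]) == 0.0

    def test_closed_form_value(self):
        # x=[1,2,3,4], y=[0,0,1,1]: cov=1, sd_x=sqrt(5)/2, sd_y=1/2
        assert pearson_cc([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(
            0.8944, abs=1e-4
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_cc([1, 2], [1, 2, 3])

    def test_ranking_orders_by_abs_pcc(self, rng):
        y = rng.integers(0, 2, 60)
        X = np.column_stack(
            [
                rng.random(60),  # noise
                y + rng.normal(scale=0.1, size=60),  # strong +
                -2.0 * y + rng.normal(scale=0.1, size=60),  # strong -
            ]
        )
        ranked = rank_by_pcc(X, y)
        assert set(ranked[:2]) == {1, 2}


def _planted_matrix(rng, n=120, n_info=10, n_noise=200, shift=1.5):
    y = np.array([0, 1] * (n // 2))
    info = rng.normal(size=(n, n_info)) + shift * y[:, None]
    noise = rng.normal(size=(n, n_noise))
    X = np.concatenate([info, noise], axis=1)
    perm = rng.permutation(X.shape[1])
    return X[:, perm], y, {int(np.where(perm == j)[0][0]) for j in range(n_info)}


class TestStepwiseSelector:
    def test_single_feature_always_selected(self, rng):
        y = np.array([0, 1] * 20)
        X = (y + rng.normal(scale=0.3, size=40)).reshape(-1, 1)
        sel = StepwiseSubtypeSelector().fit(X, y)
        assert list(sel.selected_) == [0]

    def test_duplicate_feature_rejected(self, rng):
        y = np.array([0, 1] * 30)
        x = y + rng.normal(scale=0.2, size=60)
        X = np.column_stack([x, x])  # exact copy cannot strictly improve
        sel = StepwiseSubtypeSelector().fit(X, y)
        assert list(sel.selected_) == [int(sel.ranked_[0])]

    def test_accepted_accuracies_strictly_increase(self, rng):
        X, y, _ = _planted_matrix(rng, n=80, n_info=5, n_noise=40)
        sel = StepwiseSubtypeSelector(max_candidates=25).fit(X, y)
        accepted = [acc for _, acc, ok in sel.trace_ if ok]
        assert all(b > a for a, b in zip(accepted, accepted[1:]))
        assert sel.best_accuracy_ >= accepted[0]

    def test_recovers_planted_informative_features(self):
        from methylsite.synthetic import gen_selection_benchmark

        X, y, informative = gen_selection_benchmark(seed=7)
        sel = StepwiseSubtypeSelector(random_state=7).fit(X, y)
        picked = set(int(j) for j in sel.selected_)
        assert len(picked & informative) >= 8
        assert len(picked - informative) <= 10

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            StepwiseSubtypeSelector().fit(rng.random((10, 3)), np.ones(10))

    def test_transform_uses_selection(self, rng):
        X, y, _ = _planted_matrix(rng, n=60, n_info=3, n_noise=10)
        sel = StepwiseSubtypeSelector(max_candidates=8).fit(X, y)
        assert sel.transform(X).shape == (60, len(sel.selected_))


class TestGridSearch:
    def test_separable_data_reaches_perfect_cv(self, rng):
        X = np.concatenate([rng.normal(size=(30, 2)), rng.normal(size=(30, 2)) + 8])
        y = np.array([0] * 30 + [1] * 30)
        params = grid_search_svm(X, y, cv_folds=5, seed=0)
        assert params.cv_accuracy == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 5))
        y = rng.integers(0, 2, 80)
        params = grid_search_svm(
            X, y, C_grid=(0.5, 2.0), gamma_grid=(0.01, 0.1), cv_folds=5, seed=1
        )
        assert abs(params.cv_accuracy - 0.5) <= 0.15

    def test_determinism(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        grids = dict(C_grid=(0.5, 2.0, 8.0), gamma_grid=(0.01, 0.1))
        a = grid_search_svm(X, y, cv_folds=4, seed=3, **grids)
        b = grid_search_svm(X, y, cv_folds=4, seed=3, **grids)
        assert (a.C, a.gamma, a.cv_accuracy) == (b.C, b.gamma, b.cv_accuracy)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            grid_search_svm(np.ones((10, 2)), np.array([0, 1] * 5))


@pytest.fixture(scope="module")
def small_dataset():
    proteins, truth = gen_sequence_dataset(SynthConfig(n_proteins=40, seed=21))
    return proteins


@pytest.fixture(scope="module")
def fast_config():
    return TrainConfig(
        max_candidates=8,
        C_grid=(1.0, 8.0),
        gamma_grid=(2.0**-7, 2.0**-3),
    )


class TestTwoLevelNetwork:
    def test_trained_tasks_and_prediction_gating(self, small_dataset, fast_config):
        net = train_two_level(small_dataset, "K", fast_config, seed=5)
        assert "site" in net.tasks
        assert set(net.types) <= {"mono", "di", "tri"}
        pm = {p.id: p for p in small_dataset}
        insts = build_instances(small_dataset, "K", seed=5)
        pos_probs, neg_results = [], []
        for inst in insts[:40]:
            res = predict(net, pm[inst.protein_id], inst.position)
            assert 0.0 <= res.site_prob <= 1.0
            if res.site_call:
                assert res.type_probs is not None
                assert set(res.type_probs) == set(net.types)
            else:
                assert res.type_probs is None  # gating rule
            if inst.is_positive:
                pos_probs.append(res.site_prob)
        # training positives should mostly be re-predicted as positive
        assert np.mean(np.array(pos_probs) > 0.5) >= 0.7

    def test_residue_mismatch_rejected(self, small_dataset, fast_config):
        net = train_two_level(small_dataset, "K", fast_config, seed=5)
        prot = small_dataset[0]
        non_k = prot.sequence.index("A") + 1
        with pytest.raises(ValueError, match="mismatch"):
            predict(net, prot, non_k)

    def test_prediction_determinism(self, small_dataset, fast_config):
        net = train_two_level(small_dataset, "K", fast_config, seed=5)
        prot = small_dataset[0]
        pos = prot.sequence.index("K") + 1
        a = predict(net, prot, pos)
        b = predict(net, prot, pos)
        assert a.site_prob == b.site_prob

    def test_arginine_network_has_no_tri_model(self, fast_config):
        proteins, _ = gen_sequence_dataset(
            SynthConfig(n_proteins=40, residue="R", seed=22)
        )
        net = train_two_level(proteins, "R", fast_config, seed=5)
        assert "tri" not in net.types

    def test_sparse_type_skipped_with_warning(self, fast_config, caplog):
        proteins, _ = gen_sequence_dataset(
            SynthConfig(
                n_proteins=30,
                seed=23,
                type_mixture={"mono": 0.97, "di": 0.03, "tri": 0.0},
            )
        )
        with caplog.at_level("WARNING"):
            net = train_two_level(proteins, "K", fast_config, seed=5)
        assert "tri" not in net.types

    def test_archive_roundtrip(self, small_dataset, fast_config, tmp_path):
        net = train_two_level(small_dataset, "K", fast_config, seed=5)
        save_network(net, tmp_path / "model")
        again = load_network(tmp_path / "model")
        pm = {p.id: p for p in small_dataset}
        inst = build_instances(small_dataset, "K", seed=5)[0]
        a = predict(net, pm[inst.protein_id], inst.position)
        b = predict(again, pm[inst.protein_id], inst.position)
        assert a.site_prob == b.site_prob

    def test_default_windows_match_selected_sizes(self):
        assert DEFAULT_WINDOWS["K"]["site"] == 17
        assert DEFAULT_WINDOWS["R"]["site"] == 17
        assert DEFAULT_WINDOWS["K"]["mono"] == 23
        assert DEFAULT_WINDOWS["R"]["mono"] == 17


class TestWindowScan:
    def test_degenerate_ties_break_to_smallest(self, monkeypatch):
        proteins, _ = gen_sequence_dataset(SynthConfig(n_proteins=20, seed=31))
        import methylsite.network as net_mod

        class _FakeClf:
            cv_accuracy_ = 0.5
            support_ = np.arange(1)

        def fake_fit_task(task, insts, y, pm, w, config, sources, seed):
            from methylsite.network import TaskModel

            return TaskModel(task=task, w=w, assembler=None, classifier=_FakeClf())

        monkeypatch.setattr(net_mod, "_fit_task", fake_fit_task)
        best_w, accs = net_mod.scan_window_sizes(proteins, "K", sizes=(9, 11, 13))
        assert best_w == 9
        assert set(accs) == {9, 11, 13}

    def test_center_motif_prefers_small_windows(self):
        # signal only within +/-3 of the center: no reason to pick w > 9
        motif = {(o, "K"): 12.0 for o in (-3, -2, -1, 1, 2, 3)}
        proteins, _ = gen_sequence_dataset(
            SynthConfig(n_proteins=60, seed=33, motif_effect=motif)
        )
        cfg = TrainConfig(
            subtypes=("PWAA", "EBGW", "KNN"),
            max_candidates=6,
            C_grid=(1.0, 8.0),
            gamma_grid=(2.0**-5, 2.0**-2),
        )
        best_w, accs = scan_window_sizes(
            proteins, "K", sizes=(9, 15, 21), config=cfg, seed=2
        )
        assert best_w in (9, 15)
        assert accs[9] >= accs[21] - 0.03
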