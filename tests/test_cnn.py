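"""Matrix scorer contracts: aggregation rule, embeddings, determinism,
gradient correctness and the TPE search mechanics."""

import numpy as np
import pytest

from brainheart import cnn
from brainheart.cnn import CNNConfig, SearchSpace, TrainedScorer, _Net
from brainheart.wtlcc import WTLCCMatrix, WTLCCParams

PARAMS = WTLCCParams(N=60, S=30, K=5, J=24)


def make_matrix(rng, pid="p0", shift=0.0):
    vals = np.clip(rng.normal(shift, 0.3, (PARAMS.K, PARAMS.J)), -1, 1)
    return WTLCCMatrix(vals, patient_id=pid, window_start=0, params=PARAMS,
                       pair=("a", "b"))


def tiny_config(**kw):
    base = dict(conv_blocks=((4, 3, 2),), dense_width=8, epochs=3,
                batch_size=16, seed=0)
    base.update(kw)
    return CNNConfig(**base)


@pytest.fixture(scope="module")
def toy_problem():
    """Separable toy task: matrices from two patients with shifted means."""
    rng = np.random.default_rng(0)
    mats, labels = [], {}
    for i in range(8):
        pid = f"p{i}"
        shift = 0.4 if i % 2 else -0.4
        labels[pid] = "unfav" if i % 2 else "fav"
        mats += [make_matrix(rng, pid, shift) for _ in range(6)]
    return mats, labels


class TestScorePatient:
    def _scorer(self):
        rng = np.random.default_rng(0)
        net = _Net((PARAMS.K, PARAMS.J), tiny_config(), rng)
        return TrainedScorer(net=net, config=tiny_config(),
                             input_shape=(PARAMS.K, PARAMS.J))

    def test_mean_aggregation_and_strict_threshold(self, monkeypatch):
        scorer = self._scorer()
        rng = np.random.default_rng(1)
        mats = [make_matrix(rng) for _ in range(3)]
        monkeypatch.setattr(
            scorer, "score_matrices", lambda m: np.array([0.6, 0.7, 0.8])
        )
        score, label = scorer.score_patient(mats)
        assert score == pytest.approx(0.7)
        assert label == "unfav"

    def test_boundary_half_is_favourable(self, monkeypatch):
        scorer = self._scorer()
        rng = np.random.default_rng(1)
        mats = [make_matrix(rng) for _ in range(2)]
        monkeypatch.setattr(
            scorer, "score_matrices", lambda m: np.array([0.5, 0.5])
        )
        score, label = scorer.score_patient(mats)
        assert score == 0.5 and label == "fav"

    def test_single_low_score_favourable(self, monkeypatch):
        scorer = self._scorer()
        rng = np.random.default_rng(1)
        monkeypatch.setattr(scorer, "score_matrices", lambda m: np.array([0.2]))
        assert scorer.score_patient([make_matrix(rng)]) == (pytest.approx(0.2), "fav")

    def test_empty_matrix_list_errors(self):
        with pytest.raises(ValueError, match="no matrices"):
            self._scorer().score_patient([])

    def test_scores_in_unit_interval(self):
        scorer = self._scorer()
        rng = np.random.default_rng(2)
        s = scorer.score_matrices([make_matrix(rng) for _ in range(10)])
        assert np.all((s >= 0) & (s <= 1))


class TestEmbeddings:
    def test_duplicate_matrices_embed_identically(self, toy_problem):
        mats, labels = toy_problem
        scorer = cnn.train(mats, labels, tiny_config())
        one = scorer.embed([mats[0]])
        two = scorer.embed([mats[0], mats[0]])
        np.testing.assert_allclose(one, two, atol=1e-12)

    def test_embedding_length_is_dense_width(self, toy_problem):
        mats, labels = toy_problem
        scorer = cnn.train(mats, labels, tiny_config(dense_width=8))
        assert scorer.embed(mats[:3]).shape == (8,)
        assert scorer.embedding_dim == 8


class TestTraining:
    def test_separable_toy_task_learned(self, toy_problem):
        mats, labels = toy_problem
        scorer = cnn.train(mats, labels, tiny_config(epochs=8))
        scores = {pid: scorer.score_patient([m for m in mats if m.patient_id == pid])[0]
                  for pid in labels}
        unf = [scores[p] for p, l in labels.items() if l == "unfav"]
        fav = [scores[p] for p, l in labels.items() if l == "fav"]
        assert min(unf) > max(fav)

    def test_single_class_errors(self, toy_problem):
        mats, _ = toy_problem
        labels = {f"p{i}": "unfav" for i in range(8)}
        with pytest.raises(ValueError, match="single class"):
            cnn.train(mats, labels, tiny_config())

    def test_unlabelled_patient_errors(self, toy_problem):
        mats, labels = toy_problem
        labels = {k: v for k, v in labels.items() if k != "p3"}
        with pytest.raises(ValueError, match="p3"):
            cnn.train(mats, labels, tiny_config())

    def test_same_seed_reproduces_scores(self, toy_problem):
        mats, labels = toy_problem
        s1 = cnn.train(mats, labels, tiny_config()).score_matrices(mats)
        s2 = cnn.train(mats, labels, tiny_config()).score_matrices(mats)
        np.testing.assert_array_equal(s1, s2)

    def test_shape_mismatch_errors(self, toy_problem):
        mats, labels = toy_problem
        scorer = cnn.train(mats, labels, tiny_config())
        other = WTLCCMatrix(
            np.zeros((3, 24)), patient_id="p0", window_start=0,
            params=WTLCCParams(N=60, S=30, K=3, J=24), pair=("a", "b"),
        )
        with pytest.raises(ValueError, match="shape"):
            scorer.score_matrices([other])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the full net vs central differences."""
        rng = np.random.default_rng(3)
        cfg = tiny_config(dropout=0.0)
        net = _Net((6, 10), cfg, rng)
        x = rng.normal(0, 0.5, (4, 6, 10))
        y = np.array([0.0, 1.0, 1.0, 0.0])

        def loss_fn():
            p = np.clip(net.forward(x, train=True), 1e-9, 1 - 1e-9)
            return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)), p

        loss, p = loss_fn()
        net.backward((p - y) / len(y))
        conv = net.layers[0]
        analytic = conv.dW.copy()
        eps = 1e-6
        for idx in [(0, 0), (3, 2), (8, 1)]:
            old = conv.W[idx]
            conv.W[idx] = old + eps
            lp, _ = loss_fn()
            conv.W[idx] = old - eps
            lm, _ = loss_fn()
            conv.W[idx] = old
            numeric = (lp - lm) / (2 * eps)
            assert abs(numeric - analytic[idx]) < 1e-6 * max(1, abs(numeric))


class TestSplit:
    def test_split_is_patient_level_and_stratified(self):
        labels = {f"p{i}": ("unfav" if i < 12 else "fav") for i in range(20)}
        train_ids, val_ids = cnn.split_patients(labels, val_frac=0.25, seed=1)
        assert set(train_ids) | set(val_ids) == set(labels)
        assert not set(train_ids) & set(val_ids)
        assert any(labels[p] == "fav" for p in val_ids)
        assert any(labels[p] == "unfav" for p in val_ids)


class TestSearch:
    def test_budget_one_returns_single_trial(self):
        space = SearchSpace(pairs=(("icp", "lfhf"),), N_set=(360,), S_set=(60,),
                            K_set=(15,), budget=1)
        best, score, trials = cnn.search(space, lambda cand, seed: 0.7, seed=0)
        assert len(trials) == 1 and score == 0.7

    def test_single_configuration_space(self):
        space = SearchSpace(pairs=(("icp", "lfhf"),), N_set=(360,), S_set=(60,),
                            K_set=(15,), budget=4)
        best, score, trials = cnn.search(space, lambda cand, seed: 0.9, seed=0)
        assert best["pair"] == ("icp", "lfhf") and best["N"] == 360

    def test_tpe_concentrates_on_better_choice(self):
        # a pair-dependent objective: the search should sample the good pair
        # more often than uniform after the startup phase
        def objective(cand, seed):
            base = 0.9 if cand["pair"] == ("icp", "lfhf") else 0.55
            return base + 0.01 * np.random.default_rng(seed).normal()

        space = SearchSpace(N_set=(360,), S_set=(60,), K_set=(15,), budget=30)
        best, score, trials = cnn.search(space, objective, seed=4)
        assert best["pair"] == ("icp", "lfhf")
        later = [cand["pair"] for cand, _ in trials[10:]]
        assert later.count(("icp", "lfhf")) > len(later) / 3

    def test_all_trials_failing_raises_with_reasons(self):
        def objective(cand, seed):
            raise RuntimeError("boom")

        space = SearchSpace(budget=3)
        with pytest.raises(RuntimeError, match="boom"):
            cnn.search(space, objective, seed=0)


class TestRectangularPooling:
    def test_wide_lag_pooling_shapes_and_training(self):
        """Rectangular pools (wide along the lag axis) forward and backward."""
        rng = np.random.default_rng(0)
        mats, labels = [], {}
        for i in range(4):
            pid = f"p{i}"
            labels[pid] = "unfav" if i % 2 else "fav"
            shift = 0.4 if i % 2 else -0.4
            mats += [make_matrix(rng, pid, shift) for _ in range(4)]
        cfg = tiny_config(conv_blocks=((4, 3, (1, 4)),), epochs=2)
        scorer = cnn.train(mats, labels, cfg)
        s = scorer.score_matrices(mats)
        assert s.shape == (len(mats),)
        assert np.all((s >= 0) & (s <= 1))
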