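"""LOSO fold construction, loss arithmetic, adversarial training dynamics,
fine-tuning with frozen layers."""

import numpy as np
import pytest

from adgsleep import autodiff as ad
from adgsleep import network as net
from adgsleep.autodiff import Tensor
from adgsleep.estimator import AdversarialSleepStager, cross_entropy_graph
from adgsleep.network import ConfigurationError, conv_param_names
from adgsleep.training import (DomainDataset, FoldSpec, build_domain_dataset,
                               cross_entropy, fine_tune, loso_folds,
                               total_loss, train_fold)
from tests.conftest import REDUCED_MODEL

FAST_TRAIN = dict(**REDUCED_MODEL, epochs=3, batch_size=16,
                  learning_rate=1e-3)


def _fold_dataset(small_tensors, fold_idx=0, seed=0):
    from adgsleep.preprocess import normalize_dataset
    tensors, labels = small_tensors
    fold = loso_folds(list(tensors), seed=seed)[fold_idx]
    ds = build_domain_dataset(fold, tensors, labels)
    xtr, xte, _ = normalize_dataset(ds.x_train, ds.x_test)
    return fold, DomainDataset(xtr, ds.y_train, ds.d_train, xte, ds.y_test)


class TestFolds:
    def test_ten_subjects_give_ten_folds_with_nine_domains(self):
        folds = loso_folds(range(10))
        assert len(folds) == 10
        assert all(len(f.train_subjects) == 9 for f in folds)

    def test_every_subject_tested_exactly_once(self):
        folds = loso_folds([3, 1, 4, 1, 5])  # duplicates collapse
        tested = [f.test_subject for f in folds]
        assert sorted(tested) == [1, 3, 4, 5]
        for f in folds:
            assert f.test_subject not in f.train_subjects

    def test_two_subject_minimal_case(self):
        folds = loso_folds([0, 1])
        assert [(f.test_subject, f.train_subjects) for f in folds] == \
            [(0, [1]), (1, [0])]

    def test_single_subject_rejected(self):
        with pytest.raises(ConfigurationError):
            loso_folds([0])

    def test_overlapping_fold_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            FoldSpec(0, 1, [1, 2])


class TestLosses:
    def test_perfect_predictions_have_zero_loss(self):
        onehot = np.eye(5)[[0, 3]]
        assert cross_entropy(onehot, onehot) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_five_class_prediction_is_ln5(self):
        probs = np.full((4, 5), 0.2)
        onehot = np.eye(5)[[0, 1, 2, 3]]
        assert cross_entropy(probs, onehot) == pytest.approx(1.6094379, abs=1e-6)

    def test_hand_worked_two_sample_example(self):
        probs = np.array([[0.7, 0.3], [0.4, 0.6]])
        onehot = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(probs, onehot) == pytest.approx(0.4337503, abs=1e-6)

    def test_zero_probability_clamped_not_infinite(self):
        probs = np.array([[0.0, 1.0]])
        onehot = np.array([[1.0, 0.0]])
        val = cross_entropy(probs, onehot)
        assert np.isfinite(val) and val == pytest.approx(-np.log(1e-12))

    def test_graph_cross_entropy_matches_numpy_surface(self, rng):
        probs = rng.dirichlet(np.ones(5), size=8)
        onehot = np.eye(5)[rng.integers(0, 5, 8)]
        graph_val = cross_entropy_graph(Tensor(probs), onehot).item()
        assert graph_val == pytest.approx(cross_entropy(probs, onehot),
                                          abs=1e-5)

    @pytest.mark.parametrize("l_cla,l_d,lam,expected", [
        (1.0, 0.5, 0.0, 1.0),          # discriminator-off limit
        (1.0, 0.5, 1.0, 0.5),
        (1.6094, np.log(9), 0.5, 0.5108),
    ])
    def test_total_loss_arithmetic(self, l_cla, l_d, lam, expected):
        assert total_loss(l_cla, l_d, lam) == pytest.approx(expected, abs=1e-4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            total_loss(1.0, 1.0, -0.1)


class TestTrainFold:
    def test_smoke_run_reduces_classification_loss(self, small_tensors):
        """A short seeded run on the synthetic cohort must end with a lower
        stage-classification loss than it started with."""
        fold, ds = _fold_dataset(small_tensors)
        _, history = train_fold(fold, ds, **{**FAST_TRAIN, "epochs": 5})
        assert history["l_cla"][-1] < history["l_cla"][0]

    def test_identical_seeds_give_identical_history(self, small_tensors):
        fold, ds = _fold_dataset(small_tensors)
        _, h1 = train_fold(fold, ds, **FAST_TRAIN)
        _, h2 = train_fold(fold, ds, **FAST_TRAIN)
        assert h1 == h2

    def test_loss_identity_holds_every_epoch(self, small_tensors):
        """|L_all - (L_cla - lambda*L_d)| < 1e-6 in the logged history."""
        fold, ds = _fold_dataset(small_tensors)
        _, h = train_fold(fold, ds, **FAST_TRAIN, lambda_=0.7)
        for la, lc, ld in zip(h["l_all"], h["l_cla"], h["l_d"]):
            assert abs(la - (lc - 0.7 * ld)) < 1e-6

    def test_discriminator_off_leaves_no_domain_loss(self, small_tensors):
        fold, ds = _fold_dataset(small_tensors)
        model, h = train_fold(fold, ds, **FAST_TRAIN, use_discriminator=False)
        assert all(np.isnan(v) for v in h["l_d"])
        assert not any(k.startswith("dom.") for k in model.params_)

    def test_adversarial_gradient_directions(self, small_tensors):
        """On a frozen batch, the backward pass moves the discriminator
        head down the domain loss while the extractor receives the
        reversed (ascending) domain gradient."""
        fold, ds = _fold_dataset(small_tensors)
        model, _ = train_fold(fold, ds, **{**FAST_TRAIN, "epochs": 1})
        params, cfg = model.params_, model.config_
        xb = Tensor(ds.x_train[:8])
        onehot_d = np.eye(cfg.n_domains)[ds.d_train[:8]]

        def domain_loss():
            feats = net.feature_extract(xb, params, cfg)
            probs = net.domain_predict(feats, params, lambda_=1.0)
            return cross_entropy_graph(probs, onehot_d)

        loss = domain_loss()
        for p in params.values():
            p.zero_grad()
        loss.backward()
        eps = 1e-2
        # discriminator head: step along -grad must DECREASE L_d
        dk = "dom.out.w"
        params[dk].data -= eps * params[dk].grad
        after_disc = domain_loss().item()
        params[dk].data += eps * params[dk].grad
        assert after_disc < loss.item()
        # extractor: its stored gradient is sign-reversed, so stepping
        # along -grad must INCREASE L_d (the adversarial direction)
        ek = max((k for k in params if k.startswith("enc")),
                 key=lambda k: np.abs(params[k].grad).max()
                 if params[k].grad is not None else 0)
        params[ek].data -= eps * params[ek].grad
        after_enc = domain_loss().item()
        params[ek].data += eps * params[ek].grad
        assert after_enc > loss.item()


class TestFineTune:
    def _pretrained(self, small_tensors):
        fold, ds = _fold_dataset(small_tensors)
        model, _ = train_fold(fold, ds, **FAST_TRAIN)
        return model, ds

    def test_frozen_convolutions_unchanged_bitwise(self, small_tensors):
        model, ds = self._pretrained(small_tensors)
        before = {k: model.params_[k].data.copy()
                  for k in conv_param_names(model.params_)}
        tuned = fine_tune(model, ds.x_test, ds.y_test,
                          domains=np.zeros(len(ds.y_test)),
                          use_discriminator=False, epochs=2)
        for k, v in before.items():
            np.testing.assert_array_equal(tuned.params_[k].data, v)

    def test_head_parameters_move_under_gradient(self, small_tensors):
        model, ds = self._pretrained(small_tensors)
        before = model.params_["cls.out.w"].data.copy()
        tuned = fine_tune(model, ds.x_test, ds.y_test,
                          domains=np.zeros(len(ds.y_test)),
                          use_discriminator=False, epochs=1)
        assert not np.array_equal(tuned.params_["cls.out.w"].data, before)

    def test_full_freeze_preserves_outputs(self, small_tensors):
        model, ds = self._pretrained(small_tensors)
        pred_before = model.predict_proba(ds.x_test)
        tuned = fine_tune(model, ds.x_test, ds.y_test,
                          domains=np.zeros(len(ds.y_test)),
                          use_discriminator=False, epochs=1, freeze="all")
        np.testing.assert_allclose(tuned.predict_proba(ds.x_test),
                                   pred_before, atol=1e-6)

    def test_unknown_freeze_name_rejected(self, small_tensors):
        model, ds = self._pretrained(small_tensors)
        with pytest.raises(ConfigurationError):
            fine_tune(model, ds.x_test, ds.y_test,
                      domains=np.zeros(len(ds.y_test)),
                      use_discriminator=False, freeze=["nope.w"])

    def test_domain_head_rebuilt_for_new_subject_count(self, small_tensors):
        model, ds = self._pretrained(small_tensors)
        # fine-tune on a 3-domain split of the test subject's epochs
        n = len(ds.y_test)
        domains = np.arange(n) % 3
        tuned = fine_tune(model, ds.x_test, ds.y_test, domains=domains,
                          epochs=1)
        assert tuned.params_["dom.out.w"].shape[1] == 3
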