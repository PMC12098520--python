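"""Leave-one-subject-out training: fold construction, losses, fold
training and fine-tuning with frozen layers.

Each subject is one domain.  A cohort of n subjects yields n folds; in
every fold the held-out subject is the target domain (test set) and the
remaining n−1 subjects form the multi-source training set whose domain
labels are re-based to 0..n−2 (the reference 10-subject setting gives 9
training domains).  The adversarial total loss is

    L_all = L_cla − λ · L_d

where both terms are multiclass cross-entropies (the domain term runs
over the domain classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimator import AdversarialSleepStager
from .network import ConfigurationError, conv_param_names

CE_EPS = 1e-12


@dataclass
class FoldSpec:
    """One LOSO fold: the held-out test subject and the training pool."""

    fold_index: int
    test_subject: int
    train_subjects: list[int]
    seed: int = 0

    def __post_init__(self):
        if self.test_subject in self.train_subjects:
            raise ConfigurationError(
                f"subject {self.test_subject} appears in both train and test")


@dataclass
class DomainDataset:
    """Multi-source training set + target test set for one fold."""

    x_train: np.ndarray
    y_train: np.ndarray
    d_train: np.ndarray   # contiguous 0..n_domains-1
    x_test: np.ndarray
    y_test: np.ndarray

    def __post_init__(self):
        doms = np.unique(self.d_train)
        if not np.array_equal(doms, np.arange(len(doms))):
            raise ConfigurationError(
                "domain labels must be contiguous 0..n-1 after re-basing")
        if len(self.x_train) == 0 or len(self.x_test) == 0:
            raise ConfigurationError("empty source or target set")

    @property
    def n_domains(self) -> int:
        return int(self.d_train.max()) + 1


def loso_folds(subject_ids, seed: int = 0) -> list[FoldSpec]:
    """One fold per subject; each subject is the test set exactly once."""
    subject_ids = sorted(set(int(s) for s in np.asarray(subject_ids).ravel()))
    if len(subject_ids) < 2:
        raise ConfigurationError("leave-one-subject-out needs >= 2 subjects")
    return [FoldSpec(i, sid, [s for s in subject_ids if s != sid], seed)
            for i, sid in enumerate(subject_ids)]


def build_domain_dataset(fold: FoldSpec,
                         tensors_by_subject: dict[int, np.ndarray],
                         labels_by_subject: dict[int, np.ndarray]
                         ) -> DomainDataset:
    """Assemble a fold's source/target arrays with re-based domain labels."""
    xs, ys, ds = [], [], []
    for d, sid in enumerate(fold.train_subjects):
        xs.append(tensors_by_subject[sid])
        ys.append(np.asarray(labels_by_subject[sid]))
        ds.append(np.full(len(tensors_by_subject[sid]), d, dtype=int))
    return DomainDataset(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(ds),
        np.asarray(tensors_by_subject[fold.test_subject]),
        np.asarray(labels_by_subject[fold.test_subject]))


# ---------------------------------------------------------------------------
# losses (numpy surface; the in-graph versions live in estimator.py)
# ---------------------------------------------------------------------------

def cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                  eps: float = CE_EPS) -> float:
    """−(1/M) Σ_i Σ_j y_ij log p_ij with the documented ε clamp."""
    probs = np.asarray(probs, dtype=float)
    onehot = np.asarray(onehot, dtype=float)
    if probs.shape != onehot.shape:
        raise ValueError("probs and onehot must have the same shape")
    clamped = np.maximum(probs, eps)
    if np.any((probs < eps) & (onehot > 0)):
        import logging
        logging.getLogger(__name__).warning(
            "cross_entropy: zero probability on a true class clamped at %g", eps)
    return float(-(onehot * np.log(clamped)).sum(axis=1).mean())


def total_loss(l_cla: float, l_d: float, lambda_: float) -> float:
    """Adversarial total L_all = L_cla − λ·L_d."""
    if lambda_ < 0:
        raise ConfigurationError("lambda_ must be >= 0")
    return float(l_cla - lambda_ * l_d)


# ---------------------------------------------------------------------------
# fold training / fine-tuning
# ---------------------------------------------------------------------------

def train_fold(fold: FoldSpec, dataset: DomainDataset,
               **stager_kwargs) -> tuple[AdversarialSleepStager, dict]:
    """Fit a stager on a fold's multi-source data; returns (model, history)."""
    kwargs = dict(stager_kwargs)
    kwargs.setdefault("seed", fold.seed)
    model = AdversarialSleepStager(**kwargs)
    model.fit(dataset.x_train, dataset.y_train, domains=dataset.d_train)
    return model, model.history_


def fine_tune(pretrained: AdversarialSleepStager, x, y, domains=None,
              freeze: str | list[str] = "conv",
              **overrides) -> AdversarialSleepStager:
    """Adapt a trained model to new data with most layers frozen.

    ``freeze='conv'`` (default) freezes every encoder and decoder
    convolution/SE parameter bit-exactly, leaving the Bi-GRU and the FC
    heads trainable; ``freeze='all'`` freezes everything; a list freezes
    the named parameters.  The domain head is rebuilt when the new data
    has a different number of source domains.
    """
    params = pretrained.params_
    if freeze == "conv":
        frozen = conv_param_names(params)
    elif freeze == "all":
        frozen = list(params)
    else:
        frozen = list(freeze)
        unknown = set(frozen) - set(params)
        if unknown:
            raise ConfigurationError(
                f"freeze_spec names unknown layers: {sorted(unknown)}")

    base = pretrained.get_params()
    base.update(overrides)
    model = AdversarialSleepStager(**base)

    init = dict(params)
    if model.use_discriminator and domains is not None:
        n_new = len(np.unique(np.asarray(domains)))
        if n_new != pretrained.n_domains_:
            # new fold has a different subject count: re-initialize the head
            init = {k: v for k, v in params.items() if not k.startswith("dom.")}
    if not model.use_discriminator:
        init = {k: v for k, v in init.items() if not k.startswith("dom.")}
        frozen = [k for k in frozen if not k.startswith("dom.")]
    model.fit(np.asarray(x), np.asarray(y), domains=domains,
              init_params=init, frozen=frozen)
    return model
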