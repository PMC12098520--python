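"""sklearn-style estimator for adversarially domain-generalized staging.

:class:`AdversarialSleepStager` wraps the residual channel-attention
network, the gradient reversal layer and the Adam training loop behind
the familiar ``fit`` / ``predict`` / ``predict_proba`` interface, so it
composes with sklearn model selection and pipelines.  Domains (subject
identities of the training samples) are passed to ``fit`` as a keyword;
when the discriminator is enabled the optimized objective per batch is

    L_cla + L_d   with the GRL scaling the extractor's domain gradient by −λ,

which realizes the adversarial total loss L_all = L_cla − λ·L_d for the
extractor while the discriminator head itself descends L_d.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff as ad
from . import network as net
from .autodiff import Adam, Tensor
from .network import ConfigurationError, ModelConfig, N_STAGES


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(labels), k), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def cross_entropy_graph(probs: ad.Tensor, onehot: np.ndarray) -> ad.Tensor:
    """−(1/M) Σ_i Σ_j y_ij log p_ij inside the autodiff graph (ε = 1e-12)."""
    logp = ad.safe_log(probs)
    return ad.mean(ad.tsum(ad.mul(logp, Tensor(onehot)), axis=1)) * -1.0


def dann_lambda(progress: float) -> float:
    """DANN-style ramp 2/(1+e^{−10p}) − 1 over training progress p∈[0,1]."""
    return 2.0 / (1.0 + np.exp(-10.0 * progress)) - 1.0


class AdversarialSleepStager(ClassifierMixin, BaseEstimator):
    """Five-class sleep stager with optional adversarial domain branch.

    Parameters mirror the experiment configuration: architecture widths,
    the channel-attention and discriminator ablation flags, the
    adversarial weight λ (constant by default, optional DANN ramp), and
    the optimizer settings (Adam, defaults epochs=150, batch 16,
    lr 2e-5).  Desk-scale experiments override the training defaults.

    Fitted attributes (trailing underscore): ``params_`` (weights),
    ``config_``, ``classes_``, ``n_domains_``, ``history_``.
    """

    def __init__(self, input_size: int = 128, in_channels: int = 10,
                 encoder_widths: tuple[int, ...] = (64, 128, 256, 256),
                 decoder_channels: int = 256, gru_hidden: int = 128,
                 head_hidden: tuple[int, int] = (128, 64),
                 use_se: bool = True, use_discriminator: bool = True,
                 lambda_: float = 1.0, lambda_schedule: str = "constant",
                 epochs: int = 150, batch_size: int = 16,
                 learning_rate: float = 2e-5, seed: int = 0,
                 verbose: int = 0):
        self.input_size = input_size
        self.in_channels = in_channels
        self.encoder_widths = encoder_widths
        self.decoder_channels = decoder_channels
        self.gru_hidden = gru_hidden
        self.head_hidden = head_hidden
        self.use_se = use_se
        self.use_discriminator = use_discriminator
        self.lambda_ = lambda_
        self.lambda_schedule = lambda_schedule
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.verbose = verbose

    # -- internals -------------------------------------------------------
    def _build_config(self, n_domains: int) -> ModelConfig:
        return ModelConfig(
            input_size=self.input_size, in_channels=self.in_channels,
            encoder_widths=tuple(self.encoder_widths),
            decoder_channels=self.decoder_channels,
            gru_hidden=self.gru_hidden,
            head_hidden=tuple(self.head_hidden),
            n_domains=max(n_domains, 2), use_se=self.use_se,
            use_discriminator=self.use_discriminator,
            lambda_=self.lambda_, seed=self.seed)

    def _validate_x(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError(f"X must be (N, S, S, C), got shape {X.shape}")
        return X

    def _lambda_at(self, progress: float) -> float:
        if self.lambda_schedule == "constant":
            return self.lambda_
        if self.lambda_schedule == "dann":
            return self.lambda_ * dann_lambda(progress)
        raise ConfigurationError(
            f"unknown lambda_schedule {self.lambda_schedule!r}")

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y, domains=None, init_params=None, frozen=()):
        """Train on tensors X (N, S, S, C) with stage labels y.

        ``domains`` gives per-sample source-subject labels (any hashable
        values; re-based internally to 0..n−1); required when the
        discriminator is enabled.  ``init_params``/``frozen`` support
        warm starts and fine-tuning with frozen layers.
        """
        X = self._validate_x(X)
        y_idx = np.asarray(y, dtype=int)
        if y_idx.min() < 0 or y_idx.max() >= N_STAGES:
            raise ValueError(f"stage labels must be integers in [0, {N_STAGES})")
        self.classes_ = np.arange(N_STAGES)
        n_classes = N_STAGES

        if self.use_discriminator:
            if domains is None:
                raise ConfigurationError(
                    "domains are required when use_discriminator=True")
            domain_values = np.unique(np.asarray(domains))
            d_idx = np.searchsorted(domain_values, np.asarray(domains))
            self.n_domains_ = len(domain_values)
            self.domain_values_ = domain_values
        else:
            d_idx = None
            self.n_domains_ = 0

        self.config_ = self._build_config(self.n_domains_ or 2)
        fresh = net.init_params(self.config_)
        if init_params is not None:
            self.params_ = {
                k: (Tensor(init_params[k].data.copy(), requires_grad=True)
                    if k in init_params and init_params[k].shape == p.shape
                    else p)
                for k, p in fresh.items()}
        else:
            self.params_ = fresh
        unknown = set(frozen) - set(self.params_)
        if unknown:
            raise ConfigurationError(f"frozen names not in model: {sorted(unknown)}")

        opt = Adam(self.params_, lr=self.learning_rate, frozen=frozen)
        rng = np.random.default_rng(self.seed)
        n = len(X)
        onehot_y = _one_hot(y_idx, n_classes)
        onehot_d = _one_hot(d_idx, self.n_domains_) if d_idx is not None else None

        history = {"l_cla": [], "l_d": [], "l_all": [], "train_accuracy": []}
        total_steps = max(self.epochs * max(n // self.batch_size, 1), 1)
        step = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            ep_cla, ep_d, ep_correct, ep_count = 0.0, 0.0, 0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                if len(idx) < 2:
                    continue
                lam = self._lambda_at(step / total_steps)
                xb = Tensor(X[idx])
                feats, stage_probs, dom_probs = net.forward(
                    xb, self.params_, self.config_, lambda_=lam)
                l_cla = cross_entropy_graph(stage_probs, onehot_y[idx])
                if dom_probs is not None:
                    l_d = cross_entropy_graph(dom_probs, onehot_d[idx])
                    objective = l_cla + l_d
                else:
                    l_d = None
                    objective = l_cla
                if not np.isfinite(objective.item()):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch "
                        f"{start // self.batch_size}")
                opt.zero_grad()
                objective.backward()
                opt.step()
                step += 1
                ep_cla += l_cla.item() * len(idx)
                if l_d is not None:
                    ep_d += l_d.item() * len(idx)
                ep_correct += int((stage_probs.data.argmax(1)
                                   == y_idx[idx]).sum())
                ep_count += len(idx)
            l_cla_e = ep_cla / max(ep_count, 1)
            l_d_e = ep_d / max(ep_count, 1) if self.use_discriminator else float("nan")
            lam_now = self._lambda_at(min(step / total_steps, 1.0))
            l_all_e = (l_cla_e - lam_now * l_d_e
                       if self.use_discriminator else l_cla_e)
            history["l_cla"].append(l_cla_e)
            history["l_d"].append(l_d_e)
            history["l_all"].append(l_all_e)
            history["train_accuracy"].append(ep_correct / max(ep_count, 1))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}: "
                      f"L_cla={l_cla_e:.4f} L_d={l_d_e:.4f} "
                      f"acc={history['train_accuracy'][-1]:.3f}")
        self.history_ = history
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_x(X)
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        out = []
        with ad.no_grad():
            for start in range(0, len(X), 64):
                xb = Tensor(X[start:start + 64])
                feats = net.feature_extract(xb, self.params_, self.config_)
                out.append(net.label_predict(feats, self.params_).data)
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def extract_features(self, X) -> np.ndarray:
        """Feature sequences (N, T, 2H) without the classification heads."""
        X = self._validate_x(X)
        with ad.no_grad():
            return net.feature_extract(Tensor(X), self.params_,
                                       self.config_).data
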