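"""The residual channel-attention network with adversarial heads.

The model has three parts:

* a **feature extractor** — a U-shaped stack of residual channel-attention
  blocks (Res_CAB: convolution + squeeze-and-excitation recalibration added
  to an identity or 1×1-projection shortcut, then ReLU), whose decoder
  upsamples with skip concatenations and feeds a bidirectional GRU;
* a **label predictor** — three fully connected layers ending in a 5-way
  softmax over AASM sleep stages;
* a **domain discriminator** — the same FC shape ending in an
  ``n_domains``-way softmax, reached through a gradient reversal layer so
  adversarial training pushes the extractor toward subject-invariant
  features.

For the reference configuration the shape chain is
(128, 128, 10) → encoder (8, 8, 256) → decoder + Bi-GRU (32, 256) →
heads (5,) and (9,).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

STAGE_NAMES = ("W", "N1", "N2", "N3", "REM")
N_STAGES = 5


class ConfigurationError(ValueError):
    """Inconsistent model or experiment configuration."""


@dataclass
class ModelConfig:
    """Architecture + adversarial hyperparameters.

    ``encoder_widths`` gives one output width per stride-2 encoder stage
    (each stage = projection Res_CAB stride 2 followed by one standard
    Res_CAB).  The decoder always runs two upsample-by-2 stages with skip
    concatenation, so at least three encoder stages are required and the
    input side length must be divisible by ``2 ** len(encoder_widths)``.
    SE reduction is ``r = max(C // 16, 1)`` per block.
    """

    input_size: int = 128
    in_channels: int = 10
    encoder_widths: tuple[int, ...] = (64, 128, 256, 256)
    decoder_channels: int = 256
    gru_hidden: int = 128
    head_hidden: tuple[int, int] = (128, 64)
    n_domains: int = 9
    use_se: bool = True
    use_discriminator: bool = True
    lambda_: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.encoder_widths = tuple(int(w) for w in self.encoder_widths)
        self.head_hidden = tuple(int(h) for h in self.head_hidden)
        if len(self.encoder_widths) < 3:
            raise ConfigurationError(
                "decoder needs two skip stages: provide >= 3 encoder widths"
            )
        if self.input_size % (2 ** len(self.encoder_widths)) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by "
                f"2**{len(self.encoder_widths)} encoder stages"
            )
        if self.lambda_ < 0:
            raise ConfigurationError("lambda_ must be >= 0")
        if self.use_discriminator and self.n_domains < 2:
            raise ConfigurationError("n_domains must be >= 2 for the discriminator")

    @property
    def seq_len(self) -> int:
        # decoder ends two upsamplings above the bottleneck = input / 2**(n-2)
        return self.input_size // (2 ** (len(self.encoder_widths) - 2))

    @property
    def feature_dim(self) -> int:
        return 2 * self.gru_hidden

    def se_reduction(self, channels: int) -> int:
        return max(channels // 16, 1)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _init_conv(rng, params, name, kh, kw, cin, cout):
    params[f"{name}.w"] = Tensor(
        _glorot(rng, (kh, kw, cin, cout), kh * kw * cin, kh * kw * cout),
        requires_grad=True)
    params[f"{name}.b"] = Tensor(np.zeros(cout, np.float32), requires_grad=True)


def _init_dense(rng, params, name, nin, nout):
    params[f"{name}.w"] = Tensor(_glorot(rng, (nin, nout), nin, nout),
                                 requires_grad=True)
    params[f"{name}.b"] = Tensor(np.zeros(nout, np.float32), requires_grad=True)


def _init_se(rng, params, name, channels, r):
    mid = max(channels // r, 1)
    _init_dense(rng, params, f"{name}.fc1", channels, mid)
    _init_dense(rng, params, f"{name}.fc2", mid, channels)


def _init_gru(rng, params, name, nin, hidden):
    for gate in ("z", "r", "h"):
        _init_dense(rng, params, f"{name}.x{gate}", nin, hidden)
        _init_dense(rng, params, f"{name}.h{gate}", hidden, hidden)


def init_params(config: ModelConfig) -> dict[str, Tensor]:
    """Glorot-uniform initialization of every learnable tensor, seeded."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}
    cin = config.in_channels
    for i, width in enumerate(config.encoder_widths):
        stage = f"enc{i}"
        _init_conv(rng, params, f"{stage}.proj.conv", 3, 3, cin, width)
        _init_conv(rng, params, f"{stage}.proj.shortcut", 1, 1, cin, width)
        _init_se(rng, params, f"{stage}.proj.se", width, config.se_reduction(width))
        _init_conv(rng, params, f"{stage}.std.conv", 3, 3, width, width)
        _init_se(rng, params, f"{stage}.std.se", width, config.se_reduction(width))
        cin = width
    # decoder: two fusion 1x1 convs after skip concatenation
    widths = config.encoder_widths
    dc = config.decoder_channels
    _init_conv(rng, params, "dec0.fuse", 1, 1, widths[-1] + widths[-2], dc)
    _init_conv(rng, params, "dec1.fuse", 1, 1, dc + widths[-3], dc)
    for direction in ("fwd", "bwd"):
        _init_gru(rng, params, f"gru.{direction}", dc, config.gru_hidden)
    flat = config.seq_len * config.feature_dim
    h1, h2 = config.head_hidden
    _init_dense(rng, params, "cls.fc1", flat, h1)
    _init_dense(rng, params, "cls.fc2", h1, h2)
    _init_dense(rng, params, "cls.out", h2, N_STAGES)
    if config.use_discriminator:
        _init_dense(rng, params, "dom.fc1", flat, h1)
        _init_dense(rng, params, "dom.fc2", h1, h2)
        _init_dense(rng, params, "dom.out", h2, config.n_domains)
    return params


def conv_param_names(params: dict[str, Tensor]) -> list[str]:
    """Encoder + decoder convolution/SE parameters (the fine-tune freeze set)."""
    return [k for k in params
            if k.startswith("enc") or k.startswith("dec")]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def se_block(o: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor) -> Tensor:
    """Squeeze-and-excitation channel recalibration.

    Squeeze: global average pool per channel, z_c = mean_{i,j} o_c(i, j).
    Excite:  s = sigmoid(W2 · relu(W1 · z + b1) + b2), components in (0, 1).
    Scale:   output(i, j, c) = s_c · o(i, j, c).
    """
    n, h, w, c = o.shape
    z = ad.mean(o, axis=(1, 2))                       # (N, C)
    s = ad.sigmoid(ad.matmul(ad.relu(ad.matmul(z, w1) + b1), w2) + b2)
    return ad.mul(o, ad.reshape(s, (n, 1, 1, c)))


def res_cab(x: Tensor, params: dict[str, Tensor], prefix: str,
            variant: str = "standard", stride: int = 1,
            use_se: bool = True) -> Tensor:
    """Residual channel-attention block.

    standard:   y = relu(SE(conv(x)) + x)            (channels must match)
    projection: y = relu(SE(conv(x)) + conv1x1(x))   (shortcut re-projects)

    With ``use_se=False`` the recalibration is skipped (channel-attention
    ablation) and the block degenerates to a plain residual block.
    """
    o = ad.conv2d(x, params[f"{prefix}.conv.w"], params[f"{prefix}.conv.b"],
                  stride=stride)
    if use_se:
        o = se_block(o, params[f"{prefix}.se.fc1.w"], params[f"{prefix}.se.fc1.b"],
                     params[f"{prefix}.se.fc2.w"], params[f"{prefix}.se.fc2.b"])
    if variant == "standard":
        if stride != 1 or x.shape[-1] != o.shape[-1]:
            raise ConfigurationError(
                "standard Res_CAB needs matching input/output channels and "
                "stride 1; use the projection variant")
        shortcut = x
    elif variant == "projection":
        shortcut = ad.conv2d(x, params[f"{prefix}.shortcut.w"],
                             params[f"{prefix}.shortcut.b"], stride=stride)
    else:
        raise ConfigurationError(f"unknown Res_CAB variant {variant!r}")
    return ad.relu(o + shortcut)


def _gru_direction(x: Tensor, params: dict[str, Tensor], prefix: str,
                   hidden: int, reverse: bool) -> list[Tensor]:
    n, t, _ = x.shape
    h = Tensor(np.zeros((n, hidden), np.float32))
    outs: list[Tensor | None] = [None] * t
    steps = range(t - 1, -1, -1) if reverse else range(t)
    p = params
    for ti in steps:
        xt = ad.take(x, ti, axis=1)
        z = ad.sigmoid(ad.matmul(xt, p[f"{prefix}.xz.w"]) + p[f"{prefix}.xz.b"]
                       + ad.matmul(h, p[f"{prefix}.hz.w"]) + p[f"{prefix}.hz.b"])
        r = ad.sigmoid(ad.matmul(xt, p[f"{prefix}.xr.w"]) + p[f"{prefix}.xr.b"]
                       + ad.matmul(h, p[f"{prefix}.hr.w"]) + p[f"{prefix}.hr.b"])
        hh = ad.tanh(ad.matmul(xt, p[f"{prefix}.xh.w"]) + p[f"{prefix}.xh.b"]
                     + ad.matmul(ad.mul(r, h), p[f"{prefix}.hh.w"])
                     + p[f"{prefix}.hh.b"])
        h = ad.add(ad.mul(1.0 - z, h), ad.mul(z, hh))
        outs[ti] = h
    return outs  # type: ignore[return-value]


def bigru(x: Tensor, params: dict[str, Tensor], hidden: int) -> Tensor:
    """Bidirectional GRU over a (N, T, F) sequence -> (N, T, 2*hidden)."""
    fwd = _gru_direction(x, params, "gru.fwd", hidden, reverse=False)
    bwd = _gru_direction(x, params, "gru.bwd", hidden, reverse=True)
    n = x.shape[0]
    steps = [ad.reshape(ad.concat([f, b], axis=1), (n, 1, 2 * hidden))
             for f, b in zip(fwd, bwd)]
    return ad.concat(steps, axis=1)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def encode(x: Tensor, params: dict[str, Tensor],
           config: ModelConfig) -> list[Tensor]:
    """Run the encoder; returns per-stage feature maps (last = bottleneck)."""
    feats = []
    h = x
    for i in range(len(config.encoder_widths)):
        h = res_cab(h, params, f"enc{i}.proj", variant="projection",
                    stride=2, use_se=config.use_se)
        h = res_cab(h, params, f"enc{i}.std", variant="standard",
                    use_se=config.use_se)
        feats.append(h)
    return feats


def feature_extract(x: Tensor, params: dict[str, Tensor],
                    config: ModelConfig) -> Tensor:
    """Map an input batch (N, S, S, C) to feature sequences (N, T, 2H).

    Encoder bottleneck -> two upsample-by-2 decoder stages, each
    concatenating the encoder feature map of equal resolution and fusing
    with a 1×1 convolution -> mean over the vertical (frequency) axis ->
    bidirectional GRU.
    """
    n, h, w, c = x.shape
    if (h, w, c) != (config.input_size, config.input_size, config.in_channels):
        raise ValueError(
            f"expected input ({config.input_size}, {config.input_size}, "
            f"{config.in_channels}), got ({h}, {w}, {c})")
    feats = encode(x, params, config)
    f = feats[-1]
    for k, skip in enumerate((feats[-2], feats[-3])):
        f = ad.upsample2(f)
        f = ad.concat([f, skip], axis=-1)
        f = ad.relu(ad.conv2d(f, params[f"dec{k}.fuse.w"],
                              params[f"dec{k}.fuse.b"]))
    seq = ad.mean(f, axis=1)  # collapse frequency axis -> (N, T, dc)
    out = bigru(seq, params, config.gru_hidden)
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError("non-finite values in extracted features")
    return out


def _fc_head(f: Tensor, params: dict[str, Tensor], prefix: str) -> Tensor:
    h = ad.relu(ad.matmul(f, params[f"{prefix}.fc1.w"]) + params[f"{prefix}.fc1.b"])
    h = ad.relu(ad.matmul(h, params[f"{prefix}.fc2.w"]) + params[f"{prefix}.fc2.b"])
    logits = ad.matmul(h, params[f"{prefix}.out.w"]) + params[f"{prefix}.out.b"]
    return ad.softmax(logits, axis=-1)


def label_predict(features: Tensor, params: dict[str, Tensor]) -> Tensor:
    """Stage probabilities (N, 5) from flattened feature sequences."""
    n = features.shape[0]
    flat = ad.reshape(features, (n, -1))  # step-major flattening
    return _fc_head(flat, params, "cls")


def domain_predict(features: Tensor, params: dict[str, Tensor],
                   lambda_: float = 1.0) -> Tensor:
    """Domain probabilities (N, n_domains), reached through the GRL."""
    n = features.shape[0]
    flat = ad.grl(ad.reshape(features, (n, -1)), lambda_)
    return _fc_head(flat, params, "dom")


def forward(x: Tensor, params: dict[str, Tensor], config: ModelConfig,
            lambda_: float | None = None) -> tuple[Tensor, Tensor, Tensor | None]:
    """Full forward pass: (features, stage probabilities, domain probabilities).

    Domain probabilities are ``None`` when the discriminator is disabled.
    """
    features = feature_extract(x, params, config)
    stage_probs = label_predict(features, params)
    dom_probs = None
    if config.use_discriminator:
        lam = config.lambda_ if lambda_ is None else lambda_
        dom_probs = domain_predict(features, params, lam)
    return features, stage_probs, dom_probs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: dict[str, Tensor], config: ModelConfig) -> None:
    """Write weights (.npz) plus a JSON architecture manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **{k: p.data for k, p in params.items()})
    manifest = {"config": config.to_dict(), "config_hash": config.hash(),
                "shapes": {k: list(p.shape) for k, p in params.items()}}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = manifest["config"]
    cfg_dict["encoder_widths"] = tuple(cfg_dict["encoder_widths"])
    cfg_dict["head_hidden"] = tuple(cfg_dict["head_hidden"])
    config = ModelConfig(**cfg_dict)
    with np.load(path) as data:
        params = {k: Tensor(data[k], requires_grad=True) for k in data.files}
    return params, config
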