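"""Classifier architectures for band-filtered EEG epochs.

Two multi-resolution convolutional networks operate on (batch, channels,
samples) epoch arrays:

* **MRCNN-RSE** — two parallel convolution branches with kernel ladders
  (4, 3, 3) and (10, 3, 3), each layer followed by batch normalization and a
  GELU, with max pooling after the first and third convolutions. The branch
  outputs are concatenated along the feature-channel axis, recalibrated by a
  residual squeeze-and-excitation (RSE) block, passed through temporal
  self-attention with two add-and-normalize stages, pooled over time, and
  classified by a softmax layer.

* **MRCNN-LSTM** — three parallel convolution branches (ReLU) with different
  kernel sizes capturing small/medium/large temporal receptive fields; their
  concatenated feature sequence feeds a single LSTM layer whose final hidden
  state goes through a fully connected layer with dropout and a softmax
  classifier.

Branches shrink the time axis by different amounts (valid convolutions), so
branch outputs are center-cropped to the shortest length before
concatenation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn.layers import cross_entropy, log_softmax, softmax  # noqa: F401 (re-export)

__all__ = [
    "ModelSpec",
    "build_model",
    "MRCNNRSE",
    "MRCNNLSTM",
    "RSEBlock",
    "SelfAttention",
    "FeatureMap",
    "save_model",
    "load_model",
]

#: A feature map is a (batch, feature-channels, time) tensor.
FeatureMap = Tensor


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    ``conv_filters`` gives the per-layer output channel counts used in every
    branch; ``se_reduction`` is the bottleneck ratio of the RSE block and must
    divide the concatenated feature count; ``attention_dim=None`` sets the
    attention width to the concatenated feature count.
    """

    architecture: str = "MRCNN_RSE"  # or "MRCNN_LSTM"
    in_channels: int = 6
    in_samples: int = 500
    rse_branch_kernels: tuple[tuple[int, int, int], ...] = ((4, 3, 3), (10, 3, 3))
    lstm_branch_kernels: tuple[int, ...] = (3, 5, 11)
    conv_filters: tuple[int, int, int] = (32, 64, 64)
    se_reduction: int = 8
    lstm_hidden: int = 64
    dropout_rate: float = 0.5
    attention_dim: int | None = None
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.architecture not in ("MRCNN_RSE", "MRCNN_LSTM"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        kernels = [k for br in self.rse_branch_kernels for k in br]
        kernels += list(self.lstm_branch_kernels)
        for k in kernels:
            if not 1 <= k <= self.in_samples:
                raise ValueError(
                    f"kernel size {k} outside [1, in_samples={self.in_samples}]"
                )

    @property
    def feature_channels(self) -> int:
        """Feature-channel count after branch concatenation (RSE variant)."""
        return self.conv_filters[-1] * len(self.rse_branch_kernels)

    def scaled(self, factor: int = 4) -> "ModelSpec":
        """A smaller model (filters and widths divided by ``factor``) for
        CPU-budget training runs."""
        return ModelSpec(
            architecture=self.architecture,
            in_channels=self.in_channels,
            in_samples=self.in_samples,
            rse_branch_kernels=self.rse_branch_kernels,
            lstm_branch_kernels=self.lstm_branch_kernels,
            conv_filters=tuple(max(f // factor, 4) for f in self.conv_filters),
            se_reduction=self.se_reduction,
            lstm_hidden=max(self.lstm_hidden // factor, 8),
            dropout_rate=self.dropout_rate,
            attention_dim=self.attention_dim,
            n_classes=self.n_classes,
        )


def _branch_out_len(in_samples: int, kernels: tuple[int, ...], pool_after: tuple[int, ...],
                    pool: int, branch_name: str) -> int:
    """Time-axis length after a branch; raises at build time if it collapses."""
    length = in_samples
    for i, k in enumerate(kernels):
        length = length - k + 1
        if length < 1:
            raise ValueError(
                f"{branch_name}: conv layer {i} (kernel {k}) reduces the time axis "
                f"below 1 sample"
            )
        if i in pool_after:
            length //= pool
            if length < 1:
                raise ValueError(
                    f"{branch_name}: pooling after conv layer {i} reduces the time "
                    f"axis below 1 sample"
                )
    return length


class _ConvBranch(nn.Module):
    """conv(+BN)+activation x3 with pooling after selected layers."""

    def __init__(self, in_channels: int, kernels: tuple[int, ...],
                 filters: tuple[int, ...], rng: np.random.Generator,
                 activation: str = "gelu", batch_norm: bool = True,
                 pool_after: tuple[int, ...] = (0, 2), pool: int = 2):
        super().__init__()
        layers: list[nn.Module] = []
        c = in_channels
        for i, (k, f) in enumerate(zip(kernels, filters)):
            layers.append(nn.Conv1d(c, f, k, rng))
            if batch_norm:
                layers.append(nn.BatchNorm1d(f))
            layers.append(nn.GELU() if activation == "gelu" else nn.ReLU())
            if i in pool_after:
                layers.append(nn.MaxPool1d(pool))
            c = f
        self.stack = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.stack(x)


def _center_crop(t: Tensor, length: int) -> Tensor:
    extra = t.shape[-1] - length
    if extra == 0:
        return t
    lo = extra // 2
    return t[:, :, lo : lo + length]


class MRCNNExtractor(nn.Module):
    """Parallel multi-resolution branches concatenated along feature channels."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator,
                 activation: str = "gelu", batch_norm: bool = True,
                 pool_after: tuple[int, ...] = (0, 2), pool: int = 2,
                 branch_kernels: tuple[tuple[int, ...], ...] | None = None):
        super().__init__()
        branch_kernels = branch_kernels or spec.rse_branch_kernels
        self.out_len = min(
            _branch_out_len(spec.in_samples, ks, pool_after, pool, f"branch {i}")
            for i, ks in enumerate(branch_kernels)
        )
        self.branches = [
            _ConvBranch(spec.in_channels, ks, spec.conv_filters, rng,
                        activation=activation, batch_norm=batch_norm,
                        pool_after=pool_after, pool=pool)
            for ks in branch_kernels
        ]
        self.out_channels = spec.conv_filters[-1] * len(self.branches)

    def forward(self, x: Tensor) -> FeatureMap:
        outs = [_center_crop(br(x), self.out_len) for br in self.branches]
        return nn.concatenate(outs, axis=1)


class RSEBlock(nn.Module):
    """Residual squeeze-and-excitation recalibration of a feature map.

    The residual path transforms the features with two kernel-1 convolutions;
    the gating path squeezes the incoming feature map to one descriptor per
    channel by global average pooling, bottlenecks it (ReLU, ``reduction``)
    and expands it back through a sigmoid, yielding per-channel gates in
    (0, 1). Output = input + gates * transformed.

    ``force_gate_value`` is a test hook: when set, the gates are replaced by
    that constant (1.0 isolates the pure residual path).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"feature count {channels} not divisible by se_reduction {reduction}"
            )
        self.conv1 = nn.Conv1d(channels, channels, 1, rng)
        self.conv2 = nn.Conv1d(channels, channels, 1, rng)
        self.fc_squeeze = nn.Linear(channels, channels // reduction, rng)
        self.fc_excite = nn.Linear(channels // reduction, channels, rng)
        self.force_gate_value: float | None = None

    def squeeze_descriptor(self, fm: FeatureMap) -> Tensor:
        """Global average pool: one value per feature channel, (B, C)."""
        return fm.mean(axis=2)

    def gates(self, fm: FeatureMap) -> Tensor:
        s = self.squeeze_descriptor(fm)
        return self.fc_excite(self.fc_squeeze(s).relu()).sigmoid()

    def forward(self, fm: FeatureMap) -> FeatureMap:
        t = self.conv2(self.conv1(fm).gelu())
        if self.force_gate_value is not None:
            g = Tensor(np.full(fm.shape[:2], self.force_gate_value, dtype=np.float32))
        else:
            g = self.gates(fm)
        B, C = g.shape
        return fm + g.reshape(B, C, 1) * t


class _LayerNormLast(nn.Module):
    """Layer normalization over the last (feature) axis of (B, L, F) data."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = nn.Parameter(np.ones(dim))
        self.beta = nn.Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc * ((v + self.eps) ** -0.5)) + self.beta


class SelfAttention(nn.Module):
    """Scaled dot-product self-attention over time with two add-and-normalize
    stages (residual + layer norm after attention, and again after a
    position-wise feed-forward transform). Single head, no positional
    encoding. Input and output are (B, C, L) feature maps."""

    def __init__(self, channels: int, rng: np.random.Generator, dim: int | None = None):
        super().__init__()
        self.dim = dim or channels
        self.wq = nn.Linear(channels, self.dim, rng)
        self.wk = nn.Linear(channels, self.dim, rng)
        self.wv = nn.Linear(channels, self.dim, rng)
        self.wo = nn.Linear(self.dim, channels, rng)
        self.norm1 = _LayerNormLast(channels)
        self.norm2 = _LayerNormLast(channels)
        self.ff1 = nn.Linear(channels, channels, rng)
        self.ff2 = nn.Linear(channels, channels, rng)
        self.last_attention: np.ndarray | None = None  # (B, L, L), rows sum to 1

    def forward(self, fm: FeatureMap) -> FeatureMap:
        x = fm.transpose(0, 2, 1)  # (B, L, C)
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dim))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        ctx = self.wo(attn @ v)
        x = self.norm1(x + ctx)
        x = self.norm2(x + self.ff2(self.ff1(x).gelu()))
        return x.transpose(0, 2, 1)


class MRCNNRSE(nn.Module):
    """Two-branch multi-resolution CNN + RSE recalibration + self-attention."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        if spec.architecture != "MRCNN_RSE":
            raise ValueError(f"spec is for {spec.architecture}")
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.mrcnn = MRCNNExtractor(spec, rng, activation="gelu", batch_norm=True)
        c = self.mrcnn.out_channels
        self.rse = RSEBlock(c, spec.se_reduction, rng)
        self.attention = SelfAttention(c, rng, spec.attention_dim)
        self.head = nn.Linear(c, spec.n_classes, rng)

    def forward(self, x) -> Tensor:
        """Logits (batch, n_classes); apply softmax for probabilities."""
        x = _as_batch(x, self.spec)
        fm = self.mrcnn(x)
        fm = self.rse(fm)
        fm = self.attention(fm)
        pooled = fm.mean(axis=2)
        return self.head(pooled)


class MRCNNLSTM(nn.Module):
    """Three-branch multi-resolution CNN + LSTM over the feature sequence."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        if spec.architecture != "MRCNN_LSTM":
            raise ValueError(f"spec is for {spec.architecture}")
        rng = np.random.default_rng(seed)
        self.spec = spec
        # deeper pooling (4x twice) keeps the LSTM sequence short
        branch_kernels = tuple((k, 3, 3) for k in spec.lstm_branch_kernels)
        self.mrcnn = MRCNNExtractor(
            spec, rng, activation="relu", batch_norm=True,
            pool_after=(0, 2), pool=4, branch_kernels=branch_kernels,
        )
        c = self.mrcnn.out_channels
        self.lstm = nn.LSTM(c, spec.lstm_hidden, rng)
        self.fc = nn.Linear(spec.lstm_hidden, spec.lstm_hidden // 2, rng)
        self.dropout = nn.Dropout(
            spec.dropout_rate, np.random.default_rng(rng.integers(0, 2**31))
        )
        self.head = nn.Linear(spec.lstm_hidden // 2, spec.n_classes, rng)

    def forward(self, x) -> Tensor:
        x = _as_batch(x, self.spec)
        fm = self.mrcnn(x)  # (B, C, T)
        h = self.lstm(fm.transpose(0, 2, 1))
        h = self.dropout(self.fc(h).relu())
        return self.head(h)


def _as_batch(x, spec: ModelSpec) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if t.ndim != 3 or t.shape[1] != spec.in_channels or t.shape[2] != spec.in_samples:
        raise ValueError(
            f"expected batch of shape (n, {spec.in_channels}, {spec.in_samples}), "
            f"got {tuple(t.shape)}"
        )
    return t


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Module:
    """Instantiate the architecture named by the spec with a deterministic
    initialization: identical (spec, seed) yields identical parameters."""
    if spec.architecture == "MRCNN_RSE":
        return MRCNNRSE(spec, seed)
    return MRCNNLSTM(spec, seed)


def predict_proba(model: nn.Module, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Class probabilities for an epoch array, evaluated without gradients."""
    model.eval()
    probs = []
    with nn.no_grad():
        for i in range(0, len(x), batch_size):
            logits = model(x[i : i + batch_size])
            probs.append(softmax(logits, axis=1).data)
    return np.concatenate(probs, axis=0)


def save_model(model: nn.Module, path: str | Path, extra: dict | None = None) -> Path:
    """Persist spec + parameters (npz) with a JSON description alongside."""
    path = Path(path)
    stem = path.with_suffix("")
    state = model.state_dict()
    np.savez(stem.with_suffix(".npz"), **state)
    desc = {"spec": asdict(model.spec), "n_parameters": model.n_parameters()}
    if extra:
        desc.update(extra)
    stem.with_suffix(".json").write_text(json.dumps(desc, indent=1))
    return stem.with_suffix(".npz")


def load_model(path: str | Path) -> nn.Module:
    stem = Path(path).with_suffix("")
    desc = json.loads(stem.with_suffix(".json").read_text())
    spec_dict = desc["spec"]
    spec_dict["rse_branch_kernels"] = tuple(map(tuple, spec_dict["rse_branch_kernels"]))
    spec_dict["lstm_branch_kernels"] = tuple(spec_dict["lstm_branch_kernels"])
    spec_dict["conv_filters"] = tuple(spec_dict["conv_filters"])
    spec = ModelSpec(**spec_dict)
    model = build_model(spec)
    with np.load(stem.with_suffix(".npz")) as state:
        model.load_state_dict({k: state[k] for k in state.files})
    return model
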