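"""The squiggle classifier: a 1-D convolutional stem, squeeze-and-excitation
channel weighting, three residual blocks, a second SE stage, global average
pooling and a fully connected bi-classifier over {host, target}.

Topology is fixed (conv -> SE -> 3 residual blocks -> SE -> GAP -> FC); all
layer sizes are configurable through :class:`ClassifierSpec`. Global average
pooling makes the forward pass defined for any input at or above the stem's
minimum receptive field, so the same network can score decision windows of
different lengths.
"""

from __future__ import annotations

import io as _io
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import InvalidArgumentError
from .preprocess import CLASS_LABELS, SignalChunk

__all__ = [
    "CLASS_LABELS",
    "ClassifierSpec",
    "SquiggleClassifier",
    "se_excite",
    "classify_batch",
]

FORMAT_VERSION = 1


@dataclass
class ClassifierSpec:
    """Architecture hyperparameters of the classifier.

    The residual stack depth is fixed at three blocks; channel widths,
    kernels, stride, pooling and the SE reduction ratio are free.
    """

    conv_channels: int = 32
    conv_kernel: int = 19
    conv_stride: int = 3
    stem_pool: int = 2
    se_reduction: int = 4
    n_residual_blocks: int = 3
    residual_channels: tuple[int, int, int] = (32, 64, 128)
    residual_kernel: int = 3
    residual_stride: int = 2
    n_classes: int = 2
    batch_norm: bool = True

    def __post_init__(self) -> None:
        self.residual_channels = tuple(self.residual_channels)
        if self.n_residual_blocks != 3:
            raise InvalidArgumentError("the residual stack is fixed at 3 blocks")
        if len(self.residual_channels) != 3:
            raise InvalidArgumentError("residual_channels must have 3 entries")
        if self.n_classes != 2:
            raise InvalidArgumentError("the classifier is binary")
        for c in (self.conv_channels, *self.residual_channels):
            if c % self.se_reduction != 0:
                raise InvalidArgumentError(
                    f"channel width {c} must be divisible by se_reduction {self.se_reduction}"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "ClassifierSpec":
        data = json.loads(payload)
        data["residual_channels"] = tuple(data["residual_channels"])
        return cls(**data)


def se_excite(
    x: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """Functional squeeze-and-excitation on a (C, T) or (N, C, T) map.

    squeeze s_c = mean_t x[c, t]; excitation e = sigmoid(W2 relu(W1 s + b1)
    + b2); output channel c = e_c * x[c]. Excitations lie strictly in (0, 1).
    """
    x = np.asarray(x, dtype=float)
    squeeze_batch = x.ndim == 2
    if squeeze_batch:
        x = x[None]
    if x.ndim != 3:
        raise InvalidArgumentError("input must be (C, T) or (N, C, T)")
    c = x.shape[1]
    w1, w2 = np.asarray(w1, dtype=float), np.asarray(w2, dtype=float)
    if w1.shape[1] != c or w2.shape[0] != c or w1.shape[0] != w2.shape[1]:
        raise InvalidArgumentError(
            f"excitation weights incompatible with {c} channels: "
            f"W1 {w1.shape}, W2 {w2.shape}"
        )
    s = x.mean(axis=2)
    h = np.maximum(s @ w1.T + np.asarray(b1, dtype=float), 0.0)
    e = 1.0 / (1.0 + np.exp(-(h @ w2.T + np.asarray(b2, dtype=float))))
    y = x * e[:, :, None]
    return y[0] if squeeze_batch else y


def _build_network(spec: ClassifierSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Module] = [
        nn.Conv1d(1, spec.conv_channels, spec.conv_kernel, spec.conv_stride, rng)
    ]
    if spec.batch_norm:
        layers.append(nn.BatchNorm1d(spec.conv_channels))
    layers.append(nn.ReLU())
    layers.append(nn.SE1d(spec.conv_channels, spec.se_reduction, rng))
    if spec.stem_pool > 1:
        layers.append(nn.MaxPool1d(spec.stem_pool))
    in_ch = spec.conv_channels
    for out_ch in spec.residual_channels:
        layers.append(
            nn.ResidualBlock1d(
                in_ch,
                out_ch,
                kernel=spec.residual_kernel,
                stride=spec.residual_stride,
                batch_norm=spec.batch_norm,
                rng=rng,
            )
        )
        in_ch = out_ch
    layers.append(nn.SE1d(in_ch, spec.se_reduction, rng))
    layers.append(nn.GlobalAvgPool1d())
    layers.append(nn.Linear(in_ch, spec.n_classes, rng))
    return nn.Sequential(*layers)


class SquiggleClassifier:
    """The classifier model object: architecture plus (fitted) parameters.

    Construct from a spec (randomly initialised, deterministic per seed),
    fit with :func:`nanoselect.train_eval.train`, then use
    :meth:`predict_proba` / :meth:`forward` / :func:`classify_batch`.
    """

    def __init__(self, spec: ClassifierSpec | None = None, seed: int = 0):
        self.spec = spec or ClassifierSpec()
        self.seed = seed
        self.net = _build_network(self.spec, np.random.default_rng(seed))
        self.training_meta: dict = {}
        self.history: dict[str, list[float]] = {}

    # -- introspection ----------------------------------------------------

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def min_input_length(self) -> int:
        """Smallest input length the stack accepts (final length >= 1)."""
        lo, hi = 1, 1
        while True:
            try:
                if self.net.out_length(hi) >= 1:
                    break
            except InvalidArgumentError:
                pass
            lo, hi = hi + 1, hi * 2
            if hi > 1 << 20:  # pragma: no cover - malformed spec guard
                raise InvalidArgumentError("no admissible input length below 2^20")
        while lo < hi:
            mid = (lo + hi) // 2
            try:
                ok = self.net.out_length(mid) >= 1
            except InvalidArgumentError:
                ok = False
            if ok:
                hi = mid
            else:
                lo = mid + 1
        return lo

    def describe(self) -> str:
        lines = [
            "SquiggleClassifier",
            f"  parameters: {self.param_count()}",
            f"  minimum input length: {self.min_input_length()} samples",
            f"  spec: {self.spec.to_json()}",
        ]
        if self.training_meta:
            lines.append(f"  training: {json.dumps(self.training_meta)}")
        return "\n".join(lines)

    def summary(self) -> str:
        return self.describe()

    # -- inference --------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for a (n, T) batch of equal-length signals."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None]
        min_len = self.min_input_length()
        if X.shape[1] < min_len:
            raise InvalidArgumentError(
                f"input length {X.shape[1]} is below the minimum admissible "
                f"length {min_len} for this architecture"
            )
        logits = self.net.forward(X[:, None, :], training=False)
        return nn.softmax(logits)

    def forward(self, chunk: SignalChunk | np.ndarray) -> tuple[float, float]:
        """Probability pair (p_host, p_target) for one chunk."""
        values = chunk.values if isinstance(chunk, SignalChunk) else np.asarray(chunk)
        p = self.predict_proba(values[None])[0]
        return float(p[0]), float(p[1])

    # -- serialization ----------------------------------------------------

    def save(self, path: str) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        buffers = {}
        for i, m in enumerate(self.net.modules):
            if isinstance(m, nn.BatchNorm1d):
                buffers[f"bn_{i}_mean"] = m.running_mean
                buffers[f"bn_{i}_var"] = m.running_var
            if isinstance(m, nn.ResidualBlock1d) and m.batch_norm:
                for j, bn in enumerate((m.bn1, m.bn2, m.bn_proj)):
                    buffers[f"rbn_{i}_{j}_mean"] = bn.running_mean
                    buffers[f"rbn_{i}_{j}_var"] = bn.running_var
        header = json.dumps(
            {
                "format_version": FORMAT_VERSION,
                "spec": asdict(self.spec),
                "seed": self.seed,
                "training_meta": self.training_meta,
            }
        )
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays, **buffers)

    @classmethod
    def load(cls, path: str) -> "SquiggleClassifier":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            if header["format_version"] != FORMAT_VERSION:
                raise InvalidArgumentError(
                    f"unsupported model format version {header['format_version']}"
                )
            spec_data = header["spec"]
            spec_data["residual_channels"] = tuple(spec_data["residual_channels"])
            model = cls(ClassifierSpec(**spec_data), seed=header["seed"])
            model.training_meta = header["training_meta"]
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"param_{i}"]
            for i, m in enumerate(model.net.modules):
                if isinstance(m, nn.BatchNorm1d):
                    m.running_mean[...] = data[f"bn_{i}_mean"]
                    m.running_var[...] = data[f"bn_{i}_var"]
                if isinstance(m, nn.ResidualBlock1d) and m.batch_norm:
                    for j, bn in enumerate((m.bn1, m.bn2, m.bn_proj)):
                        bn.running_mean[...] = data[f"rbn_{i}_{j}_mean"]
                        bn.running_var[...] = data[f"rbn_{i}_{j}_var"]
        return model


def classify_batch(
    model: SquiggleClassifier,
    chunks: list[SignalChunk] | np.ndarray,
    batch_size: int = 256,
) -> tuple[list[str], np.ndarray, float]:
    """Labels, probabilities and elapsed seconds for a batch of chunks.

    The label is the argmax class; exact ties go to "target" so that an
    ambiguous read is never rejected (rejecting a rare microbial read is the
    expensive error). Elapsed wall time is reported for throughput summaries
    only — it is hardware-dependent and never asserted.
    """
    if isinstance(chunks, np.ndarray):
        X = np.asarray(chunks, dtype=float)
        if X.ndim == 1:
            X = X[None]
    else:
        if len(chunks) == 0:
            raise InvalidArgumentError("batch must be non-empty")
        X = np.stack([c.values for c in chunks]).astype(float)
    if X.shape[0] == 0:
        raise InvalidArgumentError("batch must be non-empty")

    start = time.perf_counter()
    probs = np.vstack(
        [model.predict_proba(X[i : i + batch_size]) for i in range(0, X.shape[0], batch_size)]
    )
    elapsed = time.perf_counter() - start
    labels = [CLASS_LABELS[1] if p[1] >= p[0] else CLASS_LABELS[0] for p in probs]
    return labels, probs, elapsed
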