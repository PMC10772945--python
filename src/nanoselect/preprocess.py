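"""Signal normalization and fixed-length chunking.

The classifier consumes only the first ~4000 samples of each read (the part
available when a Read-Until decision must be made), normalized per chunk.
Median/MAD scaling is the default because it is robust to current spikes;
plain z-scoring is kept for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DatasetImbalanceError, DegenerateSignalError, InvalidArgumentError
from .simulate import SignalRead

__all__ = [
    "SignalChunk",
    "PreprocessConfig",
    "ChunkDataset",
    "normalize",
    "chunk_read",
    "build_dataset",
]

#: consistent factor making MAD estimate the SD under normality
MAD_SCALE = 1.4826

CLASS_LABELS = ("host", "target")


@dataclass
class PreprocessConfig:
    chunk_length: int = 4000
    skip_samples: int = 0
    normalization: str = "median_mad"  # or "zscore"

    def __post_init__(self) -> None:
        if self.chunk_length < 1:
            raise InvalidArgumentError("chunk_length must be >= 1")
        if self.skip_samples < 0:
            raise InvalidArgumentError("skip_samples must be >= 0")
        if self.normalization not in ("median_mad", "zscore"):
            raise InvalidArgumentError(f"unknown normalization {self.normalization!r}")


@dataclass
class SignalChunk:
    """A fixed-length normalized signal vector with its class label."""

    values: np.ndarray
    class_label: str
    read_id: str
    species: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if not np.isfinite(self.values).all():
            raise InvalidArgumentError("chunk values must be finite")


def normalize(signal: np.ndarray, method: str = "median_mad") -> np.ndarray:
    """Scale a pA signal to dimensionless units.

    median_mad: (x - median) / (1.4826 * MAD); zscore: (x - mean) / sd.
    Raises DegenerateSignalError when the spread is zero so callers can skip
    the read.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError("signal must have at least 2 samples")
    if method == "median_mad":
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            raise DegenerateSignalError("MAD is zero; signal has no spread")
        return (x - med) / (MAD_SCALE * mad)
    if method == "zscore":
        sd = x.std()
        if sd == 0:
            raise DegenerateSignalError("SD is zero; signal has no spread")
        return (x - x.mean()) / sd
    raise InvalidArgumentError(f"unknown normalization {method!r}")


def chunk_read(read: SignalRead, cfg: PreprocessConfig | None = None) -> SignalChunk | None:
    """Cut and normalize one decision window from the start of a read.

    Returns None (a skip) when the read is too short or its window is
    degenerate; skips are counted by :func:`build_dataset`.
    """
    cfg = cfg or PreprocessConfig()
    end = cfg.skip_samples + cfg.chunk_length
    if read.n_samples < end:
        return None
    window = read.to_pa()[cfg.skip_samples : end]
    try:
        values = normalize(window, cfg.normalization)
    except DegenerateSignalError:
        return None
    return SignalChunk(
        values=values.astype(np.float32),
        class_label=read.class_label,
        read_id=read.read_id,
        species=read.species,
    )


@dataclass
class ChunkDataset:
    """A labelled chunk set: one row per chunk, host=0 / target=1 labels."""

    X: np.ndarray  # (n_chunks, chunk_length) float32
    y: np.ndarray  # (n_chunks,) int, index into CLASS_LABELS
    read_ids: list[str]
    species: list[str]
    skipped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.X.shape[0])

    @property
    def class_labels(self) -> list[str]:
        return [CLASS_LABELS[i] for i in self.y]

    def class_counts(self) -> dict[str, int]:
        return {lbl: int((self.y == i).sum()) for i, lbl in enumerate(CLASS_LABELS)}

    def subset(self, indices: np.ndarray) -> "ChunkDataset":
        indices = np.asarray(indices)
        return ChunkDataset(
            X=self.X[indices],
            y=self.y[indices],
            read_ids=[self.read_ids[i] for i in indices],
            species=[self.species[i] for i in indices],
            skipped=dict(self.skipped),
        )


def build_dataset(
    reads: list[SignalRead], cfg: PreprocessConfig | None = None, seed: int = 0
) -> ChunkDataset:
    """Chunk every eligible read into one labelled chunk, shuffled by seed.

    Raises DatasetImbalanceError unless both classes contribute at least one
    chunk; too-short and degenerate reads are skipped and counted per class.
    """
    cfg = cfg or PreprocessConfig()
    present = {r.class_label for r in reads}
    if not set(CLASS_LABELS) <= present:
        missing = set(CLASS_LABELS) - present
        raise DatasetImbalanceError(f"no reads for class(es): {sorted(missing)}")

    chunks: list[SignalChunk] = []
    skipped = {lbl: 0 for lbl in CLASS_LABELS}
    for read in reads:
        chunk = chunk_read(read, cfg)
        if chunk is None:
            skipped[read.class_label] += 1
        else:
            chunks.append(chunk)

    counts = {lbl: sum(1 for c in chunks if c.class_label == lbl) for lbl in CLASS_LABELS}
    empty = [lbl for lbl, n in counts.items() if n == 0]
    if empty:
        raise DatasetImbalanceError(f"no eligible chunks for class(es): {empty}")

    order = np.random.default_rng(seed).permutation(len(chunks))
    X = np.stack([chunks[i].values for i in order])
    y = np.array([CLASS_LABELS.index(chunks[i].class_label) for i in order], dtype=int)
    return ChunkDataset(
        X=X,
        y=y,
        read_ids=[chunks[i].read_id for i in order],
        species=[chunks[i].species for i in order],
        skipped=skipped,
    )
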