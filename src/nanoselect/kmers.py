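"""6mer composition and per-kmer signal analysis.

The premise of raw-signal host depletion is that host and microbial genomes
use 6mers at different frequencies, and that each 6mer produces a distinct
current signature — so composition differences are visible in the squiggle
itself. This module provides the desk-scale version of that analysis:
k-mer counting and enrichment ranking on sequences, per-kmer signal pooling
from simulated reads (which carry exact window-to-sample ground truth), and
a PCA over the per-kmer signal summaries.

Real-read signal segmentation is a declared non-goal: extracting per-kmer
signals requires the simulator's ground-truth map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .errors import InvalidArgumentError
from .simulate import BASES, SignalRead, kmer_from_index

__all__ = [
    "KmerProfile",
    "KmerSignalMatrix",
    "PCAResult",
    "kmer_profile",
    "top_enriched",
    "extract_kmer_signals",
    "pca_project",
    "jensen_shannon",
]


@dataclass
class KmerProfile:
    """Counts and frequencies of every kmer on the forward strand."""

    k: int
    counts: np.ndarray  # 4^k non-negative ints
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise InvalidArgumentError(f"counts must have 4^{self.k} entries")
        if (self.counts < 0).any():
            raise InvalidArgumentError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def __add__(self, other: "KmerProfile") -> "KmerProfile":
        if self.k != other.k:
            raise InvalidArgumentError("profiles must share k")
        return KmerProfile(
            k=self.k,
            counts=self.counts + other.counts,
            n_ambiguous=self.n_ambiguous + other.n_ambiguous,
        )


def kmer_profile(sequences: list[str] | str, k: int = 6) -> KmerProfile:
    """Count every length-k window on the given strand.

    Windows containing ambiguous (non-ACGT) bases are skipped and counted in
    ``n_ambiguous``. Sequences shorter than k contribute zero counts.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(4**k, dtype=np.int64)
    n_ambiguous = 0
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        code[ord(b)] = i
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for seq in sequences:
        if len(seq) < k:
            continue
        codes = code[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows >= 0).all(axis=1)
        n_ambiguous += int((~valid).sum())
        idx = windows[valid] @ powers
        counts += np.bincount(idx, minlength=4**k)
    return KmerProfile(k=k, counts=counts, n_ambiguous=n_ambiguous)


def enrichment_scores(
    profile_a: KmerProfile, profile_b: KmerProfile, pseudocount: float = 1.0
) -> np.ndarray:
    """log2 enrichment of each kmer in a over b.

    Frequencies are put on the counts-per-4^k scale before adding the
    pseudocount, so absent kmers score finitely:
    score = log2((4^k * freq_a + p) / (4^k * freq_b + p)).
    """
    if profile_a.k != profile_b.k:
        raise InvalidArgumentError("profiles must share k")
    n = 4**profile_a.k
    fa = n * profile_a.freqs + pseudocount
    fb = n * profile_b.freqs + pseudocount
    return np.log2(fa / fb)


def top_enriched(
    profile_a: KmerProfile,
    profile_b: KmerProfile,
    n: int = 10,
    pseudocount: float = 1.0,
) -> list[tuple[str, float]]:
    """Top-n kmers enriched in profile a relative to b, ties lexicographic.

    Swapping the arguments returns the bottom-n of the (negated) scores in
    reversed order.
    """
    scores = enrichment_scores(profile_a, profile_b, pseudocount)
    kmer_names = [kmer_from_index(i, profile_a.k) for i in range(len(scores))]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], kmer_names[i]))
    return [(kmer_names[i], float(scores[i])) for i in order[:n]]


@dataclass
class KmerSignalMatrix:
    """Fixed-width per-kmer signal summaries pooled from simulated reads.

    One row per kmer seen at least ``min_occurrences`` times. Columns:
    mean current (pA), SD, mean dwell (samples), then a w-point resampled
    mean level trace. Provenance records that rows came from simulator
    ground truth.
    """

    kmers: list[str]
    features: np.ndarray  # (n_kmers, 3 + w)
    w: int
    occurrences: np.ndarray
    provenance: str = "simulator ground truth"

    @property
    def feature_names(self) -> list[str]:
        return ["mean_pa", "sd_pa", "mean_dwell"] + [f"trace_{j}" for j in range(self.w)]


def extract_kmer_signals(
    reads: list[SignalRead],
    model_k: int = 6,
    w: int = 8,
    min_occurrences: int = 5,
) -> KmerSignalMatrix:
    """Pool per-kmer signal summaries across reads using ground truth.

    Every read must carry a base-to-sample map (simulated reads do); real
    reads would require signal segmentation, which is out of scope.
    """
    powers = 4 ** np.arange(model_k - 1, -1, -1, dtype=np.int64)
    code = {b: i for i, b in enumerate(BASES)}

    sums: dict[int, float] = {}
    sqsums: dict[int, float] = {}
    counts: dict[int, int] = {}
    dwell_sums: dict[int, int] = {}
    occ: dict[int, int] = {}
    trace_sums: dict[int, np.ndarray] = {}

    for read in reads:
        if read.base_to_sample is None:
            raise InvalidArgumentError(
                "read lacks base-to-sample ground truth; per-kmer signal "
                "extraction requires simulated reads (segmentation of real "
                "reads is a non-goal)"
            )
        if read.sequence is None:
            raise InvalidArgumentError("read lacks a sequence")
        pa = read.to_pa()
        codes = np.array([code[b] for b in read.sequence], dtype=np.int64)
        for base_index, first, last in read.base_to_sample:
            kmer_codes = codes[base_index : base_index + model_k]
            if len(kmer_codes) < model_k:
                continue
            idx = int(kmer_codes @ powers)
            seg = pa[first : last + 1]
            sums[idx] = sums.get(idx, 0.0) + float(seg.sum())
            sqsums[idx] = sqsums.get(idx, 0.0) + float((seg**2).sum())
            counts[idx] = counts.get(idx, 0) + seg.size
            dwell_sums[idx] = dwell_sums.get(idx, 0) + seg.size
            occ[idx] = occ.get(idx, 0) + 1
            # resample this occurrence's samples to w points
            xp = np.linspace(0.0, 1.0, seg.size) if seg.size > 1 else np.array([0.0])
            trace = np.interp(np.linspace(0.0, 1.0, w), xp, seg)
            trace_sums[idx] = trace_sums.get(idx, np.zeros(w)) + trace

    keep = sorted(i for i, n in occ.items() if n >= min_occurrences)
    rows = []
    for i in keep:
        n = counts[i]
        mean = sums[i] / n
        var = max(sqsums[i] / n - mean**2, 0.0)
        rows.append(
            np.concatenate(
                [[mean, np.sqrt(var), dwell_sums[i] / occ[i]], trace_sums[i] / occ[i]]
            )
        )
    features = np.array(rows).reshape(len(keep), 3 + w)
    return KmerSignalMatrix(
        kmers=[kmer_from_index(i, model_k) for i in keep],
        features=features,
        w=w,
        occurrences=np.array([occ[i] for i in keep], dtype=int),
    )


@dataclass
class PCAResult:
    projections: np.ndarray  # (n_rows, n_components)
    loadings: np.ndarray  # (n_components, n_features_retained)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    retained_columns: list[int] = field(default_factory=list)


def pca_project(
    matrix: KmerSignalMatrix | np.ndarray,
    n_components: int = 2,
    scale: bool = False,
) -> PCAResult:
    """Principal components of per-kmer signal summaries.

    Columns are centered (and optionally scaled to unit variance); constant
    columns are dropped with a warning before the decomposition. Projections
    are reproducible up to component sign.
    """
    X = matrix.features if isinstance(matrix, KmerSignalMatrix) else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("matrix must be 2-D")
    if X.shape[0] < n_components + 1:
        raise InvalidArgumentError(
            f"need at least {n_components + 1} rows for {n_components} components"
        )
    variances = X.var(axis=0)
    retained = [int(j) for j in np.flatnonzero(variances > 0)]
    if len(retained) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(retained)} constant column(s) before PCA",
            stacklevel=2,
        )
    if len(retained) < 1:
        raise InvalidArgumentError("all columns are constant")
    Xr = X[:, retained]
    if scale:
        Xr = (Xr - Xr.mean(axis=0)) / Xr.std(axis=0)
    n_components = min(n_components, len(retained), Xr.shape[0] - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    projections = pca.fit_transform(Xr)
    return PCAResult(
        projections=projections,
        loadings=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        retained_columns=retained,
    )


def jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2, in bits) between two frequency
    vectors; symmetric and zero iff the distributions match."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InvalidArgumentError("distributions must have the same shape")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)
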