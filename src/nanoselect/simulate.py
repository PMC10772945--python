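"""Synthetic references, pore models, and labelled squiggle reads.

The simulator emulates a two-pool metagenomic sequencing experiment: a host
pool and one or more microbial pools whose 6mer usage diverges from the
host's. Signals follow the standard nanopore generative picture — roughly six
bases reside in the pore at measurement time, so the expected current is a
function of the current 6mer — with i.i.d. Gaussian noise around a per-6mer
level and a Gaussian dwell time (samples per base) around the translocation
speed. Reads carry an exact base-window-to-sample map as ground truth.

Current levels are expressed in picoamps (pA) and stored as signed 16-bit
DAC units via ``pa = (dac + offset) * range / digitisation``, the calibration
used by MinION-class devices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "ReferencePool",
    "PoreModel",
    "SignalRead",
    "ReadLengthDist",
    "LibraryComponent",
    "LibraryDesign",
    "uniform_kmer_bias",
    "random_kmer_bias",
    "divergent_bias_pair",
    "generate_reference_pool",
    "default_pore_model",
    "sequence_to_squiggle",
    "simulate_library",
    "molar_fractions",
    "mock_community_fmol",
]

BASES = "ACGT"
_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate(BASES)}

#: number of distinct 6mers
N_KMERS = 4096

#: MinION-like defaults: 4 kHz sampling over ~450 nt/s translocation
DEFAULT_SAMPLE_RATE = 4000.0
DEFAULT_DWELL_MEAN = 8.89  # samples per base = 4000 Hz / 450 b/s
DEFAULT_DWELL_SD = 1.0


def _encode(sequence: str) -> np.ndarray:
    """DNA string -> uint8 codes 0..3; raises on non-ACGT."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise InvalidArgumentError(f"sequence contains non-ACGT base {bad!r}")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASE_LOOKUP[codes].tobytes().decode("ascii")


def kmer_index(kmer: str) -> int:
    """Base-4 index of a kmer, first base most significant."""
    idx = 0
    for b in kmer:
        idx = idx * 4 + _CODE[b]
    return idx


def kmer_from_index(idx: int, k: int = 6) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ReferencePool:
    """A pool of synthetic reference sequences sharing one 6mer bias."""

    name: str
    sequences: list[str]
    kmer_bias: np.ndarray

    def __post_init__(self) -> None:
        self.kmer_bias = np.asarray(self.kmer_bias, dtype=float)
        if any(len(s) == 0 for s in self.sequences):
            raise InvalidArgumentError("all pool sequences must be non-empty")
        if self.kmer_bias.shape != (N_KMERS,):
            raise InvalidArgumentError("kmer_bias must have 4096 entries")
        if (self.kmer_bias < 0).any() or not np.isclose(self.kmer_bias.sum(), 1.0):
            raise InvalidArgumentError("kmer_bias must be >= 0 and sum to 1")


@dataclass
class PoreModel:
    """Per-6mer current model plus dwell-time and calibration constants.

    ``level_mean``/``level_sd`` are in pA; dwell parameters in samples per
    base; ``digitisation``, ``offset`` and ``range`` convert DAC units to pA.
    """

    level_mean: np.ndarray
    level_sd: np.ndarray
    k: int = 6
    dwell_mean: float = DEFAULT_DWELL_MEAN
    dwell_sd: float = DEFAULT_DWELL_SD
    sample_rate: float = DEFAULT_SAMPLE_RATE
    digitisation: float = 8192.0
    offset: float = 0.0
    range: float = 1400.0

    def __post_init__(self) -> None:
        self.level_mean = np.asarray(self.level_mean, dtype=float)
        self.level_sd = np.asarray(self.level_sd, dtype=float)
        n = 4**self.k
        if self.level_mean.shape != (n,) or self.level_sd.shape != (n,):
            raise InvalidArgumentError(f"level vectors must have 4^{self.k} entries")
        if (self.level_sd <= 0).any():
            raise InvalidArgumentError("level_sd must be > 0 elementwise")
        if self.dwell_mean <= 0:
            raise InvalidArgumentError("dwell_mean must be > 0")
        if self.digitisation <= 0 or self.range <= 0:
            raise InvalidArgumentError("calibration must be invertible")

    @property
    def samples_per_base(self) -> float:
        return self.dwell_mean

    def pa_to_dac(self, pa: np.ndarray) -> np.ndarray:
        dac = np.rint(np.asarray(pa) * self.digitisation / self.range - self.offset)
        return np.clip(dac, -32768, 32767).astype(np.int16)

    def dac_to_pa(self, dac: np.ndarray) -> np.ndarray:
        return (np.asarray(dac, dtype=float) + self.offset) * self.range / self.digitisation


@dataclass
class SignalRead:
    """One raw read: DAC samples, identity, and optional ground truth.

    ``base_to_sample`` lists (base_index, first_sample, last_sample) for each
    6mer window, indexed by the window's starting base; spans are ordered,
    non-overlapping and jointly cover the whole signal for simulated reads.
    """

    read_id: str
    species: str
    class_label: str  # "host" or "target"
    dac: np.ndarray
    channel: int = 1
    sequence: str | None = None
    base_to_sample: list[tuple[int, int, int]] | None = None
    digitisation: float = 8192.0
    offset: float = 0.0
    range: float = 1400.0

    def __post_init__(self) -> None:
        self.dac = np.asarray(self.dac, dtype=np.int16)
        if self.dac.size < 1:
            raise InvalidArgumentError("dac must contain at least one sample")
        if self.channel < 1:
            raise InvalidArgumentError("channel must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(self.dac.size)

    def to_pa(self) -> np.ndarray:
        return (self.dac.astype(float) + self.offset) * self.range / self.digitisation

    def full_length_bases(self, samples_per_base: float | None = None) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        if samples_per_base is None:
            raise InvalidArgumentError(
                "read has no sequence; samples_per_base required to infer length"
            )
        return int(round(self.n_samples / samples_per_base))


@dataclass
class ReadLengthDist:
    """Log-normal read-length model (bases), truncated to [min, max]."""

    median_bases: float = 3000.0
    sigma_log: float = 0.5
    min_bases: int = 500
    max_bases: int = 50000

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.lognormal(mean=np.log(self.median_bases), sigma=self.sigma_log, size=n)
        return np.clip(np.rint(draws), self.min_bases, self.max_bases).astype(int)


@dataclass
class LibraryComponent:
    species: str
    class_label: str
    molar_amount_fmol: float
    pool: ReferencePool


@dataclass
class LibraryDesign:
    """A mock community: components at designed molar amounts."""

    components: list[LibraryComponent]
    n_reads: int
    read_length_dist: ReadLengthDist = field(default_factory=ReadLengthDist)
    channel_range: tuple[int, int] = (1, 512)

    def __post_init__(self) -> None:
        if not self.components:
            raise InvalidArgumentError("design must have at least one component")
        names = [c.species for c in self.components]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("component species must be unique")
        if any(c.molar_amount_fmol <= 0 for c in self.components):
            raise InvalidArgumentError("molar amounts must be > 0")
        if self.n_reads < len(self.components):
            raise InvalidArgumentError("n_reads must be >= number of components")

    def fractions(self) -> np.ndarray:
        amounts = np.array([c.molar_amount_fmol for c in self.components], dtype=float)
        return amounts / amounts.sum()


# ---------------------------------------------------------------------------
# kmer bias construction


def uniform_kmer_bias(k: int = 6) -> np.ndarray:
    n = 4**k
    return np.full(n, 1.0 / n)


def random_kmer_bias(seed: int, concentration: float = 1.0, k: int = 6) -> np.ndarray:
    """Dirichlet-distributed bias; lower concentration -> spikier usage."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(4**k, concentration))


def _gc_count_per_kmer(k: int) -> np.ndarray:
    """Number of G/C bases in each kmer, indexed base-4 (A=0,C=1,G=2,T=3)."""
    n = 4**k
    idx = np.arange(n)
    gc = np.zeros(n, dtype=int)
    for _ in range(k):
        base = idx % 4
        gc += (base == 1) | (base == 2)
        idx //= 4
    return gc


def divergent_bias_pair(seed: int, tv: float = 0.5, k: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Two biases at an exact total-variation distance ``tv``, structured by
    GC content the way real host/microbe composition differences are.

    The GC-richer half of the kmers (ties broken by a seeded shuffle) is
    up-weighted by a relative factor (1 + tv) in pool A and down-weighted to
    (1 - tv), mirrored in pool B, so TV(a, b) = tv exactly while both remain
    valid distributions. Structuring the divergence along GC content — rather
    than over a random kmer subset — mirrors the composition axis on which
    host and microbial genomes actually differ, and keeps the divergence
    visible in the current signal because pore levels are themselves
    composition-correlated.
    """
    if not 0.0 <= tv <= 1.0:
        raise InvalidArgumentError("tv must be in [0, 1]")
    n = 4**k
    rng = np.random.default_rng(seed)
    key = _gc_count_per_kmer(k) + rng.uniform(0.0, 0.5, n)  # seeded tie-break within GC class
    sign = np.full(n, -1.0)
    sign[np.argsort(key)[n // 2 :]] = 1.0  # GC-rich half up in pool A
    a = (1.0 + tv * sign) / n
    b = (1.0 - tv * sign) / n
    return a, b


# ---------------------------------------------------------------------------
# generators


def generate_reference_pool(
    seed: int,
    n_sequences: int,
    length: int,
    kmer_bias: np.ndarray,
    name: str = "pool",
    k: int = 6,
) -> ReferencePool:
    """Sample sequences from a (k-1)-order Markov chain matching a kmer bias.

    The chain's conditional P(next base | previous k-1 bases) is proportional
    to the bias of the kmer they form, so the stationary kmer distribution
    approximates ``kmer_bias``; the approximation is exact when the bias has
    consistent prefix/suffix marginals (e.g. uniform).
    """
    if length < k:
        raise InvalidArgumentError(f"length must be >= {k}")
    bias = np.asarray(kmer_bias, dtype=float)
    if bias.shape != (4**k,):
        raise InvalidArgumentError(f"kmer_bias must have 4^{k} entries")
    if (bias < 0).any() or bias.sum() <= 0:
        raise InvalidArgumentError("kmer_bias must be non-negative with positive sum")
    bias = bias / bias.sum()

    rng = np.random.default_rng(seed)
    n_ctx = 4 ** (k - 1)
    cond = bias.reshape(n_ctx, 4).copy()
    row_sums = cond.sum(axis=1, keepdims=True)
    dead = row_sums[:, 0] == 0
    cond[dead] = 0.25  # unreachable contexts under the bias: fall back to uniform
    row_sums[dead] = 1.0
    cond_cum = np.cumsum(cond / row_sums, axis=1)

    bias_cum = np.cumsum(bias)
    seqs = np.empty((n_sequences, length), dtype=np.uint8)

    # initial kmer drawn from the bias itself
    first = np.searchsorted(bias_cum, rng.random(n_sequences), side="right")
    first = np.minimum(first, 4**k - 1)
    for j in range(k - 1, -1, -1):
        seqs[:, j] = first % 4
        first //= 4

    state = np.zeros(n_sequences, dtype=np.int64)
    for j in range(k - 1):
        state = state * 4 + seqs[:, j + 1]  # last k-1 bases of the seed kmer
    for pos in range(k, length):
        u = rng.random(n_sequences)
        nxt = (u[:, None] > cond_cum[state]).sum(axis=1)
        seqs[:, pos] = nxt
        state = (state % (4 ** (k - 2))) * 4 + nxt

    sequences = [_decode(seqs[i]) for i in range(n_sequences)]
    return ReferencePool(name=name, sequences=sequences, kmer_bias=bias)


def default_pore_model(seed: int) -> PoreModel:
    """A 6mer pore model with distinct per-kmer levels in 60-120 pA.

    Levels are composition-driven, as in real pore chemistry: each base
    contributes a per-position current offset (centre positions weighted
    most), a small seeded deviation individualises each kmer, and the
    resulting scores are rank-mapped onto unique slots of the 60-120 pA
    range. All 4096 means are therefore pairwise distinct while kmers of
    similar composition keep similar levels — the property that lets
    composition differences between sequence pools show up in the raw
    current. level_sd is a constant 1.5 pA, a typical ONT event spread.
    """
    rng = np.random.default_rng(seed)
    # per-base current contributions; G/C block more current than A/T
    base_contrib = np.array([-1.0, 0.9, 1.1, -1.2])  # A, C, G, T
    pos_weight = np.array([0.6, 0.9, 1.2, 1.2, 0.9, 0.6])
    idx = np.arange(N_KMERS)
    score = np.zeros(N_KMERS)
    for j in range(6):  # base j counted from the kmer's 3' end
        score += pos_weight[5 - j] * base_contrib[idx % 4]
        idx = idx // 4
    score += rng.normal(0.0, 0.15, N_KMERS)  # per-kmer deviation
    ranks = np.argsort(np.argsort(score)).astype(float)
    jitter = rng.uniform(0.05, 0.95, N_KMERS)
    level_mean = 60.0 + 60.0 * (ranks + jitter) / N_KMERS
    level_sd = np.full(N_KMERS, 1.5)
    return PoreModel(level_mean=level_mean, level_sd=level_sd)


def sequence_to_squiggle(
    sequence: str,
    model: PoreModel,
    seed: int,
    read_id: str = "read-0",
    species: str = "unknown",
    class_label: str = "target",
    channel: int = 1,
) -> SignalRead:
    """Simulate the raw signal of one read.

    For each 6mer window i the dwell d_i ~ round(N(dwell_mean, dwell_sd))
    clipped to >= 1 samples, then d_i current samples ~ N(level_mean[kmer_i],
    level_sd[kmer_i]) in pA, converted to int16 DAC units. The returned read
    carries the exact window->sample map.
    """
    k = model.k
    if len(sequence) < k:
        raise InvalidArgumentError(f"sequence must be at least {k} bases")
    codes = _encode(sequence)
    n_windows = len(sequence) - k + 1
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    kmer_idx = windows @ powers

    rng = np.random.default_rng(seed)
    if model.dwell_sd > 0:
        dwell = np.rint(rng.normal(model.dwell_mean, model.dwell_sd, n_windows))
    else:
        dwell = np.full(n_windows, np.rint(model.dwell_mean))
    dwell = np.maximum(dwell, 1).astype(np.int64)

    means = np.repeat(model.level_mean[kmer_idx], dwell)
    sds = np.repeat(model.level_sd[kmer_idx], dwell)
    pa = means + rng.standard_normal(means.size) * sds
    dac = model.pa_to_dac(pa)

    ends = np.cumsum(dwell)
    starts = ends - dwell
    base_to_sample = [(int(i), int(s), int(e - 1)) for i, (s, e) in enumerate(zip(starts, ends))]
    return SignalRead(
        read_id=read_id,
        species=species,
        class_label=class_label,
        dac=dac,
        channel=channel,
        sequence=sequence,
        base_to_sample=base_to_sample,
        digitisation=model.digitisation,
        offset=model.offset,
        range=model.range,
    )


def simulate_library(
    design: LibraryDesign, model: PoreModel, seed: int
) -> list[SignalRead]:
    """Simulate a sequencing run of a mock community.

    Each read's source component is drawn with probability equal to its molar
    fraction, its length from the design's log-normal, its channel uniformly
    over the design's channel range, and its sequence as a random window of a
    random reference in the component's pool.
    """
    rng = np.random.default_rng(seed)
    fractions = design.fractions()
    comp_idx = rng.choice(len(design.components), size=design.n_reads, p=fractions)
    lengths = design.read_length_dist.sample(rng, design.n_reads)
    lengths = np.maximum(lengths, model.k)
    channels = rng.integers(design.channel_range[0], design.channel_range[1] + 1, design.n_reads)
    sub_seeds = rng.integers(0, 2**31 - 1, design.n_reads)

    reads: list[SignalRead] = []
    for i in range(design.n_reads):
        comp = design.components[int(comp_idx[i])]
        ref = comp.pool.sequences[int(rng.integers(len(comp.pool.sequences)))]
        length = int(min(lengths[i], len(ref)))
        start = int(rng.integers(0, len(ref) - length + 1))
        reads.append(
            sequence_to_squiggle(
                ref[start : start + length],
                model,
                seed=int(sub_seeds[i]),
                read_id=f"sim-{seed}-{i:06d}",
                species=comp.species,
                class_label=comp.class_label,
                channel=int(channels[i]),
            )
        )
    return reads


def molar_fractions(amounts: Sequence[float]) -> list[float]:
    """Molar percentages of library components, to two decimals.

    >>> molar_fractions([6, 6, 6, 6, 6, 6, 3, 250])[-1]
    86.51
    """
    amounts = list(amounts)
    if not amounts or any(a <= 0 for a in amounts):
        raise InvalidArgumentError("all molar amounts must be > 0")
    total = float(sum(amounts))
    return [round(100.0 * a / total, 2) for a in amounts]


def mock_community_fmol() -> dict[str, float]:
    """The designed mock community: six microbes at 6 fmol, one at 3 fmol,
    and a 250 fmol host component."""
    return {
        "S_epidermidis": 6.0,
        "R_mucosa": 6.0,
        "P_aeruginosa": 6.0,
        "S_hominis": 6.0,
        "N_gonorrhoeae": 6.0,
        "S_aureus": 6.0,
        "E_coli": 3.0,
        "human": 250.0,
    }
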