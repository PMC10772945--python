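"""Simulated Read-Until adaptive sampling and enrichment statistics.

The flow cell's channels are split into an adaptive arm (default 1-255),
where each read's first ``decision_samples`` raw samples are classified and
host-called reads are ejected, and a control arm (default 256-512) sequenced
normally. A rejected molecule still emits the signal acquired up to the
decision plus a latency allowance, so its emitted length in bases is the
closed form

    min(full_length, round((decision_samples + latency_samples) / samples_per_base)).

Reads are treated as independent events per channel: the simulator does not
model pore-time economics (re-capture, queuing), so enrichment is measured
as the microbial share of emitted bases per arm rather than as absolute
throughput gain.

Live-device integration is specified only as an interface contract
(:class:`SignalSource` / :class:`DecisionSink`); implementing it against
hardware is out of scope.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol

import numpy as np

from .errors import DegenerateSignalError, InvalidArgumentError
from .model import SquiggleClassifier
from .preprocess import normalize
from .simulate import SignalRead

__all__ = [
    "AdaptiveConfig",
    "AdaptiveOutcome",
    "EnrichmentReport",
    "run_adaptive_simulation",
    "enrichment_report",
    "time_budget_check",
    "SignalSource",
    "DecisionSink",
]

DECISIONS = ("accepted", "rejected", "no_decision")


@dataclass
class AdaptiveConfig:
    decision_samples: int = 4000
    latency_samples: int = 1000
    threshold: float = 0.5  # reject when p_host > threshold
    adaptive_channels: tuple[int, int] = (1, 255)
    control_channels: tuple[int, int] = (256, 512)
    samples_per_base: float = 8.89
    normalization: str = "median_mad"

    def __post_init__(self) -> None:
        if self.decision_samples < 1:
            raise InvalidArgumentError("decision_samples must be >= 1")
        if self.latency_samples < 0:
            raise InvalidArgumentError("latency_samples must be >= 0")
        if not 0.0 < self.threshold <= 1.0:
            raise InvalidArgumentError("threshold must be in (0, 1]")
        a, c = self.adaptive_channels, self.control_channels
        if a[0] > a[1] or c[0] > c[1] or not (a[1] < c[0] or c[1] < a[0]):
            raise InvalidArgumentError("channel ranges must be valid and disjoint")
        if self.samples_per_base <= 0:
            raise InvalidArgumentError("samples_per_base must be > 0")

    def arm_of(self, channel: int) -> str:
        if self.adaptive_channels[0] <= channel <= self.adaptive_channels[1]:
            return "adaptive"
        if self.control_channels[0] <= channel <= self.control_channels[1]:
            return "control"
        raise InvalidArgumentError(
            f"channel {channel} outside adaptive {self.adaptive_channels} "
            f"and control {self.control_channels} ranges"
        )

    def rejected_emitted_bases(self, full_length: int) -> int:
        emitted = round((self.decision_samples + self.latency_samples) / self.samples_per_base)
        return int(min(full_length, emitted))


@dataclass
class AdaptiveOutcome:
    """Per-read record of the adaptive-sampling decision and its yield."""

    read_id: str
    arm: str  # "adaptive" or "control"
    decision: str  # "accepted", "rejected", "no_decision"
    emitted_bases: int
    full_length_bases: int
    class_label: str
    species: str
    p_host: float | None = None


def run_adaptive_simulation(
    reads: Iterable[SignalRead],
    model: SquiggleClassifier | None,
    cfg: AdaptiveConfig | None = None,
    classify_fn: Callable[[SignalRead, np.ndarray], float] | None = None,
    batch_size: int = 256,
) -> list[AdaptiveOutcome]:
    """Run the Read-Until loop over a set of finished reads.

    Control-arm reads pass through untouched. Adaptive-arm reads shorter than
    the decision window get ``no_decision`` and full emission; otherwise the
    first ``decision_samples`` samples are normalized, classified, and the
    read is truncated (rejected, when p_host exceeds the threshold) or
    emitted in full. ``classify_fn(read, window) -> p_host`` replaces the
    model when given (e.g. an oracle for testing the loop's bookkeeping).
    """
    cfg = cfg or AdaptiveConfig()
    if model is None and classify_fn is None:
        raise InvalidArgumentError("either a model or a classify_fn is required")

    reads = list(reads)
    outcomes: list[AdaptiveOutcome | None] = [None] * len(reads)
    pending: list[tuple[int, np.ndarray]] = []

    for i, read in enumerate(reads):
        arm = cfg.arm_of(read.channel)
        full = read.full_length_bases(cfg.samples_per_base)
        if arm == "control":
            outcomes[i] = AdaptiveOutcome(
                read.read_id, "control", "accepted", full, full, read.class_label, read.species
            )
            continue
        if read.n_samples < cfg.decision_samples:
            outcomes[i] = AdaptiveOutcome(
                read.read_id, "adaptive", "no_decision", full, full, read.class_label, read.species
            )
            continue
        window_pa = read.to_pa()[: cfg.decision_samples]
        try:
            window = normalize(window_pa, cfg.normalization)
        except DegenerateSignalError:
            outcomes[i] = AdaptiveOutcome(
                read.read_id, "adaptive", "no_decision", full, full, read.class_label, read.species
            )
            continue
        if classify_fn is not None:
            p_host = float(classify_fn(reads[i], window))
            outcomes[i] = _decide(reads[i], p_host, full, cfg)
        else:
            pending.append((i, window))

    for start in range(0, len(pending), batch_size):
        block = pending[start : start + batch_size]
        X = np.stack([w for _, w in block])
        probs = model.predict_proba(X)
        for (i, _), p in zip(block, probs):
            full = reads[i].full_length_bases(cfg.samples_per_base)
            outcomes[i] = _decide(reads[i], float(p[0]), full, cfg)

    return [o for o in outcomes if o is not None]


def _decide(
    read: SignalRead, p_host: float, full: int, cfg: AdaptiveConfig
) -> AdaptiveOutcome:
    if p_host > cfg.threshold:
        return AdaptiveOutcome(
            read.read_id,
            "adaptive",
            "rejected",
            cfg.rejected_emitted_bases(full),
            full,
            read.class_label,
            read.species,
            p_host=p_host,
        )
    return AdaptiveOutcome(
        read.read_id, "adaptive", "accepted", full, full, read.class_label, read.species,
        p_host=p_host,
    )


@dataclass
class EnrichmentReport:
    """Aggregated yield and enrichment statistics from an adaptive run.

    Ratio fields are host-count / target-count within a decision group of the
    adaptive arm; when the denominator is zero the ratio is +inf (serialized
    as null with an ``infinite`` flag). ``fold_enrichment`` maps species to
    adaptive-arm read count over control-arm read count.
    """

    read_counts: dict  # arm -> class -> decision -> count
    emitted_bases: dict  # arm -> class -> total emitted bases
    full_bases: dict  # arm -> class -> total full-length bases
    host_microbial_ratio_rejected: float
    host_microbial_ratio_accepted: float
    fold_enrichment: dict[str, float]
    length_summaries: dict  # arm -> class -> {mean, median} emitted length

    def microbial_emitted_fraction(self, arm: str) -> float:
        bases = self.emitted_bases.get(arm, {})
        total = sum(bases.values())
        return bases.get("target", 0) / total if total else 0.0

    def to_dict(self) -> dict:
        def ratio_field(value: float) -> dict:
            if math.isinf(value):
                return {"value": None, "infinite": True}
            return {"value": value, "infinite": False}

        return {
            "read_counts": self.read_counts,
            "emitted_bases": self.emitted_bases,
            "full_bases": self.full_bases,
            "host_microbial_ratio_rejected": ratio_field(self.host_microbial_ratio_rejected),
            "host_microbial_ratio_accepted": ratio_field(self.host_microbial_ratio_accepted),
            "fold_enrichment": {
                sp: (None if math.isinf(v) else v) for sp, v in self.fold_enrichment.items()
            },
            "length_summaries": self.length_summaries,
        }


def _group_ratio(outcomes: list[AdaptiveOutcome], decision: str) -> float:
    host = sum(1 for o in outcomes if o.arm == "adaptive" and o.decision == decision and o.class_label == "host")
    target = sum(1 for o in outcomes if o.arm == "adaptive" and o.decision == decision and o.class_label == "target")
    if target == 0:
        return math.inf if host > 0 else 0.0
    return host / target


def enrichment_report(outcomes: list[AdaptiveOutcome]) -> EnrichmentReport:
    """Tabulate an outcome list into the enrichment statistics."""
    if not outcomes:
        raise InvalidArgumentError("outcomes must be non-empty")

    read_counts: dict = {}
    emitted: dict = {}
    full: dict = {}
    lengths: dict = {}
    for o in outcomes:
        arm_counts = read_counts.setdefault(o.arm, {})
        cls_counts = arm_counts.setdefault(o.class_label, {d: 0 for d in DECISIONS})
        cls_counts[o.decision] += 1
        emitted.setdefault(o.arm, {}).setdefault(o.class_label, 0)
        emitted[o.arm][o.class_label] += o.emitted_bases
        full.setdefault(o.arm, {}).setdefault(o.class_label, 0)
        full[o.arm][o.class_label] += o.full_length_bases
        lengths.setdefault(o.arm, {}).setdefault(o.class_label, []).append(o.emitted_bases)

    length_summaries = {
        arm: {
            cls: {"mean": float(np.mean(v)), "median": float(np.median(v))}
            for cls, v in per_cls.items()
        }
        for arm, per_cls in lengths.items()
    }

    species_counts: dict[str, dict[str, int]] = {}
    for o in outcomes:
        per_arm = species_counts.setdefault(o.species, {"adaptive": 0, "control": 0})
        per_arm[o.arm] += 1
    fold = {}
    for sp, c in species_counts.items():
        if c["control"] == 0:
            fold[sp] = math.inf if c["adaptive"] > 0 else 0.0
        else:
            fold[sp] = c["adaptive"] / c["control"]

    return EnrichmentReport(
        read_counts=read_counts,
        emitted_bases=emitted,
        full_bases=full,
        host_microbial_ratio_rejected=_group_ratio(outcomes, "rejected"),
        host_microbial_ratio_accepted=_group_ratio(outcomes, "accepted"),
        fold_enrichment=fold,
        length_summaries=length_summaries,
    )


def time_budget_check(
    model: SquiggleClassifier,
    chunks: np.ndarray,
    sample_rate: float,
    decision_samples: int = 4000,
) -> tuple[bool, float, float]:
    """Check that classification keeps up with acquisition.

    Classifies a batch of 50 decision windows and compares per-read wall time
    with the acquisition budget ``decision_samples / sample_rate`` seconds.
    Returns (passed, seconds_per_read, budget_seconds); the measurement is
    hardware-dependent and reported, never asserted against reference timings.
    """
    X = np.asarray(chunks, dtype=float)
    if X.shape[0] != 50:
        raise InvalidArgumentError("time budget check is defined for a batch of 50 reads")
    start = time.perf_counter()
    model.predict_proba(X)
    elapsed = time.perf_counter() - start
    per_read = elapsed / X.shape[0]
    budget = decision_samples / sample_rate
    return per_read < budget, per_read, budget


class SignalSource(Protocol):
    """Live-device contract: yields (channel, read_id, signal so far).

    A hardware integration would poll this from the sequencer's Read-Until
    API; the simulator fulfils the same role from finished reads.
    """

    def __iter__(self):  # pragma: no cover - interface contract only
        ...


class DecisionSink(Protocol):
    """Live-device contract: accepts (channel, read_id, action) where action
    is "unblock" (eject the molecule) or "stop_receiving" (sequence fully)."""

    def send(self, channel: int, read_id: str, action: str):  # pragma: no cover
        ...
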