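"""Read-Until loop semantics and enrichment bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

import nanoselect as ns
from nanoselect.adaptive import AdaptiveConfig
from nanoselect.errors import InvalidArgumentError


def oracle_p_host(read, window):
    """Perfect classifier: certainty from the true label."""
    return 1.0 if read.class_label == "host" else 0.0


def make_reads(n_host, n_target, n_samples, channel_fn, seed=0):
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_host + n_target):
        label = "host" if i < n_host else "target"
        reads.append(
            ns.SignalRead(
                read_id=f"r{i}",
                species="human" if label == "host" else "microbe",
                class_label=label,
                dac=rng.integers(-500, 500, n_samples).astype(np.int16),
                channel=channel_fn(i),
            )
        )
    return reads


class TestRunAdaptiveSimulation:
    def test_rejected_host_reads_emit_closed_form_length(self):
        cfg = AdaptiveConfig(decision_samples=4000, latency_samples=1000, samples_per_base=10)
        reads = make_reads(20, 20, n_samples=6000, channel_fn=lambda i: 1 + i % 255)
        outcomes = ns.run_adaptive_simulation(reads, None, cfg, classify_fn=oracle_p_host)
        rejected = [o for o in outcomes if o.decision == "rejected"]
        assert rejected and all(o.class_label == "host" for o in rejected)
        for o in rejected:
            # 6000 samples at 10 samples/base = 600 full bases; cap at 500
            assert o.full_length_bases == 600
            assert o.emitted_bases == min(o.full_length_bases, 500)
        accepted = [o for o in outcomes if o.decision == "accepted"]
        assert all(o.emitted_bases == o.full_length_bases for o in accepted)

    def test_threshold_one_rejects_nothing(self):
        cfg = AdaptiveConfig(threshold=1.0, samples_per_base=10)
        reads = make_reads(10, 10, n_samples=5000, channel_fn=lambda i: 1 + i % 510)
        outcomes = ns.run_adaptive_simulation(reads, None, cfg, classify_fn=oracle_p_host)
        assert all(o.decision != "rejected" for o in outcomes)
        # adaptive arm emits exactly what the control arm would
        assert all(o.emitted_bases == o.full_length_bases for o in outcomes)

    def test_short_reads_get_no_decision(self):
        cfg = AdaptiveConfig(decision_samples=4000, samples_per_base=10)
        reads = make_reads(5, 5, n_samples=3000, channel_fn=lambda i: 1)
        outcomes = ns.run_adaptive_simulation(reads, None, cfg, classify_fn=oracle_p_host)
        assert all(o.decision == "no_decision" for o in outcomes)
        assert all(o.emitted_bases == o.full_length_bases for o in outcomes)

    def test_control_arm_untouched(self):
        cfg = AdaptiveConfig(samples_per_base=10)
        reads = make_reads(5, 5, n_samples=6000, channel_fn=lambda i: 300)
        outcomes = ns.run_adaptive_simulation(reads, None, cfg, classify_fn=oracle_p_host)
        assert all(o.arm == "control" for o in outcomes)
        assert all(o.emitted_bases == o.full_length_bases == 600 for o in outcomes)

    def test_channel_outside_both_ranges_rejected(self):
        cfg = AdaptiveConfig()
        reads = make_reads(1, 0, n_samples=5000, channel_fn=lambda i: 513)
        with pytest.raises(InvalidArgumentError):
            ns.run_adaptive_simulation(reads, None, cfg, classify_fn=oracle_p_host)

    def test_oracle_on_host_dominated_library(self):
        # 90% host: every host read in the adaptive arm is rejected, no
        # microbial read is, so the rejected-set ratio is infinite
        cfg = AdaptiveConfig(samples_per_base=10)
        channels = np.random.default_rng(8).integers(1, 513, 200)
        reads = make_reads(180, 20, n_samples=9000, channel_fn=lambda i: int(channels[i]), seed=1)
        outcomes = ns.run_adaptive_simulation(reads, None, cfg, classify_fn=oracle_p_host)
        report = ns.enrichment_report(outcomes)
        assert math.isinf(report.host_microbial_ratio_rejected)
        assert report.microbial_emitted_fraction("adaptive") > report.microbial_emitted_fraction("control")

    def test_imperfect_classifier_ratio_matches_recount(self):
        # classifier with a small microbial false-rejection rate
        rng = np.random.default_rng(5)

        def noisy(read, window):
            if read.class_label == "host":
                return 1.0
            return 1.0 if rng.random() < 0.10 else 0.0

        cfg = AdaptiveConfig(samples_per_base=10)
        # random channels so both arms see both classes
        channels = np.random.default_rng(9).integers(1, 513, 2000)
        reads = make_reads(1800, 200, n_samples=9000, channel_fn=lambda i: int(channels[i]), seed=2)
        outcomes = ns.run_adaptive_simulation(reads, None, cfg, classify_fn=noisy)
        report = ns.enrichment_report(outcomes)
        df = pd.DataFrame([vars(o) for o in outcomes])
        rej = df[(df.arm == "adaptive") & (df.decision == "rejected")]
        expected = len(rej[rej.class_label == "host"]) / len(rej[rej.class_label == "target"])
        assert report.host_microbial_ratio_rejected == pytest.approx(expected)

    def test_base_conservation(self):
        cfg = AdaptiveConfig(samples_per_base=10)
        reads = make_reads(50, 50, n_samples=8000, channel_fn=lambda i: 1 + i % 510, seed=3)
        outcomes = ns.run_adaptive_simulation(reads, None, cfg, classify_fn=oracle_p_host)
        adaptive = [o for o in outcomes if o.arm == "adaptive"]
        assert sum(o.emitted_bases for o in adaptive) <= sum(o.full_length_bases for o in adaptive)
        untouched = ns.run_adaptive_simulation(
            reads, None, AdaptiveConfig(threshold=1.0, samples_per_base=10), classify_fn=oracle_p_host
        )
        assert sum(o.emitted_bases for o in untouched) == sum(o.full_length_bases for o in untouched)


class TestEnrichmentReport:
    @staticmethod
    def _outcome(i, arm, decision, cls, emitted=100, full=100, species=None):
        return ns.AdaptiveOutcome(
            read_id=f"o{i}",
            arm=arm,
            decision=decision,
            emitted_bases=emitted,
            full_length_bases=full,
            class_label=cls,
            species=species or ("human" if cls == "host" else "microbe"),
        )

    def test_rejected_ratio_division(self):
        outcomes = [
            self._outcome(i, "adaptive", "rejected", "host") for i in range(99)
        ] + [self._outcome(100 + i, "adaptive", "rejected", "target") for i in range(2)]
        report = ns.enrichment_report(outcomes)
        assert report.host_microbial_ratio_rejected == pytest.approx(49.5)

    def test_no_adaptive_reads_keeps_control_section(self):
        outcomes = [self._outcome(i, "control", "accepted", "host") for i in range(5)]
        report = ns.enrichment_report(outcomes)
        assert "adaptive" not in report.read_counts
        assert report.read_counts["control"]["host"]["accepted"] == 5
        assert report.host_microbial_ratio_rejected == 0.0

    def test_counts_conserve_arm_totals_vs_groupby_oracle(self):
        rng = np.random.default_rng(4)
        outcomes = [
            self._outcome(
                i,
                rng.choice(["adaptive", "control"]),
                rng.choice(["accepted", "rejected", "no_decision"]),
                rng.choice(["host", "target"]),
                emitted=int(rng.integers(10, 500)),
                full=int(rng.integers(500, 1000)),
            )
            for i in range(300)
        ]
        report = ns.enrichment_report(outcomes)
        df = pd.DataFrame([vars(o) for o in outcomes])
        for arm, arm_df in df.groupby("arm"):
            for cls, cls_df in arm_df.groupby("class_label"):
                assert sum(report.read_counts[arm][cls].values()) == len(cls_df)
                assert report.emitted_bases[arm][cls] == cls_df.emitted_bases.sum()
                for decision, d_df in cls_df.groupby("decision"):
                    assert report.read_counts[arm][cls][decision] == len(d_df)

    def test_infinite_ratio_serializes_as_null_with_flag(self):
        outcomes = [self._outcome(0, "adaptive", "rejected", "host")]
        payload = ns.enrichment_report(outcomes).to_dict()
        assert payload["host_microbial_ratio_rejected"] == {"value": None, "infinite": True}

    def test_fold_enrichment_per_species(self):
        outcomes = [
            self._outcome(i, "adaptive", "accepted", "target", species="m1") for i in range(6)
        ] + [self._outcome(10 + i, "control", "accepted", "target", species="m1") for i in range(3)]
        report = ns.enrichment_report(outcomes)
        assert report.fold_enrichment["m1"] == pytest.approx(2.0)

    def test_empty_outcomes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ns.enrichment_report([])


class TestTimeBudget:
    def test_budget_arithmetic_and_positive_timing(self, tiny_spec):
        model = ns.SquiggleClassifier(tiny_spec, seed=0)
        chunks = np.random.default_rng(0).standard_normal((50, 300))
        passed, per_read, budget = ns.time_budget_check(
            model, chunks, sample_rate=4000.0, decision_samples=4000
        )
        assert budget == pytest.approx(1.0)  # 4000 samples at 4000 Hz
        assert per_read > 0

    def test_infinite_sample_rate_fails_by_construction(self, tiny_spec):
        model = ns.SquiggleClassifier(tiny_spec, seed=0)
        chunks = np.random.default_rng(0).standard_normal((50, 300))
        passed, per_read, budget = ns.time_budget_check(
            model, chunks, sample_rate=math.inf, decision_samples=4000
        )
        assert budget == 0.0
        assert not passed

    def test_requires_batch_of_50(self, tiny_spec):
        model = ns.SquiggleClassifier(tiny_spec, seed=0)
        with pytest.raises(InvalidArgumentError):
            ns.time_budget_check(model, np.zeros((10, 300)), sample_rate=4000.0)


class TestConfigValidation:
    def test_overlapping_channel_ranges_rejected(self):
        with pytest.raises(InvalidArgumentError):
            AdaptiveConfig(adaptive_channels=(1, 300), control_channels=(256, 512))

    def test_default_channel_split(self):
        cfg = AdaptiveConfig()
        assert cfg.arm_of(1) == "adaptive" and cfg.arm_of(255) == "adaptive"
        assert cfg.arm_of(256) == "control" and cfg.arm_of(512) == "control"

    def test_default_rejected_length_near_600_bases(self):
        # 5000 samples of signal at 8.89 samples/base ~ 562 bases retained
        cfg = AdaptiveConfig()
        assert cfg.rejected_emitted_bases(10_000) == 562
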