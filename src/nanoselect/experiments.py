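"""The desk-scale end-to-end experiment: simulate, train, enrich.

This is the package's reference experiment, sized to run in minutes on one
CPU while keeping the study's structure intact:

1. two reference pools whose 6mer biases sit at total-variation distance 0.5
   (GC-structured, as real host/microbe composition differences are);
2. a balanced training library chunked into 2000 decision windows per class
   (4000 raw samples each, the signal available at Read-Until decision
   time), split 80/20 into train and held-out sets;
3. a compact classifier configuration (same fixed topology as the default
   spec: conv -> SE -> 3 residual blocks -> SE -> GAP -> FC) trained for a
   few epochs;
4. a host-dominated (90% host by moles) long-read library pushed through the
   adaptive-sampling simulator with that classifier, adaptive arm on
   channels 1-255 and control arm on 256-512.

Reported quantities: held-out AUC and accuracy, the microbial share of
emitted bases in each arm, rejected-read lengths, and the composition of the
rejected read set.
"""

from __future__ import annotations

import numpy as np

from .adaptive import AdaptiveConfig, enrichment_report, run_adaptive_simulation
from .model import ClassifierSpec
from .preprocess import PreprocessConfig, build_dataset
from .simulate import (
    LibraryComponent,
    LibraryDesign,
    ReadLengthDist,
    default_pore_model,
    divergent_bias_pair,
    generate_reference_pool,
    simulate_library,
)
from .train_eval import TrainConfig, evaluate, train

__all__ = ["desk_scale_spec", "run_desk_scale_experiment"]


def desk_scale_spec() -> ClassifierSpec:
    """Compact classifier configuration used by the reference experiment."""
    return ClassifierSpec(
        conv_channels=16,
        conv_kernel=19,
        conv_stride=3,
        stem_pool=6,
        se_reduction=4,
        residual_channels=(16, 32, 64),
    )


def run_desk_scale_experiment(
    seed: int = 1,
    n_chunks_per_class: int = 2000,
    epochs: int = 5,
    bias_tv: float = 0.5,
    n_adaptive_reads: int = 1500,
    host_molar_fraction: float = 0.9,
) -> dict:
    """Run the full pipeline and return its measured quantities.

    All randomness derives from ``seed``. Returns a dict with the trained
    model, evaluation report, enrichment report and headline numbers.
    """
    seeds = np.random.SeedSequence(seed).generate_state(12) % (2**31 - 1)

    bias_gc_rich, bias_gc_poor = divergent_bias_pair(seed=int(seeds[0]), tv=bias_tv)
    pore = default_pore_model(seed=int(seeds[1]))

    # -- training library: balanced, short reads (one decision window each)
    host_pool = generate_reference_pool(
        int(seeds[2]), n_sequences=4, length=25000, kmer_bias=bias_gc_poor, name="host"
    )
    microbe_pool = generate_reference_pool(
        int(seeds[3]), n_sequences=4, length=25000, kmer_bias=bias_gc_rich, name="microbe"
    )
    train_design = LibraryDesign(
        components=[
            LibraryComponent("human", "host", 1.0, host_pool),
            LibraryComponent("microbe", "target", 1.0, microbe_pool),
        ],
        n_reads=int(np.ceil(2.15 * n_chunks_per_class)),
        read_length_dist=ReadLengthDist(
            median_bases=700, sigma_log=0.3, min_bases=520, max_bases=2000
        ),
    )
    reads = simulate_library(train_design, pore, seed=int(seeds[4]))
    dataset = build_dataset(reads, PreprocessConfig(chunk_length=4000), seed=int(seeds[5]))
    idx_host = np.flatnonzero(dataset.y == 0)[:n_chunks_per_class]
    idx_target = np.flatnonzero(dataset.y == 1)[:n_chunks_per_class]
    dataset = dataset.subset(np.sort(np.concatenate([idx_host, idx_target])))

    order = np.random.default_rng(int(seeds[6])).permutation(len(dataset))
    split = int(0.8 * len(dataset))
    train_set = dataset.subset(order[:split])
    heldout_set = dataset.subset(order[split:])

    model = train(
        desk_scale_spec(),
        train_set,
        TrainConfig(epochs=epochs, batch_size=64, seed=int(seeds[7])),
    )
    report = evaluate(model, heldout_set)

    # -- host-dominated long-read library through the Read-Until simulator
    adaptive_host_pool = generate_reference_pool(
        int(seeds[8]), n_sequences=4, length=25000, kmer_bias=bias_gc_poor, name="host"
    )
    adaptive_microbe_pool = generate_reference_pool(
        int(seeds[9]), n_sequences=4, length=25000, kmer_bias=bias_gc_rich, name="microbe"
    )
    host_fmol = 100.0 * host_molar_fraction
    adaptive_design = LibraryDesign(
        components=[
            LibraryComponent("human", "host", host_fmol, adaptive_host_pool),
            LibraryComponent(
                "microbe", "target", 100.0 - host_fmol, adaptive_microbe_pool
            ),
        ],
        n_reads=n_adaptive_reads,
        read_length_dist=ReadLengthDist(median_bases=3000, sigma_log=0.5),
    )
    adaptive_reads = simulate_library(adaptive_design, pore, seed=int(seeds[10]))
    adaptive_cfg = AdaptiveConfig(samples_per_base=pore.samples_per_base)
    outcomes = run_adaptive_simulation(adaptive_reads, model, adaptive_cfg)
    enrichment = enrichment_report(outcomes)

    rejected_lengths = [o.emitted_bases for o in outcomes if o.decision == "rejected"]
    n_rejected_host = sum(
        1 for o in outcomes if o.decision == "rejected" and o.class_label == "host"
    )
    n_rejected_target = sum(
        1 for o in outcomes if o.decision == "rejected" and o.class_label == "target"
    )

    return {
        "model": model,
        "eval_report": report,
        "enrichment": enrichment,
        "outcomes": outcomes,
        "heldout_auc": report.auc,
        "heldout_accuracy": report.accuracy,
        "microbial_emitted_fraction_adaptive": enrichment.microbial_emitted_fraction("adaptive"),
        "microbial_emitted_fraction_control": enrichment.microbial_emitted_fraction("control"),
        "rejected_read_median_bases": float(np.median(rejected_lengths)) if rejected_lengths else 0.0,
        "rejected_read_length_closed_form": adaptive_cfg.rejected_emitted_bases(10**9),
        "n_rejected_host": n_rejected_host,
        "n_rejected_target": n_rejected_target,
        "host_microbial_ratio_rejected": enrichment.host_microbial_ratio_rejected,
        "n_train_chunks": len(train_set),
        "n_heldout_chunks": len(heldout_set),
        "n_adaptive_reads": len(outcomes),
    }
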