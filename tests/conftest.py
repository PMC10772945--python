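import numpy as np
import pytest

import nanoselect as ns


@pytest.fixture(scope="session")
def pore_model():
    return ns.default_pore_model(seed=5)


@pytest.fixture(scope="session")
def tiny_spec():
    """A small architecture (same fixed topology) for fast training tests;
    accepts inputs of >= 179 samples."""
    return ns.ClassifierSpec(
        conv_channels=8,
        conv_kernel=9,
        conv_stride=2,
        stem_pool=2,
        se_reduction=4,
        residual_channels=(8, 8, 8),
    )


def make_separable_dataset(n_per_class: int, length: int = 300, seed: int = 0) -> ns.ChunkDataset:
    """Well-separated synthetic chunks: noise vs noise plus a smooth wave."""
    rng = np.random.default_rng(seed)
    wave = np.sin(np.linspace(0, 12 * np.pi, length))
    X0 = rng.standard_normal((n_per_class, length))
    X1 = rng.standard_normal((n_per_class, length)) + 2.0 * wave
    X = np.vstack([X0, X1]).astype(np.float32)
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    order = rng.permutation(len(y))
    return ns.ChunkDataset(
        X=X[order],
        y=y[order],
        read_ids=[f"r{i}" for i in order],
        species=["human" if y[i] == 0 else "microbe" for i in order],
    )


def make_divergent_library(
    n_reads: int,
    pore: ns.PoreModel,
    seed: int = 7,
    tv: float = 0.5,
    host_fraction_fmol: tuple[float, float] = (1.0, 1.0),
    median_bases: int = 700,
    n_species: int = 1,
    ref_length: int = 20000,
) -> list[ns.SignalRead]:
    """A two-pool (host vs 1+ microbial species) simulated library."""
    bias_gc_rich, bias_gc_poor = ns.divergent_bias_pair(seed=seed, tv=tv)
    host_pool = ns.generate_reference_pool(
        seed=seed + 1, n_sequences=3, length=ref_length, kmer_bias=bias_gc_poor, name="host"
    )
    components = [
        ns.LibraryComponent("human", "host", host_fraction_fmol[0], host_pool)
    ]
    for s in range(n_species):
        pool = ns.generate_reference_pool(
            seed=seed + 2 + s,
            n_sequences=3,
            length=ref_length,
            kmer_bias=bias_gc_rich,
            name=f"microbe_{s}",
        )
        components.append(
            ns.LibraryComponent(
                f"microbe_{s}", "target", host_fraction_fmol[1] / n_species, pool
            )
        )
    design = ns.LibraryDesign(
        components=components,
        n_reads=n_reads,
        read_length_dist=ns.ReadLengthDist(
            median_bases=median_bases, sigma_log=0.3, min_bases=120, max_bases=3000
        ),
    )
    return ns.simulate_library(design, pore, seed=seed + 50)
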