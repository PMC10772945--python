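# Methods

## Signal model

A read is simulated from its base sequence under the standard nanopore
generative picture: about six bases reside in the pore at measurement time,
so the expected current of sample window *i* is a function of the 6mer
starting at base *i*. For each of the `L − 5` windows the simulator draws a
dwell `d_i ~ round(N(dwell_mean, dwell_sd))`, clipped to at least one
sample, then `d_i` current samples `~ N(level_mean[kmer_i],
level_sd[kmer_i])` in picoamps, converted to signed 16-bit DAC units via
`pA = (dac + offset) · range / digitisation`. Consequences used as oracles
throughout the tests: the dwells sum exactly to the sample count, the
window-to-sample map covers the signal exactly once, and in the
`level_sd → 0` limit the squiggle is reconstructable from the pore model
sample-by-sample (exactly at DAC resolution; the pA round-trip carries a
quantisation offset of at most half an LSB, ~0.085 pA at the default
calibration).

Defaults: `dwell_mean = 8.89` samples/base (4 kHz sampling over ~450 nt/s
translocation), `dwell_sd = 1.0` samples/base (our choice; narrow enough
that a 500-base read never falls below one 4000-sample decision window),
`level_sd = 1.5` pA (a typical ONT event spread), calibration
`digitisation 8192, offset 0, range 1400` (MinION-like constants chosen for
bit-exact container round-trips). Read lengths are log-normal, median 3 kb,
σ_log 0.5, truncated to [500 b, 50 kb] — the long-read regime in which a
4000-sample decision truncates most of a host read.

### Pore model construction

`default_pore_model` assigns each 6mer a current level that is
*composition-driven*: each base contributes a per-position offset (G/C block
more current than A/T; centre positions weighted most), a small seeded
deviation individualises each kmer, and the resulting scores are rank-mapped
onto unique slots of the 60–120 pA range. This guarantees all 4096 means
are pairwise distinct while kmers of similar composition keep similar
levels — the property of real pore chemistry that makes composition
differences between genomes visible in the raw current. An earlier design
that permuted levels randomly over kmers was discarded: with 4096 levels
packed into 60 pA and 1.5 pA noise, a random level↔kmer map lets the noise
kernel average ~200 neighbouring kmers whose usage differences cancel, so
the two pools' current densities coincide and no classifier — however good —
can separate them. That failure mode is a property of the generator, not of
the method, and does not correspond to real data.

### Divergent composition

`divergent_bias_pair(seed, tv)` produces two 6mer distributions at an exact
total-variation distance `tv`: the GC-richer half of the kmers (ties broken
by a seeded shuffle) is re-weighted by `(1 ± tv)` in pool A and mirrored in
pool B. Structuring the divergence along GC content mirrors the axis on
which host and microbial genomes actually differ and keeps the divergence
visible in the current (see above); a random half-split would place the
divergence largely inside the noise kernel. Sequences are drawn from a
5th-order Markov chain whose conditional next-base law is proportional to
the bias of the 6mer formed, so the stationary 6mer distribution
approximates the bias (exactly when the bias has consistent marginals, e.g.
uniform; empirically within TV 0.03 of uniform at 1 Mb).

### Mock community

Library composition follows designed molar amounts; read counts per
component are multinomial in the molar fractions. The reference design is
six microbial species at 6 fmol (2.08% each), one at 3 fmol (1.04%), and a
250 fmol host component (86.51%).

## Preprocessing

The classifier consumes one decision window per read: samples
`[skip, skip + 4000)` after pA conversion, normalized per chunk. Median/MAD
(consistency factor 1.4826) is the default — robust to current spikes;
z-scoring is kept for ablation. `skip_samples` defaults to 0 because
simulated reads carry no adapter; 1000–1500 is recommended for real FAST5
input. Degenerate (zero-spread) windows and too-short reads are skipped and
counted, never silently dropped. One chunk per read: the adaptive-sampling
use case only ever sees the read start, so multi-chunk augmentation would
misrepresent the deployment distribution.

## Classifier

Topology (fixed): 1-D convolutional stem → squeeze-and-excitation (SE)
weighting → three residual blocks → SE → global average pooling → fully
connected softmax bi-classifier over {host, target}. The SE block squeezes
each channel to its temporal mean, passes the vector through a two-layer
bottleneck (reduction `r`, ReLU then sigmoid) and rescales the channels;
excitations lie strictly in (0, 1). Each residual block is two convolutions
with batch normalisation and ReLU plus a projected shortcut (strided 1×1
convolution + BN); the stack downsamples by stride 2 per block.

All layer sizes are free configuration. Default spec: 32 stem channels,
kernel 19, stride 3, max-pool 2, SE reduction 4, residual widths
(32, 64, 128), kernel 3 — 121 450 parameters, minimum admissible input 274
samples. The desk-scale experiment uses a compact configuration of the same
topology (16 stem channels, pool 6, widths (16, 32, 64); 31 158 parameters)
sized so the full reference experiment runs in minutes on one CPU.

Two numerical choices are load-bearing:

* **Valid (unpadded) convolutions everywhere.** A constant input then stays
  exactly constant through every layer, so with global average pooling the
  output on constant signals is independent of input length — a testable
  oracle for the length-invariance that GAP is meant to provide.
* **Ties classify as "target".** Rejecting a rare microbial read is the
  expensive error; ambiguity must never trigger a rejection.

The network is implemented in numpy with explicit backpropagation
(`nanoselect.nn`); every layer's backward pass is verified against central
finite differences in the test suite. Training is mini-batch Adam
(default lr 1e-3, batch 64) on softmax cross-entropy, deterministic given
the config seed (seeded initialisation and data order; single-threaded
numpy). Saturation takes ~30 epochs at full scale; the separable synthetic
task converges in a handful.

## Evaluation and cross-validation

AUC is computed two independent ways: the trapezoid area under the
empirical ROC (stored in every report) and the Mann–Whitney probability
that a random target outranks a random host with ties counted half
(`auc_mann_whitney`, via midranks). The two agree to 1e-9 on random score
sets with ties, and both equal exhaustive pair enumeration; the test suite
asserts all three routes against each other. Precision takes "target" as
the positive class.

Stratified k-fold assignment deals each class's shuffled items cyclically
across folds, carrying the dealing offset between classes — per-class
counts are as even as possible *and* total fold sizes differ by at most
one (a stronger guarantee than off-the-shelf stratified splitters, hence
hand-rolled). Leave-one-species-out holds out every chunk of one microbial
species and evaluates it against an equal-sized sample of host chunks also
excluded from that run's training, so both classes in the evaluation set
are unseen.

## Adaptive-sampling simulation

Channels 1–255 form the adaptive arm, 256–512 the control arm. Control
reads pass through untouched. An adaptive read shorter than the decision
window gets `no_decision` and full emission; otherwise its first 4000
samples are normalized and classified, and the read is rejected when
`p_host` exceeds the threshold (default 0.5; ties accept). A rejected read
emits `min(full_length, round((decision_samples + latency_samples) /
samples_per_base))` bases — with the defaults (4000 + 1000 samples at 8.89
samples/base) that is 562 bases, the simulator's analogue of the truncated
reads a rejection leaves behind. The latency allowance (1000 samples) is
our choice of a plausible decision-to-reversal delay and is config-exposed.

Reads are independent events per channel: the simulator has no
pore-occupancy model, so it cannot (and does not try to) reproduce absolute
throughput gains that arise from pore-time economics on a real device.
Enrichment is therefore measured as the microbial share of *emitted bases*
per arm, where the effect is literally true in the simulation, plus the
composition of the rejected read set. `time_budget_check` reports whether
classifying 50 decision windows keeps up with acquisition
(`decision_samples / sample_rate` per read); the measurement is
hardware-dependent and reported, never asserted.

## 6mer analysis

Profiles count every length-k window on the forward strand (a flag adds
reverse-complement counting; strand treatment is otherwise forward-only).
Enrichment scores are `log2((4096·freq_a + 1) / (4096·freq_b + 1))` — the
pseudocount on the counts-per-4096 scale keeps absent kmers finite — with
lexicographic tie-breaking. Per-kmer signal summaries (mean current, SD,
mean dwell, and a w-point resampled level trace; w = 8 by default) are
pooled from the simulator's ground-truth window map; real-read segmentation
is a declared non-goal, so reads without ground truth are rejected with a
pointer to that fact. PCA centres (optionally scales) columns, drops
constant columns with a warning, and is reproducible up to component sign.

## The desk-scale reference experiment

`nanoselect.experiments.run_desk_scale_experiment` fixes the problem sizes:
pools at bias TV 0.5 (four 25 kb references each), 2000 decision windows
per class split 80/20, the compact spec trained 5 epochs, and a 1500-read
90%-host library (median 3 kb) through the adaptive simulator. With these
conditions the held-out AUC is ≥ 0.95 (typically ≈ 1.0) and the adaptive
arm's microbial emitted-base share exceeds the control arm's several-fold.

## What the simulator does and does not establish

Passing tests show the pipeline is correct and that the classifier recovers
composition signal *under the generative model*: i.i.d. Gaussian levels
keyed by 6mer identity, clean pool divergence, no adapter/stall artifacts,
no base modifications (modification signal is deliberately not simulated),
no basecalling noise, and no pore-time economics. Real-data performance —
AUCs against deposited sequencing runs, absolute read-count gains, wall-
clock speedups — depends on exactly those unmodelled factors and is outside
what this package measures. The synthetic task is easier than the real one;
results here bound the pipeline's correctness, not its field performance.

## Known limitations

* No event segmentation: per-kmer signal extraction requires simulator
  ground truth.
* The FAST5 adapter reads the common multi-read Raw/Signal layout only and
  attaches labels supplied by the caller.
* The Markov sequence generator matches a target 6mer distribution only
  approximately when the target's prefix/suffix marginals are inconsistent.
* Training is CPU-bound numpy; full-scale (30-epoch, default-spec) runs are
  possible but slow — the package's scope is desk-scale verification, not
  production training throughput.
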