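# Methods

`phenotrace` reimplements, as a tested pipeline on synthetic data, an
unsupervised workflow for phenotyping single chondrocytes from multi-channel
fluorescence time series recorded after mechanical impact of articular
cartilage. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data does and does not establish.

## The measurement being emulated

Each cell carries three stain channels: calcium concentration (Calbryte-type
indicator), mitochondrial polarity (TMRM), and nuclear membrane permeability
(NMP, a Sytox-type death indicator). Long-term imaging covers ~3 h at ~12 s
per frame over a 660 μm × 660 μm field rendered as 512 × 512 px; cells at the
impact site additionally carry a ~60 s calcium trace at 40 fps capturing the
peracute response. Cell tracking is out of scope: traces arrive already
cell-indexed.

## Synthetic data generator

The generator defines the study conditions for every test in the package.

**Phenotype library.** Fourteen parametric phenotypes span the taxonomy seen
in impacted cartilage: nine viable classes combining low/medium/high calcium
baselines, decaying or flat calcium, and ordinary vs fast mitochondrial decay
(all with low NMP), and five death classes — instantaneous death (initial NMP
spike, no other signal), early death variants with decaying calcium, and two
delayed-death classes in which a calcium transient or fall at ~2 h / ~1.3–1.5 h
precedes a logistic NMP rise. Kinetics are built from four primitives:
exponential decay `b·exp(−kt)`, logistic rise `A/(1+exp(−k(t−t₀)))`, Gaussian
transients, and spike-then-exponential-decay. These are the simplest forms
reproducing the qualitative channel descriptions; two library rows whose
verbal descriptions coincide are separated by distinct calcium baselines so
all 14 mean traces are mutually distinguishable.

**Units and noise.** Intensities are arbitrary units scaled to ≈[0, 1] per
channel so the decoder's final linear layer is well conditioned. Noise is
additive i.i.d. Gaussian per sample, clamped at zero; the default
`noise_sd = 0.05` (~5% of full scale) is a realistic signal-to-noise level
for confocal stain traces. No optical physics, photobleaching, or stain
leakage is modeled beyond an optional piecewise-constant background field in
rendered frames.

**Spatial structure.** Positions are uniform over the field; phenotype
assignment probability is the global phenotype weight multiplied by a
per-phenotype monotone spatial bias in distance to the impact point,
renormalised per cell. Death phenotypes default to `exp(−d/80–200 μm)`
biases, producing the enrichment of death behaviors near the impact site that
the spatial hypothesis tests rely on.

**Impact calcium pulses.** The peracute calcium response is a logistic rise
followed by exponential decay, parameterised by a single `sharpness ∈ [0, 1]`:
onset moves from ~17 s (broad) to ~1 s (sharp), the post-peak decay rate grows
from 0.005 to 0.255 s⁻¹, and amplitude grows from 0.4 to 1.0. This family
was chosen over a gamma-shaped pulse because it keeps all the qualitative
features coherent at once: peak time and full width at half maximum are
strictly decreasing in sharpness, `sharpness = 0` yields a plateau peaking
after 10 s that barely decays within the minute, and — because broad pulses
have *late onset* while sharp pulses decay over several seconds rather than
instantly — the mean intensity in the first quarter of the window correlates
positively with sharpness, which is what anchors the sign of the sharpness
score (below). A gamma pulse sharp enough to have monotone FWHM decays within
~2 s and inverts that correlation.

**Fate linkage.** In full datasets, impact-site cells draw sharpness from
Beta(5, 2) when their phenotype is a death class and Beta(2, 5) otherwise.
The dedicated cohort generator used in calibration studies instead draws
sharpness uniformly and assigns death by a Bernoulli with logistic link
(slope 6, midpoint 0.5), with an exchangeable-label null variant.

**What passing tests do not show.** The generator's phenotypes are separable
by construction, its noise is homoscedastic and white, and its spatial biases
are smooth monotone functions. Success on this data demonstrates that the
pipeline machinery is correct and calibrated — not that a VAE would resolve
the messier, drifting, autocorrelated signals of real microscopy with the
same fidelity.

## Preprocessing

Image-level background subtraction divides each square frame into an 8×8
grid and subtracts, per subset, the mean of its 20 lowest non-zero pixel
values, clamping at zero (subsets with fewer than 20 non-zero pixels use all
of them; all-zero subsets pass through). Traces are then smoothed with a
centered moving average of window 10 — boundary windows shrink by clipping to
the available samples, which preserves length and avoids phase shift — and
linearly resampled to exactly 750 uniform time points, endpoints preserved.
The channel order (calcium, mito, nmp) is fixed throughout the codebase.
Image subtraction precedes trace smoothing; repeated assembly of an
already-smoothed 750-point matrix is nearly but not exactly idempotent
(repeated smoothing keeps shrinking edge windows), which is documented rather
than asserted.

## Variational autoencoder

**Architecture.** Encoder: three 1-D convolutions (channels 3→4→8→16, kernel
3, stride 2, padding 1), each followed by batch normalization then tanh; the
temporal length contracts 750 → 375 → 188 → 94, giving 16 × 94 = 1504
flattened features; a 1504→256 tanh trunk feeds two 256→128→32 heads (tanh on
the hidden layer, linear output) producing the posterior mean and
log-variance. The log-variance parameterisation guarantees positive
variances. Decoder: 32→128→256→1504 fully connected tanh layers, reshape to
(B, 16, 94), then three transposed convolutions (16→8→4→3, same kernel/
stride/padding) with output paddings (1, 0, 1) — solved at construction so
the length sequence inverts exactly to 94 → 188 → 375 → 750; the last
transposed convolution is linear with no batch normalization. Both
arithmetic identities (1504 and 94) are asserted when the architecture is
instantiated.

**Objective.** The negative ELBO with a unit-variance Gaussian decoder
likelihood: reconstruction is the sum of squared errors over channels and
time (constants dropped), the regulariser is the closed-form KL of the
diagonal-Gaussian posterior to the standard-normal prior, weight 1. Latents
are sampled by reparameterisation, `z = μ + √v ⊙ ε`.

**Training.** A seeded 80/20 train/validation split; at most 100 epochs
(default 20), batch size 32, Adam with learning rate 10⁻³. Encoder inputs
are perturbed with N(0, 0.01 I) noise while reconstruction targets stay
clean — a denoising scheme encouraging robust representations. Validation
losses are computed on clean inputs in evaluation mode (running
batch-normalization statistics) with `z = μ`, making them deterministic.
There is no early stopping and no KL annealing. Traces enter in raw
intensity units with no per-cell normalization.

**Implementation.** The network is a compact NumPy implementation with
hand-written forward/backward passes for every layer (im2col convolutions,
their adjoints, batch-normalization, Adam), verified against central finite
differences layer-by-layer to machine precision. Float32 is used throughout
training. Default problem sizes (≤2000 cells, 20 epochs) train in well under
a minute on one CPU core; the encoder and latent geometry, not decoder
photorealism, carry the scientific weight. One practical failure mode is
documented: with very few optimisation steps (tens) and strongly imbalanced
classes, the decoder can linger near the data-mean output before learning to
use the latent code; the package defaults (hundreds of steps, roughly
balanced synthetic classes) avoid this regime.

## Reconstruction evaluation (STL)

Seasonal-Trend decomposition using LOESS splits each series additively into
trend, seasonal, and residual (residual defined as remainder, so additivity
is exact). The seasonal smoother length is 35 (rounded up to odd if an even
value is passed). STL requires a nominal period; the default of 35 resampled
steps (~8.4 min of imaging) puts few-minute calcium transients into
seasonal+residual while slow decays stay in trend, and is configurable.
Long-timescale error is the trend difference between original and
reconstruction, short-timescale error the (seasonal+residual) difference,
each normalised by the standard deviation of the original channel series;
zero-variance channels are reported as raw differences and flagged. Pooled
and per-channel tidy exports are both provided.

## Latent analysis

PCA on the per-cell posterior means is centered (the standard convention,
noted as a reproduction caveat) and retains all components. Per-cell
coordinates are `αᵢ = (μ_z − mean)·eᵢ`. Traversal decodes
`mean + α·sᵢ·eᵢ` with the remaining coordinates at zero, where `sᵢ` is the
standard deviation of `αᵢ` across cells, so the conventional α ∈ [−3, 3]
range is in standardized units; a raw mode (`sᵢ = 1`) is retained. The PCA
mean is added back before decoding because an uncentered coordinate sum
would place `z` far from the data manifold.

## Divergence clustering

Each cell's latent representation is a 32-dimensional diagonal Gaussian; the
closed-form KL between two such distributions, and its symmetrized average
sKL = ½(KL(P‖Q)+KL(Q‖P)), quantify dissimilarity in nats. In the pairwise
matrix the log-variance terms cancel, leaving
¼Σ[vᵢ/vⱼ + vⱼ/vᵢ − 2 + (μᵢ−μⱼ)²(1/vᵢ + 1/vⱼ)], computed vectorised. sKL is
not a metric, so clustering operates strictly on the precomputed matrix —
average linkage by default (monotone dendrograms, the usual choice for
non-metric dissimilarities; complete and single are available) with scipy's
deterministic merge ordering. Cuts are by sKL threshold (severing merges
above it) or by cluster count; lowering a threshold only ever splits
clusters. The pairwise matrix is O(n²) memory; the CLI warns above 20 000
cells and supports subsampling. Cluster summaries report per-cluster counts,
mean traces, and coarse channel descriptors (mean-level terciles across
clusters, a monotone-decay flag with a 2%-of-range tolerance, and a peak
time when the maximum exceeds both endpoints by 10% of the range).

## Hypothesis tests

**Sharpness vs fate.** Impact calcium traces are normalised by their maximum
(zero-max traces dropped and flagged; z-scoring is a config option), centered
PCA is fit, and the first-PC coordinate is the sharpness score. PCA sign is
arbitrary, so the score is oriented to correlate positively with mean
intensity over the first quarter of the window. Dead vs viable score
distributions are compared with the two-sided two-sample Kolmogorov–Smirnov
test — exact null distribution when n·m ≤ 10⁴, asymptotic otherwise.

**Fate labeling.** A cluster is "dead" when the maximum of its mean NMP
trace exceeds a threshold; the default is the midpoint between the lowest
and highest cluster-level NMP maxima in the dataset (the field provides no
canonical cutoff; the midpoint rule is a documented stand-in and degenerate
cases — one cluster, one fate class — are flagged). Cells inherit their
cluster's label.

**Late death vs distance.** Death time is the time of maximum NMP (matching
how a delayed permeability rise peaks), restricted to cells dying more than
1 h after impact. Death time is regressed on Euclidean distance to the
impact point and the slope tested with the overall regression F (identical
to the squared slope t in the single-covariate model). Fewer than three
qualifying cells yields an explicit insufficient-data report.

**Mitochondrial polarity vs distance.** High- vs low-TMRM cells' distance
distributions are compared by KS, with group medians reported.

All three procedures are calibrated by matched null simulations (type-I
error ≈ 0.05 at the nominal level); no multiple-testing correction is
applied across the three hypotheses.

## Orchestration and reproducibility

The CLI chains simulate → preprocess → train → embed → analyze → cluster →
test. A single global seed fans out to per-stage seeds (CRC32 of the stage
name, mod 2³¹) so stages rerun independently yet reproducibly. Every derived
artifact carries a SHA-256 content fingerprint of the data it consumed;
stages refuse mismatched fingerprints. Datasets and matrices live in HDF5
containers; labels, latents, coordinates, and summaries export as CSV; test
reports as JSON.

## Problem sizes

The default verification sizes — 2000 traces for training quality, 1200
cells for cluster recovery, 400-cell impact cohorts with 50 power seeds and
200-replicate null calibrations — were chosen as the smallest sets at which
the respective statistics are stable, and run end-to-end in a few minutes on
one CPU core.

## Known limitations

- The VAE, like the workflow it reimplements, does not capture sparse
  spontaneous calcium spikes; they surface in the short-timescale error
  tail rather than in the reconstruction.
- Latent coordinates have no enforced biological meaning; the package maps
  components to behaviors only through decoding, never through a named
  death-mode ontology.
- The exact-KS path is only used for small samples; very large tied samples
  fall back to the asymptotic approximation.
- Cluster-count cuts rely on scipy's `maxclust` criterion, which can return
  fewer clusters than requested under exact ties (continuous divergences
  make this vanishingly rare).
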