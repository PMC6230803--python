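# Methods

## Sorting chain

The sorter assumes extracellular spikes are (i) rare threshold crossings of a
band-limited trace, (ii) stereotyped per neuron up to additive noise, and
(iii) separable in a low-dimensional wavelet feature space. Stages:

**Filtering.** Second-order elliptic band-pass, 300–3000 Hz, applied
forward-backward (`sosfiltfilt`) for zero phase distortion so spike peaks do
not move. Ripple 0.1 dB and stop-band attenuation 40 dB are conventional for
this filter family and are exposed in `DetectionParams`.

**Threshold.** Thr = k·median(|x|)/0.6745 with k = 5. The divisor is the
median of |N(0,1)|, so the estimator reads the noise SD off the trace while
remaining insensitive to the spikes themselves (they occupy ≪ half the
samples). Estimated once over the whole trace; slow drift is out of scope.

**Detection.** Crossings of the rectified trace (polarity `both` by default;
`negative`/`positive` available because real preparations differ). The peak
is the rectified maximum within w_post = 44 samples of the crossing; a
lockout of w_post samples suppresses double triggers. Windows are
w_pre + 1 + w_post = 64 samples with the peak at sample 20 (1-based); events
whose window leaves the trace are dropped, not padded. Tetrode mode detects
per channel, merges crossings within ±0.5 ms keeping the largest |peak|, and
concatenates all four channel windows.

**Realignment.** Each peak-channel block is interpolated with a cubic spline
at 5× resolution (320 points); the extremum is located on the fine grid
within ±2 samples of the alignment point, ties broken toward the earlier
sample, and all channel blocks are resampled with that shift. Shifts of at
most one fine-grid step (0.2 samples) count as aligned — this bounds the
residual jitter at 0.2 samples and makes the operation exactly idempotent.

**Features.** Periodized orthonormal Haar transform, four levels, so each
64-sample block maps 1:1 onto 64 coefficients (a4‖d4‖d3‖d2‖d1) and energy is
conserved; channel blocks are transformed independently and concatenated.
Per coefficient, a Lilliefors statistic is computed across spikes: one
trimming pass removes values outside mean ± 3 SD (plain sample SD), then the
statistic is the KS sup-distance between the empirical CDF and a normal CDF
with the retained sample's mean and SD (ddof = 1). Columns with fewer than
10 retained values or zero variance score 0 (uninformative).

**Coefficient selection.** With the statistics sorted ascending into
s(1..M), the slope estimate is d(j) = [s(j+9) − s(j)]/10 · M/max(s) (the
first quotient spans s(1)..s(10)). The knee is the first j with d > 1 at
three consecutive positions; selected coefficients are those with
ks_stat *strictly* greater than s(knee) (ties at the knee value are
excluded). If no knee exists — e.g. an exactly linear sequence, whose d is
constant at 0.9 under this normalization — the selection falls back to the
10 largest statistics per channel, reproducing fixed-count behaviour.
`fixed10` and `all` modes are available for A/B comparison.

**SPC.** Interaction graph: symmetric-union KNN (K = 11) unioned with a
minimum spanning tree so the graph is always connected. Couplings
J_ij = (1/K̂)·exp(−d²_ij/2a²), a = mean nearest-neighbour distance, K̂ = mean
degree; coincident points get the maximal coupling. Swendsen–Wang dynamics
on q = 20 Potts states: per sweep, an edge with equal endpoint spins freezes
with probability 1 − exp(−J/T); frozen components redraw one uniform spin
each. At T = 0 every positive-J edge freezes (the zero-temperature limit),
giving a single cluster. Temperatures 0…0.25 in steps of 0.01; 100 burn-in
plus 300 measurement sweeps per temperature; per-edge correlation is the
equal-spin fraction f shifted to G = (qf − 1)/(q − 1). Edges with G > 0.5
are links; in addition each point links to its maximum-correlation
neighbour provided that correlation exceeds half the link threshold. The
capture step keeps cluster peripheries attached until the whole cluster
decorrelates — without it, peripheral points (which have the weakest
couplings) peel off one by one as T rises, the principal cluster shrinks
*gradually*, and the regime-border criterion below (which looks for an
abrupt collapse) has nothing to detect. The lower bar on the capture
correlation prevents random near-zero correlations from percolating the
paramagnetic phase. A mutual-KNN graph (the stricter neighbourhood rule) is
available via `mutual_knn=True`; it thins peripheral degree to 2–4 and
reintroduces the erosion, which is why union is the default. Partitions are
deterministic given the seed. Features are clustered as-is (no
standardization); `zscore=True` enables it.

**Cluster selection.** Sizes are compared rank-against-rank between
consecutive temperatures (the temperature-map convention), with all sizes at
the virtual temperature before T₀ equal to 0 — so the first partition's
clusters of at least N_inc spikes always register. N_inc = 20 by default;
smaller values over-select, larger ones miss sparse units. The border
T_B = min{T_i : (|C₁^{T_i}| + LI^{T_i})/|C₁^{T_{i−1}}| < 0.4} with
LI = max_{j>1}(|C_j^{T_i}| − |C_j^{T_{i−1}}|) floored at 0 (a negative
"largest increment" is no increment); if the condition never holds nothing
is discarded. The documented operating ranges (0.25–0.45 for the border
threshold, 0.5–0.95 for the overlap cutoff k_O = 0.9) leave results
unchanged on separable data, which the test suite checks. Overlap
resolution walks temperatures high → low and keeps a candidate only if its
overlap coefficient with every kept higher-temperature candidate is below
k_O; this matches "keep the higher-temperature copy" and is independent of
candidate order. Clusters pulled in by the "all larger clusters" rule get no
special treatment in overlap resolution, and no extra minimum-size filter is
applied. When two surviving clusters from different temperatures share
events, the higher-temperature (more refined) cluster takes them.

**Templates.** Centroid = per-sample mean over the raw concatenated
waveform (64·n_channels dims, not feature space); σ_T = √Σᵢ var(xᵢ) with
the unbiased (n−1) variance — at cluster sizes ≥ 100 the convention is
immaterial. Unclustered spikes go to the argmin-distance centroid when that
distance is below 3σ_T of that cluster (each cluster's own radius),
otherwise label 0. Distance ties go to the lowest cluster id. Singleton
clusters have σ_T = 0, are flagged, and can capture nothing. Spikes whose
cluster was discarded during selection re-enter through template matching
like any other unclassified spike.

**Subsampling.** Above `subsample_cap` = 20,000 spikes, feature screening
and SPC run on a seeded uniform subsample; the overflow is assigned by
template matching. This bounds the Monte Carlo cost while keeping every
spike labelled.

**Seeding.** A single global seed fans out per stage as
SeedSequence([seed, hash(stage name)]), so a staged CLI run and the one-shot
pipeline are bit-identical, and each stage is reproducible standalone.

## Simulator

A recording is Σ(unit template trains) + multiunit layer + background noise:

- **Units** (1–20): 64-sample templates with peak amplitude normalized to 1
  at the alignment sample, from a parametric family (asymmetric Gaussian
  depolarization lobe, opposite-sign after-hyperpolarization, optional
  leading lobe and late overshoot, both polarities). Two bank styles:
  `diverse` (default) — eight fixed, clearly distinct shapes (pairwise L2
  ≥ 1.7) extended by broad random draws with a 0.9 minimum-distance
  rejection rule, emulating easily separable units; `similar` — canonical
  negative biphasic spikes differing only in width/AHP detail (minimum
  distance 0.25), emulating a library of real average waveforms where
  sorting is hard. Firing is Poisson at 3 Hz (exponential ISIs) with a 2 ms
  absolute refractory floor. Spikes are placed on-grid (times rounded to
  samples); `jitter=True` adds sub-sample offsets via spline-shifted
  templates.
- **Multiunit** (optional): template spikes at peak 0.4–0.6, Poisson at a
  rate chosen so the requested fraction of events is multiunit; infeasible
  fractions (> ~200 Hz) raise.
- **Noise**: a dense Poisson train (20,000 events/s) of the template shapes
  at uniform ±amplitudes, band-passed to 300–3000 Hz and rescaled so the
  noise-only SD equals `noise_sd` exactly. The density matters: at this rate
  ~50 shapes overlap per sample and the sum is Gaussian-like by the central
  limit theorem while keeping the spectral footprint of neural background;
  sparse trains would instead inject detectable spike-like events (which is
  the multiunit layer's job).
- **Tetrode** mode: per-unit random channel gains in [0.2, 1], with one lead
  channel pinned to 1 so every unit stays detectable; independent noise per
  channel.

What the simulator does *not* model: electrode drift, bursting amplitude
decrement, overlapping-spike superposition beyond what Poisson collisions
produce, and biophysically detailed background (distance-scaled compartment
models). Passing tests therefore demonstrate the algorithm's correctness and
its behaviour under calibrated noise, not performance on every pathology of
real tissue.

## Problem sizes and tolerances

Tests and the acceptance script run desk-scale: 60 s single-channel
simulations (~500–550 spikes), 3 units, noise SD 0.05–0.20, five seeds per
condition; SPC fixtures of 600 points in 10-d; the subsample/overflow path
exercised at 2,550 spikes with a cap of 2,000 (the cap is configuration,
the default stays 20,000). End-to-end recovery is asserted as hits = 3 with
zero false positives in at least 4 of 5 seeds per noise level; the threshold
estimator is asserted at 5.00 ± 0.01 on 10⁶ Gaussian samples; Haar energy
conservation at 10⁻⁸ relative; realignment idempotence at 10⁻¹⁰.

## Known limitations

- The unit-count / selected-coefficient rank correlation is positive only on
  the rising branch (2→8 units) of parametric-bank ladders and plateaus
  beyond; banks of parametric shapes stop activating new wavelet
  coefficients past ~8 units, unlike libraries of real average waveforms
  whose shape diversity keeps growing. The acceptance script reports the
  measured correlation; it is not asserted.
- SPC hyperparameters (q, K, link threshold, sweep counts) follow the
  literature's conventions and are exposed, but only statistical — not
  bitwise — agreement with other SPC implementations can be expected.
- Overlapping-spike resolution and multi-session drift tracking are out of
  scope.
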