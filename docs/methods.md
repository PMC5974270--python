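# Methods

`paintrace` re-creates, on simulated data, a decoding analysis of acute pain
signals in rat anterior cingulate cortex (ACC): multi-channel local field
potentials (LFP) and sorted-unit spike trains are recorded around brief laser
stimulations of three intensities — non-noxious (NS, 50 mW), low noxious
(LS, 150 mW) and high noxious (HS, 250 mW) — in naive animals and after
Complete Freund's Adjuvant (CFA) inflammation, a chronic-pain model. The
package implements the full analysis chain and a generative stand-in for the
recordings, so every stage is testable without animal data.

## Synthetic sessions

A session holds `2 * n_trials_per_class` trials (default 60) of two stimulus
classes, balanced and randomly interleaved. Each trial spans [−5, +5) s
around laser onset at 1 kHz (half-open grid: sample k at −5 + k/1000 s;
10,000 samples), with three linked components:

**LFP.** Each of the 8 channels is pink noise (1/f^α spectrum, α = 1,
flattened below 1 Hz, σ = 50 µV) mixing a latent component shared across
channels (60% of variance) with independent channel noise. Event-related
synchronization (ERS) is modeled as band-limited Gaussian noise added to the
shared component during the stimulus epoch, scaled so that the power of band
b is multiplied by a configurable gain g(b, intensity). Defaults place the
ERS where nociceptive responses are seen empirically — theta (4–8 Hz):
1 / 2.5 / 5 for NS / LS / HS; high gamma (60–100 Hz): 1 / 2 / 4; other bands
stay at 1. The epoch runs from onset (optionally delayed by
`ers_onset_delay`) to paw withdrawal, or the full 5 s when the animal does
not withdraw, with 50-ms raised-cosine ramps at the edges to avoid spectral
splatter. Under CFA the ERS *excess* of noxious stimuli is amplified:
g_eff = 1 + m·(g − 1) with m = 1.5 for LS and HS. Scaling the excess rather
than the raw gain keeps null bands (g = 1) exactly null under CFA, so the
chronic-pain manipulation cannot manufacture signal where the naive
condition has none; its strongest proportional effect lands on LS, matching
the empirical pattern of chronic pain inflating responses to moderate
stimuli.

**Spikes.** Each of 16 units is a Poisson process at 5 spikes/s. A fixed
minority (25%, i.e. 4 units; round-half-up, identities drawn once per
session) switches during the stimulus epoch to
`base_rate · (1 + (modulated_rate_gain − 1) · φ(intensity))` with φ = 0, 0.6,
1 for NS, LS, HS and a default gain of 3. The affine form makes
`modulated_rate_gain = 1` an exact null for every intensity.

**Withdrawal latency.** NS never withdraws (epoch = 5 s). LS and HS draw
from per-intensity gamma distributions truncated to (0, 5] by rejection —
defaults Gamma(9, 1/3) (mean ≈ 3 s) for LS and Gamma(9, 2/9) (mean ≈ 2 s)
for HS, so hotter lasers withdraw earlier. No latency statistics were
available to fit, so these are plausibility choices exposed in the config.

All randomness flows from one `SeedSequence`; a (config, seed) pair
reproduces a session bit for bit (checked via SHA-256 of all arrays).

What the generator does **not** emulate: biophysical LFP genesis, electrode
geometry and impedance, line noise, movement artifacts, spike waveforms or
sorting errors, non-Poisson spike statistics (bursting, refractoriness),
cross-frequency coupling, and trial-to-trial adaptation. Passing tests
therefore certify the *analysis chain* — its bookkeeping, calibration and
sensitivity under the stated statistical structure — not performance on real
tetrode recordings.

## Preprocessing

Per trial: each channel is linearly detrended (least squares); channels
whose log total power has robust Z (median/MAD across channels, consistency
0.6745) exceeding 3 in absolute value are rejected (all-alike channels, MAD
= 0, keep everything; an empty result raises an unusable-trial error); the
surviving channels are projected onto the first principal axis of their
covariance, with the eigen-sign fixed to correlate non-negatively with the
channel mean. PCA is fitted per trial on the trial's own samples — trials
are the decoding unit, and per-trial fits avoid leaking cross-trial
structure. Note that a robust Z threshold of 3 on a handful of channels has
a non-trivial false-rejection rate (the MAD is noisy at n = 8); this is the
price of a scale-equivariant rule.

## Spectral estimation

Multitaper estimation with discrete prolate spheroidal (Slepian) tapers,
time–bandwidth product TW = 3 and K = 2·TW − 1 = 5 tapers (each unit-norm;
requesting K > 2·TW warns about ill-concentrated tapers). The PSD is the
mean one-sided eigenspectrum; no zero padding, so the frequency resolution
is fs/N. The spectrogram slides a window (display default 500 ms, step
50 ms) and reports window-center times. Band power sums PSD bins over
half-open bands — theta [4, 8), alpha [8, 15), beta [15, 30), low gamma
[30, 60), high gamma [60, 100) Hz — which tile 4–100 Hz exactly once
(published band lists share edges; the half-open convention resolves the
double counting).

The ERS Z-score references the response epoch [0, 5) s to the baseline
[−5, 0) s: z_i = (P_response,i − mean_j P_baseline,j) / sd_j P_baseline,j,
with dispersion across trials — the standard ERS normalization, and the only
reading that gives single-trial Z-scores a meaningful scale.

## Decoding features

Features live on a 50-ms grid over (0, 5] — 100 bins. Spike features are
per-unit counts in consecutive 50-ms bins, membership (start, end] so a
spike exactly at onset belongs to the baseline. LFP features are multitaper
band-power sums (TW = 3, K = 5) over the trailing 1-s window [t − 1, t) at
each step; windows ending before 1 s reach into the baseline, keeping the
grid aligned with the spike bins. The "all frequency" feature concatenates
the five band powers (4–100 Hz; the 1–3 Hz range is excluded as
artifact-prone). Both modalities *accumulate*: the design matrix at bin k
concatenates steps 1..k (bin-major), so dimensionality grows from C (or 5)
to 100·C (or 500) and each bin's columns are a prefix of the next bin's. A
non-accumulated per-window mode is available. Combined features concatenate
spike and LFP columns per bin.

## Decoding and chance level

A polynomial-kernel SVM (degree 3, C = 1, coef0 = 1; libsvm's SMO dual
solver via scikit-learn) is evaluated per bin by stratified 5-fold
cross-validation — each fold tests on ~20% of trials, the per-fold view of
an 80/20 split. Default 100 Monte-Carlo repetitions each draw a fresh fold
partition, reused across all bins of that run so the trajectory shape is not
blurred by partition noise; the result is mean ± SEM accuracy per bin.
Features are z-scaled using training-fold statistics only (toggleable) —
necessary when integer counts and µV²-scale powers share a kernel. Seeds
spawn from one `SeedSequence`, so run i is identical whether 1 or 100 runs
are requested. The polynomial degree is a conventional default, exposed in
`SVMSpec`.

The chance level permutes labels across trials (features untouched), runs
one stratified CV per shuffle at the final bin (500 shuffles by default),
and reports the mean ± SD shuffled accuracy — close to 50% for balanced
classes, drifting toward the majority rate otherwise.

## Onset detection

The dynamic range is peak accuracy minus chance. The onset under criterion
f (1/e ≈ 0.37 by default; ½ as the alternative) is the crossing of
`chance + f · dynamic_range`. The default reading follows the curve down
from the peak: the onset is the **last** upward crossing before the
earliest-peak time, i.e. the moment after which accuracy stays above the
threshold until the peak. On monotone trajectories this coincides with the
first crossing from onset (also available as `direction="forward"`), but it
is robust to transient noise bumps before the signal arrives, which
otherwise capture the first-crossing scan in finite-Monte-Carlo
trajectories. Crossings are linearly interpolated between the straddling
50-ms bins (`interpolate=False` snaps to the bin grid). A gate — dynamic
range must exceed 3× the chance SD by default — returns an explicit "no
detectable onset" on flat trajectories instead of a spurious time. Onsets
are compared with withdrawal latencies by signed differences (median, IQR),
Spearman correlation, and a two-sided Mann-Whitney rank-sum test; group
contrasts elsewhere in the package use the same rank-sum test (exact null
when feasible, mid-ranked ties).

## Numerical and testing choices

- Pink-noise and band-limited components are synthesized in the Fourier
  domain and normalized empirically per realization; ERS gain calibration
  uses the analytic band-variance fraction of the background weights.
- Withdrawal truncation uses rejection sampling (bounded retries).
- Accuracy argmax ties resolve to the earliest time (affects `peak_time`).
- Tests run at desk scale: the minimum session size (15 trials/class),
  4 channels, 8 units, 3–10 Monte-Carlo runs with evaluation-bin strides,
  and 20–100 permutation shuffles; the chance-level check runs at the full
  stated scale (30 trials/class, 500 shuffles, 5-fold). The
  shift-equivariance check uses a deliberately high-SNR configuration
  (theta/high-gamma gains 30/20, withdrawal near 5 s, 24 trials/class):
  with accumulated features, every pre-signal bin contributes pure-noise
  dimensions, so a delayed ERS is slightly diluted and the onset shift
  acquires a positive bias of ~0.05–0.1 s at moderate SNR; the property
  holds within ±0.15 s in the steep regime.

## Known limitations

- Reported decoding accuracies describe the synthetic model, not rat ACC;
  absolute values depend directly on the configured ERS gains.
- The artifact-rejection rule and spectrogram display parameters are
  reasonable defaults, not fitted to data.
- Session-level onset only; no single-trial onset or changepoint methods.
- No spike–field coherence, phase or wavelet features, and no multi-region
  analyses.
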