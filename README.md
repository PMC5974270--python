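# paintrace

Decoding the intensity and onset of acute pain signals from cortical
population activity — as a fully simulated, testable pipeline.

Neural recordings in rat anterior cingulate cortex (ACC) show that brief
noxious laser stimuli evoke event-related synchronization (ERS): a
stimulus-locked power increase in theta (4–8 Hz) and high-gamma (60–100 Hz)
local field potential (LFP) bands that scales with stimulus intensity and is
amplified in chronic pain. From such recordings one can ask two quantitative
questions: *how well* does population activity distinguish stimulus
intensities, and *when* does the discriminative signal emerge relative to
the behavioral withdrawal reflex? `paintrace` implements the full analysis
chain that answers both —

- a **synthetic session generator** with the statistical structure of the
  experiment (pink-noise LFP with intensity-scaled band-limited ERS, sparse
  Poisson units with a 20–30% stimulus-modulated minority,
  intensity-dependent withdrawal latencies, naive vs. CFA chronic-pain
  conditions), fully seed-deterministic;
- **preprocessing**: linear detrend, robust artifact-channel rejection,
  projection onto the first principal component;
- **multitaper spectral estimation** (Slepian tapers, TW = 3, K = 5) with
  per-band power and baseline Z-scores,
  z = (P_response − mean(P_baseline)) / sd(P_baseline);
- **cumulative decoding features** on a 50-ms grid over (0, 5] s: per-unit
  spike counts and trailing-1-s-window band powers, accumulated so the
  design matrix grows from C to 100·C columns;
- **SVM decoding trajectories**: polynomial-kernel SVM
  (y = Σᵢ αᵢ K(x, xᵢ) + b), stratified 5-fold cross-validation over
  Monte-Carlo repartitions (mean ± SEM), and a 500-shuffle label-permutation
  **chance level**;
- **onset detection**: with dynamic range D = peak − chance, the onset is
  the crossing of chance + f·D before the peak, f = 1/e ≈ 0.37 (or ½),
  compared against withdrawal latency by rank statistics.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import numpy as np
import paintrace as pt

config = pt.SynthConfig(n_trials_per_class=15, channels=4, n_units=8)
session = pt.make_session(config, "NS-HS", condition="naive", seed=42)
pt.denoise_session(session)

theta = pt.zscore_band_power(session, "theta")
labels = session.labels()
for lab in ("NS", "HS"):
    z = theta.z[labels == lab]
    print(f"theta Z ({lab}): {z.mean():+.2f} +/- {z.std(ddof=1):.2f}")

feats = pt.lfp_band_features(session)          # all-frequency, accumulated
traj = pt.decode_trajectory(feats, n_mc=10, seed=0, eval_bins=5)
traj.with_chance(pt.chance_level(feats, n_shuffle=100, seed=1))
print(f"chance = {traj.chance:.3f} +/- {traj.chance_sd:.3f}")
print(f"peak accuracy = {traj.peak_acc:.3f} at t = {traj.peak_time:.2f} s")

est = pt.onset_from_trajectory(traj)           # 1/e criterion
hs_lat = [t.withdrawal_latency for t in session.trials if t.withdrawal_latency]
print(f"decoded onset = {est.onset_time:.2f} s (threshold {est.threshold_acc:.3f})")
print(f"mean HS withdrawal latency = {np.mean(hs_lat):.2f} s")
```

prints

```
theta Z (NS): -0.69 +/- 0.80
theta Z (HS): +9.57 +/- 5.09
chance = 0.513 +/- 0.103
peak accuracy = 0.990 at t = 0.75 s
decoded onset = 0.12 s (threshold 0.688)
mean HS withdrawal latency = 2.23 s
```

High-intensity trials carry a strong theta ERS (Z ≈ +9.6) while non-noxious
trials sit at baseline, so the decoder separates the two classes almost
perfectly (peak 0.99 against a 0.51 permutation chance), and the
discriminative signal crosses the 1/e threshold ~0.1 s after laser onset —
far earlier than the ~2.2-s withdrawal reflex, as expected when the
simulated ERS starts at the stimulus itself.

## Command line

Each stage is also a subcommand of a single `paintrace` executable, reading
and writing HDF5 session containers, NPZ feature tensors and tidy CSV/JSON
tables:

```sh
paintrace synth --config cfg.yaml --pair NS-HS --condition naive --seed 3 --out out/
paintrace preprocess --in out/session_naive_NS-HS_seed3.h5 --z-thresh 3 --out out/denoised.h5
paintrace spectra    --in out/denoised.h5 --band theta --out out/spectra.csv
paintrace features   --in out/denoised.h5 --modality lfp_all --out out/feat.npz
paintrace decode     --features out/feat.npz --n-mc 100 --n-shuffle 500 --out out/traj.csv
paintrace onset      --trajectory out/traj.csv --criterion 1/e --out out/onset.json
paintrace run        --config cfg.yaml --out study/   # all conditions x pairs x modalities
```

`paintrace run` executes the whole study (2 conditions × 3 class pairs ×
3 feature modalities), emitting Z-score tables, trajectory CSVs,
onset-vs-withdrawal tables for both criteria, and a manifest with per-stage
timings and SHA-256 checksums of every output.

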