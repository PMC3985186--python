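# rnptrack

Single-particle analysis of mRNA–motor complex (RNP) motility on
microtubules.

In vitro reconstitution assays image fluorescently labelled RNPs moving
along polarity-marked microtubules by TIRF microscopy and track them to
sub-pixel precision. Two behaviours dominate: highly processive,
dynein-driven transport toward the microtubule minus end, and diffusive
back-and-forth motion along the lattice. `rnptrack` implements the full
downstream analysis for this kind of experiment, for anyone who has
particle coordinates (e.g. a TrackMate spot table) and microtubule axis
annotations:

- **Projection** of 2D positions onto the oriented microtubule axis,
  yielding signed on-axis positions s (nm), with s = 0 at the minus end;
  the tracking accuracy is calibrated as the SD of frame-to-frame
  displacements of immobile particles (11.3 nm in the reference assay).
- **Run segmentation**: a run is a maximal block of consecutive same-sign
  displacements each exceeding a cutoff of ~2× the tracking accuracy
  (22 nm by default); sub-cutoff frames are pauses; a reversal is scored
  between consecutive above-cutoff displacements of opposite sign,
  |sign(dᵢ) − sign(dᵢ₊₁)| = 2. Tracks are classified stationary
  (range ≤ 1 pixel), unidirectional, or bidirectional, and per-chamber
  population fractions are reported as mean ± SEM over chambers.
- **MSD analysis**: internally averaged mean square displacement
  (all pairs per lag, lags capped at a quarter of the track duration);
  the log–log slope separates transport (slope ≈ 2, MSD = v²t²) from
  diffusion (slope ≈ 1, MSD = 2Dt), and D is estimated from a linear fit
  whose intercept absorbs the localization-noise floor.
- **Stepwise photobleaching**: an edge-preserving Chung–Kennedy filter
  for visual/manual counting, an automated top-down step fitter with
  penalized-likelihood model selection, and the copy-number arithmetic
  mean steps / labelled fraction → subunit copies → motors (two tagged
  light-intermediate chains per dynein).
- **Encounter scoring**: outcomes (reversal / pass / pause / detach) of
  encounters with static microtubule-associated obstacles, a
  chance-coincidence null built by superimposing obstacle layouts from an
  independent source on obstacle-free tracks, Fisher's exact comparison,
  and microtubule-end encounters with pause-duration statistics.
- **Synthetic data** with ground truth for every stage: Brownian and
  constant-velocity on-axis motion with Gaussian localization noise,
  mixed populations, blocking obstacles, exponential end dwells, and
  binomially labelled stepwise-bleaching traces.

## Worked example

Simulate one imaging chamber of 60 motile RNPs (24% processive at
−1200 nm/s, the rest diffusive with D = 5000 nm²/s, 15 fps, 8 nm
localization noise), then run the analysis:

```python
import numpy as np
import rnptrack as rt

cfg = rt.SimConfig(frame_rate=15.0, n_frames=300, loc_noise_sd=8.0, seed=11)
axis = rt.default_axis(cfg)
pairs = rt.simulate_population(60, cfg, processive_fraction=0.24)

tables = []
slopes = {"unidirectional_minus": [], "bidirectional": []}
for traj, truth in pairs:
    onaxis = rt.project_onto_axis(traj, axis)
    table = rt.segment_runs(onaxis)
    label = rt.classify_track(table)
    tables.append(table)
    if label in slopes:
        slope = rt.loglog_slope(rt.msd_internal(onaxis), noise_floor=2 * 8.0**2).slope
        slopes[label].append(slope)

summary = rt.population_stats(tables)
print(f"unidirectional fraction: {100 * summary.fraction_mean:.1f}%")
for label, vals in slopes.items():
    print(f"{label}: n={len(vals)}, mean log-log MSD slope {np.mean(vals):.2f}")

uni_runs = [r for t in tables if t.classification == "unidirectional_minus" for r in t.runs]
print(f"unidirectional run velocity: {np.mean([r.velocity for r in uni_runs]):.0f} nm/s")
```

prints

```
unidirectional fraction: 20.0%
unidirectional_minus: n=12, mean log-log MSD slope 2.00
bidirectional: n=48, mean log-log MSD slope 0.94
unidirectional run velocity: 1200 nm/s
```

The classifier found 12 of 60 tracks exclusively minus-end-directed
(20%; the generative fraction is 24%, and single chambers of 60 scatter
around it). Their MSD slope of 2.00 identifies active transport at the
generative 1.2 µm/s, while the bidirectional tracks' slope of ~1
identifies diffusion. Copy numbers follow the same arithmetic as the
bleaching assay:

```python
>>> rt.copy_number_chain(2.14, label_fraction=0.49, subunits_per_motor=2)
(4.36734693877551, 2.183673469387755)
```

i.e. a mean of 2.14 bleaching steps with 49% of subunits labelled implies
≈4.37 tagged-subunit copies and ≈2.18 dynein motors per RNP.

A command-line interface mirrors the library
(`rnptrack simulate | project | segment | msd | bleach | encounters |
null-sim | report`); `rnptrack report --config cfg.yaml --out-dir out/`
runs the whole pipeline from a YAML config and writes CSVs plus a JSON
manifest with the seed and parameters.

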