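# exotirf

Simulation and kinetic analysis of receptor exocytosis in TIRF microscopy
movies.

## The problem

Total internal reflection fluorescence (TIRF) imaging of neurons expressing
pH-sensitive receptor tags (superecliptic pHluorin, SEP) shows individual
exocytic events as abrupt fluorescence spots: the vesicle lumen is acidic
(SEP quenched) until the fusion pore opens, then the spot appears within a
frame and decays as receptors disperse. Two kinetic modes coexist:

- **transient** events — full release, single-exponential spot decay with
  half-life t½ ≈ 2 s;
- **persistent** events — receptors remain clustered at the insertion site
  for more than 4 s; under control conditions the spot dims slowly
  (t½ ≈ 17 s) because the pore closes and the vesicle *reacidifies*, and
  blocking reacidification (bafilomycin) converts the decay into a plateau
  followed by a fast (t½ ≈ 2 s) drop when the retained cargo is finally
  released. A fraction of persistent events is followed by a second event
  at the same site (within 1 µm²) — kiss-and-run pore reopening.

Whether such *consecutive* events could arise by chance is settled with a
Monte Carlo null model: N events are placed uniformly at random on the
thresholded neuron footprint I_t(i,j) (I_t = 1 iff I ≥ T), given a random
time order, with a fixed 10% marked persistent; the probability that any
persistent event is followed by a later event inside a 1 µm² window is
estimated over ≥10⁵ replicates. For a 15,318-pixel mask and 40 events this
probability is ≈ 0.02 — far below observed consecutive-event frequencies
(12–19% of persistent events), hence consecutive events are not random
co-occurrences.

This package provides, for anyone analyzing (or teaching the analysis of)
such data:

- `exotirf.synthetic` — a mechanistic, seeded generator of dual-channel
  (SEP / pH-insensitive mCherry / clathrin) movies with ground truth:
  vesicle state machine (open → partial release → close → reacidify →
  reopen), EMCCD-like Poisson+Gaussian noise, photobleaching, neuron-shaped
  masks;
- `exotirf.detect` — background subtraction, bleaching correction,
  difference-filter event detection, ROI trace extraction, 10–90% rise
  times, kymographs;
- `exotirf.kinetics` — plateau-plus-one-phase-decay fitting
  F(t) = F0 for t < t0, (F0 − B)·exp(−k(t − t0)) + B for t ≥ t0 with
  t½ = ln 2 / k, and dwell-based transient / persistent /
  biphasic-persistent classification (dwell = time from the initial peak
  until the trace falls below 2× background);
- `exotirf.spatial` — the random-placement null model, observed
  consecutive-event pairing, Pearson colocalization;
- `exotirf.pipeline` / `exotirf.stats` — end-to-end orchestration across
  cells and conditions, pooled-variance Student's t-test and
  D'Agostino–Pearson normality (per-cell as the statistical unit).

## Worked example

```python
import exotirf as xt

cfg = xt.SimulationConfig(seed=11)       # 10 Hz, 60 s, 256x256, ~40 events
movie, truth, mask = xt.simulate_movie(cfg)
events = xt.analyze_movie(movie)         # detect -> trace -> classify
print(len(truth), len(events))
print(events["label"].value_counts().to_dict())
print(round(events.loc[events.label == "transient", "half_life_s"].median(), 2))

res = xt.estimate_probability(
    xt.generate_mask({"kind": "neuron", "target_px": 15318}, 256, 256, seed=1),
    xt.NullModelConfig(N=40, persistent_fraction=0.10, window_px=2,
                       replicates=100_000, seed=7),
)
print(round(res.p_hat, 4))
```

prints

```
46 46
{'transient': 40, 'persistent': 5, 'unclassified': 1}
2.03
0.0204
```

i.e. all 46 simulated events are recovered, ~11% classify as persistent
(the generator draws the persistent label at 9.8%), the median fitted
transient half-life matches the generating 2 s, and the chance of a random
consecutive pair at 40 events on a 15,318-pixel footprint is ≈ 0.02.

The same workflow is available from the shell:

```bash
exotirf simulate --seed 11 --out movie.tif
exotirf detect movie.tif --out detections.csv
exotirf classify movie.tif detections.csv --out labels.csv
exotirf nullmodel --seed 7 --events 40 --replicates 100000
exotirf run --n-cells 10 --seed 42 --outdir results/basal
```

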