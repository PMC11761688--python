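# paintkit

Simulation and analysis of live-cell PAINT single-molecule localization
microscopy (SMLM) experiments.

In PAINT-style live-cell imaging, a fluorescent imager peptide transiently
binds a tag on a protein of interest; each binding event appears as a
short-lived diffraction-limited spot in a TIRF movie (50 ms frames). Fitting
every spot with a sub-pixel 2D Gaussian and accumulating the fitted
positions over tens of seconds builds an image resolved far below the
diffraction limit. `paintkit` implements the full computational chain for
such experiments — and a synthetic-data generator with known ground truth to
validate every stage:

* **Simulation** (`paintkit.sim`) — clustered ("clutch") or motile tube
  ground-truth scenes, Poisson binding with exponential residence times,
  direct ground-truth localization tables, and Poisson-noise camera frame
  rendering.
* **Localization** (`paintkit.localize`) — difference-of-Gaussians spot
  detection, least-squares 2D Gaussian fitting, Thompson-style precision
  σ<sub>loc</sub> = √((s² + a²/12)/N + 8π s⁴ b²/(a² N²)), and the strict
  < 30 nm precision filter.
* **Merging** (`paintkit.linking`) — links per-frame localizations of one
  binding event (20 nm radius, max 1 off-frame) and recovers the
  exponential mean residence time from chain-length statistics.
* **Rendering** (`paintkit.render`) — histogram / Gaussian SR
  reconstructions, maximum-intensity projections, temporal color maps, and
  moving-window stacks (25 s window, 0.5 s step) for dynamic structures.
* **Resolution** (`paintkit.frc`) — Fourier ring correlation on random
  half-dataset splits with the fixed 1/7 threshold, plus the
  resolution-vs-integration-time analysis (n = 3 random frame subsets).
* **Clustering** (`paintkit.cluster`) — DBSCAN (eps 0.3 µm, min 5),
  per-cluster convex-hull area, axis lengths, eccentricity (minor/major
  ratio), and the nearest-neighbor local-density map with the 5× mean-NN
  highlight.
* **I/O and pipeline** (`paintkit.io`, `paintkit.pipeline`, `paintkit.cli`)
  — ThunderSTORM-dialect CSV, multi-page TIFF stacks, YAML config, a
  manifest-writing `run_pipeline`, and a `paintkit` CLI with one subcommand
  per stage.

## Worked example

Simulate a clustered nuclear acquisition and push it through the pipeline:

```sh
paintkit simulate --kind clutch --n-structures 20 --sites 10 --sigma 50 \
    --fov 20000 --duration 30 --seed 1 --out sim.csv
paintkit run sim.csv --table --outdir out --seed 3
```

The numbered drivers under `analysis/` run the complete study on larger
synthetic acquisitions (`python analysis/01_simulate_acquisitions.py`, then
02–07 in order). Representative output:

```
nuclear: 6000 sites, 11875 binding events, 23232 localizations (232/s)
4887 localizations -> 1859 binding-event chains
recovered mean residence time: 101.8 ms (simulated: 100 ms exponential)
full-acquisition FRC resolution: 61.9 nm (117570 localizations, 1/7 threshold)
    20.0 s :   98.8 +/-  2.6 nm
   200.0 s :   62.3 +/-  0.6 nm
23232 localizations -> 988 clusters, 99.92% clustered
mean cluster area: 1.40e-02 um^2
```

Reading: the simulated acquisition produces ~232 localizations per second;
merging recovers the simulated 100 ms exponential residence time within 2%;
FRC resolution improves from ~99 nm at 20 s of integration toward ~62 nm
for the full 200 s; and DBSCAN recovers 988 of the 1000 simulated clusters
(1.2% lost to chance cluster-center proximity) with >99.9% of localizations
clustered. Small tables land under `results/`; bulky per-localization
artifacts under `scratch/`.

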