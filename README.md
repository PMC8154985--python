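# etlscan

Simulation and analysis pipeline for volumetric two-photon calcium imaging
with an electrically tunable lens (ETL) remote focus. The package covers the
full computational chain of a 3D-scanning whole-brain imaging experiment in
larval zebrafish:

- **`etlscan.synthetic`** — ground-truth generators: synthetic brains with
  non-overlapping 6 µm nuclei, calcium activity with exponential reporter
  kinetics (τ = 3.5–4.1 s) and four planted stimulus-response motifs,
  rendered interleaved frame streams with tilted-plane geometry, Poisson
  shot noise and rigid motion, fluorescent-bead z-stacks, and noisy LUT
  calibration point sets.
- **`etlscan.etl`** — remote-focus calibration: degree-5 least-squares fit of
  drive current against normalized depth z\* ∈ [0, 1], sawtooth z\*(t)
  scheduling (default 30 frames/cycle, 3 ms updates), and the per-row depth
  of the continuously ramping acquisition (each frame is tilted ≈ 6 µm from
  first to last row at whole-brain defaults).
- **`etlscan.psf`** — PSF metrology from bead stacks: reslice →
  average-project → profile → `FWHM = 2√(2 ln 2)·σ`, with a moment-based σ
  estimator (Gaussian-fit cross-check available) and FOV measurement from
  stage-travel records.
- **`etlscan.preprocess`** — plane de-interleaving, rigid subpixel motion
  correction by phase cross-correlation, 3-frame running average, and
  pre-stimulus noise-floor estimation.
- **`etlscan.segmentation`** — nuclear ROI detection on mean images (local
  maxima with minimum separation of one cell diameter) and per-ROI trace
  extraction; external ROI tables can be imported from CSV.
- **`etlscan.responses`** — looming-stimulus geometry, stimulus regressors
  convolved with a unit-sum exponential kernel, per-trace OLS fits, the
  score = β/MSE statistic, top-quantile responsive selection, and z-score
  (> 5) event detection.
- **`etlscan.clustering`** — Ward-linkage hierarchical clustering of
  response profiles with an auditable merge tree.
- **`etlscan.pipeline`** — end-to-end orchestration (simulate → preprocess →
  segment → analyze → cluster → report) from a YAML config, with per-stage
  seeds derived from a single root seed.

## CLI

```bash
etlscan calibrate-lut --points points.csv --degree 5   # fit the LUT polynomial
etlscan sawtooth --lut lut.json --frames 30 --rate 30 --dt 0.003
etlscan psf --stack beads.tif --axis z --center 40 50 50
etlscan preprocess --stream stream.tif --planes 30 --window 3
etlscan segment --series plane000.h5 --diameter 6
etlscan analyze --traces traces.h5 --protocol protocol.yaml --tau 3.5 --top 0.05
etlscan cluster --traces selected.h5 --k 4
etlscan run --config run.yaml                          # full synthetic pipeline
```

A minimal `run.yaml`:

```yaml
seed: 1
output_dir: scratch/run
brain: {n_cells: 2000}
protocol: {n_presentations: 10, interval: 150.0, stim_duration: 17.0}
analysis: {fraction: 0.05}
clustering: {k: 4}
```

Set `render: {enabled: true}` to rasterize the frame stream and run the full
imaging chain (slower); otherwise traces are scored directly.

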