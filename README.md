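# moldseed

Hyperspectral classification of seed mildew severity. The package covers the
full chain from raw imager output to a tuned classifier:

1. **hsi_io** — ENVI cube I/O (BIL/BIP/BSQ) and white/dark reflectance
   calibration `(raw − dark) / (white − dark)`.
2. **segmentation** — Otsu binarization of a single band (default: nearest
   598.71 nm), morphological open/close cleanup, deterministic raster-order
   seed numbering, per-seed mean spectrum extraction.
3. **preprocessing** — SNV, MSC, Savitzky–Golay smoothing and 1st/2nd
   derivatives.
4. **feature_selection** — random-forest impurity-importance screening and
   CARS (Monte Carlo PLS, exponentially decreasing retention, RMSECV
   minimization).
5. **jyssa** — sparrow search optimizer (producer/follower/scout roles) with
   an elite reverse (opposition) strategy over dynamic boundaries; used to
   tune the forest's tree count and per-split feature-subset size.
6. **classify** — cross-validated RF fitness for the optimizer, final model
   training, confusion-matrix evaluation with per-class precision/recall.
7. **synthetic_data** — ground-truthed spectra tables and renderable seed
   plates with five ordered severity classes (peak reflectance near 560 and
   800 nm decreasing with severity), affine scatter and additive noise.
8. **pipeline** — end-to-end orchestration with one global seed, comparing
   plain RF (n_estimators=5, max_features=3), SSA-RF and JYSSA-RF on a
   shared stratified split.

The study this reproduces did not deposit its maize cubes, so all testing
and acceptance run against the synthetic generator, whose distortions are
designed to exercise every stage.

## CLI

```bash
moldseed simulate --config sim.yaml --out-dir fixtures/   # synthetic ENVI set
moldseed calibrate --raw raw.hdr --white white.hdr --dark dark.hdr --out cs.hdr
moldseed segment --cube cs.hdr --band-nm 598.71 --out labels.png
moldseed extract --cube cs.hdr --labels labels.png --classes plate.yaml --out spectra.csv
moldseed preprocess --in spectra.csv --method snv --out spectra_snv.csv
moldseed select-bands --in spectra.csv --method cars --seed 7 --out bands.json
moldseed optimize --in spectra.csv --bands bands.json --algo jyssa --seed 7 \
    --out best_params.json --history history.csv
moldseed run --config pipeline.yaml      # full pipeline, all model arms
```

A minimal `pipeline.yaml`:

```yaml
out_dir: runs/demo
seed: 7
synthetic: {n_bands: 40, seeds_per_class: 30, noise_sd: 0.08}
band_mode: full          # full | rfimp | cars
algorithms: [rf, ssa-rf, jyssa-rf]
pop_size: 10
max_iter: 10
```

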