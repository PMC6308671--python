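# hsifuse

Fusion of two hyperspectral imaging instruments with complementary spectral
ranges for fruit bruise detection, as a reusable, tested pipeline:

* **synthetic data** (`hsifuse.synth`) — seeded generator emulating a
  push-broom imager (480–960 nm, 102 bands) and an LCTF imager
  (965–1655 nm, 139 bands): healthy/bruised mean-reflectance tables with
  water-absorption dips, a hard "calyx-like" bruised subgroup, bruise-ratio
  ground truth with a 25 % labeling rule, plus small raw/white/dark ENVI
  cube triplets;
* **cube preprocessing** (`hsifuse.imaging`, `hsifuse.envi`) — white/dark
  reflectance calibration, single-band masking with small-object removal,
  1200/1075 nm band-ratio sepal exclusion, mean-spectrum extraction,
  spectral-range trimming; minimal ENVI (.hdr + BIL float32) I/O;
* **chemometrics** (`hsifuse.chemometrics`) — PLS-DA (hand-written SIMPLS,
  oracle-tested against scikit-learn) on ±1 class codes with a Gaussian
  class-density probability calibration and equal-density cut-off,
  10-fold-CV latent-variable selection, autoscaling, cross-validated
  sensitivity/specificity, and a grid-searched RBF-SVM slot with the same
  probabilistic contract;
* **wavelength selection** (`hsifuse.featsel`) — random-frog subset chain
  with per-wavelength selection probabilities and CV-error subset sizing;
* **fusion** (`hsifuse.fusion`) — data level (autoscale + concatenate),
  feature level (separate or joint selection), and three decision-level
  rules: weighted majority vote, Bayesian sensor fusion using CV
  sensitivity/specificity as conditionals, and fuzzy-template matching of
  decision profiles;
* **evaluation** (`hsifuse.evaluation`) — confusion metrics (bruised is the
  positive class), ROC/AUC, and agreement-partition bookkeeping of fused
  decisions.

## CLI

```bash
# write synthetic paired spectrum tables + ground truth
hsifuse simulate --seed 1 --out-dir out/sim --n-healthy 60 --n-bruised 60

# calibrate an ENVI cube triplet, mask, extract mean spectra
hsifuse preprocess out/raw out/white out/dark --out out/spectra.csv \
    --mask-band 1075 --mask-threshold 0.3 --sepal-ratio 1.2

# fit a probability-calibrated PLS-DA model on a labeled CSV
hsifuse train --table out/sim/spectra_pb.csv --model-out out/model.json

# random-frog wavelength selection
hsifuse select --table out/sim/spectra_pb.csv --out out/selection.csv

# end-to-end seeded run from a key=value config file
hsifuse run --config configs/demo.cfg --out-dir out/run
hsifuse evaluate --metrics out/run/metrics.json
```

The config file is flat `key = value` text (see `configs/demo.cfg`); any
key can be overridden by a CLI flag. Fusion level is selected with
`level = data | feature-separate | feature-joint | decision` and the
decision rule with `decision_rule = wmv | bayes | fuzzy | all`. Runs are
fully seeded: identical configs produce byte-identical outputs
(`metrics.json`, fused-decision CSVs, selection tables, manifest).

## Conventions

Labels are `+1` healthy / `-1` bruised everywhere; sensitivity is the
recall of the bruised class and specificity the recall of the healthy
class; probability ties at 0.5 resolve to bruised (the detection-positive
class). Fused tables namespace columns by instrument (`PB:850.8`,
`LCTF:1205.0`).
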