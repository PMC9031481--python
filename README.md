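# palsygest

Facial-palsy gesture recognition from landmark geometry.

From 51 facial-landmark coordinates (selected from a standard 68-point
prediction) the package computes 29 handcrafted left/right asymmetry
features and classifies the face into six posed gestures — rest, eyebrow
elevation, eye closure, wide-open smile, closed-mouth smile, pucker — with
a multilayer perceptron. The pipeline includes head-tilt correction via a
similarity transform, rotation augmentation, five-fold cross-validation,
and per-palsy-grade evaluation. A parametric synthetic-face generator
(six gestures, one-sided movement attenuation by palsy severity, coordinate
noise) makes the whole pipeline testable without clinical image data.

## Package layout

| module | contents |
|---|---|
| `palsygest.landmarks` | 68→51 selection, tilt correction, rotation, JSON I/O |
| `palsygest.features` | geometry primitives, the 30 face measures, the 29 features |
| `palsygest.classifier` | seeded online-backprop MLP (one hidden layer, sigmoid, momentum) |
| `palsygest.evaluation` | rotation augmentation, grouped stratified k-fold, metrics, per-grade CV |
| `palsygest.synthetic` | symmetric face template, gesture displacement fields, palsy model, dataset generator |
| `palsygest.data`, `palsygest.arff`, `palsygest.cli` | dataset containers, ARFF/CSV interop, command line |

Coordinate convention everywhere: origin top-left, y increasing downward
(image convention); "left" means image-left.

## Command line

```sh
palsygest simulate --subjects 50 --seed 1 --out landmarks.json
palsygest augment  --in landmarks.json --out augmented.json      # x7 samples
palsygest extract  --in augmented.json --out features.arff       # or .csv
palsygest train    --in features.arff -H 95 -N 5000 --out model.json
palsygest evaluate --in features.arff --folds 5 --per-grade --out report.json
palsygest predict  --model model.json --in features.csv --out predictions.csv
```

Every run logs its full effective configuration (seeds included). A YAML
file passed with `--config` can preset any subcommand's options; explicit
flags win.

Classifier defaults are the tuned operating point: learning rate 0.2045,
momentum 0.1909, 95 hidden units, 5000 epochs, seed 0. Training is
deterministic given data order, hyperparameters, and seed.

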