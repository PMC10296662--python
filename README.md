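# myogrip

Surface-EMG gesture classification and confidence-gated prosthesis control,
end to end: synthetic sEMG session generation, RMS-envelope smoothing and
peak normalization, time-domain feature extraction, a small five-layer MLP
classifier, cross-validated evaluation, and a streaming decision loop that
maps gated predictions to virtual gripper / turn-base motor commands.

The pipeline targets three forearm muscle tasks recorded on three EMG
channels at 1 kHz (class 1 = wrist flexion, 2 = fist, 3 = wrist extension),
with six near-constant inertial channels carried along in the file format.
Everything is reproducible from integer seeds, and the synthetic generator
means no recorded dataset is required to exercise any stage.

## Package layout

| module | role |
|---|---|
| `myogrip.synthgen` | protocol-driven synthetic sEMG sessions (cue schedule, band-limited bursts, tunable class-2 overlap) |
| `myogrip.dataio` | CSV recording I/O (`class<k>_<trial>.csv`, 3 EMG + 6 IMU columns) and window segmentation |
| `myogrip.preprocess` | Nyquist sizing, blockwise RMS envelope (50 ms), per-channel peak normalization |
| `myogrip.features` | subwindow-RMS (500 ms) and six-statistic (MAV/MAV1/MAV2/MedAV/VAR/SD) feature vectors |
| `myogrip.classify` | five-layer dense/dropout MLP, Adam training, random hyperparameter search, JSON model files |
| `myogrip.evaluate` | stratified k-fold CV, confusion/macro metrics, feature-method comparison, window-duration sweep |
| `myogrip.realtime` | streaming 2 s decision loop with a 0.70 confidence gate and a virtual two-axis prosthesis |
| `myogrip.scenarios` | seeded end-to-end recovery benchmarks used by the acceptance tests |

## CLI

One entry point, `myogrip`, with subcommands `generate`, `inspect`,
`featurize`, `train`, `search`, `evaluate`, `sweep`, `compare`, and
`stream`. Every artifact-producing run writes a `<command>.config.json`
echo beside its outputs. A typical session:

```sh
myogrip generate --out-dir data --seed 7 --n-trials-per-task 20
myogrip evaluate --data-dir data --out-dir report --seed 7          # 10-fold CV
myogrip featurize --data-dir data --out feats.csv
myogrip train --features feats.csv --model-out model.json --seed 7
myogrip stream --recording data/class1_t00.csv --model model.json --out log.csv
```

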