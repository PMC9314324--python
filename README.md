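# qrskit

QRS detection and beat classification (normal / PAC / PVC) for single-lead
Holter ECG in **one inference step**: a per-sample 4-channel segmentation
network (five 1-D residual blocks → gated recurrent layer → per-position
fully connected head) plus deterministic post-processing that turns the
probability mask into time-stamped, classified beat annotations.

Because the environment provides no deep-learning framework, the network
(1-D convolutions, batch norm, GRU, AdamW, gradient clipping, softmax
cross-entropy) is implemented in NumPy with hand-written backward passes,
verified by numerical gradient checks in the test suite. A bundled
synthetic Holter ECG generator (45 s @ 200 Hz records with N/PAC/PVC beats,
baseline wander, broadband noise and movement-artifact bursts) makes the
whole pipeline trainable and testable without any external data.

## Pipeline

1. **records_io** — `EcgRecord` / `BeatAnnotation` data model; minimal WFDB
   reader (header, signal formats 16/212/8, binary annotations with a frozen
   beat-symbol → {N, PAC, PVC} mapping), CSV and JSON annotation dialects.
   Lead "I" is preferred; otherwise the first lead is used.
2. **synthesis** — analytic Gaussian-mixture beat templates, sinus/irregular
   rhythm placement with premature-beat shortening and compensatory pauses,
   Poisson-placed artifact bursts; fully seeded and bit-reproducible.
3. **preprocessing** — resample to 100 Hz, standardize to zero mean / unit
   population variance, random 30 s crop + random inversion (p = 0.5)
   augmentation, 10-sample-widened 4-class target masks, weighted
   oversampling to balance class exposure.
4. **network** — `ModelConfig`/`TrainConfig`, builder, inference (softmax
   probabilities), AdamW training loop (batch 64, lr 0.001, grad-L2 clip
   1.0, no weight decay, 70 epochs by default) with best-validation-F1
   checkpointing, save/load round-trip.
5. **postprocessing** — per-sample argmax → maximal same-class runs →
   segment centers as candidate peaks → iterative suppression of the weaker
   of any two peaks closer than 0.15 s (strict); long records processed in
   50 %-overlapping 30 s windows.
6. **evaluation** — maximum-cardinality one-to-one beat matching within
   0.1 s (inclusive), detection F1, per-class / micro / macro
   classification F1, dataset pooling and mean ± population-std aggregation.

## CLI

```bash
qrskit simulate --n-records 200 --duration-s 30 --pac-fraction 0.1 \
    --pvc-fraction 0.1 --noise-level 0.2 --seed 42 --out-dir data/train
qrskit split --dataset-dir data/train --seed 0 --out data/split.json
qrskit train --dataset-dir data/train --split-file data/split.json \
    --epochs 10 --seed 1 --out-dir runs/demo
qrskit detect --model-path runs/demo/model.npz \
    --record data/train/<record_id>.json --out pred.csv
qrskit evaluate --predictions pred.csv --references data/train/<record_id>.csv \
    --fs 200 --out metrics.json
```

`qrskit detect` also accepts WFDB records (pass the record path without
extension suffix as `--record path/to/100.json`-style JSON, or a `.hea`
sibling path). Training accepts a YAML config
(`epochs`, `batch_size`, `learning_rate`, `channels_per_block`, …);
unknown keys are rejected.

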