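# ethopipe

Non-neural core of a nightly animal behavior-classification pipeline:
detection postfiltering, 7-second interval aggregation and multiframe
encoding, two-stream prediction fusion with rolling averages, a configurable
transition-rule postprocessor, and ethogram evaluation (accuracy metrics,
phase counts, durations). A synthetic-night simulator makes every stage
testable end to end without real video data.

## Behavior model

Each 7-s interval of a 14-hr night carries one of four states:
`standing`, `lhu` (lying, head up), `lhd` (lying, head down), `absent`.
A *phase* is a maximal run of one state; per-behavior phase counts and total
durations are the behavioral key figures.

The prediction pipeline per night:

1. **Detection postfilter** — keep at most one bounding box per frame, at
   confidence ≥ 0.97; no box means absence evidence.
2. **Interval aggregation** — average per-frame class probabilities over the
   detected frames of each 7-frame interval (stream 1); encode four of the
   seven cut-out frames as a 2×2 mosaic for the temporal stream (stream 2).
3. **Fusion & smoothing** — average the two streams, apply a centered
   rolling average over consecutive intervals, inject the absent class from
   the detected-frame fraction, and take the argmax label.
4. **Transition rules** — replace interior phases that are shorter than a
   rule's minimum and flanked by configured states with the previous phase's
   label, iterating to a fixpoint.
5. **Evaluation** — accuracy / recall / precision / f-score, the binary
   standing-vs-lying collapse, per-night key figures with across-night
   mean ± SEM, and detection IoU / AP@t.

## CLI

Every phase is independently invocable:

```sh
# synthetic nights: ground truth + two noisy prediction streams
ethopipe simulate --seed 1 --out sim/ --nights 2

# fuse, roll-average, and apply the transition rules
ethopipe smooth --stream1 sim/night000_stream1.csv \
                --stream2 sim/night000_stream2.csv \
                --out sim/night000_smoothed.csv

# compare against ground truth
ethopipe evaluate --truth sim/night000_truth.csv --pred sim/night000_smoothed.csv

# per-night phase counts / durations with mean ± SEM
ethopipe keyfigures sim/night000_smoothed.csv

# detection utilities
ethopipe filter-detections --in raw.json --out filtered.json --threshold 0.97
ethopipe ap --pred filtered.json --truth boxes.json -t 50 -t 75
```

Timelines are plain CSV
(`interval_index,start_s,label[,p_standing,p_lhu,p_lhd[,p_absent]]`),
detections are COCO-style JSON. Custom rule sets are YAML lists of
`{prev: [...], current: ..., next: [...], min_intervals: N}`; the shipped
default set lives at `src/ethopipe/data/default_rules.yaml`. Pipeline
parameters (interval length, fusion window, rule file, ...) go in a YAML
config passed via `--config`; unknown keys are rejected.

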