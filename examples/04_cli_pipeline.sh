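#!/usr/bin/env bash
# Full shell pipeline: generate -> stats -> train -> predict -> evaluate.
# Writes everything under ./scratch/cli-demo (created fresh each run).
set -euo pipefail

DIR=scratch/cli-demo
rm -rf "$DIR"
mkdir -p "$DIR"

triplecast generate --n-sentences 800 --seed 5 --out-dir "$DIR/data"
triplecast stats --input "$DIR/data/train.jsonl"

triplecast train \
    --train-file "$DIR/data/train.jsonl" \
    --val-file "$DIR/data/val.jsonl" \
    --epochs 30 --seed 5 \
    --checkpoint "$DIR/model.npz" \
    --log-file "$DIR/train.tsv"

triplecast predict \
    --checkpoint "$DIR/model.npz" \
    --input "$DIR/data/test.jsonl" \
    --out "$DIR/pred.jsonl"

triplecast evaluate \
    --pred "$DIR/pred.jsonl" \
    --gold "$DIR/data/test.jsonl" \
    --json-out "$DIR/metrics.json"
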