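#!/usr/bin/env bash
# End-to-end shell pipeline on a small synthetic cohort:
# simulate -> build tables -> calibrate SD thresholds -> evaluate.
# Writes per-gene three-row confusion tables plus adjusted PPV/NPV.
set -euo pipefail
out=$(mktemp -d)

historyweight simulate-cohort --seed 7 --n-probands 8000 --out-dir "$out/cohort"
historyweight build-tables --cohort "$out/cohort/probands.tsv" --out-dir "$out/tables"
historyweight calibrate --cohort "$out/cohort/probands.tsv" --gene MLH1 --seed 13 \
    --n-pathogenic 100 --n-benign 300 --out "$out/calibration.yaml"
historyweight evaluate --cohort "$out/cohort/probands.tsv" \
    --calibration "$out/calibration.yaml" --gene MLH1 --seed 13 \
    --n-pathogenic 200 --n-benign 400 --out-dir "$out/eval"
historyweight profile --details "$out/eval/details.tsv" --out "$out/profile.tsv"

echo; echo "=== confusion table ==="; cat "$out/eval/confusion.tsv"
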