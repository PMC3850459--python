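#!/usr/bin/env bash
# End-to-end pipeline through the command-line interface:
#   simulate -> build-matrix -> decompose -> cross-validate -> report
# Every step writes a manifest (config + seed + input checksums), so any
# artifact directory can be re-produced bit-identically.
set -euo pipefail

OUT="${1:-/tmp/phenofactor-demo}"
rm -rf "$OUT"

phenofactor simulate --n 400 --noise-rate 0.1 --seed 7 --out "$OUT/cohort"
phenofactor build-matrix --encounters "$OUT/cohort/encounters.csv" \
    --out "$OUT/matrix"
phenofactor decompose --matrix "$OUT/matrix/matrix.txt" --k 4 \
    --out "$OUT/factors"
phenofactor cross-validate --encounters "$OUT/cohort/encounters.csv" \
    --labels "$OUT/cohort/labels.csv" --k 4 --seed 7 --out "$OUT/cv"
phenofactor report --encounters "$OUT/cohort/encounters.csv" --k 4 \
    --out "$OUT/report"

echo
echo "cutoff table:"
column -s, -t "$OUT/cv/cutoff_table.csv"
echo
echo "artifacts in $OUT:"
find "$OUT" -type f | sort
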