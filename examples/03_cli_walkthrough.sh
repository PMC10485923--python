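#!/usr/bin/env bash
# The same pipeline as example 02, driven entirely through the hdx2ss CLI.
# Every subcommand wraps one library call; files are plain CSV/PDB/JSON.
set -euo pipefail

workdir=$(mktemp -d)
echo "working in $workdir"

# 1. generate a synthetic experiment: uptake.csv, kint.csv, model.pdb, truth.csv
hdx2ss simulate --seed 5 --n-residues 120 --outdir "$workdir"

# 2. correct raw RFUs for back-/forward-exchange
hdx2ss correct --in "$workdir/uptake.csv" --out "$workdir/corrected.csv"

# 3. fit residue-level rates with replicate confidence scores
hdx2ss optimize --rfu "$workdir/corrected.csv" --kint "$workdir/kint.csv" \
    --replicates 5 --seed 0 --out "$workdir/rates.csv"

# 4. label helix/strand from the reference structure's dihedrals
hdx2ss label --pdb "$workdir/model.pdb" --out "$workdir/labels.csv"

# 5. join rates and labels into a feature table (library one-liner)
python - "$workdir" <<'EOF'
import sys

import pandas as pd

workdir = sys.argv[1]
rates = pd.read_csv(f"{workdir}/rates.csv")
labels = pd.read_csv(f"{workdir}/labels.csv")
df = rates.merge(labels, on="residue")
out = df[["k_obs", "k_int", "r_matrix", "aa_code"]].assign(y=df["label"])
out.to_csv(f"{workdir}/features.csv", index=False)
print(f"features: {len(out)} residues")
EOF

# 6. cross-validate the classifier and write the report
hdx2ss evaluate --features "$workdir/features.csv" --folds 5 --seed 0 \
    --report "$workdir/report.json"

# 7. or train on everything and save the model for reuse
hdx2ss train --features "$workdir/features.csv" --seed 0 --out "$workdir/model.json"

echo "artifacts in $workdir:"
ls "$workdir"
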