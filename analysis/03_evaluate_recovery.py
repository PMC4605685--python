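#!/usr/bin/env python
"""Score the pipeline's output from 02_run_pipeline.py against the planted
truth from 01_simulate_dataset.py: per-species module recovery (adjusted
Rand index), differential-block recall per comparison, and per-type
candidate precision/recall.  Writes results/evaluation.tsv."""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from c4net.io import write_table

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
PIPE = ROOT / "results" / "pipeline"

rows = []

# --- module recovery ------------------------------------------------------
truth_modules = pd.read_csv(DATA / "truth_modules.tsv", sep="\t")
for sp, group in truth_modules.groupby("species"):
    found = pd.read_csv(PIPE / f"modules_{sp}.tsv", sep="\t",
                        index_col="gene_id")["module"]
    genes = [g for g in group["gene_id"] if g in found.index]
    truth = group.set_index("gene_id").loc[genes, "module"]
    ari = adjusted_rand_score(truth, found.loc[genes])
    rows.append({"metric": "module_recovery_ari", "subject": sp,
                 "value": ari, "n": len(genes)})

# --- differential-block recall --------------------------------------------
truth_diff = pd.read_csv(DATA / "truth_diff_blocks.tsv", sep="\t")
diff = pd.read_csv(PIPE / "diff_modules.tsv", sep="\t")
for sp, group in truth_diff.groupby("c4_species"):
    planted = set(group["group_id"])
    found = set(diff.loc[diff["comparison"] == f"{sp}R", "group_id"])
    rows.append({"metric": "diff_block_recall", "subject": f"{sp}-vs-R",
                 "value": len(planted & found) / len(planted),
                 "n": len(planted)})

# --- candidate typing ------------------------------------------------------
truth_cand = pd.read_csv(DATA / "truth_candidates.tsv", sep="\t")
cand = pd.read_csv(PIPE / "candidates.tsv", sep="\t")
for t in ("I", "II", "III"):
    actual = set(truth_cand.loc[truth_cand["type"] == t, "group_id"])
    predicted = set(cand.loc[cand["type"] == t, "group_id"])
    tp = len(actual & predicted)
    rows.append({"metric": f"type_{t}_precision", "subject": "candidates",
                 "value": tp / max(len(predicted), 1), "n": len(predicted)})
    rows.append({"metric": f"type_{t}_recall", "subject": "candidates",
                 "value": tp / len(actual), "n": len(actual)})

table = pd.DataFrame(rows, columns=["metric", "subject", "value", "n"])
write_table(table, ROOT / "results" / "evaluation.tsv")
print(table.to_string(index=False))
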