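#!/usr/bin/env python
"""Curate a small demonstration compound library: parse a SMILES/activity
table, convert potencies to pActivity, cluster chemotypes by UPGMA on
Tanimoto distances, and assign active/inactive roles under per-chemotype
cutoffs.

The table is a synthetic demonstration set written by this script (three
hand-picked scaffold families plus one stereoisomer pair with a 100-fold
potency gap and one malformed row to exercise the rejection report).

Writes, under results/curation/: demo_library.tsv (input), curated.json,
rejections.tsv, dendrogram.txt, chemotypes.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from retroscreen import library as lib

OUT = Path(__file__).resolve().parent.parent / "results" / "curation"
OUT.mkdir(parents=True, exist_ok=True)

# synthetic demonstration compounds: amide series, sulfonamide series,
# piperazine series; activities are invented for the demonstration
ROWS = [
    # id, smiles, alias, chemotype, value, unit
    ("amide_1", "O=C(Nc1ccc(Cl)cc1)c1ccccc1", "series-A 1", "", 5, "nM"),
    ("amide_2", "O=C(Nc1ccc(F)cc1)c1ccccc1", "", "", 12, "nM"),
    ("amide_3", "O=C(Nc1ccccc1)c1ccc(C)cc1", "", "", 480, "nM"),
    ("sulfa_1", "O=S(=O)(Nc1ccccc1)c1ccc(C)cc1", "", "", 8, "nM"),
    ("sulfa_2", "O=S(=O)(Nc1ccc(Cl)cc1)c1ccc(C)cc1", "", "", 150, "nM"),
    ("pipz_1", "CN1CCN(Cc2ccccc2)CC1", "", "", 40, "nM"),
    ("pipz_2", "CCN1CCN(Cc2ccc(F)cc2)CC1", "", "", 2000, "nM"),
    # stereoisomer pair: identical 2D graph, ~100x apart (an activity cliff)
    ("stereo_R", "C[C@H](O)c1ccc(NC(=O)c2ccccc2)cc1", "", "", 3, "nM"),
    ("stereo_S", "C[C@@H](O)c1ccc(NC(=O)c2ccccc2)cc1", "", "", 300, "nM"),
    ("broken_1", "not_a_molecule", "", "", 1, "nM"),
]
demo = OUT / "demo_library.tsv"
pd.DataFrame(
    ROWS, columns=["compound_id", "smiles", "alias", "chemotype", "value", "unit"]
).assign(receptor="hCCR2", site="orthosteric", measure="IC50").to_csv(
    demo, sep="\t", index=False
)

library = lib.parse_compound_table(demo)
dendro, labels = lib.cluster_chemotypes(library, cut_height=0.6)
library.thresholds = {label: 7.5 for label in set(labels.values())}
library = lib.assign_roles(library, "hCCR2", "orthosteric")

pd.DataFrame(
    [{"row": r.row, "compound_id": r.compound_id, "reason": r.reason}
     for r in library.rejections]
).to_csv(OUT / "rejections.tsv", sep="\t", index=False)
pd.DataFrame(
    [{"compound_id": cid, "chemotype": label} for cid, label in sorted(labels.items())]
).to_csv(OUT / "chemotypes.tsv", sep="\t", index=False)
(OUT / "dendrogram.txt").write_text(
    "\n".join(f"{a} + {b} @ {h:.4f}" for a, b, h in dendro.merges) + "\n"
)
(OUT / "curated.json").write_text(json.dumps({
    "compounds": [
        {"compound_id": c.compound_id, "chemotype": c.chemotype, "role": c.role,
         "pactivity": c.best_pactivity("hCCR2", "orthosteric")}
        for c in library.compounds
    ]}, indent=1))

n_clusters = len(set(labels.values()))
roles = [c.role for c in library.compounds]
print(f"curated {len(library.compounds)} compounds "
      f"({len(library.rejections)} rejected: see rejections.tsv)")
print(f"UPGMA at cut height 0.6 finds {n_clusters} chemotypes: "
      f"{sorted(set(labels.values()))}")
print(f"roles under pIC50>7.5: {roles.count('active')} active, "
      f"{roles.count('inactive')} inactive")
print("the stereoisomer pair lands in one chemotype "
      f"(similarity 1.0): {labels['stereo_R'] == labels['stereo_S']}")
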