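#!/usr/bin/env python
"""Generate the synthetic study inputs: screening library, pose-score
table, and idealized receptor structures.

Writes, under results/synthetic/:
  library.tsv        compound roster (id, chemotype, role, true pactivity)
  pose_scores.tsv    (compound × conformer × pose) scores for both scorers
  truth.json         generator ground truth (native poses, pactivities)
  toy_complex.pdb    7TM+H8 helix bundle with an axial ligand
  bundle_inactive.pdb / bundle_active.pdb   two-state helix bundle pair
  bw_map.tsv         Ballesteros–Weinstein annotation table for the bundles
"""

import json
from pathlib import Path

import pandas as pd

from retroscreen import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

config = syn.SyntheticConfig(seed=2024)
library, truth = syn.gen_library(config)
table = syn.gen_pose_scores(config, library, truth)

pd.DataFrame(
    [
        {
            "compound_id": c.compound_id,
            "chemotype": c.chemotype,
            "role": c.role,
            "pactivity": truth.pactivity.get(c.compound_id),
        }
        for c in library.compounds
    ]
).to_csv(OUT / "library.tsv", sep="\t", index=False)
table.to_csv(OUT / "pose_scores.tsv")
(OUT / "truth.json").write_text(
    json.dumps(
        {
            "chemotype": truth.chemotype,
            "role": truth.role,
            "pactivity": truth.pactivity,
            "native_pose": {f"{c}/{m}": p for (c, m), p in truth.native_pose.items()},
        },
        indent=1,
    )
)

toy = syn.make_toy_complex()
toy.to_pdb(OUT / "toy_complex.pdb")

# two-state bundle: the "active-like" state shifts TM7 toward TM1,
# collapsing the fenestration-like gap between them
axes = [(0, 0), (11, 0), (17, 11), (11, 22), (0, 24), (-7, 15), (-6, 4)]
inactive = syn.gen_helix_bundle(axes, residues_per_helix=30, name="bundle_inactive")
active = syn.gen_helix_bundle(
    axes, residues_per_helix=30, state_shifts={7: (3.0, -2.0, 0.0)}, name="bundle_active"
)
inactive.to_pdb(OUT / "bundle_inactive.pdb")
active.to_pdb(OUT / "bundle_active.pdb")
pd.DataFrame(
    [{"chain": c, "resnum": r, "generic_number": gn} for (c, r), gn in inactive.bw.items()]
).to_csv(OUT / "bw_map.tsv", sep="\t", index=False)

n_act = sum(1 for r in truth.role.values() if r == "active")
print(f"library: {len(library.compounds)} compounds "
      f"({n_act} actives across {config.n_chemotypes} chemotypes, "
      f"{sum(1 for r in truth.role.values() if r == 'decoy')} decoys)")
print(f"pose scores: {len(table.df)} rows, scorers {table.scorers}, "
      f"{config.poses_per_pair} poses per (compound, conformer)")
print(f"structures: toy 7TM+H8 complex and a two-state helix bundle -> {OUT}")
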