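# retroscreen

Retrospective virtual-screening evaluation for GPCR antagonist discovery:
compound-library curation and chemotype clustering, property-matched
decoy selection, two-stage (pose-selection | compound-ranking) scoring
schemes over receptor conformer ensembles, ROC/enrichment metrics with
activity-cliff detection, and receptor pocket geometry analysis with
declarative induced-fit refinement specifications.

## The problem

Retrospective virtual ligand screening (VLS) asks whether a receptor
model can *recognize* known active compounds hidden among a much larger
set of property-matched decoys. Screening proceeds in two decoupled
stages: for each compound one docked pose is selected by a scorer *X*,
then compounds are ranked against each other by a (possibly different)
scorer *Y* — the `X|Y` scheme. Success is quantified as ROC AUC on a
0–100% scale: 100% means every active outranks every decoy, 50% means no
recognition, below 50% is anti-predictive. Because binding pockets adapt
to their ligands (induced fit), a pocket conformer tends to recognize
the chemotype it was solved with and fail on others; pooling several
conformers into an ensemble — poses pooled per compound, one selector
argmin over the pool — can recover recognition across chemotypes.

`retroscreen` implements everything downstream of the docking engine.
Docking itself and the internals of the scoring functions are out of
scope: scores arrive as named columns of a pose-score table, and a
seeded synthetic generator produces libraries, score tables and
idealized receptor structures that reproduce the induced-fit phenomena,
so the entire pipeline is testable without proprietary data.

## Worked example

```python
from retroscreen import synthetic as syn, schemes as sch, metrics

cfg = syn.SyntheticConfig(seed=2024)          # 3 chemotypes × 30 actives,
lib, truth = syn.gen_library(cfg)             # 30 inactives, 600 decoys
table = syn.gen_pose_scores(cfg, lib, truth)  # 3 conformers × 10 poses

labels = {c.compound_id: c.role == "active" for c in lib.compounds}
for models in (["conf1"], ["conf1", "conf2", "conf3"]):
    auc, _ = sch.scheme_matrix(table, lib, ["physics"], ["physics", "neural"],
                               model_set=models, labels=labels)
    print(models, auc.round(2).to_dict())
```

```
['conf1'] {'physics': {'physics': 67.24}, 'neural': {'physics': 72.18}}
['conf1', 'conf2', 'conf3'] {'physics': {'physics': 99.98}, 'neural': {'physics': 100.0}}
```

Read (the dict is keyed ranker → selector): on a single conformer the
strict physics-like scheme (`physics|physics`) reaches only 67% AUC —
each conformer recognizes its cognate chemotype and largely misses the
other two — and swapping in the tolerant AI-like ranker at the same
selected poses (`physics|neural`) helps only modestly (72%), because on
incompatible conformers the strict selector often never picks the native
pose in the first place. Pooling all three conformers rescues both
schemes to ~100%: the ensemble contains a compatible pocket, and hence a
well-scoring native pose, for every chemotype.

The numbered scripts under `analysis/` run the full study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate.py           # library, pose scores, structures
python analysis/02_curate_library.py     # parsing, pActivity, UPGMA chemotypes
python analysis/03_select_decoys.py      # 50 actives + 59-fold decoy set
python analysis/04_screen_schemes.py     # chemotype×conformer AUC benchmark
python analysis/05_activity_cliffs.py    # stereoisomer cliff detection
python analysis/06_receptor_geometry.py  # distances, boxes, fragment specs
```

A `retroscreen` console script exposes the same operations
(`curate`, `decoys`, `screen`, `evaluate`, `simulate`, `geometry …`) for
shell use; see `retroscreen --help`.

## Layout

```
src/retroscreen/     library.py    curation, fingerprints, UPGMA
                     decoys.py     property-matched decoy selection
                     schemes.py    X|Y schemes, ensembles, rankings
                     metrics.py    ROC/AUC, enrichment, cliffs
                     geometry.py   BW annotation, superposition, fragments
                     synthetic.py  seeded generators
                     benchmark.py  end-to-end experiment drivers
analysis/            numbered narrative drivers (write to results/)
tests/               pytest suite incl. acceptance properties
docs/methods.md      model, defaults, and design rationale
```
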