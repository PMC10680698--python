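# Methods

## Scope and model

`retroscreen` implements the evaluation layer of retrospective virtual
ligand screening (VLS) against G-protein-coupled receptor pocket
conformers, together with the curation and geometry steps that surround
it. It deliberately does **not** dock: pose generation and the scoring
functions themselves (force-field, knowledge-based, or neural) are
treated as an external engine whose output arrives as a pose-score table
— one row per (compound, receptor model, pose) with one numeric column
per named scorer. Everything downstream of that table is computed here.

### Two-stage scoring schemes

Screening success is decided in two decoupled stages. For each compound,
one pose is chosen among the alternatives by a *selector* scorer (stage
ii, pose selection); compounds are then ordered by a *ranker* scorer
evaluated at their selected poses (stage iii, compound ranking). A scheme
is written `X|Y`. With *m* selectors and *n* rankers available, all
*m × n* combinations form a scheme matrix, each cell evaluated by ROC
AUC. Over a conformer ensemble the default semantics pool a compound's
poses across all models first and take a single selector-argmin over the
pool; the per-model-select-then-best alternative is available via
`pool_first=False`. Pool-first is used because a single cross-model
argmin is the natural reading of pooled rescoring and makes the ensemble
selector score provably no worse than any single model's (argmin over a
superset); the alternative can differ only when selector and ranker
disagree about the best model.

All scores are normalized lower-is-better at table ingestion (energy-like
convention); per-scorer orientation flags flip maximizing columns.
Tie-breaks are deterministic everywhere (pose_id, then model_id, then
compound_id) so rankings are bit-reproducible.

### Metrics

ROC AUC is reported on a 0–100% scale (50% = no recognition, below 50% =
anti-predictive) and computed by midranks in O(n log n): 100 × (concordant
pairs + ½·tied pairs) / (n_act · n_non), the Mann–Whitney half-credit
convention. The ROC curve advances tied scores jointly (diagonal
segments), which makes its trapezoidal area identical to the pairwise
statistic to 1e−9; the suite checks this against a brute-force all-pairs
oracle. Early enrichment EF(f) is the actives concentration in the best
⌈f·N⌉ compounds relative to random; f is configuration (default 0.01,
0.05, 0.1) since no single canonical fraction exists. Activity cliffs are
unordered pairs with 2D-fingerprint Tanimoto similarity ≥ 0.85 and
|Δ pActivity| ≥ 2.0 — the defaults are calibrated so a 100-fold potency
gap between stereoisomers (similarity exactly 1.0 on 2D fingerprints)
always registers. Per-atom score attributions are accepted when their sum
matches the declared total within 1e−6 (scorer-native units).

### Library curation

Potencies are converted to pActivity = −log10(concentration in molar);
units must be explicit (M/mM/uM/nM/pM), no guessing. A compound is
*active* iff its pActivity **strictly** exceeds its chemotype's cutoff —
boundary values are inactive, matching the convention that "actives of
pX > c" is a strict inequality. With several measurements at one
(receptor, site), the most potent wins, reflecting curation practice in
which a compound is active if any reliable measurement passes.
Fingerprints are hashed circular (Morgan) substructure fingerprints,
radius 2, 2048 bits, with stereochemistry removed: stereo-insensitivity
is a requirement, not a shortcut, because stereochemical activity cliffs
must register similarity 1.0. Chemotype clustering is UPGMA
(arithmetic-average linkage) on Tanimoto distances, implemented in-house
(O(n³), adequate for library-scale n) so that ties break on the
lexicographically smallest member id and cluster labels (the first
member id) are invariant to input permutation; scipy's average linkage
serves as an independent cross-check in the tests. The default cut
height of 0.6 Tanimoto distance is a conventional scaffold-family cut
and is configurable; the method is insensitive to it for well-separated
series.

### Decoy selection

Decoys follow the DUD-E convention: six matched properties (molecular
weight, Crippen logP, H-bond donors, acceptors, rotatable bonds, formal
charge) with windows ±25 Da, ±1.0 logP, ±1 HBD, ±2 HBA, ±2 rotatable
bonds, exact charge, and a Tanimoto-similarity cap of 0.35 against
*every* active. A candidate qualifies if it sits inside every window of
at least one active; qualifying candidates count toward a single pooled
quota (ratio × |actives|) rather than per-active quotas, matching how
pooled fold-ratios (54×, 59×) are reported. Selection among qualifiers
is a seeded uniform draw over id-sorted candidates — deterministic and
pool-order invariant. Shortfalls raise an error carrying per-active
match counts.

### Receptor geometry

Structures (PDB/mmCIF via gemmi; altloc A kept, insertion codes
preserved) are annotated with Ballesteros–Weinstein generic numbers from
a user-supplied table — no network dependency — with loop-style ("45.52")
and helix-8 ("8.49") labels treated as opaque. All distances are in Å
(the only chemically sensible unit at these scales). Superposition is a
Kabsch least-squares fit over BW-matched backbone atoms (N, CA, C;
≥3 required), with proper-rotation correction; scipy's independent
rotation alignment is the oracle in tests. Cα–Cα distance tables are
intra-structure and therefore superposition-invariant; unresolvable
cells are NaN-flagged, never dropped. The shipped default pair list
(3.29 against 6.48/7.40/7.43, plus 1.39 against 7.39/7.40 spanning the
TM1–TM7 fenestration) is a reconstruction of a representative set, not
an authoritative one. Ligand sampling boxes are axis-aligned bounding
boxes with a 4 Å margin per direction.

Mutation edits are bookkeeping only: shrinking edits truncate to the
target residue's atom set; growing edits add placeholder atoms with
occupancy 0 and NaN coordinates — no coordinates are ever invented,
rebuilding is the external engine's job.

### Induced-fit fragment specification

`build_fragment_spec` emits a declarative recipe, not a simulation. Seed
residues are those within 5.5 Å of the ligand (residue granularity);
contiguous segments grow by alternating N-/C-terminal extension
(N-terminal first; termini clipped with compensating extension at the
open end) until they reach 9 residues (orthosteric) or 18 (allosteric),
then overlapping segments merge. Whether the original expansion was
symmetric or directional is not documented; alternating growth was
chosen as the deterministic symmetric reading. Disulfide-bonded cysteine
pairs are never split: a retained cysteine pulls its partner's segment
in, even across the allosteric TM4/TM5 omission. Mobility classes:
orthosteric — TM1/TM2/TM7 fragments fully flexible, others side-chain
only; allosteric — TM6 and TM7–H8 fully flexible, TM1–ICL1–TM2 and TM3
stationary, TM4/TM5 (and ECL2) omitted. Tethers anchor fragment-end
backbone atoms plus, in orthosteric mode, the backbone carbons at BW
2.53/2.56/2.60/2.63; hydrogen-bond restraints (1.8–2.4 Å, weight 1.0)
reference the polar side-chain atoms at BW 1.39/3.32/7.36/7.39/7.40/7.44
(orthosteric) or the backbone amides at 8.49/8.50 (allosteric). Sampling
directives record 10,000 (orthosteric) or 100,000 (allosteric)
pre-minimization steps and 10⁶ global Monte Carlo steps. An independent
validator re-checks length minima and disulfide closure on every emitted
spec.

## Synthetic data generator

The generator defines the study conditions; it is the only data source
the tests and reproduction script use.

**Library.** Chemotypes are random 120-bit templates on 2048 bits; each
compound keeps template bits with probability 0.9 and adds ~12 random
bits, giving within-chemotype Tanimoto similarity ≈0.7 versus ≈0.03
between chemotypes and against decoys — the clustered-fingerprint
structure of real discovery-program series. Property vectors jitter
around per-chemotype bases drawn from antagonist-like ranges (MW 350–500
Da, logP 2–5, small donor/acceptor/rotor counts); decoy properties are
drawn inside the windows of randomly chosen actives so the selector's
happy path is exercised (violations exercise its rejection path). Active
pActivity is uniform on 7.5–10.5, inactives on 4.0–7.0, against a 7.5
cutoff. Defaults: 3 chemotypes × 30 actives, 30 inactives, 600 decoys
(a 20-fold pool relative to one chemotype's actives).

**Pose scores.** Ten poses per (compound, conformer). One native pose
per (active, conformer) scores

    −(α·p·(1 − λ_s·(1 − C[k, j])) + β) + ε,  ε ~ N(0, σ²)

with α = 2, β = 5, σ = 1; all other poses, and all poses of inactives
and decoys, draw from a background N(−8, 3) truncated above the
theoretical native optimum. `C[k, j] ∈ [0, 1]` is the chemotype ×
conformer compatibility (default identity-dominant: diagonal 1.0,
off-diagonal 0.2), the minimal encoding of induced fit. λ_s is each
scorer's compatibility sensitivity and is the *single* knob contrasting
a strict physics-like scorer (λ = 0.9) with a tolerant AI-like one
(λ = 0.2); no attempt is made to model real scoring-function forms. The
constants were chosen so single-conformer AUCs fall in a ~50–100%
dynamic range rather than saturating.

**Structures.** Idealized α-helix bundles: Cα traces at 2.3 Å radius,
1.5 Å rise and 100° twist per residue (consecutive Cα–Cα ≈ 3.83 Å), with
per-helix BW numbering and optional rigid per-helix shifts emulating a
second conformational state. The toy 7TM+H8 complex places a 4-atom
ligand on the bundle axis so that the 5.5 Å proximity selection yields
several 1–5-residue seed segments — the adversarial input for the
fragment-expansion minima.

**What passing does and does not show.** The generator reproduces the
*statistical* phenomena — chemotype-selective recognition, scorer
tolerance, ensemble rescue, null AUC = 50 — not molecular reality: no 3D
ligand geometry, no pose coordinates, no correlation between fingerprint
and property vectors, no distinct mean-force scorer behavior, and helix
bundles with approximate backbone placement. Results on it validate the
evaluation machinery, not any docking engine.

## Problem sizes

Default runs are sized for a single CPU: the selectivity benchmark uses
10 seeds × (720 compounds × 3 conformers × 10 poses × 2 scorers); the
null-AUC calibration uses 1,000 draws of 2,475 scores; the AUC oracle
sweep uses 500 instances of ≤200 compounds; the UPGMA oracle sweep uses
200 random 6-leaf matrices. These sizes are the package's chosen study
conditions and complete in a few minutes in total.

## Known limitations

* Pose-score tables are held in memory as pandas frames; libraries of
  ~10⁶ compounds × ensembles would need chunking.
* UPGMA is O(n³) and intended for library-scale (≤ a few thousand)
  clustering, not corporate-collection scale.
* Decoy selection matches properties against each active independently;
  it does not deduplicate near-identical decoys among themselves.
* The fragment builder assumes single-conformation chains with numeric
  residue ordering; insertion-code-ordered chains are preserved in
  parsing but not re-ordered for segment arithmetic.
* AUC comparisons ship without bootstrap confidence intervals; that is
  an extension point, not a requirement of the evaluation layer.
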