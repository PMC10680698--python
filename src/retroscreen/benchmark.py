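"""End-to-end benchmark experiments on the synthetic screening data.

Reusable drivers shared by the analysis scripts, the test suite, and the
reproduction script: null-AUC calibration, chemotype × conformer
selectivity screens, scorer-tolerance contrasts, ensemble rescue, decoy
set assembly, and the toy induced-fit fragment experiment.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import geometry as geo
from . import metrics
from . import schemes as sch
from . import synthetic as syn
from .decoys import MatchCriteria, select_decoys

__all__ = [
    "null_auc_mean",
    "screen_aucs",
    "selectivity_summary",
    "build_allosteric_master",
    "toy_fragment_min_lengths",
    "envelope_margin_offsets",
]


def null_auc_mean(
    n_actives: int = 45,
    n_nonactives: int = 2430,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Mean ROC AUC (0–100) of a label-free random scorer.

    Draws i.i.d. continuous scores for ``n_actives`` + ``n_nonactives``
    compounds ``n_permutations`` times; with no association between score
    and label the expectation is 50%.
    """
    rng = np.random.default_rng(seed)
    n = n_actives + n_nonactives
    scores = rng.normal(size=(n_permutations, n))
    ranks = rankdata(scores, axis=1)
    u_worse = ranks[:, :n_actives].sum(axis=1) - n_actives * (n_actives + 1) / 2.0
    aucs = 100.0 * (1.0 - u_worse / (n_actives * n_nonactives))
    return float(aucs.mean())


def screen_aucs(
    config: syn.SyntheticConfig,
    library,
    truth: syn.SyntheticTruth,
    table: sch.PoseScoreTable,
) -> pd.DataFrame:
    """AUC of every X|X scheme on every conformer and the full ensemble.

    For each scorer and each receptor model (every single conformer plus
    the pooled ensemble of all of them), ranks the library and computes
    chemotype-specific AUCs (actives of one chemotype vs all decoys) and
    the all-chemotype AUC (all actives vs all decoys). Tidy output with
    columns ``scorer, model, chemotype, auc``.
    """
    decoy_ids = [c.compound_id for c in library.compounds if c.role == "decoy"]
    actives_by_ct = {
        ct: [c.compound_id for c in library.compounds
             if c.role == "active" and c.chemotype == ct]
        for ct in config.chemotype_names
    }
    all_actives = [cid for ids in actives_by_ct.values() for cid in ids]
    model_sets = {m: [m] for m in config.conformer_names}
    model_sets["ensemble"] = list(config.conformer_names)

    rows = []
    for scorer, _lam in config.scorers:
        scheme = sch.ScoringScheme(scorer, scorer)
        for model, mset in model_sets.items():
            ranking = sch.rank_library(table, library.ids, scheme, mset)
            scores = ranking.scores()
            for ct, act_ids in list(actives_by_ct.items()) + [("all", all_actives)]:
                ids = act_ids + decoy_ids
                auc = metrics.roc_auc(
                    scores.loc[ids].values, [i in set(act_ids) for i in ids]
                )
                rows.append(
                    {"scorer": scorer, "model": model, "chemotype": ct, "auc": auc}
                )
    return pd.DataFrame(rows)


def selectivity_summary(
    seeds: Sequence[int],
    base_config: Optional[syn.SyntheticConfig] = None,
) -> dict:
    """Chemotype selectivity, scorer tolerance and ensemble rescue over seeds.

    For each seed the full pipeline runs under the study conditions
    (defaults: 3 chemotypes = 3 conformers, identity-dominant compatibility,
    strict λ=0.9 vs tolerant λ=0.2, 30 actives/chemotype, 600 decoys).
    Chemotype *k*'s cognate conformer is conformer *k*. Reports:

    * ``gap_median``: per chemotype, the median over seeds of
      (cognate AUC − best non-cognate AUC) for the strict scorer;
    * ``strict_drop_median`` / ``tolerant_drop_median``: median over seeds
      of the mean cognate-minus-non-cognate AUC drop per scorer;
    * ``ensemble_rescue``: per seed, whether the all-chemotype ensemble AUC
      is within 2 points of (or above) the best single-conformer
      all-chemotype AUC for the strict scorer.
    """
    base_config = base_config or syn.SyntheticConfig()
    strict = max(base_config.scorers, key=lambda s: s[1])[0]
    tolerant = min(base_config.scorers, key=lambda s: s[1])[0]
    chemotypes = base_config.chemotype_names
    conformers = base_config.conformer_names

    gaps = {ct: [] for ct in chemotypes}
    drops = {strict: [], tolerant: []}
    rescue = []
    tables = []
    for seed in seeds:
        cfg = replace(base_config, seed=int(seed))
        library, truth = syn.gen_library(cfg)
        table = syn.gen_pose_scores(cfg, library, truth)
        df = screen_aucs(cfg, library, truth, table)
        df["seed"] = seed
        tables.append(df)
        for scorer in (strict, tolerant):
            per_ct_drops = []
            for k, ct in enumerate(chemotypes):
                sub = df[(df.scorer == scorer) & (df.chemotype == ct)]
                cognate = float(sub[sub.model == conformers[k]].auc.iloc[0])
                noncog = sub[
                    sub.model.isin([c for i, c in enumerate(conformers) if i != k])
                ].auc
                if scorer == strict:
                    gaps[ct].append(cognate - float(noncog.max()))
                per_ct_drops.append(cognate - float(noncog.mean()))
            drops[scorer].append(float(np.mean(per_ct_drops)))
        alls = df[(df.scorer == strict) & (df.chemotype == "all")]
        best_single = float(alls[alls.model != "ensemble"].auc.max())
        ensemble = float(alls[alls.model == "ensemble"].auc.iloc[0])
        rescue.append(ensemble >= best_single - 2.0)

    return {
        "gap_median": {ct: float(np.median(v)) for ct, v in gaps.items()},
        "strict_drop_median": float(np.median(drops[strict])),
        "tolerant_drop_median": float(np.median(drops[tolerant])),
        "ensemble_rescue": rescue,
        "strict_scorer": strict,
        "tolerant_scorer": tolerant,
        "per_seed_tables": pd.concat(tables, ignore_index=True),
    }


def build_allosteric_master(seed: int = 0, n_actives: int = 50, ratio: int = 59):
    """Assemble a synthetic master screen: diverse actives + ratioed decoys.

    Emulates the allosteric master-library construction: ``n_actives``
    diverse actives (5 chemotypes) and a property-matched decoy set
    ``ratio`` times larger, drawn from a synthetic qualifying pool.
    Returns (actives, decoys).
    """
    per_ct = n_actives // 5
    cfg = syn.SyntheticConfig(
        n_chemotypes=5,
        actives_per_chemotype=per_ct,
        n_inactives=0,
        decoy_pool_size=int(ratio * n_actives * 1.15),  # modest qualifying surplus
        seed=seed,
    )
    library, _truth = syn.gen_library(cfg)
    actives = [c for c in library.compounds if c.role == "active"]
    pool = [c for c in library.compounds if c.role == "decoy"]
    decoys = select_decoys(actives, pool, MatchCriteria(ratio=ratio), seed=seed)
    return actives, decoys


def toy_fragment_min_lengths(**toy_kwargs) -> dict[str, int]:
    """Minimum fragment length emitted per mode on the toy receptor–ligand complex."""
    st = syn.make_toy_complex(**toy_kwargs)
    return {
        mode: geo.build_fragment_spec(st, "LIG", mode).min_fragment_length()
        for mode in ("orthosteric", "allosteric")
    }


def envelope_margin_offsets(margin: float = 4.0, **toy_kwargs) -> np.ndarray:
    """Per-axis offsets between the toy ligand envelope and its sampling box."""
    st = syn.make_toy_complex(**toy_kwargs)
    pts = st.coords(st.ligands["LIG"])
    box = geo.build_envelope_box(pts, margin=margin)
    lower = pts.min(axis=0) - np.asarray(box.min_corner)
    upper = np.asarray(box.max_corner) - pts.max(axis=0)
    return np.concatenate([lower, upper])
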