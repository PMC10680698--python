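"""Two-stage scoring schemes over pose-score tables.

Virtual screening is evaluated as two decoupled stages: (ii) *pose
selection* — for each compound, one pose is chosen among the generated
alternatives by a selector scorer — and (iii) *compound ranking* — the
chosen poses are compared across compounds by a (possibly different)
ranker scorer. A scheme is written ``selector|ranker``, e.g. ``FA|RTCNN``.

Over a conformational ensemble, a compound's poses are pooled across all
receptor models first and a single selector-argmin is taken over the pool
(the per-model-first alternative is available via ``pool_first=False``).

All scores are oriented lower-is-better at ingestion; per-scorer
orientation flags in the table header flip higher-is-better columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ScoreTableError

__all__ = ["PoseScoreTable", "ScoringScheme", "CompoundRanking", "select_pose",
           "score_compound", "rank_library", "scheme_matrix"]

_KEY = ["compound_id", "model_id", "pose_id"]


class PoseScoreTable:
    """Per-(compound, receptor model, pose) scores under named scorers.

    Wraps a DataFrame with key columns ``compound_id, model_id, pose_id``
    and one numeric column per scorer. ``orientation`` maps scorer name to
    ``"lower"`` (default; energy-like, already lower-is-better) or
    ``"higher"`` (negated at ingestion).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        scorers: Optional[Sequence[str]] = None,
        orientation: Optional[dict[str, str]] = None,
    ):
        df = df.copy()
        for k in _KEY:
            if k not in df.columns:
                raise ScoreTableError(f"missing key column {k!r}")
        if scorers is None:
            scorers = [c for c in df.columns if c not in _KEY]
        if not scorers:
            raise ScoreTableError("table declares no scorer columns")
        self.scorers = list(scorers)
        orientation = orientation or {}
        for s in self.scorers:
            if s not in df.columns:
                raise ScoreTableError(f"declared scorer {s!r} absent from table")
            if df[s].isna().any():
                bad = df.loc[df[s].isna(), _KEY].iloc[0].tolist()
                raise ScoreTableError(f"missing {s} value for record {bad}")
            if orientation.get(s, "lower") == "higher":
                df[s] = -df[s]
        if (df["pose_id"] < 1).any():
            raise ScoreTableError("pose_id must be >= 1")
        if df.duplicated(_KEY).any():
            dup = df.loc[df.duplicated(_KEY), _KEY].iloc[0].tolist()
            raise ScoreTableError(f"duplicate (compound, model, pose) record: {dup}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def read_csv(cls, path, sep=None, **kw) -> "PoseScoreTable":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep), **kw)

    def to_csv(self, path, sep="\t"):
        self.df.to_csv(path, sep=sep, index=False)

    @property
    def model_ids(self) -> list[str]:
        return sorted(self.df["model_id"].unique())

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self.df["compound_id"].unique())

    def _check_scorer(self, name: str):
        if name not in self.scorers:
            raise ScoreTableError(
                f"unknown scorer {name!r}; table declares {self.scorers}"
            )


@dataclass(frozen=True)
class ScoringScheme:
    """A (pose-selector, compound-ranker) scorer pair, noted ``X|Y``."""

    selector: str
    ranker: str

    @classmethod
    def parse(cls, notation: str) -> "ScoringScheme":
        try:
            sel, rank = notation.split("|")
        except ValueError:
            raise ScoreTableError(f"scheme notation must be 'X|Y', got {notation!r}")
        return cls(sel, rank)

    @property
    def notation(self) -> str:
        return f"{self.selector}|{self.ranker}"

    def __str__(self):
        return self.notation


@dataclass
class CompoundRanking:
    """Compounds ordered by ranking score ascending (better first)."""

    entries: pd.DataFrame  # columns: compound_id, model_id, pose_id, score
    scheme: ScoringScheme
    model_set: tuple[str, ...]
    excluded: list[str] = field(default_factory=list)

    @property
    def ordered_ids(self) -> list[str]:
        return self.entries["compound_id"].tolist()

    def scores(self) -> pd.Series:
        return self.entries.set_index("compound_id")["score"]


def _pool(table: PoseScoreTable, model_set: Iterable[str]) -> pd.DataFrame:
    models = list(model_set)
    missing = set(models) - set(table.df["model_id"].unique())
    if missing:
        raise ScoreTableError(f"model(s) absent from table: {sorted(missing)}")
    return table.df[table.df["model_id"].isin(models)]


def _argmin_rows(df: pd.DataFrame, selector: str) -> pd.DataFrame:
    """One row per compound: selector-minimal pose, ties by pose_id then model_id."""
    ordered = df.sort_values([selector, "pose_id", "model_id"], kind="mergesort")
    return ordered.drop_duplicates("compound_id", keep="first")


def select_pose(
    table: PoseScoreTable, compound_id: str, model_id: str, selector: str
) -> tuple[int, dict[str, float]]:
    """Pose minimizing the selector score for (compound, model); ties → lowest pose_id."""
    table._check_scorer(selector)
    sub = table.df[
        (table.df["compound_id"] == compound_id) & (table.df["model_id"] == model_id)
    ]
    if sub.empty:
        raise ScoreTableError(f"no poses for compound {compound_id!r} in model {model_id!r}")
    row = _argmin_rows(sub, selector).iloc[0]
    return int(row["pose_id"]), {s: float(row[s]) for s in table.scorers}


def score_compound(
    table: PoseScoreTable,
    compound_id: str,
    scheme: ScoringScheme,
    model_set: Optional[Iterable[str]] = None,
    pool_first: bool = True,
) -> float:
    """Ranking score of one compound under ``scheme`` over ``model_set``.

    Pool-first (default): the compound's poses across all models are pooled,
    the selector-argmin pose is chosen over the pool, and that pose's ranker
    score is returned. With ``pool_first=False``, a pose is selected per
    model and the ranker-minimal of the per-model selections is returned.
    For a single model the two coincide with plain ``X|Y`` scoring.
    """
    table._check_scorer(scheme.selector)
    table._check_scorer(scheme.ranker)
    model_set = list(model_set) if model_set is not None else table.model_ids
    sub = _pool(table, model_set)
    sub = sub[sub["compound_id"] == compound_id]
    if sub.empty:
        raise ScoreTableError(
            f"compound {compound_id!r} absent from all models in {model_set}"
        )
    if pool_first:
        row = _argmin_rows(sub, scheme.selector).iloc[0]
        return float(row[scheme.ranker])
    per_model = sub.sort_values([scheme.selector, "pose_id"], kind="mergesort").groupby(
        "model_id", sort=True
    ).first()
    return float(per_model[scheme.ranker].min())


def rank_library(
    table: PoseScoreTable,
    library,
    scheme: ScoringScheme,
    model_set: Optional[Iterable[str]] = None,
    pool_first: bool = True,
) -> CompoundRanking:
    """Complete ordered ranking of a library under ``scheme``.

    ``library`` is a ScreeningLibrary or an iterable of compound ids.
    Compounds missing from the table are listed in ``excluded`` rather than
    failing, but an empty intersection is an error. Ties in ranking score
    are ordered by compound_id, so rankings are bit-reproducible.
    """
    table._check_scorer(scheme.selector)
    table._check_scorer(scheme.ranker)
    ids = list(getattr(library, "ids", library))
    model_set = tuple(model_set) if model_set is not None else tuple(table.model_ids)
    sub = _pool(table, model_set)
    sub = sub[sub["compound_id"].isin(ids)]
    present = set(sub["compound_id"].unique())
    excluded = [i for i in ids if i not in present]
    if not present:
        raise ScoreTableError("no library compound appears in the pose-score table")
    if pool_first:
        chosen = _argmin_rows(sub, scheme.selector)
    else:
        per_model = sub.sort_values(
            [scheme.selector, "pose_id"], kind="mergesort"
        ).drop_duplicates(["compound_id", "model_id"], keep="first")
        chosen = per_model.sort_values(
            [scheme.ranker, "model_id"], kind="mergesort"
        ).drop_duplicates("compound_id", keep="first")
    entries = chosen[["compound_id", "model_id", "pose_id"]].copy()
    entries["score"] = chosen[scheme.ranker].values
    entries = entries.sort_values(
        ["score", "compound_id"], kind="mergesort"
    ).reset_index(drop=True)
    return CompoundRanking(
        entries=entries, scheme=scheme, model_set=model_set, excluded=excluded
    )


def scheme_matrix(
    table: PoseScoreTable,
    library,
    selectors: Sequence[str],
    rankers: Sequence[str],
    model_set: Optional[Iterable[str]] = None,
    labels: Optional[dict[str, bool]] = None,
    pool_first: bool = True,
):
    """AUC of every selector × ranker scheme; returns (DataFrame, evaluations).

    ``labels`` maps compound_id → is-active; when omitted, roles on the
    library are used (active vs everything else). Each cell is the ROC AUC
    (0–100) of the corresponding ``selector|ranker`` ranking, computed by
    the metrics module; ``evaluations`` maps scheme notation →
    :class:`~retroscreen.metrics.ScreenEvaluation`.
    """
    from . import metrics

    for s in list(selectors) + list(rankers):
        table._check_scorer(s)
    if labels is None:
        labels = {c.compound_id: c.role == "active" for c in library.compounds}
    auc = pd.DataFrame(index=list(selectors), columns=list(rankers), dtype=float)
    evaluations = {}
    for sel in selectors:
        for rnk in rankers:
            scheme = ScoringScheme(sel, rnk)
            ranking = rank_library(table, library, scheme, model_set, pool_first)
            scored = ranking.scores()
            lab = [labels[c] for c in scored.index]
            ev = metrics.evaluate_screen(scored.values, lab)
            auc.loc[sel, rnk] = ev.auc
            evaluations[scheme.notation] = ev
    return auc, evaluations
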