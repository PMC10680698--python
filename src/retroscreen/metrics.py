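"""Screen evaluation metrics.

ROC curves and AUC on a 0–100% scale (50% = no recognition, <50% =
anti-predictive), early enrichment factors, activity-cliff detection, and
per-atom score-attribution consistency checks.

Scores are oriented lower-is-better throughout. Tied scores receive
half credit (the Mann–Whitney convention), which makes the AUC identical
to the trapezoidal area under the tie-grouped ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import MetricError
from .library import ScreeningLibrary, tanimoto_distance

__all__ = [
    "ScreenEvaluation",
    "ActivityCliffPair",
    "AtomContributionSet",
    "roc_auc",
    "roc_curve",
    "enrichment_factor",
    "evaluate_screen",
    "find_activity_cliffs",
    "verify_atom_attribution",
]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricError("scores and labels must be equal-length 1-D arrays")
    n_act = int(labels.sum())
    n_non = int((~labels).sum())
    if n_act == 0 or n_non == 0:
        raise MetricError(
            f"need at least one active and one non-active (got {n_act}/{n_non})"
        )
    return scores, labels, n_act, n_non


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """ROC AUC in percent: 100 × P(active scores strictly better) + half-credit ties.

    Equals 100 × (concordant + 0.5 × tied) / (n_active × n_nonactive),
    computed via midranks in O(n log n); exactly the trapezoidal area
    under the tie-grouped ROC curve.
    """
    scores, labels, n_act, n_non = _validate(scores, labels)
    ranks = rankdata(scores)  # ascending: best (lowest) score → rank 1
    # pairs where the active ranks worse than the non-active, ties half
    u_worse = ranks[labels].sum() - n_act * (n_act + 1) / 2.0
    return 100.0 * (1.0 - u_worse / (n_act * n_non))


def roc_curve(
    scores: Sequence[float], labels: Sequence[bool]
) -> list[tuple[float, float]]:
    """Stepwise (FPR, TPR) curve over distinct score thresholds.

    Starts at (0,0), ends at (1,1); tied scores advance both coordinates
    jointly (a diagonal segment), so the trapezoidal area agrees with
    :func:`roc_auc` to 1e−9.
    """
    scores, labels, n_act, n_non = _validate(scores, labels)
    order = np.argsort(scores, kind="mergesort")
    points = [(0.0, 0.0)]
    fp = tp = 0
    i = 0
    s, l = scores[order], labels[order]
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int(l[i:j].sum())
        fp += (j - i) - int(l[i:j].sum())
        points.append((fp / n_non, tp / n_act))
        i = j
    return points


def trapezoid_area(points: Sequence[tuple[float, float]]) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def enrichment_factor(
    scores: Sequence[float], labels: Sequence[bool], top_fraction: float
) -> float:
    """Actives concentration in the best ⌈f·N⌉ compounds relative to random.

    EF(f) = (hits / ⌈f·N⌉) / (n_actives / N). Ties at the cutoff are
    resolved by stable sort order of the input (the ranking's deterministic
    order when scores come from :func:`~retroscreen.schemes.rank_library`).
    """
    scores, labels, n_act, _ = _validate(scores, labels)
    if not (0 < top_fraction <= 1):
        raise MetricError("top_fraction must be in (0, 1]")
    n = len(scores)
    n_top = math.ceil(top_fraction * n)
    order = np.argsort(scores, kind="mergesort")
    hits = int(labels[order[:n_top]].sum())
    return (hits / n_top) / (n_act / n)


@dataclass
class ScreenEvaluation:
    """Ranked-screen summary: ROC points, AUC (0–100), early enrichment."""

    roc_points: list[tuple[float, float]]
    auc: float
    enrichment: dict[float, float]
    n_actives: int
    n_nonactives: int

    def __post_init__(self):
        if not (0.0 <= self.auc <= 100.0):
            raise MetricError(f"AUC {self.auc} outside [0, 100]")


def evaluate_screen(
    scores: Sequence[float],
    labels: Sequence[bool],
    top_fractions: Sequence[float] = (0.01, 0.05, 0.1),
) -> ScreenEvaluation:
    scores, labels, n_act, n_non = _validate(scores, labels)
    return ScreenEvaluation(
        roc_points=roc_curve(scores, labels),
        auc=round(roc_auc(scores, labels), 2),
        enrichment={f: enrichment_factor(scores, labels, f) for f in top_fractions},
        n_actives=n_act,
        n_nonactives=n_non,
    )


@dataclass(frozen=True)
class ActivityCliffPair:
    """Two near-identical compounds with a large potency difference."""

    compound_a: str
    compound_b: str
    similarity: float  # Tanimoto similarity of 2D fingerprints
    delta_pactivity: float  # |Δ(−log10 potency)|; 2.0 ≈ a 100-fold cliff


def find_activity_cliffs(
    library: ScreeningLibrary,
    receptor: str,
    site: str,
    min_similarity: float = 0.85,
    min_delta: float = 2.0,
) -> list[ActivityCliffPair]:
    """All unordered pairs with similarity ≥ min_similarity and |Δp| ≥ min_delta.

    Compound potency is the most potent measurement at (receptor, site).
    Stereoisomer pairs — identical 2D graphs — have similarity 1.0, so a
    stereochemical ~100-fold cliff (Δp = 2) is always reported under the
    defaults. Sorted by Δ descending, then by compound ids.
    """
    comps = [
        (c.compound_id, c.fingerprint, c.best_pactivity(receptor, site))
        for c in library.compounds
        if c.fingerprint is not None and c.best_pactivity(receptor, site) is not None
    ]
    cliffs = []
    for (ida, fpa, pa), (idb, fpb, pb) in combinations(comps, 2):
        delta = abs(pa - pb)
        if delta < min_delta:
            continue
        sim = 1.0 - tanimoto_distance(fpa, fpb)
        if sim >= min_similarity:
            a, b = sorted((ida, idb))
            cliffs.append(ActivityCliffPair(a, b, sim, delta))
    cliffs.sort(key=lambda p: (-p.delta_pactivity, p.compound_a, p.compound_b))
    return cliffs


@dataclass
class AtomContributionSet:
    """Per-atom score contributions and the declared total score."""

    contributions: list[tuple[int, float]]  # (atom index, contribution)
    total: float


def verify_atom_attribution(
    contribs: AtomContributionSet, tolerance: float = 1e-6
) -> tuple[bool, float]:
    """Check Σ per-atom contributions against the declared total score.

    Returns (pass, discrepancy); passes iff |Σ − total| ≤ tolerance.
    """
    s = sum(v for _, v in contribs.contributions)
    discrepancy = abs(s - contribs.total)
    return discrepancy <= tolerance, discrepancy
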