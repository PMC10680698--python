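"""Property-matched decoy selection.

Selects, from a candidate pool, decoys that are physicochemically matched
to a set of actives yet topologically dissimilar from all of them, at a
fixed pooled decoys:actives ratio — the DUD-E-style construction used to
benchmark screening discrimination.

The six matched properties follow the DUD-E convention: molecular weight,
an additive atomic-contribution logP estimate (Crippen), hydrogen-bond
donor and acceptor counts, rotatable-bond count, and net formal charge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .errors import DecoySelectionError, StructureParseError
from .library import CompoundRecord, tanimoto_distance

__all__ = [
    "PropertyVector",
    "MatchCriteria",
    "compute_property_vector",
    "select_decoys",
]


@dataclass(frozen=True)
class PropertyVector:
    mol_weight: float  # Da
    logp: float  # unitless additive estimate
    hbd: int
    hba: int
    rotatable_bonds: int
    formal_charge: int

    def __post_init__(self):
        if self.mol_weight <= 0:
            raise DecoySelectionError("mol_weight must be positive")
        for name in ("hbd", "hba", "rotatable_bonds"):
            if getattr(self, name) < 0:
                raise DecoySelectionError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MatchCriteria:
    """Per-property windows, a topological-similarity cap, and the pooled ratio.

    Defaults: ±25 Da weight, ±1.0 logP, ±1 donor, ±2 acceptors, ±2
    rotatable bonds, exact formal charge, Tanimoto similarity to every
    active < 0.35, and one decoy set sized ratio × |actives| overall.
    """

    mw_window: float = 25.0
    logp_window: float = 1.0
    hbd_window: int = 1
    hba_window: int = 2
    rotb_window: int = 2
    charge_exact: bool = True
    max_similarity_to_actives: float = 0.35
    ratio: int = 50

    def __post_init__(self):
        if self.ratio < 1:
            raise DecoySelectionError("ratio must be >= 1")
        if not (0 < self.max_similarity_to_actives < 1):
            raise DecoySelectionError("similarity cap must be in (0, 1)")

    def matches(self, active: PropertyVector, candidate: PropertyVector) -> bool:
        if abs(candidate.mol_weight - active.mol_weight) > self.mw_window:
            return False
        if abs(candidate.logp - active.logp) > self.logp_window:
            return False
        if abs(candidate.hbd - active.hbd) > self.hbd_window:
            return False
        if abs(candidate.hba - active.hba) > self.hba_window:
            return False
        if abs(candidate.rotatable_bonds - active.rotatable_bonds) > self.rotb_window:
            return False
        if self.charge_exact and candidate.formal_charge != active.formal_charge:
            return False
        return True


def compute_property_vector(structure: str) -> PropertyVector:
    """Six-property descriptor vector of a SMILES structure (deterministic)."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureParseError(f"unparsable SMILES: {structure!r}")
    return PropertyVector(
        mol_weight=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rotatable_bonds=Descriptors.NumRotatableBonds(mol),
        formal_charge=Chem.GetFormalCharge(mol),
    )


def _ensure_annotations(records: Sequence[CompoundRecord]):
    for r in records:
        if r.property_vector is None:
            if r.structure is None:
                raise DecoySelectionError(
                    f"{r.compound_id}: no property vector and no structure"
                )
            r.property_vector = compute_property_vector(r.structure)
        if r.fingerprint is None:
            if r.structure is None:
                raise DecoySelectionError(
                    f"{r.compound_id}: no fingerprint and no structure"
                )
            from .library import compute_fingerprint

            r.fingerprint = compute_fingerprint(r.structure)


def select_decoys(
    actives: Sequence[CompoundRecord],
    pool: Sequence[CompoundRecord],
    criteria: Optional[MatchCriteria] = None,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Select ``ratio × |actives|`` property-matched, dissimilar decoys.

    A pool candidate qualifies when it lies inside every property window
    of at least one active *and* its Tanimoto similarity to **all** actives
    is below the cap. Qualification counts toward a single pooled quota
    (ratio × number of actives), not per-active quotas. Selection among
    qualifying candidates is a seeded uniform draw over candidates sorted
    by id, so it is deterministic given the seed and invariant to pool
    order. Insufficient qualifiers raise an error reporting the
    per-active match shortfall.
    """
    criteria = criteria or MatchCriteria()
    if not actives:
        raise DecoySelectionError("no actives given")
    active_ids = {a.compound_id for a in actives}
    overlap = active_ids & {p.compound_id for p in pool}
    if overlap:
        raise DecoySelectionError(f"pool overlaps actives: {sorted(overlap)[:5]}")
    _ensure_annotations(actives)
    _ensure_annotations(pool)

    per_active_matches = {a.compound_id: 0 for a in actives}
    qualifying: list[CompoundRecord] = []
    for cand in pool:
        prop_ok = False
        for a in actives:
            if criteria.matches(a.property_vector, cand.property_vector):
                per_active_matches[a.compound_id] += 1
                prop_ok = True
        if not prop_ok:
            continue
        sim_ok = all(
            1.0 - tanimoto_distance(cand.fingerprint, a.fingerprint)
            < criteria.max_similarity_to_actives
            for a in actives
        )
        if sim_ok:
            qualifying.append(cand)

    needed = criteria.ratio * len(actives)
    if len(qualifying) < needed:
        shortfall = "; ".join(
            f"{cid}: {n} property matches" for cid, n in sorted(per_active_matches.items())
        )
        raise DecoySelectionError(
            f"only {len(qualifying)} qualifying candidates for {needed} requested "
            f"decoys ({criteria.ratio} x {len(actives)} actives). "
            f"Per-active property matches: {shortfall}"
        )

    qualifying.sort(key=lambda c: c.compound_id)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(qualifying), size=needed, replace=False)
    selected = [qualifying[i] for i in sorted(chosen)]
    return [replace(c, role="decoy", activities=[]) for c in selected]
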