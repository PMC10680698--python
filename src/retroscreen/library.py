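"""Compound library curation.

Parses compound/activity tables, converts potencies to the pActivity
(−log10 molar) scale, assigns active/inactive screening roles under
per-chemotype potency cutoffs, fingerprints compounds, and clusters them
into chemotypes by UPGMA on Tanimoto distances.

Fingerprints are hashed circular (Morgan) substructure fingerprints,
radius 2, 2048 bits, computed on the 2D connectivity graph only:
stereoisomers receive identical fingerprints, so stereochemical activity
cliffs register with similarity 1.0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .errors import CurationError, StructureParseError

__all__ = [
    "ActivityRecord",
    "CompoundRecord",
    "ScreeningLibrary",
    "Dendrogram",
    "RejectedRow",
    "compute_pactivity",
    "compute_fingerprint",
    "tanimoto_distance",
    "parse_compound_table",
    "assign_roles",
    "cluster_chemotypes",
    "upgma",
]

#: molar conversion factors for accepted concentration units
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}

_FP_RADIUS = 2
_FP_NBITS = 2048

ROLES = ("active", "inactive", "decoy", "unassigned")


def compute_pactivity(value: float, unit: str = "M") -> float:
    """−log10 of a potency concentration expressed in molar units.

    ``compute_pactivity(1, "nM") == 9.0``; a 100-fold potency loss is a
    drop of exactly 2 pActivity units.
    """
    if unit not in _UNIT_TO_MOLAR:
        raise CurationError(
            f"unknown concentration unit {unit!r}; accepted: {sorted(_UNIT_TO_MOLAR)}"
        )
    if not (value > 0):
        raise CurationError(f"concentration must be positive, got {value!r}")
    return -math.log10(value * _UNIT_TO_MOLAR[unit])


@dataclass(frozen=True)
class ActivityRecord:
    """One measured potency of a compound at a receptor site."""

    receptor: str  # e.g. hCCR2, hCCR5, mCCR2, hCCR1, other
    site: str  # orthosteric | allosteric
    measure: str = "IC50"  # IC50 | Ki | other
    value: Optional[float] = None  # concentration in molar units
    pactivity: Optional[float] = None  # −log10(value in M)

    def __post_init__(self):
        if self.value is not None:
            p = compute_pactivity(self.value, "M")
            if self.pactivity is None:
                object.__setattr__(self, "pactivity", p)
            elif abs(self.pactivity - p) > 1e-9:
                raise CurationError(
                    f"pactivity {self.pactivity} inconsistent with value {self.value} M"
                )


@dataclass
class CompoundRecord:
    """A small molecule with identifiers, structure, activities and role."""

    compound_id: str
    structure: Optional[str] = None  # SMILES
    aliases: list[str] = field(default_factory=list)
    activities: list[ActivityRecord] = field(default_factory=list)
    chemotype: Optional[str] = None
    role: str = "unassigned"
    fingerprint: Optional[frozenset[int]] = None
    property_vector: Optional["PropertyVector"] = None  # noqa: F821 (decoys module)

    def best_pactivity(self, receptor: str, site: str) -> Optional[float]:
        """Most potent (max) pactivity among records for (receptor, site)."""
        vals = [
            a.pactivity
            for a in self.activities
            if a.receptor == receptor and a.site == site and a.pactivity is not None
        ]
        return max(vals) if vals else None


@dataclass
class RejectedRow:
    row: int
    compound_id: Optional[str]
    reason: str


@dataclass
class ScreeningLibrary:
    """A curated screening library with per-chemotype potency cutoffs."""

    compounds: list[CompoundRecord] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)
    provenance: str = ""
    rejections: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.compound_id for c in self.compounds]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CurationError(f"duplicate compound_id(s) in library: {sorted(dupes)}")

    def get(self, compound_id: str) -> CompoundRecord:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)

    @property
    def ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    def subset(self, roles: Iterable[str]) -> list[CompoundRecord]:
        roles = set(roles)
        return [c for c in self.compounds if c.role in roles]


def compute_fingerprint(structure: str) -> frozenset[int]:
    """Hashed circular fingerprint (radius 2, 2048 bits) as a set of on-bits.

    Deterministic in the molecular graph: any two SMILES of the same
    molecule, including stereoisomers, give identical bit sets.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureParseError(f"unparsable SMILES: {structure!r}")
    Chem.RemoveStereochemistry(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=_FP_RADIUS, fpSize=_FP_NBITS)
    fp = gen.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


def tanimoto_distance(a: frozenset[int], b: frozenset[int]) -> float:
    """1 − |a∩b| / |a∪b|; symmetric, zero iff the bit sets are identical."""
    if a is None or b is None:
        raise CurationError("fingerprints must be non-null")
    union = len(a | b)
    if union == 0:
        warnings.warn("Tanimoto distance of two empty fingerprints defined as 0")
        return 0.0
    return 1.0 - len(a & b) / union


# ---------------------------------------------------------------------------
# table parsing

_TSV_REQUIRED = ("compound_id", "smiles")
_TSV_OPTIONAL = ("alias", "chemotype", "receptor", "site", "measure", "value", "unit")


def _activity_from_row(row: pd.Series) -> Optional[ActivityRecord]:
    value, unit = row.get("value"), row.get("unit")
    if pd.isna(value) or value in (None, ""):
        return None
    if pd.isna(unit) or unit in (None, ""):
        raise CurationError("activity value given without an explicit unit")
    value = float(value)
    pact = compute_pactivity(value, str(unit))
    receptor = str(row.get("receptor") or "other")
    site = str(row.get("site") or "orthosteric")
    measure = str(row.get("measure") or "IC50")
    return ActivityRecord(
        receptor=receptor,
        site=site,
        measure=measure,
        value=value * _UNIT_TO_MOLAR[str(unit)],
        pactivity=pact,
    )


def parse_compound_table(
    path, format: str = "smiles_tsv", thresholds: Optional[dict[str, float]] = None
) -> ScreeningLibrary:
    """Parse a compound/activity table into a :class:`ScreeningLibrary`.

    ``smiles_tsv``: tab-separated with columns ``compound_id, smiles`` and
    optionally ``alias`` (``|``-separated), ``chemotype, receptor, site,
    measure, value, unit``. ``sdf``: an SD file whose entries carry the
    same fields as properties.

    Malformed rows (unparsable structure, bad activity value) are collected
    into ``library.rejections`` rather than silently dropped. Two rows
    sharing a ``compound_id`` raise an error naming both rows.
    """
    if format == "smiles_tsv":
        rows = _read_tsv_rows(path)
    elif format == "sdf":
        rows = _read_sdf_rows(path)
    else:
        raise CurationError(f"unknown format {format!r}")

    seen: dict[str, int] = {}
    compounds: list[CompoundRecord] = []
    rejections: list[RejectedRow] = []
    for i, row in rows:
        cid = row.get("compound_id")
        if cid is None or (isinstance(cid, float) and pd.isna(cid)) or cid == "":
            rejections.append(RejectedRow(i, None, "missing compound_id"))
            continue
        cid = str(cid)
        if cid in seen:
            raise CurationError(
                f"duplicate compound_id {cid!r} in rows {seen[cid]} and {i}"
            )
        seen[cid] = i
        smiles = row.get("smiles")
        if smiles is None or (isinstance(smiles, float) and pd.isna(smiles)):
            rejections.append(RejectedRow(i, cid, "missing smiles"))
            continue
        try:
            fp = compute_fingerprint(str(smiles))
        except StructureParseError as e:
            rejections.append(RejectedRow(i, cid, str(e)))
            continue
        try:
            activity = _activity_from_row(pd.Series(row))
        except CurationError as e:
            rejections.append(RejectedRow(i, cid, str(e)))
            continue
        alias = row.get("alias")
        aliases = (
            [a for a in str(alias).split("|") if a]
            if alias not in (None, "") and not (isinstance(alias, float) and pd.isna(alias))
            else []
        )
        chemo = row.get("chemotype")
        if chemo in ("",) or (isinstance(chemo, float) and pd.isna(chemo)):
            chemo = None
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                structure=str(smiles),
                aliases=aliases,
                activities=[activity] if activity else [],
                chemotype=str(chemo) if chemo is not None else None,
                fingerprint=fp,
            )
        )
    if not compounds:
        warnings.warn(f"empty compound table: {path}")
    return ScreeningLibrary(
        compounds=compounds,
        thresholds=dict(thresholds or {}),
        provenance=str(path),
        rejections=rejections,
    )


def _read_tsv_rows(path):
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise CurationError(f"missing required column(s) {missing} in {path}")
    return [(int(i), row.to_dict()) for i, row in df.iterrows()]


def _read_sdf_rows(path):
    suppl = Chem.SDMolSupplier(str(path), sanitize=True)
    rows = []
    for i, mol in enumerate(suppl):
        if mol is None:
            rows.append((i, {"compound_id": f"<entry {i}>", "smiles": None}))
            continue
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        props.setdefault("compound_id", mol.GetProp("_Name") if mol.HasProp("_Name") else "")
        props["smiles"] = Chem.MolToSmiles(mol)
        if "value" in props:
            props["value"] = float(props["value"])
        rows.append((i, props))
    return rows


# ---------------------------------------------------------------------------
# role assignment


def assign_roles(
    library: ScreeningLibrary, receptor: str, site: str
) -> ScreeningLibrary:
    """Assign active/inactive roles under per-chemotype potency cutoffs.

    A compound with a measured pactivity at (receptor, site) is *active*
    iff that pactivity strictly exceeds its chemotype's cutoff, otherwise
    *inactive*. Compounds already marked ``decoy`` are untouched; compounds
    without a matching measurement keep their current role. Idempotent.
    """
    out = []
    for c in library.compounds:
        if c.role == "decoy":
            out.append(c)
            continue
        pact = c.best_pactivity(receptor, site)
        if pact is None:
            out.append(c)
            continue
        chemo = c.chemotype if c.chemotype is not None else "__default__"
        if chemo not in library.thresholds:
            raise CurationError(
                f"no activity threshold for chemotype {chemo!r} "
                f"(compound {c.compound_id})"
            )
        cutoff = library.thresholds[chemo]
        role = "active" if pact > cutoff else "inactive"
        out.append(replace(c, role=role))
    return ScreeningLibrary(
        compounds=out,
        thresholds=dict(library.thresholds),
        provenance=library.provenance,
        rejections=list(library.rejections),
    )


# ---------------------------------------------------------------------------
# UPGMA chemotype clustering


@dataclass
class Dendrogram:
    """UPGMA merge tree over compound ids.

    ``merges`` lists, in order, the two clusters joined (as sorted member
    tuples) and the merge height in Tanimoto-distance units; heights are
    non-decreasing (ultrametric property of UPGMA).
    """

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    leaf_order: list[str]

    def cut(self, height: float) -> list[tuple[str, ...]]:
        """Disjoint exhaustive clusters obtained by cutting at ``height``.

        Merges with height ≤ the cut are applied; clusters are returned
        sorted by their lexicographically first member.
        """
        clusters = {(leaf,): None for leaf in self.leaf_order}
        for a, b, h in self.merges:
            if h <= height:
                del clusters[a]
                del clusters[b]
                clusters[tuple(sorted(a + b))] = None
        return sorted(clusters, key=lambda t: t[0])

    def labels(self, height: float) -> dict[str, str]:
        """Chemotype label per compound: the lexicographically first member id."""
        out = {}
        for cluster in self.cut(height):
            for member in cluster:
                out[member] = cluster[0]
        return out


def upgma(ids: Sequence[str], dist: "pd.DataFrame | dict | list") -> Dendrogram:
    """Unweighted pair-group (arithmetic-mean) agglomeration.

    ``dist`` is a square matrix (indexable by integer position) of pairwise
    distances aligned with ``ids``. Ties are broken in favour of the pair
    whose lexicographically smallest member id is smallest, then by the
    other member, so output is invariant to input permutation.
    """
    import numpy as np

    n = len(ids)
    if n == 0:
        raise CurationError("cannot cluster an empty set")
    D = np.asarray(dist, dtype=float)
    if D.shape != (n, n):
        raise CurationError(f"distance matrix shape {D.shape} != ({n},{n})")
    clusters: dict[tuple[str, ...], dict] = {
        (str(ids[i]),): {"idx": i, "size": 1} for i in range(n)
    }
    # current average distance between cluster pairs, keyed by member tuples
    d: dict[frozenset, float] = {}
    keys = list(clusters)
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((keys[i], keys[j]))] = float(D[i, j])

    merges = []
    while len(clusters) > 1:
        best = None
        for pair, dd in d.items():
            a, b = sorted(pair)
            cand = (dd, a, b)
            if best is None or cand < best:
                best = cand
        dd, a, b = best
        sa, sb = clusters[a]["size"], clusters[b]["size"]
        merged = tuple(sorted(a + b))
        merges.append((a, b, dd))
        for other in list(clusters):
            if other in (a, b):
                continue
            dab = (
                sa * d[frozenset((a, other))] + sb * d[frozenset((b, other))]
            ) / (sa + sb)
            d[frozenset((merged, other))] = dab
            del d[frozenset((a, other))]
            del d[frozenset((b, other))]
        del d[frozenset((a, b))]
        del clusters[a]
        del clusters[b]
        clusters[merged] = {"idx": None, "size": sa + sb}

    leaf_order = _leaf_order(merges, [str(i) for i in ids])
    return Dendrogram(merges=merges, leaf_order=leaf_order)


def _leaf_order(merges, ids):
    """Leaves ordered by recursive traversal of the merge tree."""
    if not merges:
        return sorted(ids)
    order: dict[tuple, list] = {(i,): [i] for i in ids}
    for a, b, _h in merges:
        order[tuple(sorted(a + b))] = order.pop(a) + order.pop(b)
    (root,) = order
    return order[root] if isinstance(order[root], list) else list(root)


def cluster_chemotypes(
    library: ScreeningLibrary, cut_height: float = 0.6, assign: bool = True
) -> tuple[Dendrogram, dict[str, str]]:
    """Cluster library compounds into chemotypes by UPGMA on Tanimoto distances.

    Compounds must carry fingerprints. Returns the dendrogram and a mapping
    compound_id → chemotype label (lexicographically first member of the
    cluster obtained by cutting at ``cut_height``); when ``assign`` is true,
    labels are written onto compounds lacking a chemotype.
    """
    comps = [c for c in library.compounds if c.fingerprint is not None]
    if not comps:
        raise CurationError("no fingerprinted compounds to cluster")
    ids = [c.compound_id for c in comps]
    import numpy as np

    n = len(comps)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tanimoto_distance(
                comps[i].fingerprint, comps[j].fingerprint
            )
    dendro = upgma(ids, D)
    labels = dendro.labels(cut_height)
    if assign:
        for c in comps:
            if c.chemotype is None:
                c.chemotype = labels[c.compound_id]
    return dendro, labels
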