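"""Receptor geometry analysis and induced-fit refinement specification.

Parses receptor structures (PDB/mmCIF via gemmi), attaches
Ballesteros–Weinstein (BW) generic numbers from a user-supplied mapping
table, superposes TM backbones (Kabsch least squares), computes Cα–Cα
distance tables between BW-addressed residue pairs, builds ligand-envelope
sampling boxes, applies mutation-edit bookkeeping, and emits a declarative
fragment/tether/restraint specification for induced-fit conformational
refinement. No refinement is executed here — the spec is a recipe for an
external sampling engine.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GeometryError

__all__ = [
    "Atom",
    "AnnotatedStructure",
    "EnvelopeBox",
    "MutationEdit",
    "FragmentSpec",
    "Fragment",
    "AtomSelector",
    "DistanceRestraint",
    "load_and_annotate",
    "read_bw_table",
    "superpose_backbones",
    "bw_distance_table",
    "select_proximal_atoms",
    "build_envelope_box",
    "build_fragment_spec",
    "apply_mutation_edits",
    "validate_fragment_spec",
    "DEFAULT_POCKET_PAIRS",
]

#: Reconstructed default Cα–Cα pair list for pocket-contraction analysis:
#: the TM3 pocket floor (3.29) against mid-bilayer TM6/TM7 positions, plus
#: TM1-vs-TM7 pairs spanning the inactive-state fenestration. These are a
#: reconstruction of a representative pair set, not an authoritative list.
DEFAULT_POCKET_PAIRS: list[tuple[str, str]] = [
    ("3.29", "6.48"),
    ("3.29", "7.40"),
    ("3.29", "7.43"),
    ("1.39", "7.39"),
    ("1.39", "7.40"),
]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
_BACKBONE = ("N", "CA", "C", "O")

#: canonical heavy-atom names per residue type (PDB naming)
RESIDUE_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": _BACKBONE,
    "ALA": _BACKBONE + ("CB",),
    "SER": _BACKBONE + ("CB", "OG"),
    "CYS": _BACKBONE + ("CB", "SG"),
    "THR": _BACKBONE + ("CB", "OG1", "CG2"),
    "VAL": _BACKBONE + ("CB", "CG1", "CG2"),
    "LEU": _BACKBONE + ("CB", "CG", "CD1", "CD2"),
    "ILE": _BACKBONE + ("CB", "CG1", "CG2", "CD1"),
    "MET": _BACKBONE + ("CB", "CG", "SD", "CE"),
    "PRO": _BACKBONE + ("CB", "CG", "CD"),
    "PHE": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": _BACKBONE + ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ASP": _BACKBONE + ("CB", "CG", "OD1", "OD2"),
    "GLU": _BACKBONE + ("CB", "CG", "CD", "OE1", "OE2"),
    "ASN": _BACKBONE + ("CB", "CG", "OD1", "ND2"),
    "GLN": _BACKBONE + ("CB", "CG", "CD", "OE1", "NE2"),
    "HIS": _BACKBONE + ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "LYS": _BACKBONE + ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": _BACKBONE + ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
}


@dataclass
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    xyz: np.ndarray  # shape (3,), Å; NaN for placeholder atoms
    occupancy: float = 1.0
    icode: str = ""
    element: str = ""


@dataclass
class AnnotatedStructure:
    """Atomic coordinates with chain/residue identity and BW generic numbers."""

    atoms: list[Atom]
    bw: dict[tuple[str, int], str] = field(default_factory=dict)
    ligands: dict[str, list[int]] = field(default_factory=dict)  # name → atom indices
    name: str = ""
    unmatched_bw: list[dict] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resnum, a.icode, a.name)
            if key in seen:
                raise GeometryError(f"duplicate atom {key}")
            seen.add(key)
        self._check_bw_injective()

    def _check_bw_injective(self):
        per_chain: dict[str, dict[str, int]] = {}
        for (chain, resnum), gn in self.bw.items():
            prev = per_chain.setdefault(chain, {}).get(gn)
            if prev is not None and prev != resnum:
                raise GeometryError(
                    f"BW number {gn!r} assigned to residues {prev} and {resnum} "
                    f"in chain {chain}"
                )
            per_chain[chain][gn] = resnum

    # -- lookups ------------------------------------------------------------

    def residues(self) -> list[tuple[str, int, str]]:
        out, seen = [], set()
        for a in self.atoms:
            key = (a.chain, a.resnum)
            if key not in seen:
                seen.add(key)
                out.append((a.chain, a.resnum, a.resname))
        return out

    def residue_atoms(self, chain: str, resnum: int) -> list[int]:
        return [
            i for i, a in enumerate(self.atoms)
            if a.chain == chain and a.resnum == resnum
        ]

    def get_atom(self, chain: str, resnum: int, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return a
        return None

    def bw_residue(self, generic: str, chain: Optional[str] = None) -> tuple[str, int]:
        """(chain, resnum) carrying a BW generic number; first chain if ambiguous."""
        hits = sorted(
            (ch, rn) for (ch, rn), gn in self.bw.items()
            if gn == generic and (chain is None or ch == chain)
        )
        if not hits:
            raise GeometryError(f"no residue annotated {generic!r}")
        return hits[0]

    def ca(self, chain: str, resnum: int) -> np.ndarray:
        a = self.get_atom(chain, resnum, "CA")
        if a is None or np.isnan(a.xyz).any():
            raise GeometryError(f"no Cα for {chain}{resnum}")
        return a.xyz

    def chain_range(self, chain: str) -> tuple[int, int]:
        nums = [a.resnum for a in self.atoms if a.chain == chain]
        if not nums:
            raise GeometryError(f"no such chain {chain!r}")
        return min(nums), max(nums)

    def coords(self, indices: Optional[Iterable[int]] = None) -> np.ndarray:
        if indices is None:
            return np.array([a.xyz for a in self.atoms])
        return np.array([self.atoms[i].xyz for i in indices])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "AnnotatedStructure":
        new = copy.deepcopy(self)
        for a in new.atoms:
            if not np.isnan(a.xyz).any():
                a.xyz = R @ a.xyz + t
        return new

    def disulfide_pairs(self, max_sg_dist: float = 2.5) -> list[tuple[tuple[str, int], tuple[str, int]]]:
        """CYS pairs whose SG atoms lie within ``max_sg_dist`` Å."""
        sgs = [
            a for a in self.atoms
            if a.resname == "CYS" and a.name == "SG" and not np.isnan(a.xyz).any()
        ]
        pairs = []
        for i in range(len(sgs)):
            for j in range(i + 1, len(sgs)):
                if np.linalg.norm(sgs[i].xyz - sgs[j].xyz) <= max_sg_dist:
                    pairs.append(
                        ((sgs[i].chain, sgs[i].resnum), (sgs[j].chain, sgs[j].resnum))
                    )
        return pairs

    # -- I/O ----------------------------------------------------------------

    def to_pdb(self, path):
        """Write coordinates as a PDB file (placeholder NaN atoms skipped)."""
        import gemmi

        st = gemmi.Structure()
        st.name = self.name or "structure"
        model = gemmi.Model("1")
        chains: dict[str, gemmi.Chain] = {}
        for a in self.atoms:
            if np.isnan(a.xyz).any():
                continue
            ch = chains.get(a.chain)
            if ch is None:
                ch = gemmi.Chain(a.chain)
                chains[a.chain] = ch
            res = None
            if len(ch) and ch[-1].seqid.num == a.resnum and ch[-1].name == a.resname:
                res = ch[-1]
            else:
                res = gemmi.Residue()
                res.name = a.resname
                res.seqid = gemmi.SeqId(a.resnum, a.icode or " ")
                ch.add_residue(res)
                res = ch[-1]
            at = gemmi.Atom()
            at.name = a.name
            at.pos = gemmi.Position(*a.xyz)
            at.occ = a.occupancy
            at.element = gemmi.Element(a.element or a.name[0])
            res.add_atom(at)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# loading & annotation

_STANDARD_AA = set(RESIDUE_HEAVY_ATOMS)


def read_bw_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "generic_number": str})
    required = {"chain", "resnum", "generic_number"}
    if not required <= set(df.columns):
        raise GeometryError(f"BW table must have columns {sorted(required)}")
    return df


def load_and_annotate(structure_path, bw_table=None, name: str = "") -> AnnotatedStructure:
    """Load a PDB/mmCIF file and attach BW generic numbers from a mapping table.

    ``bw_table`` is a TSV path or DataFrame with columns
    ``chain, resnum, generic_number``; loop-style numbers ("45.52") and
    helix-8 numbers ("8.49") are accepted as opaque labels. Mapping rows
    that reference residues absent from the file are collected in
    ``unmatched_bw``. Alternate locations keep altloc A; insertion codes
    are preserved verbatim. Non-polymer (non amino-acid) residues become
    named ligand groups.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(structure_path))
    except Exception as e:  # gemmi raises RuntimeError on malformed files
        raise GeometryError(f"cannot parse {structure_path}: {e}") from e
    if len(st) == 0:
        raise GeometryError(f"no models in {structure_path}")
    st.setup_entities()
    model = st[0]
    atoms: list[Atom] = []
    ligands: dict[str, list[int]] = {}
    for chain in model:
        for res in chain:
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    continue
                idx = len(atoms)
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        name=at.name,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        icode=(res.seqid.icode or "").strip(),
                        element=at.element.name,
                    )
                )
                if res.name not in _STANDARD_AA and res.name not in ("HOH", "WAT"):
                    ligands.setdefault(
                        f"{res.name}_{chain.name}{res.seqid.num}", []
                    ).append(idx)
                    ligands.setdefault(res.name, []).append(idx)

    bw: dict[tuple[str, int], str] = {}
    unmatched: list[dict] = []
    if bw_table is not None:
        df = bw_table if isinstance(bw_table, pd.DataFrame) else read_bw_table(bw_table)
        present = {(a.chain, a.resnum) for a in atoms}
        for _, row in df.iterrows():
            key = (str(row["chain"]), int(row["resnum"]))
            gn = str(row["generic_number"])
            if key not in present:
                unmatched.append({"chain": key[0], "resnum": key[1], "generic_number": gn})
                continue
            if key in bw and bw[key] != gn:
                raise GeometryError(f"conflicting BW assignments for {key}: {bw[key]} vs {gn}")
            bw[key] = gn
    return AnnotatedStructure(
        atoms=atoms, bw=bw, ligands=ligands,
        name=name or str(structure_path), unmatched_bw=unmatched,
    )


# ---------------------------------------------------------------------------
# superposition

def _expand_bw_selection(selection: Sequence[str]) -> "callable":
    """Predicate over BW labels from items like '2.63' or '1.30-1.55'."""
    singles, ranges = set(), []
    for item in selection:
        item = str(item)
        if "-" in item:
            lo, hi = item.split("-")
            h1, p1 = lo.split(".")
            h2, p2 = hi.split(".")
            if h1 != h2:
                raise GeometryError(f"range {item!r} spans helices")
            ranges.append((h1, int(p1), int(p2)))
        else:
            singles.add(item)

    def pred(gn: str) -> bool:
        if gn in singles:
            return True
        try:
            h, p = gn.split(".")
            p = int(p)
        except ValueError:
            return False
        return any(h == rh and lo <= p <= hi for rh, lo, hi in ranges)

    return pred


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping P onto Q."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def superpose_backbones(
    reference: AnnotatedStructure,
    mobile: AnnotatedStructure,
    selection: Optional[Sequence[str]] = None,
    atom_names: Sequence[str] = ("N", "CA", "C"),
) -> tuple[AnnotatedStructure, float]:
    """Rigid-body least-squares fit of mobile onto reference TM backbones.

    Atoms are matched by BW generic number and atom name; ``selection``
    limits matching to the given BW labels/ranges (default: all shared BW
    positions). Returns the transformed mobile copy and the RMSD (Å) over
    the matched atoms. The reference is unchanged.
    """
    pred = _expand_bw_selection(selection) if selection is not None else (lambda gn: True)
    ref_by_bw = {gn: key for key, gn in reference.bw.items() if pred(gn)}
    mob_by_bw = {gn: key for key, gn in mobile.bw.items() if pred(gn)}
    P, Q = [], []
    for gn in sorted(set(ref_by_bw) & set(mob_by_bw)):
        rc, rr = ref_by_bw[gn]
        mc, mr = mob_by_bw[gn]
        for an in atom_names:
            ra, ma = reference.get_atom(rc, rr, an), mobile.get_atom(mc, mr, an)
            if ra is not None and ma is not None:
                Q.append(ra.xyz)
                P.append(ma.xyz)
    if len(P) < 3:
        raise GeometryError(
            f"need >= 3 matched backbone atoms for superposition, got {len(P)}"
        )
    P, Q = np.array(P), np.array(Q)
    R, t = _kabsch(P, Q)
    moved = mobile.transformed(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return moved, rmsd


# ---------------------------------------------------------------------------
# distance tables & selections

def bw_distance_table(
    structures: Sequence[AnnotatedStructure],
    pairs: Sequence[tuple[str, str]] = tuple(DEFAULT_POCKET_PAIRS),
) -> pd.DataFrame:
    """Cα–Cα distances (Å): one row per structure, one column per BW pair.

    Distances are intra-structure, hence invariant to superposition.
    Missing annotations yield NaN cells (flagged, not silently dropped);
    a pair resolvable in no structure at all is an error.
    """
    cols = [f"{i}-{j}" for i, j in pairs]
    rows = {}
    resolved = {c: False for c in cols}
    for k, st in enumerate(structures):
        label = st.name or f"structure_{k}"
        row = {}
        for (i, j), col in zip(pairs, cols):
            try:
                ci, ri = st.bw_residue(i)
                cj, rj = st.bw_residue(j)
                row[col] = float(np.linalg.norm(st.ca(ci, ri) - st.ca(cj, rj)))
                resolved[col] = True
            except GeometryError:
                row[col] = np.nan
        rows[label] = row
    bad = [c for c, ok in resolved.items() if not ok]
    if bad:
        raise GeometryError(f"pair(s) {bad} unresolvable in every structure")
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def select_proximal_atoms(
    structure: AnnotatedStructure,
    reference_group: "str | Sequence[int]",
    cutoff: float,
    granularity: str = "atom",
) -> list[int]:
    """Atom indices within ``cutoff`` Å of any reference-group atom.

    ``reference_group`` is a ligand-group name or explicit atom indices.
    Atom granularity returns exactly the atoms within the cutoff; residue
    granularity returns all atoms of any residue with ≥1 atom within it.
    Atoms of the reference group itself are excluded.
    """
    if isinstance(reference_group, str):
        if reference_group not in structure.ligands:
            raise GeometryError(f"no ligand group {reference_group!r}")
        ref_idx = structure.ligands[reference_group]
    else:
        ref_idx = list(reference_group)
    if not ref_idx:
        raise GeometryError("empty reference group")
    if granularity not in ("atom", "residue"):
        raise GeometryError(f"granularity must be atom|residue, got {granularity!r}")
    ref_set = set(ref_idx)
    ref_residues = {(structure.atoms[i].chain, structure.atoms[i].resnum) for i in ref_idx}
    tree = cKDTree(structure.coords(ref_idx))
    hits = []
    for i, a in enumerate(structure.atoms):
        if i in ref_set or (a.chain, a.resnum) in ref_residues:
            continue
        if np.isnan(a.xyz).any():
            continue
        if tree.query(a.xyz, k=1)[0] <= cutoff:
            hits.append(i)
    if granularity == "atom":
        return hits
    residues = {(structure.atoms[i].chain, structure.atoms[i].resnum) for i in hits}
    return [
        i for i, a in enumerate(structure.atoms)
        if (a.chain, a.resnum) in residues
    ]


@dataclass(frozen=True)
class EnvelopeBox:
    """Axis-aligned sampling box around a ligand envelope."""

    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]
    margin: float
    n_points: int

    def contains(self, point) -> bool:
        p = np.asarray(point)
        return bool(
            (p >= np.asarray(self.min_corner)).all()
            and (p <= np.asarray(self.max_corner)).all()
        )


def build_envelope_box(points, margin: float = 4.0) -> EnvelopeBox:
    """Rectangular box encompassing ``points`` with ``margin`` Å on each side."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.size == 0:
        raise GeometryError("cannot build a box from an empty point set")
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    return EnvelopeBox(tuple(lo), tuple(hi), float(margin), len(pts))


# ---------------------------------------------------------------------------
# mutation-edit bookkeeping

@dataclass(frozen=True)
class MutationEdit:
    """Bookkeeping record for reverting an engineered point mutation."""

    chain: str
    resnum: int
    from_res: str  # 1- or 3-letter code of the residue currently in the file
    to_res: str  # target (wild-type) identity


def _to3(code: str) -> str:
    code = code.upper()
    if len(code) == 1:
        if code not in _AA3:
            raise GeometryError(f"unknown residue code {code!r}")
        return _AA3[code]
    if code not in RESIDUE_HEAVY_ATOMS:
        raise GeometryError(f"unknown residue name {code!r}")
    return code


def apply_mutation_edits(
    structure: AnnotatedStructure, edits: Sequence[MutationEdit]
) -> AnnotatedStructure:
    """Apply residue-identity edits without inventing any coordinates.

    Shrinking edits (e.g. X→Ala) rename the residue and delete side-chain
    atoms beyond the target's atom set; growing edits rename and add
    placeholder atoms for the missing target atoms with occupancy 0 and
    NaN coordinates (to be rebuilt by an external engine). An edit whose
    ``from_res`` does not match the structure is an error naming the residue.
    """
    new = copy.deepcopy(structure)
    for e in edits:
        frm, to = _to3(e.from_res), _to3(e.to_res)
        idx = new.residue_atoms(e.chain, e.resnum)
        if not idx:
            raise GeometryError(f"no residue {e.chain}{e.resnum} to edit")
        current = new.atoms[idx[0]].resname
        if current != frm:
            raise GeometryError(
                f"edit {frm}->{to} at {e.chain}{e.resnum}: structure has {current}"
            )
        target_atoms = set(RESIDUE_HEAVY_ATOMS[to])
        present = {new.atoms[i].name for i in idx}
        keep, drop = [], []
        for i in idx:
            (keep if new.atoms[i].name in target_atoms else drop).append(i)
        for i in sorted(drop, reverse=True):
            del new.atoms[i]
            # reindex ligand groups
            for g in new.ligands.values():
                for k, gi in enumerate(g):
                    if gi > i:
                        g[k] = gi - 1
        for i, a in enumerate(new.atoms):
            if a.chain == e.chain and a.resnum == e.resnum:
                a.resname = to
        for missing in sorted(target_atoms - present):
            new.atoms.append(
                Atom(
                    chain=e.chain, resnum=e.resnum, resname=to, name=missing,
                    xyz=np.full(3, np.nan), occupancy=0.0,
                    element=missing[0],
                )
            )
    return new


# ---------------------------------------------------------------------------
# induced-fit fragment specification

@dataclass(frozen=True)
class AtomSelector:
    chain: str
    resnum: int
    atom_name: str
    bw: Optional[str] = None


@dataclass(frozen=True)
class DistanceRestraint:
    """Declarative hydrogen-bond preservation restraint (1.8–2.4 Å, weight 1)."""

    chain: str
    resnum: int
    bw: str
    atoms: tuple[str, ...]  # anchor atoms on the residue ('' set may be empty for Cα traces)
    partner: str = "hbond_partner"
    dmin: float = 1.8
    dmax: float = 2.4
    weight: float = 1.0


@dataclass(frozen=True)
class Fragment:
    chain: str
    start: int
    end: int
    mobility: str  # stationary | sidechain_only | fully_flexible

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, resnum: int) -> bool:
        return self.start <= resnum <= self.end


@dataclass
class FragmentSpec:
    """Declarative induced-fit refinement recipe for an external engine."""

    mode: str  # orthosteric | allosteric
    fragments: list[Fragment]
    tethers: list[AtomSelector]
    restraints: list[DistanceRestraint]
    pre_minimization_steps: int
    global_steps: int
    seed_segments: list[tuple[str, int, int]] = field(default_factory=list)

    def min_fragment_length(self) -> int:
        return min(f.length for f in self.fragments)


#: per-mode minimum fragment lengths in residues
MIN_FRAGMENT_LENGTH = {"orthosteric": 9, "allosteric": 18}
#: per-mode pre-minimization step counts; global sampling is 1e6 steps in both
PRE_MINIMIZATION_STEPS = {"orthosteric": 10_000, "allosteric": 100_000}
GLOBAL_STEPS = 1_000_000

ORTHOSTERIC_TETHER_BW = ("2.53", "2.56", "2.60", "2.63")
ORTHOSTERIC_RESTRAINT_BW = ("1.39", "3.32", "7.36", "7.39", "7.40", "7.44")
ALLOSTERIC_RESTRAINT_BW = ("8.49", "8.50")

#: side-chain hydrogen-bonding atoms used for restraint anchors
_POLAR_SIDECHAIN = {
    "TYR": ("OH",), "THR": ("OG1",), "SER": ("OG",),
    "GLN": ("OE1", "NE2"), "ASN": ("OD1", "ND2"),
    "GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2"),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}


def _helix_of(gn: str) -> Optional[int]:
    """Leading helix/loop index of a BW label ('2.63'→2, '45.52'→45, '8.49'→8)."""
    try:
        return int(gn.split(".")[0])
    except (ValueError, AttributeError):
        return None


def _contiguous_segments(resnums: Sequence[int]) -> list[tuple[int, int]]:
    nums = sorted(set(resnums))
    segs = []
    lo = prev = nums[0]
    for n in nums[1:]:
        if n == prev + 1:
            prev = n
            continue
        segs.append((lo, prev))
        lo = prev = n
    segs.append((lo, prev))
    return segs


def _expand_segment(lo: int, hi: int, cmin: int, cmax: int, min_len: int) -> tuple[int, int]:
    """Grow [lo, hi] to min_len by alternating N-/C-terminal extension.

    Growth starts at the N-terminal end; an end clipped at a chain
    terminus is compensated by extending the open end.
    """
    grow_n = True
    while hi - lo + 1 < min_len:
        if grow_n and lo > cmin:
            lo -= 1
        elif not grow_n and hi < cmax:
            hi += 1
        elif lo > cmin:
            lo -= 1
        elif hi < cmax:
            hi += 1
        else:
            raise GeometryError(
                f"chain span {cmin}-{cmax} shorter than minimum fragment length {min_len}"
            )
        grow_n = not grow_n
    return lo, hi


def _merge_segments(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    segs = sorted(segs)
    merged = [segs[0]]
    for lo, hi in segs[1:]:
        mlo, mhi = merged[-1]
        if lo <= mhi + 1:
            merged[-1] = (mlo, max(mhi, hi))
        else:
            merged.append((lo, hi))
    return merged


def _fragment_helices(structure: AnnotatedStructure, chain: str, lo: int, hi: int) -> set[int]:
    helices = set()
    for rn in range(lo, hi + 1):
        gn = structure.bw.get((chain, rn))
        h = _helix_of(gn) if gn else None
        if h is not None:
            helices.add(h)
    return helices


def _mobility(mode: str, helices: set[int]) -> Optional[str]:
    """Mobility class of a fragment from the TM helices/loops it covers.

    Orthosteric: TM1/TM2/TM7 fragments are fully flexible, everything else
    samples side chains only. Allosteric: TM6 and TM7–H8 move, TM1–ICL1–TM2
    and TM3 are held stationary (side chains still sampled by the engine),
    and TM4/TM5 (with ECL2, the 45.x loop) fragments are omitted as not
    proximal to the intracellular pocket (returns None).
    """
    if mode == "orthosteric":
        return "fully_flexible" if helices & {1, 2, 7} else "sidechain_only"
    # allosteric
    if helices & {6, 7, 8}:
        return "fully_flexible"
    if helices and helices <= {4, 5, 45}:
        return None  # omitted: not proximal to the allosteric pocket
    return "stationary"


def build_fragment_spec(
    structure: AnnotatedStructure,
    ligand_group: "str | Sequence[int]",
    mode: str,
    proximity_cutoff: float = 5.5,
) -> FragmentSpec:
    """Build the declarative induced-fit fragment/restraint specification.

    Seed residues are selected at residue granularity within
    ``proximity_cutoff`` Å of the ligand; contiguous segments are expanded
    symmetrically (alternating ends, N-terminal first, clipped at chain
    termini with compensating extension) to the mode's minimum length —
    9 residues for orthosteric complexes, 18 for allosteric. Segments
    holding one cysteine of a disulfide pull in their partner's segment.
    Tethers anchor fragment-end backbone atoms, plus (orthosteric mode)
    the backbone carbons at BW 2.53/2.56/2.60/2.63. Hydrogen-bond
    distance restraints (1.8–2.4 Å, weight 1.0) reference the polar
    side-chain atoms at BW 1.39/3.32/7.36/7.39/7.40/7.44 (orthosteric) or
    the backbone amides at BW 8.49/8.50 (allosteric). Sampling directives
    record 10,000 (orthosteric) or 100,000 (allosteric) pre-minimization
    steps and 10^6 global Monte Carlo steps.
    """
    if mode not in MIN_FRAGMENT_LENGTH:
        raise GeometryError(f"mode must be orthosteric|allosteric, got {mode!r}")
    min_len = MIN_FRAGMENT_LENGTH[mode]

    required = (
        ORTHOSTERIC_TETHER_BW + ORTHOSTERIC_RESTRAINT_BW
        if mode == "orthosteric"
        else ALLOSTERIC_RESTRAINT_BW
    )
    annotated = set(structure.bw.values())
    missing = [gn for gn in required if gn not in annotated]
    if missing:
        raise GeometryError(f"required BW anchors missing from annotation: {missing}")

    seed_idx = select_proximal_atoms(
        structure, ligand_group, proximity_cutoff, granularity="residue"
    )
    if not seed_idx:
        raise GeometryError("no residues within the proximity cutoff of the ligand")
    seed_res: dict[str, list[int]] = {}
    for i in seed_idx:
        a = structure.atoms[i]
        seed_res.setdefault(a.chain, []).append(a.resnum)

    seed_segments: list[tuple[str, int, int]] = []
    expanded: dict[str, list[tuple[int, int]]] = {}
    for chain, resnums in sorted(seed_res.items()):
        cmin, cmax = structure.chain_range(chain)
        for lo, hi in _contiguous_segments(resnums):
            seed_segments.append((chain, lo, hi))
            expanded.setdefault(chain, []).append(
                _expand_segment(lo, hi, cmin, cmax, min_len)
            )

    # pull in disulfide partners of any included cysteine
    ss_pairs = structure.disulfide_pairs()
    changed = True
    while changed:
        changed = False
        for (ca_, ra), (cb_, rb) in ss_pairs:
            a_in = any(lo <= ra <= hi for lo, hi in expanded.get(ca_, []))
            b_in = any(lo <= rb <= hi for lo, hi in expanded.get(cb_, []))
            if a_in and not b_in:
                cmin, cmax = structure.chain_range(cb_)
                expanded.setdefault(cb_, []).append(
                    _expand_segment(rb, rb, cmin, cmax, min_len)
                )
                changed = True
            elif b_in and not a_in:
                cmin, cmax = structure.chain_range(ca_)
                expanded.setdefault(ca_, []).append(
                    _expand_segment(ra, ra, cmin, cmax, min_len)
                )
                changed = True

    def _build_fragments() -> list[Fragment]:
        frags = []
        for chain in sorted(expanded):
            for lo, hi in _merge_segments(expanded[chain]):
                helices = _fragment_helices(structure, chain, lo, hi)
                mob = _mobility(mode, helices)
                if mob is None:
                    # disulfide closure trumps the TM4/TM5 omission: keep the
                    # segment (stationary) if dropping it would orphan a
                    # disulfide partner retained elsewhere
                    orphan = False
                    for (pa, ra2), (pb, rb2) in ss_pairs:
                        for (c1, r1), (c2, r2) in (((pa, ra2), (pb, rb2)),
                                                   ((pb, rb2), (pa, ra2))):
                            if c1 == chain and lo <= r1 <= hi:
                                if any(
                                    lo2 <= r2 <= hi2
                                    for lo2, hi2 in expanded.get(c2, [])
                                    if not (c2 == chain and (lo2, hi2) == (lo, hi))
                                ):
                                    orphan = True
                    if not orphan:
                        continue
                    mob = "stationary"
                frags.append(Fragment(chain, lo, hi, mob))
        return frags

    fragments = _build_fragments()
    if not fragments:
        raise GeometryError("all candidate fragments were omitted for this mode")

    tethers: list[AtomSelector] = []
    for f in fragments:
        for rn in (f.start, f.end):
            for an in ("N", "CA", "C"):
                if structure.get_atom(f.chain, rn, an) is not None:
                    tethers.append(AtomSelector(f.chain, rn, an, structure.bw.get((f.chain, rn))))
    if mode == "orthosteric":
        for gn in ORTHOSTERIC_TETHER_BW:
            ch, rn = structure.bw_residue(gn)
            for an in ("CA", "C"):  # backbone carbons
                if structure.get_atom(ch, rn, an) is not None:
                    tethers.append(AtomSelector(ch, rn, an, gn))

    restraints: list[DistanceRestraint] = []
    if mode == "orthosteric":
        for gn in ORTHOSTERIC_RESTRAINT_BW:
            ch, rn = structure.bw_residue(gn)
            resname = next(
                (a.resname for a in structure.atoms if a.chain == ch and a.resnum == rn),
                "",
            )
            anchors = tuple(
                an for an in _POLAR_SIDECHAIN.get(resname, ())
                if structure.get_atom(ch, rn, an) is not None
            )
            restraints.append(DistanceRestraint(ch, rn, gn, anchors))
    else:
        for gn in ALLOSTERIC_RESTRAINT_BW:
            ch, rn = structure.bw_residue(gn)
            anchors = ("N",) if structure.get_atom(ch, rn, "N") is not None else ()
            restraints.append(DistanceRestraint(ch, rn, gn, anchors))

    spec = FragmentSpec(
        mode=mode,
        fragments=fragments,
        tethers=tethers,
        restraints=restraints,
        pre_minimization_steps=PRE_MINIMIZATION_STEPS[mode],
        global_steps=GLOBAL_STEPS,
        seed_segments=seed_segments,
    )
    validate_fragment_spec(spec, structure)
    return spec


def validate_fragment_spec(spec: FragmentSpec, structure: AnnotatedStructure):
    """Independent checker: length minima and disulfide-closure invariants."""
    min_len = MIN_FRAGMENT_LENGTH[spec.mode]
    for f in spec.fragments:
        if f.length < min_len:
            raise GeometryError(
                f"fragment {f.chain}:{f.start}-{f.end} shorter than {min_len} aa"
            )
    for (ca_, ra), (cb_, rb) in structure.disulfide_pairs():
        a_in = any(f.chain == ca_ and f.contains(ra) for f in spec.fragments)
        b_in = any(f.chain == cb_ and f.contains(rb) for f in spec.fragments)
        if a_in != b_in:
            raise GeometryError(
                f"disulfide {ca_}{ra}-{cb_}{rb} split across the fragment boundary"
            )


def fragment_spec_to_json(spec: FragmentSpec) -> dict:
    """JSON-serializable form of a fragment specification."""
    return {
        "mode": spec.mode,
        "fragments": [
            {"chain": f.chain, "start": f.start, "end": f.end,
             "length": f.length, "mobility": f.mobility}
            for f in spec.fragments
        ],
        "tethers": [
            {"chain": t.chain, "resnum": t.resnum, "atom": t.atom_name, "bw": t.bw}
            for t in spec.tethers
        ],
        "restraints": [
            {"chain": r.chain, "resnum": r.resnum, "bw": r.bw,
             "atoms": list(r.atoms), "partner": r.partner,
             "min": r.dmin, "max": r.dmax, "weight": r.weight}
            for r in spec.restraints
        ],
        "sampling": {
            "pre_minimization_steps": spec.pre_minimization_steps,
            "global_steps": spec.global_steps,
        },
        "seed_segments": [
            {"chain": c, "start": lo, "end": hi} for c, lo, hi in spec.seed_segments
        ],
    }
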