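"""Seeded synthetic data: screening libraries, pose-score tables, helix bundles.

The generator stands in for proprietary docking output so every pipeline
stage is testable end to end. It emulates three phenomena of retrospective
GPCR antagonist screening:

* **Chemotype structure** — compounds fall into a few structurally related
  families; fingerprints are per-chemotype bit templates with per-compound
  bit flips, so within-chemotype Tanimoto similarity far exceeds
  between-chemotype similarity, and decoys carry property vectors drawn
  from the actives' matching windows.
* **Induced fit** — each receptor conformer recognizes native poses of its
  cognate chemotype best. A compatibility matrix ``C[chemotype, conformer]``
  in [0, 1] attenuates the native-pose signal on non-cognate conformers.
* **Scorer tolerance** — each named scorer has a compatibility sensitivity
  λ ∈ [0, 1]. A strict, physics-like scorer (high λ) loses most of the
  native signal on incompatible conformers; a tolerant, AI-like scorer
  (low λ) retains it.

The native-pose score of an active of chemotype *k* docked to conformer
*j* under scorer *s* is

    −(α · pactivity · (1 − λ_s · (1 − C[k, j])) + β) + ε,   ε ~ N(0, σ²)

with α = 2, β = 5, σ = 1 by default. All other poses — non-native poses of
actives, and every pose of inactives and decoys — are drawn from a
background N(−8, 3) truncated so no background score beats the theoretical
native optimum. Defaults put single-conformer AUCs in a ~50–100% dynamic
range rather than saturating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import RetroscreenError
from .geometry import AnnotatedStructure, Atom
from .library import ActivityRecord, CompoundRecord, ScreeningLibrary
from .decoys import PropertyVector
from .schemes import PoseScoreTable

__all__ = ["SyntheticConfig", "SyntheticTruth", "gen_library", "gen_pose_scores",
           "gen_helix_bundle", "make_toy_complex"]

_FP_NBITS = 2048
_TEMPLATE_BITS = 120  # on-bits per chemotype template
_KEEP_PROB = 0.9  # per-compound retention of template bits
_NOISE_BITS = 12  # per-compound random extra bits


def _identity_dominant(n: int, off: float = 0.2) -> np.ndarray:
    C = np.full((n, n), off)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic screening benchmark."""

    n_chemotypes: int = 3
    actives_per_chemotype: int = 30
    n_inactives: int = 30
    decoy_pool_size: int = 600  # 20 × actives_per_chemotype
    n_conformers: int = 3
    compatibility: Optional[np.ndarray] = None  # C[chemotype, conformer] ∈ [0,1]
    active_pactivity_range: tuple[float, float] = (7.5, 10.5)
    inactive_pactivity_range: tuple[float, float] = (4.0, 7.0)
    poses_per_pair: int = 10
    scorers: tuple[tuple[str, float], ...] = (("physics", 0.9), ("neural", 0.2))
    alpha: float = 2.0
    beta: float = 5.0
    noise_sd: float = 1.0
    background_mean: float = -8.0
    background_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.compatibility is None:
            n = max(self.n_chemotypes, self.n_conformers)
            self.compatibility = _identity_dominant(n)[
                : self.n_chemotypes, : self.n_conformers
            ]
        self.compatibility = np.asarray(self.compatibility, dtype=float)
        if self.compatibility.shape != (self.n_chemotypes, self.n_conformers):
            raise RetroscreenError(
                f"compatibility shape {self.compatibility.shape} != "
                f"({self.n_chemotypes}, {self.n_conformers})"
            )
        if ((self.compatibility < 0) | (self.compatibility > 1)).any():
            raise RetroscreenError("compatibility entries must lie in [0, 1]")
        for n in ("n_chemotypes", "actives_per_chemotype", "n_inactives",
                  "decoy_pool_size", "n_conformers", "poses_per_pair"):
            if getattr(self, n) < 0:
                raise RetroscreenError(f"{n} must be non-negative")

    @property
    def chemotype_names(self) -> list[str]:
        return [f"CT{k + 1}" for k in range(self.n_chemotypes)]

    @property
    def conformer_names(self) -> list[str]:
        return [f"conf{j + 1}" for j in range(self.n_conformers)]

    @property
    def native_optimum(self) -> float:
        """Best achievable native score (no noise, full compatibility)."""
        return -(self.alpha * self.active_pactivity_range[1] + self.beta)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated library and its pose scores."""

    chemotype: dict[str, str] = field(default_factory=dict)
    role: dict[str, str] = field(default_factory=dict)
    pactivity: dict[str, float] = field(default_factory=dict)
    native_pose: dict[tuple[str, str], int] = field(default_factory=dict)


def _chemotype_fingerprint(rng, template: np.ndarray) -> frozenset[int]:
    keep = template[rng.random(len(template)) < _KEEP_PROB]
    noise = rng.integers(0, _FP_NBITS, size=_NOISE_BITS)
    return frozenset(int(b) for b in np.concatenate([keep, noise]))


def _random_fingerprint(rng) -> frozenset[int]:
    return frozenset(
        int(b) for b in rng.choice(_FP_NBITS, size=_TEMPLATE_BITS, replace=False)
    )


def _chemotype_property_base(rng) -> dict:
    return {
        "mw": rng.uniform(350, 500),
        "logp": rng.uniform(2.0, 5.0),
        "hbd": int(rng.integers(1, 3)),
        "hba": int(rng.integers(3, 7)),
        "rotb": int(rng.integers(4, 9)),
        "charge": int(rng.choice([0, 0, 0, 1])),
    }


def _jitter_properties(rng, base: dict) -> PropertyVector:
    return PropertyVector(
        mol_weight=float(base["mw"] + rng.uniform(-20, 20)),
        logp=float(base["logp"] + rng.uniform(-0.5, 0.5)),
        hbd=max(0, base["hbd"] + int(rng.integers(-1, 2))),
        hba=max(0, base["hba"] + int(rng.integers(-1, 2))),
        rotatable_bonds=max(0, base["rotb"] + int(rng.integers(-1, 2))),
        formal_charge=base["charge"],
    )


def gen_library(config: SyntheticConfig) -> tuple[ScreeningLibrary, SyntheticTruth]:
    """Generate a multi-chemotype actives/inactives/decoys library.

    Actives draw pactivity uniformly within the configured active range
    (above the 7.5 cutoff by construction); inactives sit below it; decoys
    carry no activities and property vectors drawn from per-active windows
    so they are matchable by the decoy selector. Fully reproducible from
    ``config.seed``.
    """
    if config.n_chemotypes == 0 and (config.actives_per_chemotype or config.n_inactives):
        raise RetroscreenError("cannot place actives/inactives in 0 chemotypes")
    rng = np.random.default_rng(config.seed)
    templates = [
        rng.choice(_FP_NBITS, size=_TEMPLATE_BITS, replace=False)
        for _ in range(config.n_chemotypes)
    ]
    bases = [_chemotype_property_base(rng) for _ in range(config.n_chemotypes)]
    names = config.chemotype_names

    compounds: list[CompoundRecord] = []
    truth = SyntheticTruth()
    lo, hi = config.active_pactivity_range
    for k, chemo in enumerate(names):
        for i in range(config.actives_per_chemotype):
            cid = f"act_{chemo}_{i + 1:03d}"
            pact = float(rng.uniform(lo, hi))
            compounds.append(
                CompoundRecord(
                    compound_id=cid,
                    chemotype=chemo,
                    role="active",
                    fingerprint=_chemotype_fingerprint(rng, templates[k]),
                    property_vector=_jitter_properties(rng, bases[k]),
                    activities=[
                        ActivityRecord("hCCR2", "orthosteric", "IC50", 10.0 ** (-pact))
                    ],
                )
            )
            truth.chemotype[cid] = chemo
            truth.role[cid] = "active"
            truth.pactivity[cid] = pact

    ilo, ihi = config.inactive_pactivity_range
    for i in range(config.n_inactives):
        k = int(rng.integers(0, config.n_chemotypes)) if config.n_chemotypes else 0
        chemo = names[k]
        cid = f"inact_{chemo}_{i + 1:03d}"
        pact = float(rng.uniform(ilo, ihi))
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                chemotype=chemo,
                role="inactive",
                fingerprint=_chemotype_fingerprint(rng, templates[k]),
                property_vector=_jitter_properties(rng, bases[k]),
                activities=[
                    ActivityRecord("hCCR2", "orthosteric", "IC50", 10.0 ** (-pact))
                ],
            )
        )
        truth.chemotype[cid] = chemo
        truth.role[cid] = "inactive"
        truth.pactivity[cid] = pact

    actives = [c for c in compounds if c.role == "active"]
    for i in range(config.decoy_pool_size):
        cid = f"dec_{i + 1:04d}"
        if actives:
            a = actives[int(rng.integers(0, len(actives)))]
            pv = a.property_vector
            prop = PropertyVector(
                mol_weight=float(pv.mol_weight + rng.uniform(-25, 25)),
                logp=float(pv.logp + rng.uniform(-1, 1)),
                hbd=max(0, pv.hbd + int(rng.integers(-1, 2))),
                hba=max(0, pv.hba + int(rng.integers(-2, 3))),
                rotatable_bonds=max(0, pv.rotatable_bonds + int(rng.integers(-2, 3))),
                formal_charge=pv.formal_charge,
            )
        else:
            prop = _jitter_properties(rng, _chemotype_property_base(rng))
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                role="decoy",
                fingerprint=_random_fingerprint(rng),
                property_vector=prop,
            )
        )
        truth.role[cid] = "decoy"

    library = ScreeningLibrary(
        compounds=compounds,
        thresholds={c: 7.5 for c in names},
        provenance=f"synthetic(seed={config.seed})",
    )
    return library, truth


def gen_pose_scores(
    config: SyntheticConfig, library: ScreeningLibrary, truth: SyntheticTruth
) -> PoseScoreTable:
    """Generate the pose-score table for a synthetic library.

    ``poses_per_pair`` poses per (compound, conformer); every configured
    scorer is populated; one native pose per (active, conformer) carries
    the compatibility-modulated signal, all other scores are background.
    Deterministic given ``config.seed``.
    """
    if not config.scorers:
        raise RetroscreenError("scorer list must not be empty")
    rng = np.random.default_rng(config.seed + 1)  # independent of library stream
    scorer_names = [s for s, _ in config.scorers]
    lam = {s: l for s, l in config.scorers}
    P = config.poses_per_pair
    conformers = config.conformer_names
    chem_index = {c: k for k, c in enumerate(config.chemotype_names)}

    ids = library.ids
    n_rows = len(ids) * len(conformers) * P
    cols = {
        "compound_id": np.repeat(ids, len(conformers) * P),
        "model_id": np.tile(np.repeat(conformers, P), len(ids)),
        "pose_id": np.tile(np.arange(1, P + 1), len(ids) * len(conformers)),
    }
    bound = config.native_optimum
    data = {}
    for s in scorer_names:
        bg = rng.normal(config.background_mean, config.background_sd, size=n_rows)
        while (bg < bound).any():  # truncate below the theoretical native optimum
            redo = bg < bound
            bg[redo] = rng.normal(config.background_mean, config.background_sd, redo.sum())
        data[s] = bg

    df = pd.DataFrame({**cols, **data})
    # overwrite native poses for actives
    native_rows = []
    for cid in ids:
        if truth.role.get(cid) != "active":
            continue
        k = chem_index[truth.chemotype[cid]]
        pact = truth.pactivity[cid]
        for j, conf in enumerate(conformers):
            key = (cid, conf)
            if key not in truth.native_pose:
                truth.native_pose[key] = int(rng.integers(1, P + 1))
            pose = truth.native_pose[key]
            row = {"compound_id": cid, "model_id": conf, "pose_id": pose}
            for s in scorer_names:
                signal = config.alpha * pact * (
                    1.0 - lam[s] * (1.0 - config.compatibility[k, j])
                ) + config.beta
                row[s] = -signal + rng.normal(0.0, config.noise_sd)
            native_rows.append(row)
    if native_rows:
        nat = pd.DataFrame(native_rows)
        df = df.set_index(["compound_id", "model_id", "pose_id"])
        nat = nat.set_index(["compound_id", "model_id", "pose_id"])
        df.loc[nat.index, scorer_names] = nat[scorer_names]
        df = df.reset_index()
    return PoseScoreTable(df, scorers=scorer_names)


# ---------------------------------------------------------------------------
# idealized helix bundles

_HELIX_RADIUS = 2.3  # Å, Cα radius of an ideal α-helix
_RISE = 1.5  # Å per residue
_TWIST = 100.0  # degrees per residue


def gen_helix_bundle(
    axis_positions: Sequence[tuple[float, float]],
    residues_per_helix: "int | Sequence[int]" = 30,
    rise: float = _RISE,
    twist_deg: float = _TWIST,
    radius: float = _HELIX_RADIUS,
    state_shifts: Optional[dict[int, Sequence[float]]] = None,
    helix_labels: Optional[Sequence[int]] = None,
    bw_start: "int | Sequence[int]" = 20,
    chain: str = "A",
    name: str = "bundle",
    backbone: bool = True,
) -> AnnotatedStructure:
    """Idealized α-helix bundle on vertical axes, with BW-style annotation.

    Each helix is a Cα trace (plus approximate N/C backbone atoms when
    ``backbone`` is true) wound at ``radius`` Å around a z-axis through its
    (x, y) axis position, rising ``rise`` Å and twisting ``twist_deg``° per
    residue; consecutive Cα–Cα separation is ≈3.8 Å at the defaults.
    Helix *h* (1-based index, or ``helix_labels[h-1]``) gets BW numbers
    ``f"{label}.{bw_start + i}"``; ``bw_start`` may be per-helix.
    ``state_shifts`` maps helix index (1-based)
    to a rigid displacement vector, emulating an alternative conformational
    state. Residue numbering is sequential across helices in one chain.
    """
    n_helices = len(axis_positions)
    if n_helices < 1:
        raise RetroscreenError("need at least one helix")
    if isinstance(residues_per_helix, int):
        residues_per_helix = [residues_per_helix] * n_helices
    if helix_labels is None:
        helix_labels = list(range(1, n_helices + 1))
    if isinstance(bw_start, int):
        bw_start = [bw_start] * n_helices
    state_shifts = state_shifts or {}
    seen_axes = set()
    for ax in axis_positions:
        if tuple(ax) in seen_axes:
            import warnings

            warnings.warn(f"overlapping helix axes at {ax}")
        seen_axes.add(tuple(ax))

    atoms: list[Atom] = []
    bw: dict[tuple[str, int], str] = {}
    resnum = 0
    for h, ((ax, ay), n_res, label, start) in enumerate(
        zip(axis_positions, residues_per_helix, helix_labels, bw_start), start=1
    ):
        shift = np.asarray(state_shifts.get(h, (0.0, 0.0, 0.0)), dtype=float)

        def point(t: float) -> np.ndarray:
            theta = math.radians(twist_deg) * t
            return np.array(
                [ax + radius * math.cos(theta), ay + radius * math.sin(theta), rise * t]
            ) + shift

        for i in range(n_res):
            resnum += 1
            bw[(chain, resnum)] = f"{label}.{start + i}"
            if backbone:
                atoms.append(Atom(chain, resnum, "ALA", "N", point(i - 0.35), element="N"))
            atoms.append(Atom(chain, resnum, "ALA", "CA", point(i), element="C"))
            if backbone:
                atoms.append(Atom(chain, resnum, "ALA", "C", point(i + 0.35), element="C"))
    return AnnotatedStructure(atoms=atoms, bw=bw, name=name)


def make_toy_complex(
    bundle_radius: float = 7.0,
    residues_per_helix: int = 30,
    h8_residues: int = 10,
    ligand_z: float = 3.0,
    n_ligand_atoms: int = 4,
) -> AnnotatedStructure:
    """A 7TM + helix-8 bundle with a small ligand near the intracellular side.

    Seven 30-residue helices sit on a circle of radius ``bundle_radius``
    around the z-axis, plus a short helix 8 (BW 8.47+) displaced outward,
    emulating the intracellular amphipathic helix. Per-helix BW numbering
    follows typical receptor spans (TM1 1.30+, TM2 2.37+, TM3 3.25+,
    TM7 7.30+), so every tether/restraint anchor needed by both
    induced-fit modes is annotated (1.39, 2.53–2.63, 3.32, 7.36–7.44,
    8.49/8.50). A
    ligand of ``n_ligand_atoms`` dummy atoms sits on the bundle axis at
    ``z = ligand_z``; with the default geometry, residue-level selection at
    the 5.5 Å proximity cutoff yields several 1–5 residue seed segments.
    """
    axes = [
        (
            bundle_radius * math.cos(2 * math.pi * h / 7.0),
            bundle_radius * math.sin(2 * math.pi * h / 7.0),
        )
        for h in range(7)
    ]
    # helix 8 runs near the membrane-proximal end of TM7, shifted outward
    axes.append((bundle_radius + 4.0, 2.0))
    st = gen_helix_bundle(
        axis_positions=axes,
        residues_per_helix=[residues_per_helix] * 7 + [h8_residues],
        helix_labels=[1, 2, 3, 4, 5, 6, 7, 8],
        bw_start=[30, 37, 25, 30, 30, 30, 30, 47],
        name="toy_complex",
    )
    # ligand atoms clustered on the bundle axis
    lig_idx = []
    for i in range(n_ligand_atoms):
        st.atoms.append(
            Atom(
                chain="L", resnum=1, resname="LIG", name=f"C{i + 1}",
                xyz=np.array([0.6 * (i % 2), 0.6 * (i // 2), ligand_z + 0.8 * i]),
                element="C",
            )
        )
        lig_idx.append(len(st.atoms) - 1)
    st.ligands["LIG"] = lig_idx
    return st
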