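"""Geometric hydrogen-bond detection and occupancy aggregation.

A bond is recorded when the donor--acceptor distance is within the cutoff
(default 3.5 A, inclusive) and the angle at the donor between the D->H and
D->A vectors is within the angular cutoff (default 30 deg, inclusive) —
the convention under which those cutoff values are standard in MD H-bond
analysis.  Donors and acceptors are N/O/S; a donor must carry an explicit
covalently attached hydrogen (same residue, D-H < 1.25 A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import AtomSelection, StructureModel, TrajectoryEnsemble

__all__ = [
    "HBondCriterion",
    "HBondRecord",
    "OccupancyTable",
    "detect_hbonds",
    "hbond_count_series",
    "occupancy_table",
]

DONOR_ACCEPTOR_ELEMENTS = {"N", "O", "S"}
MAX_DH_BOND = 1.25  # A, covalent D-H attachment cutoff


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric criterion; both cutoffs are inclusive.

    ``angle_def`` selects the angular convention: ``"donor"`` is the angle
    at the donor between D->H and D->A; ``"dha"`` interprets ``max_angle``
    as the allowed deviation of the D-H...A angle from linearity (180 deg).
    """

    max_da_distance: float = 3.5  # A
    max_angle: float = 30.0  # degrees
    angle_def: str = "donor"

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.max_angle < 90:
            raise ValueError("angle cutoff must lie in (0, 90) degrees")
        if self.angle_def not in ("donor", "dha"):
            raise ValueError(f"unknown angle_def {self.angle_def!r}")


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor: int  # atom index
    hydrogen: int
    acceptor: int
    da_distance: float  # A
    angle: float  # degrees, per the criterion's convention


@dataclass
class OccupancyTable:
    """Per-residue H-bond occupancy versus a partner group."""

    rows: pd.DataFrame  # columns: residue, residue_index, occupancy
    n_frames: int

    @property
    def nonzero(self) -> pd.DataFrame:
        return self.rows[self.rows["occupancy"] > 0].reset_index(drop=True)


def _donor_hydrogen_pairs(model: StructureModel, coords: np.ndarray,
                          selection: AtomSelection) -> tuple[list[tuple[int, int]], int]:
    """(donor, hydrogen) atom-index pairs; also counts H-less candidates."""
    hydrogens_by_res: dict[int, list[int]] = {}
    for i, atom in enumerate(model.atoms):
        if atom.element == "H":
            hydrogens_by_res.setdefault(atom.residue_index, []).append(i)
    pairs: list[tuple[int, int]] = []
    missing = 0
    for i in selection.indices:
        atom = model.atoms[i]
        if atom.element not in DONOR_ACCEPTOR_ELEMENTS:
            continue
        attached = [
            h for h in hydrogens_by_res.get(atom.residue_index, [])
            if np.linalg.norm(coords[h] - coords[i]) < MAX_DH_BOND
        ]
        if attached:
            pairs.extend((i, h) for h in attached)
        else:
            missing += 1
    return pairs, missing


def detect_hbonds(model: StructureModel, coords: np.ndarray,
                  donors_from: AtomSelection, acceptors_from: AtomSelection,
                  criterion: HBondCriterion = HBondCriterion(),
                  frame: int = 0, allow_intra: bool = False) -> list[HBondRecord]:
    """Detect hydrogen bonds in one coordinate frame.

    Every satisfying (donor, hydrogen, acceptor) triple is reported exactly
    once.  Donors without an attached hydrogen are skipped (counted in a
    warning); a structure without any explicit hydrogens raises.
    """
    coords = np.asarray(coords, dtype=float)
    if not any(a.element == "H" for a in model.atoms):
        raise ValueError(
            "structure contains no explicit hydrogens; protonate the model "
            "before hydrogen-bond analysis"
        )
    dh_pairs, missing = _donor_hydrogen_pairs(model, coords, donors_from)
    if missing:
        warnings.warn(f"{missing} donor candidate(s) without an attached "
                      "hydrogen were skipped")
    acceptors = [i for i in acceptors_from.indices
                 if model.atoms[i].element in DONOR_ACCEPTOR_ELEMENTS]
    records: list[HBondRecord] = []
    for d, h in dh_pairs:
        for a in acceptors:
            if a == d or a == h:
                continue
            if not allow_intra and \
                    model.atoms[a].residue_index == model.atoms[d].residue_index:
                continue
            da = coords[a] - coords[d]
            dist = float(np.linalg.norm(da))
            if dist > criterion.max_da_distance or dist == 0.0:
                continue
            if criterion.angle_def == "donor":
                dh = coords[h] - coords[d]
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * dist)
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            else:  # deviation of D-H...A from linearity
                hd = coords[d] - coords[h]
                ha = coords[a] - coords[h]
                denom = np.linalg.norm(hd) * np.linalg.norm(ha)
                if denom == 0.0:
                    continue
                cosang = np.dot(hd, ha) / denom
                dha = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                angle = 180.0 - dha
            if angle <= criterion.max_angle:
                records.append(HBondRecord(frame=frame, donor=int(d),
                                           hydrogen=int(h), acceptor=int(a),
                                           da_distance=dist, angle=angle))
    return records


def _cross_group_records(model: StructureModel, coords: np.ndarray,
                         group_a: AtomSelection, group_b: AtomSelection,
                         criterion: HBondCriterion, frame: int
                         ) -> list[HBondRecord]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = detect_hbonds(model, coords, group_a, group_b, criterion, frame)
        rec += detect_hbonds(model, coords, group_b, group_a, criterion, frame)
    seen = set()
    out = []
    for r in rec:
        key = (r.donor, r.hydrogen, r.acceptor)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def hbond_count_series(ensemble: TrajectoryEnsemble, group_a: AtomSelection,
                       group_b: AtomSelection,
                       criterion: HBondCriterion = HBondCriterion()) -> np.ndarray:
    """Per-frame count of distinct H-bonds between two disjoint groups."""
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise ValueError("groups overlap; they must be disjoint")
    counts = np.zeros(ensemble.n_frames, dtype=int)
    for f in range(ensemble.n_frames):
        counts[f] = len(_cross_group_records(
            ensemble.topology, ensemble.frames[f], group_a, group_b,
            criterion, f))
    return counts


def occupancy_table(ensemble: TrajectoryEnsemble, group_residues: AtomSelection,
                    group_partner: AtomSelection,
                    criterion: HBondCriterion = HBondCriterion()) -> OccupancyTable:
    """Fraction of frames in which each residue of ``group_residues`` forms
    at least one H-bond with the partner group.

    Rows are sorted by descending occupancy (ties: residue order).
    """
    if ensemble.n_frames == 0:
        raise ValueError("ensemble has zero frames")
    if np.intersect1d(group_residues.indices, group_partner.indices).size:
        raise ValueError("groups overlap; they must be disjoint")
    top = ensemble.topology
    atom_res = np.array([a.residue_index for a in top.atoms])
    group_res_ids = sorted({int(atom_res[i]) for i in group_residues.indices})
    bonded_frames: dict[int, set[int]] = {r: set() for r in group_res_ids}
    for f in range(ensemble.n_frames):
        for r in _cross_group_records(top, ensemble.frames[f], group_residues,
                                      group_partner, criterion, f):
            for atom in (r.donor, r.acceptor):
                rid = int(atom_res[atom])
                if rid in bonded_frames:
                    bonded_frames[rid].add(f)
    res_by_index = {res.index: res for res in top.residues}
    rows = pd.DataFrame({
        "residue": [res_by_index[r].label for r in group_res_ids],
        "residue_index": group_res_ids,
        "occupancy": [len(bonded_frames[r]) / ensemble.n_frames
                      for r in group_res_ids],
    })
    rows = rows.sort_values("occupancy", ascending=False,
                            kind="stable").reset_index(drop=True)
    return OccupancyTable(rows=rows, n_frames=ensemble.n_frames)
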