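"""Ensemble stability metrics: superposed RMSD, per-residue RMSF, SASA.

RMSD/RMSF operate on least-squares rigid-body superposed coordinates
(SVD-based optimal rotation with a reflection guard).  SASA uses
Shrake–Rupley sphere sampling on a deterministic golden-spiral point set
and reports nm^2, matching the convention of MD analysis tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AtomSelection, StructureModel, TrajectoryEnsemble

__all__ = [
    "RMSDSeries",
    "RMSFTable",
    "SASASeries",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "superpose_ensemble",
    "rmsf_table",
    "sasa_series",
    "VDW_RADII_NM",
]

#: van der Waals radii in nm used by the SASA calculator.
VDW_RADII_NM = {"C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18, "H": 0.12,
                "P": 0.18, "F": 0.147, "CL": 0.175, "BR": 0.185}

ANGSTROM_PER_NM = 10.0


@dataclass
class RMSDSeries:
    times: np.ndarray  # ps
    values: np.ndarray  # Angstrom
    reference_label: str = ""
    selection_label: str = ""


@dataclass
class RMSFTable:
    residue_labels: list[str]
    residue_indices: np.ndarray
    values: np.ndarray  # Angstrom


@dataclass
class SASASeries:
    times: np.ndarray  # ps
    values: np.ndarray  # nm^2
    probe_radius: float = 0.14  # nm


# ---------------------------------------------------------------------------
# rigid-body superposition


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: AtomSelection | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation least-squares fit of ``mobile`` onto
    ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD over the
    selected atoms.  The rotation is guarded against reflections
    (det = +1 always).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference shapes differ")
    idx = selection.indices if selection is not None else np.arange(len(mobile))
    if len(idx) < 3:
        raise ValueError("superposition requires at least 3 selected atoms")
    p = mobile[idx]
    q = reference[idx]
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    p0 = p - pc
    q0 = q - qc
    if np.linalg.matrix_rank(q0, tol=1e-8) < 2:
        raise ValueError("selected reference atoms are collinear")
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    fitted = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def superpose_ensemble(ensemble: TrajectoryEnsemble, selection: AtomSelection,
                       n_iter: int = 3) -> np.ndarray:
    """Superpose every frame onto the iteratively refined mean structure.

    Frames are first fitted to frame 0, then the fit-to-mean cycle
    (fit -> recompute mean -> refit) is run ``n_iter`` times.  Returns the
    superposed coordinate array (n_frames, n_atoms, 3).
    """
    if ensemble.n_frames < 2:
        raise ValueError("at least 2 frames required")
    frames = ensemble.frames.copy()
    ref = frames[0]
    for i in range(ensemble.n_frames):
        rot, trans, _ = superpose(frames[i], ref, selection)
        frames[i] = apply_transform(frames[i], rot, trans)
    for _ in range(n_iter):
        mean = frames.mean(axis=0)
        for i in range(ensemble.n_frames):
            rot, trans, _ = superpose(frames[i], mean, selection)
            frames[i] = apply_transform(frames[i], rot, trans)
    return frames


# ---------------------------------------------------------------------------
# RMSD / RMSF


def rmsd_series(ensemble: TrajectoryEnsemble, reference_frame: int = 0,
                selection: AtomSelection | None = None) -> RMSDSeries:
    """Per-frame superposed RMSD against a reference frame."""
    if selection is None or len(selection) == 0:
        raise ValueError("a non-empty atom selection is required")
    if not 0 <= reference_frame < ensemble.n_frames:
        raise ValueError(f"reference frame {reference_frame} out of range")
    ref = ensemble.frames[reference_frame]
    values = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        _, _, values[i] = superpose(ensemble.frames[i], ref, selection)
    values[reference_frame] = 0.0
    return RMSDSeries(times=ensemble.times.copy(), values=values,
                      reference_label=f"frame {reference_frame}",
                      selection_label=selection.label)


def rmsf_table(ensemble: TrajectoryEnsemble,
               selection: AtomSelection) -> RMSFTable:
    """Per-residue RMSF of Calpha atoms about the time-average position.

    Frames are superposed onto the iteratively refined mean structure over
    the selection before fluctuations are accumulated.  Residues in the
    selection without a Calpha are omitted with a warning.
    """
    frames = superpose_ensemble(ensemble, selection)
    mean = frames.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))

    top = ensemble.topology
    sel_set = set(selection.indices.tolist())
    labels: list[str] = []
    ridx: list[int] = []
    vals: list[float] = []
    skipped = 0
    for res in top.residues:
        in_sel = [i for i in res.atom_indices if i in sel_set]
        if not in_sel:
            continue
        ca = [i for i in in_sel if top.atoms[i].name == "CA"]
        if not ca:
            skipped += 1
            continue
        labels.append(res.label)
        ridx.append(res.index)
        vals.append(float(per_atom[ca[0]]))
    if skipped:
        warnings.warn(f"{skipped} selected residue(s) lack a CA atom and "
                      "were omitted from the RMSF table")
    return RMSFTable(residue_labels=labels,
                     residue_indices=np.array(ridx, dtype=int),
                     values=np.array(vals))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)


def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(coords_nm: np.ndarray, radii_nm: np.ndarray,
                  probe_radius: float = 0.14, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (nm^2).

    Each atom's accessible sphere (vdW + probe radius) is sampled at
    ``n_points`` golden-spiral points; a point is accessible when outside
    every neighbour's accessible sphere.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for usable quadrature")
    coords_nm = np.asarray(coords_nm, dtype=float)
    n = len(coords_nm)
    sphere = _golden_spiral_points(n_points)
    expanded = radii_nm + probe_radius
    areas = np.empty(n)
    dists = cdist(coords_nm, coords_nm)
    for i in range(n):
        others = np.arange(n) != i
        # an exact duplicate of equal radius occludes all later copies, so a
        # fully overlapping pair contributes the area of a single sphere
        dup = others & (dists[i] < 1e-9) & (expanded == expanded[i])
        if np.flatnonzero(dup).size and np.flatnonzero(dup)[0] < i:
            areas[i] = 0.0
            continue
        neigh = np.flatnonzero(others & ~dup & (dists[i] < expanded[i] + expanded))
        pts = coords_nm[i] + expanded[i] * sphere
        if len(neigh):
            d2 = cdist(pts, coords_nm[neigh], "sqeuclidean")
            # slight shrink keeps points exactly on a neighbour's surface
            # accessible (deterministic boundary rule)
            buried = (d2 < (expanded[neigh] ** 2)[None, :] * (1 - 1e-9)).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


def sasa_series(ensemble: TrajectoryEnsemble, selection: AtomSelection,
                probe_radius: float = 0.14, n_points: int = 960) -> SASASeries:
    """Total SASA of the selected atoms per frame, in nm^2.

    Only selected atoms participate (both as surface and as occluders),
    mirroring selection-restricted SASA in MD analysis tools.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    elements = [ensemble.topology.atoms[i].element.upper()
                for i in selection.indices]
    unknown = sorted({e for e in elements if e not in VDW_RADII_NM})
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {unknown}")
    radii = np.array([VDW_RADII_NM[e] for e in elements])
    values = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        coords_nm = ensemble.frames[f][selection.indices] / ANGSTROM_PER_NM
        values[f] = shrake_rupley(coords_nm, radii, probe_radius, n_points).sum()
    return SASASeries(times=ensemble.times.copy(), values=values,
                      probe_radius=probe_radius)
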