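"""Minimum-energy representative selection and low-energy clustering.

The total conformational energy is an input series aligned to the frames
(two-column time/energy text, xvg-compatible comments tolerated) — energies
come from the MD engine, not from an internal forcefield.  The k lowest-
energy frames are clustered by pairwise superposed RMSD (single linkage);
the representative is the lowest-energy member of the largest cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stability import superpose
from .structure_io import AtomSelection, TrajectoryEnsemble

__all__ = [
    "EnergyProfile",
    "RepresentativeSet",
    "read_energy_file",
    "select_representative",
    "energy_rmsd_scatter",
]


@dataclass
class EnergyProfile:
    times: np.ndarray  # ps
    energy: np.ndarray  # kJ/mol (as supplied)
    label: str = "energy"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.times.shape != self.energy.shape:
            raise ValueError("times and energy must have equal length")
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("energy series contains non-finite values")


@dataclass
class RepresentativeSet:
    lowest_energy_frame: int
    top_k_frames: np.ndarray  # ascending by energy
    cluster_assignment: np.ndarray  # per top-k frame, 0-based cluster ids
    representative_frame: int


def read_energy_file(path, label: str = "energy") -> EnergyProfile:
    """Two-column whitespace text (time_ps, energy); '#'/'@' comments."""
    times, energies = [], []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ValueError(f"bad energy line: {line!r}")
            times.append(float(parts[0]))
            energies.append(float(parts[1]))
    if not times:
        raise ValueError("energy file contains no data rows")
    return EnergyProfile(times=np.array(times), energy=np.array(energies),
                         label=label)


def _pairwise_rmsd(ensemble: TrajectoryEnsemble, frames: np.ndarray,
                   selection: AtomSelection) -> np.ndarray:
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = superpose(ensemble.frames[frames[i]],
                                ensemble.frames[frames[j]], selection)
            mat[i, j] = mat[j, i] = r
    return mat


def select_representative(ensemble: TrajectoryEnsemble, profile: EnergyProfile,
                          selection: AtomSelection, k: int = 20,
                          rmsd_cutoff: float = 2.0) -> RepresentativeSet:
    """Cluster the k lowest-energy frames and pick the representative.

    Single-linkage clusters are cut at ``rmsd_cutoff`` (A).  The
    representative is the lowest-energy member of the largest cluster;
    cluster-size ties go to the cluster containing the global minimum
    (else the one with the lowest-energy member), and energy ties to the
    earliest frame.
    """
    if len(profile.energy) != ensemble.n_frames:
        raise ValueError(
            f"energy series length {len(profile.energy)} does not match "
            f"{ensemble.n_frames} frames"
        )
    if not 1 <= k <= ensemble.n_frames:
        raise ValueError("k must be between 1 and n_frames")
    # stable argsort: energy ties resolve to the earliest frame
    order = np.argsort(profile.energy, kind="stable")
    top_k = order[:k]
    lowest = int(top_k[0])

    if k == 1:
        assignment = np.zeros(1, dtype=int)
    else:
        dmat = _pairwise_rmsd(ensemble, top_k, selection)
        z = linkage(squareform(dmat, checks=False), method="single")
        assignment = fcluster(z, t=rmsd_cutoff, criterion="distance") - 1

    sizes = np.bincount(assignment)
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size)
    if len(candidates) == 1:
        chosen = candidates[0]
    elif assignment[0] in candidates:  # cluster holding the global minimum
        chosen = assignment[0]
    else:
        # lowest-energy member wins; top_k is energy-ordered, so the first
        # occurrence of any candidate cluster decides
        chosen = assignment[np.isin(assignment, candidates).argmax()]
    members = top_k[assignment == chosen]
    rep = int(members[0])  # energy-ordered; ties already time-resolved
    return RepresentativeSet(lowest_energy_frame=lowest,
                             top_k_frames=top_k.astype(int),
                             cluster_assignment=assignment,
                             representative_frame=rep)


def energy_rmsd_scatter(ensemble: TrajectoryEnsemble, profile: EnergyProfile,
                        selection: AtomSelection,
                        reference: int | None = None) -> pd.DataFrame:
    """Per-frame (time, rmsd, energy) table for energy-vs-RMSD scatter.

    RMSD is measured against ``reference`` (default: the lowest-energy
    frame).
    """
    if len(profile.energy) != ensemble.n_frames:
        raise ValueError("energy series length does not match frame count")
    if reference is None:
        reference = int(np.argsort(profile.energy, kind="stable")[0])
    ref = ensemble.frames[reference]
    rmsds = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        _, _, rmsds[i] = superpose(ensemble.frames[i], ref, selection)
    rmsds[reference] = 0.0
    return pd.DataFrame({
        "time_ps": ensemble.times,
        "rmsd_A": rmsds,
        profile.label: profile.energy,
    })
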