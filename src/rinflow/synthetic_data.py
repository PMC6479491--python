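"""Synthetic ensembles and graphs with known, parameterized properties.

The generator emulates the statistical structure the analysis stages
assume in real trajectories — per-residue fluctuation amplitudes, residue
pairs held in hydrogen-bond geometry at a target occupancy, a dominant
collective motion, and a hub residue bridging two spatial clusters — on an
idealized extended polypeptide backbone (bond lengths N-CA 1.46, CA-C
1.52, C-O 1.23, C-N 1.33 A).  Amide hydrogens are placed explicitly so
the H-bond detector needs no inference.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .representative import EnergyProfile
from .structure_io import Atom, StructureModel, TrajectoryEnsemble

__all__ = [
    "HBondPairSpec",
    "CollectiveMode",
    "HubSpec",
    "EnsembleSpec",
    "generate_ensemble",
    "collective_mode_field",
    "generate_hub_structure",
    "generate_energy_series",
]

#: Sampling cadence of the emulated trajectories (ps between frames).
DEFAULT_STRIDE_PS = 100.0

# idealized residue template: name -> (element, offset within residue, A);
# CA sits off the N--C axis (|N-CA| = 1.46, |CA-C| = 1.52) and its z sign
# alternates along the chain so Calpha positions are never collinear
_RESIDUE_TEMPLATE = [
    ("N", "N", np.array([0.000, 0.000, 0.000])),
    ("H", "H", np.array([-0.350, 0.950, 0.000])),
    ("CA", "C", np.array([1.340, 0.420, 0.400])),
    ("CB", "C", np.array([1.340, 1.020, 1.800])),
    ("C", "C", np.array([2.745, 0.000, 0.000])),
    ("O", "O", np.array([3.045, -1.193, 0.000])),
]
_ZIGZAG_ATOMS = {"CA", "CB"}
_RESIDUE_PERIOD = 4.075  # A along x; gives C(i)-N(i+1) = 1.33 A

_HB_DISTANCE = 2.9  # D-A distance in designed bonded frames, A
_HB_BROKEN_DISTANCE = 5.5  # strictly outside the criterion (> 4.5 A)
_MIN_ATOM_SEPARATION = 0.5  # A


@dataclass(frozen=True)
class HBondPairSpec:
    """Donor/acceptor residue pair held at a target H-bond occupancy."""

    donor_residue: int  # 0-based residue index (its backbone N-H donates)
    acceptor_residue: int  # its backbone O accepts
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class CollectiveMode:
    """A shared Gaussian-amplitude displacement along one direction field.

    ``direction`` is either a single 3-vector — applied to every atom with
    a Gaussian envelope over the chain so the motion is not a rigid
    translation — or an explicit per-atom (n_atoms, 3) field.  The field's
    rigid-body (translation/rotation) component is projected out and the
    remainder normalized to unit length in the flattened 3N space, so
    superposition cannot remove the designed mode;
    :func:`collective_mode_field` returns this realized unit field.  The
    per-frame coefficient is drawn from N(0, amplitude^2) — Gaussian, not
    sinusoidal, so the mode's projection has low cosine content by
    construction.
    """

    direction: np.ndarray
    amplitude: float  # A (std of the mode coefficient)
    variance_fraction: float | None = None  # target, for documentation


@dataclass(frozen=True)
class HubSpec:
    hub_residue: int
    cluster_a: tuple[int, ...]
    cluster_b: tuple[int, ...]

    def __post_init__(self) -> None:
        a, b = set(self.cluster_a), set(self.cluster_b)
        if a & b or self.hub_residue in a | b:
            raise ValueError("clusters must be disjoint and exclude the hub")


@dataclass
class EnsembleSpec:
    n_residues: int = 20
    n_frames: int = 50
    fluctuation_profile: float | np.ndarray = 0.5  # per-coordinate sd, A
    hbond_pairs: tuple[HBondPairSpec, ...] = ()
    collective_mode: CollectiveMode | None = None
    hub_spec: HubSpec | None = None
    stride_ps: float = DEFAULT_STRIDE_PS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        prof = np.broadcast_to(np.asarray(self.fluctuation_profile, dtype=float),
                               (self.n_residues,))
        if np.any(prof < 0):
            raise ValueError("fluctuation amplitudes must be >= 0")
        self.hbond_pairs = tuple(
            p if isinstance(p, HBondPairSpec) else HBondPairSpec(*p)
            for p in self.hbond_pairs
        )
        for p in self.hbond_pairs:
            for r in (p.donor_residue, p.acceptor_residue):
                if not 0 <= r < self.n_residues:
                    raise ValueError(f"H-bond pair residue {r} out of range")
        acceptors = [p.acceptor_residue for p in self.hbond_pairs]
        if len(set(acceptors)) != len(acceptors):
            raise ValueError("each residue may be the designed acceptor of "
                             "at most one pair")


def _build_chain(n_residues: int) -> StructureModel:
    atoms: list[Atom] = []
    serial = 1
    for r in range(n_residues):
        shift = np.array([r * _RESIDUE_PERIOD, 0.0, 0.0])
        zsign = 1.0 if r % 2 == 0 else -1.0
        for name, element, offset in _RESIDUE_TEMPLATE:
            pos = offset.copy()
            if name in _ZIGZAG_ATOMS:
                pos[2] *= zsign
            atoms.append(Atom(serial=serial, name=name, element=element,
                              residue_index=r, residue_name="ALA",
                              chain_id="A", position=pos + shift,
                              res_seq=r + 1))
            serial += 1
    return StructureModel(atoms)


def _check_separation(coords: np.ndarray) -> None:
    from scipy.spatial.distance import pdist
    if len(coords) > 1 and pdist(coords).min() < _MIN_ATOM_SEPARATION:
        raise ValueError("infeasible geometry: atoms closer than "
                         f"{_MIN_ATOM_SEPARATION} A")


def generate_ensemble(spec: EnsembleSpec) -> TrajectoryEnsemble:
    """Generate a trajectory ensemble with the designed properties.

    Designed H-bond pairs satisfy the 3.5 A / 30 deg criterion exactly in
    ``round(occupancy * n_frames)`` frames (acceptor placed on the donor
    N-H axis at 2.9 A) and fail it by a margin otherwise (5.5 A), so
    occupancy recovery by the detector is exact.
    """
    rng = np.random.default_rng(spec.seed)
    prof = np.broadcast_to(np.asarray(spec.fluctuation_profile, dtype=float),
                           (spec.n_residues,))
    if spec.hub_spec is not None:
        # hub geometry packs residues too tightly for full side chains;
        # the topology degrades to Calpha-only (as in generate_hub_structure)
        if spec.hbond_pairs:
            raise ValueError("hub_spec ensembles are Calpha-only and cannot "
                             "host designed H-bond pairs")
        topology = _hub_ca_model(spec, rng)
        atom_sd = prof[:, None]
    else:
        topology = _build_chain(spec.n_residues)
        atom_sd = np.repeat(prof, len(_RESIDUE_TEMPLATE))[:, None]
    base = topology.coords
    _check_separation(base)
    n_atoms = base.shape[0]

    frames = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        frames[f] = base + rng.normal(0.0, 1.0, (n_atoms, 3)) * atom_sd

    if spec.collective_mode is not None:
        field_ = _realized_mode_field(spec.collective_mode, base)
        coeffs = rng.normal(0.0, spec.collective_mode.amplitude, spec.n_frames)
        frames += coeffs[:, None, None] * field_[None, :, :]

    # designed H-bond geometry overrides noise for the involved atoms
    atom_index = {(a.residue_index, a.name): i
                  for i, a in enumerate(topology.atoms)}
    for pair in spec.hbond_pairs:
        d_idx = atom_index[(pair.donor_residue, "N")]
        h_idx = atom_index[(pair.donor_residue, "H")]
        a_idx = atom_index[(pair.acceptor_residue, "O")]
        m = round(pair.occupancy * spec.n_frames)
        bonded = set(rng.choice(spec.n_frames, size=m, replace=False).tolist())
        for f in range(spec.n_frames):
            frames[f, d_idx] = base[d_idx]
            frames[f, h_idx] = base[h_idx]
            u = frames[f, h_idx] - frames[f, d_idx]
            u /= np.linalg.norm(u)
            dist = _HB_DISTANCE if f in bonded else _HB_BROKEN_DISTANCE
            frames[f, a_idx] = frames[f, d_idx] + dist * u

    times = np.arange(spec.n_frames, dtype=float) * spec.stride_ps
    return TrajectoryEnsemble(topology=topology, frames=frames, times=times)


# ---------------------------------------------------------------------------
# collective mode field


def _rigid_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of rigid translations/rotations, 3N space."""
    n = len(base)
    vecs = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        vecs.append(t.ravel())
    centered = base - base.mean(axis=0)
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        vecs.append(np.cross(np.tile(e, (n, 1)), centered).ravel())
    q, r = np.linalg.qr(np.array(vecs).T)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep].T


def _realized_mode_field(mode: CollectiveMode, base: np.ndarray) -> np.ndarray:
    n_atoms = len(base)
    direction = np.asarray(mode.direction, dtype=float)
    if direction.shape == (3,):
        # Gaussian envelope along the chain: a uniform vector alone would
        # be a rigid translation, invisible after superposition
        idx = np.arange(n_atoms, dtype=float)
        env = np.exp(-0.5 * ((idx - (n_atoms - 1) / 2) / (n_atoms / 6.0)) ** 2)
        field_ = env[:, None] * direction[None, :]
    elif direction.shape == (n_atoms, 3):
        field_ = direction.copy()
    else:
        raise ValueError("collective mode direction must be (3,) or (n_atoms, 3)")
    flat = field_.ravel()
    rigid = _rigid_basis(base)
    flat = flat - rigid.T @ (rigid @ flat)
    norm = np.linalg.norm(flat)
    if norm < 1e-8:
        raise ValueError("collective mode direction is purely rigid-body "
                         "motion and would vanish under superposition")
    return (flat / norm).reshape(n_atoms, 3)


def collective_mode_field(spec: EnsembleSpec) -> np.ndarray:
    """The realized unit mode field (n_atoms, 3) for a spec's ensemble.

    This is the direction the covariance PC1 recovers when the mode
    amplitude dominates the noise.
    """
    if spec.collective_mode is None:
        raise ValueError("spec has no collective mode")
    rng = np.random.default_rng(spec.seed)
    if spec.hub_spec is not None:
        base = _hub_ca_model(spec, rng).coords
    else:
        base = _build_chain(spec.n_residues).coords
    return _realized_mode_field(spec.collective_mode, base)


# ---------------------------------------------------------------------------
# hub fixture


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return radius * np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _hub_layout(n_per_cluster: int, rng: np.random.Generator) -> np.ndarray:
    """Calpha positions: cluster A (gateway first), hub, cluster B.

    Intra-cluster pairwise distances stay below 7 A (each cluster is a
    clique at the contact cutoff), inter-cluster distances exceed 12 A
    (no direct cluster-cluster contact is geometrically possible while the
    hub touches both), and the hub lies within 7 A of each gateway.
    """
    if n_per_cluster < 3:
        raise ValueError("n_per_cluster must be >= 3")
    gateway = np.array([6.2, 0.0, 0.0])
    blob = _fibonacci_sphere(n_per_cluster - 1, radius=2.2) + \
        np.array([8.8, 0.0, 0.0])
    cluster = np.vstack([gateway, blob])
    jitter = rng.uniform(-0.1, 0.1, size=(2 * n_per_cluster + 1, 3))
    pts = np.vstack([-cluster, np.zeros(3), cluster])  # A, hub, B
    return pts + jitter


def generate_hub_structure(n_per_cluster: int, seed: int = 0) -> StructureModel:
    """Calpha-only model of two clusters bridged by a single hub residue.

    Residue order: cluster A (0 .. n-1), hub (index ``n_per_cluster``),
    cluster B.  At a 7 A contact cutoff the hub is the unique articulation
    point of the resulting network and attains the maximal betweenness.
    """
    rng = np.random.default_rng(seed)
    pts = _hub_layout(n_per_cluster, rng)
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", residue_index=i,
             residue_name="GLY", chain_id="A", position=pts[i], res_seq=i + 1)
        for i in range(len(pts))
    ]
    model = StructureModel(atoms)
    _check_separation(pts)
    return model


# ---------------------------------------------------------------------------
# energy fixture


def generate_energy_series(n_frames: int, minimum_at: int, seed: int = 0,
                           baseline: float = -5.0e4, noise_sd: float = 50.0,
                           stride_ps: float = DEFAULT_STRIDE_PS) -> EnergyProfile:
    """Noisy total-energy series with a unique designed global minimum.

    The value at ``minimum_at`` undercuts every other frame by at least
    one energy unit.
    """
    if not 0 <= minimum_at < n_frames:
        raise ValueError("minimum_at out of range")
    rng = np.random.default_rng(seed)
    energy = baseline + rng.normal(0.0, noise_sd, n_frames)
    others = np.delete(energy, minimum_at)
    energy[minimum_at] = others.min() - 1.5
    times = np.arange(n_frames, dtype=float) * stride_ps
    return EnergyProfile(times=times, energy=energy, label="energy_kJ_mol")


def _hub_ca_model(spec: EnsembleSpec, rng: np.random.Generator) -> StructureModel:
    """Calpha-only model whose residues follow the hub layout of the spec."""
    hub = spec.hub_spec
    assert hub is not None
    if len(hub.cluster_a) != len(hub.cluster_b):
        raise ValueError("hub clusters must have equal size")
    members = list(hub.cluster_a) + [hub.hub_residue] + list(hub.cluster_b)
    if any(not 0 <= r < spec.n_residues for r in members):
        raise ValueError("hub spec residue index out of range")
    pts = _hub_layout(len(hub.cluster_a), rng)
    positions = np.zeros((spec.n_residues, 3))
    for target, res_idx in zip(pts, members):
        positions[res_idx] = target
    leftover = [r for r in range(spec.n_residues) if r not in set(members)]
    for i, res_idx in enumerate(leftover):
        # park unassigned residues on a remote line so they cannot contact
        positions[res_idx] = np.array([40.0 + 8.0 * i, 0.0, 0.0])
    atoms = [
        Atom(serial=r + 1, name="CA", element="C", residue_index=r,
             residue_name="GLY", chain_id="A", position=positions[r],
             res_seq=r + 1)
        for r in range(spec.n_residues)
    ]
    return StructureModel(atoms)
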