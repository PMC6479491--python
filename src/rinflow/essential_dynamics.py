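"""Essential dynamics: covariance eigen-analysis of a superposed ensemble,
PC projections, cosine content, and 2-D free-energy landscapes.

The covariance matrix of the 3M-dimensional selected-coordinate vector is
accumulated after iterative superposition onto the mean structure, so rigid
translation/rotation does not contribute.  Eigenvalues are reported in nm^2
(population normalization, 1/N), matching the convention of MD covariance
tools; the projection variance along eigenvector i then equals the i-th
eigenvalue exactly.

The free-energy landscape is the Boltzmann inversion of the 2-D projection
histogram, dG = -kB * T * ln(n / n_max), so the most populated bin sits at
dG = 0 and empty bins are masked (NaN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stability import superpose_ensemble
from .structure_io import AtomSelection, TrajectoryEnsemble

__all__ = [
    "KB_KJ_PER_MOL_K",
    "EssentialDynamicsModel",
    "ProjectionSeries",
    "FreeEnergySurface",
    "fit_essential_dynamics",
    "project",
    "cosine_content",
    "free_energy_surface",
    "locate_minimum_frames",
]

#: Boltzmann constant in kJ mol^-1 K^-1.
KB_KJ_PER_MOL_K = 0.0083145

ANGSTROM_PER_NM = 10.0


@dataclass
class EssentialDynamicsModel:
    mean_coordinates: np.ndarray  # (M, 3), Angstrom, superposed mean
    eigenvalues: np.ndarray  # descending, nm^2
    eigenvectors: np.ndarray  # (3M, 3M); row i = eigenvector i
    selection: AtomSelection
    selection_label: str = ""
    fit_selection: AtomSelection | None = None  # superposition atoms

    def cumulative_variance(self) -> np.ndarray:
        """Cumulative variance fraction captured by the first k modes."""
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return np.cumsum(self.eigenvalues) / total


@dataclass
class ProjectionSeries:
    times: np.ndarray  # ps
    coordinates: np.ndarray  # (n_frames, k), nm

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class FreeEnergySurface:
    pc_pair: tuple[int, int]  # 1-based PC indices
    edges_x: np.ndarray
    edges_y: np.ndarray
    counts: np.ndarray  # (n_bins, n_bins) integers
    delta_g: np.ndarray  # kJ/mol; NaN on empty bins
    temperature: float  # K


def fit_essential_dynamics(ensemble: TrajectoryEnsemble,
                           selection: AtomSelection,
                           fit_selection: AtomSelection | None = None
                           ) -> EssentialDynamicsModel:
    """Diagonalize the coordinate covariance of the superposed ensemble.

    ``fit_selection`` optionally names the atoms used for the rigid-body
    superposition (default: the analyzed selection itself), the usual way
    to keep a localized motion of interest out of the fit.
    """
    if ensemble.n_frames < 2:
        raise ValueError("at least 2 frames required")
    if len(selection) == 0 or len(selection) > ensemble.n_atoms:
        raise ValueError("selection empty or larger than the frame atom count")
    frames = superpose_ensemble(ensemble, fit_selection or selection)
    x = frames[:, selection.indices, :] / ANGSTROM_PER_NM  # nm
    n_frames, m, _ = x.shape
    flat = x.reshape(n_frames, 3 * m)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are eigenvectors
    return EssentialDynamicsModel(
        mean_coordinates=mean.reshape(m, 3) * ANGSTROM_PER_NM,
        eigenvalues=evals,
        eigenvectors=evecs,
        selection=selection,
        selection_label=selection.label,
        fit_selection=fit_selection,
    )


def project(ensemble: TrajectoryEnsemble, model: EssentialDynamicsModel,
            k: int) -> ProjectionSeries:
    """Project superposed, mean-removed coordinates onto the first k modes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(model.eigenvalues):
        raise ValueError("k exceeds the number of eigenvectors")
    frames = superpose_ensemble(ensemble, model.fit_selection or model.selection)
    x = frames[:, model.selection.indices, :] / ANGSTROM_PER_NM
    flat = x.reshape(ensemble.n_frames, -1)
    mean = (model.mean_coordinates / ANGSTROM_PER_NM).reshape(-1)
    proj = (flat - mean) @ model.eigenvectors[:k].T
    return ProjectionSeries(times=ensemble.times.copy(), coordinates=proj)


def cosine_content(series: ProjectionSeries, i: int = 1) -> float:
    """Cosine content of the i-th projection (1-based).

    c_i = (2/T) * (int cos(i*pi*t/T) p_i(t) dt)^2 / int p_i(t)^2 dt,
    evaluated by trapezoidal quadrature on the frame time grid.  Values
    near 1 indicate random-diffusion-like sampling.
    """
    if series.n_frames < 4:
        raise ValueError("at least 4 frames required for cosine content")
    if not 1 <= i <= series.coordinates.shape[1]:
        raise ValueError(f"projection index {i} out of range")
    p = series.coordinates[:, i - 1]
    t = series.times - series.times[0]
    big_t = t[-1]
    denom = np.trapezoid(p * p, t)
    if denom == 0.0:
        warnings.warn("all-zero projection; cosine content defined as 0")
        return 0.0
    num = np.trapezoid(np.cos(i * np.pi * t / big_t) * p, t)
    return float((2.0 / big_t) * num * num / denom)


def free_energy_surface(series: ProjectionSeries, pc_pair: tuple[int, int] = (1, 2),
                        n_bins: int = 32, temperature: float = 300.0,
                        cosine_threshold: float = 0.2,
                        force: bool = False) -> FreeEnergySurface:
    """Boltzmann-inverted 2-D histogram over a pair of PC projections.

    Unless ``force`` is given, both projections must have cosine content
    at or below ``cosine_threshold`` — the admissibility rule that keeps a
    landscape from being built on drift-like (cosine-shaped) modes.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    a, b = pc_pair
    if not force:
        for idx in (a, b):
            c = cosine_content(series, idx)
            if c > cosine_threshold:
                raise ValueError(
                    f"cosine content of PC{idx} is {c:.3f} > "
                    f"{cosine_threshold}; landscape not admissible "
                    "(use force=True to override)"
                )
    px = series.coordinates[:, a - 1]
    py = series.coordinates[:, b - 1]
    edges_x = _edges_with_margin(px, n_bins)
    edges_y = _edges_with_margin(py, n_bins)
    counts, _, _ = np.histogram2d(px, py, bins=[edges_x, edges_y])
    counts = counts.astype(int)
    nmax = counts.max()
    with np.errstate(divide="ignore"):
        delta_g = -KB_KJ_PER_MOL_K * temperature * np.log(
            np.where(counts > 0, counts, np.nan) / nmax
        )
    return FreeEnergySurface(pc_pair=(a, b), edges_x=edges_x, edges_y=edges_y,
                             counts=counts, delta_g=delta_g,
                             temperature=temperature)


def _edges_with_margin(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo
    if span == 0.0:
        span = 1e-6
    width = span / (n_bins - 1)
    return np.linspace(lo - width / 2, hi + width / 2, n_bins + 1)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # replicate np.histogram2d assignment (right edge closed on last bin)
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(edges) - 2
    return idx


def locate_minimum_frames(surface: FreeEnergySurface,
                          series: ProjectionSeries) -> np.ndarray:
    """Frame indices falling in the dG = 0 (most populated) bin.

    Ties between equally populated bins resolve to the first bin in scan
    order; returned frames are in time order.
    """
    flat = np.argmax(surface.counts)  # first maximum in C order
    bx, by = np.unravel_index(flat, surface.counts.shape)
    a, b = surface.pc_pair
    ix = _bin_index(series.coordinates[:, a - 1], surface.edges_x)
    iy = _bin_index(series.coordinates[:, b - 1], surface.edges_y)
    return np.flatnonzero((ix == bx) & (iy == by))
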