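"""Essential dynamics: coordinate PCA and free-energy landscapes.

The collective motions of a protein are summarised by diagonalising the
3N × 3N covariance matrix of its Cα coordinates.  The top eigenvectors (the
"essential" subspace) capture the dominant concerted motions; the trace of
the covariance measures the total fluctuation amplitude; and a 2-D histogram
of frame projections onto PC1/PC2 converts, via Boltzmann inversion, into a
Gibbs free-energy landscape whose minima are metastable conformational
sub-states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_metrics import _fitted_coordinates
from .trajectory_io import Selection, Trajectory

__all__ = [
    "CovarianceResult",
    "EigenResult",
    "Projection",
    "FELGrid",
    "BOLTZMANN_KJ_PER_MOL_K",
    "build_covariance",
    "eigendecompose",
    "project_frames",
    "fel_from_projections",
    "fel_minima",
]

BOLTZMANN_KJ_PER_MOL_K = 0.0083144621  # kJ·mol⁻¹·K⁻¹


@dataclass
class CovarianceResult:
    """Population covariance of flattened (3N) selected coordinates, Å²."""

    matrix: np.ndarray  # (3N, 3N)
    mean_structure: np.ndarray  # (3N,)
    n_frames: int
    fitted_coordinates: np.ndarray | None = None  # (M, N, 3), Å

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))


@dataclass
class EigenResult:
    eigenvalues: np.ndarray  # descending, Å²
    eigenvectors: np.ndarray  # orthonormal columns
    trace: float  # Å²

    @property
    def percent_variance(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()

    @property
    def trace_nm2(self) -> float:
        """Trace in nm² (1 nm² = 100 Å²), the conventional reporting unit."""
        return self.trace / 100.0


@dataclass
class Projection:
    times: np.ndarray  # ps
    coordinates: np.ndarray  # (n_frames, k), Å

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))


@dataclass
class FELGrid:
    """Gibbs free-energy surface over (PC1, PC2) bins.

    ``delta_g`` is −k_B·T·ln(P/P_max) per bin, kJ·mol⁻¹; empty bins are
    masked (NaN), never assigned a pseudo-count.
    """

    pc1_edges: np.ndarray
    pc2_edges: np.ndarray
    counts: np.ndarray  # (n1, n2)
    delta_g: np.ndarray  # kJ·mol⁻¹, NaN where empty
    temperature: float  # K

    @property
    def occupied_mask(self) -> np.ndarray:
        return self.counts > 0


def build_covariance(
    traj: Trajectory, selection: Selection, fit: bool = True
) -> CovarianceResult:
    """Covariance (population 1/M divisor) of selected coordinates.

    Frames are two-pass Kabsch-fitted to the mean structure when ``fit``;
    the covariance is unweighted (the selection is one atom per residue, so
    mass weighting would only rescale by a near-constant).
    """
    if len(traj) < 2:
        raise ValueError("covariance is undefined for a single frame")
    coords = _fitted_coordinates(traj, selection, fit)  # (M, N, 3)
    m = coords.shape[0]
    flat = coords.reshape(m, -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / m
    cov = 0.5 * (cov + cov.T)  # kill round-off asymmetry
    return CovarianceResult(cov, mean, m, fitted_coordinates=coords)


def eigendecompose(cov: CovarianceResult) -> EigenResult:
    """Diagonalise the covariance; eigenvalues descending, trace preserved.

    Eigenvector signs are fixed by making each column's largest-magnitude
    component positive, so projections are reproducible across runs.
    """
    vals, vecs = np.linalg.eigh(cov.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for k in range(vecs.shape[1]):
        col = vecs[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            vecs[:, k] = -col
    return EigenResult(vals, vecs, trace=cov.trace)


def project_frames(
    traj: Trajectory,
    selection: Selection,
    eig: EigenResult,
    k: int = 2,
    cov: CovarianceResult | None = None,
    fit: bool = True,
) -> Projection:
    """Project fitted, mean-centred frames onto the first ``k`` eigenvectors.

    Passing the ``cov`` that produced ``eig`` reuses its fitted coordinates
    and mean, guaranteeing the projection is of exactly the centred data the
    eigenvectors describe.
    """
    dim = eig.eigenvectors.shape[0]
    if not 1 <= k <= dim:
        raise ValueError(f"k must be in [1, {dim}]")
    if cov is not None and cov.fitted_coordinates is not None:
        flat = cov.fitted_coordinates.reshape(cov.n_frames, -1)
        mean = cov.mean_structure
    else:
        coords = _fitted_coordinates(traj, selection, fit)
        flat = coords.reshape(coords.shape[0], -1)
        mean = flat.mean(axis=0)
    proj = (flat - mean) @ eig.eigenvectors[:, :k]
    return Projection(traj.times, proj)


def fel_from_projections(
    proj: Projection,
    n_bins: tuple[int, int] = (32, 32),
    temperature: float = 300.0,
    pad_fraction: float = 0.01,
) -> FELGrid:
    """Boltzmann-invert a 2-D histogram of (PC1, PC2) projections.

    ΔG(bin) = −k_B·T·ln(P(bin)/P_max): the most populated bin sits at 0 and
    every occupied bin carries a non-negative free energy.  The grid spans
    the data range padded by ``pad_fraction`` on each side.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    xy = proj.coordinates
    if xy.shape[0] < 1:
        raise ValueError("need at least one frame")
    if xy.shape[1] < 2:
        raise ValueError("need projections on at least two components")
    x, y = xy[:, 0], xy[:, 1]

    def edges(v: np.ndarray, nb: int) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        pad = pad_fraction * span if span > 0 else 0.5
        return np.linspace(lo - pad, hi + pad, nb + 1)

    e1, e2 = edges(x, n_bins[0]), edges(y, n_bins[1])
    counts, _, _ = np.histogram2d(x, y, bins=(e1, e2))
    p = counts / counts.sum()
    dg = np.full_like(p, np.nan)
    occ = counts > 0
    kbt = BOLTZMANN_KJ_PER_MOL_K * temperature
    dg[occ] = -kbt * np.log(p[occ] / p.max()) + 0.0  # +0.0 normalises -0.0
    return FELGrid(e1, e2, counts, dg, temperature)


def fel_minima(grid: FELGrid, proj: Projection) -> list[dict]:
    """Local minima of the landscape and their representative frames.

    A bin is a local minimum when occupied and no occupied 8-neighbour has a
    strictly lower ΔG.  For each minimum the frame nearest the bin centre in
    (PC1, PC2) is reported as the representative conformer.
    """
    dg = grid.delta_g
    n1, n2 = dg.shape
    c1 = 0.5 * (grid.pc1_edges[:-1] + grid.pc1_edges[1:])
    c2 = 0.5 * (grid.pc2_edges[:-1] + grid.pc2_edges[1:])
    minima = []
    for i in range(n1):
        for j in range(n2):
            if not np.isfinite(dg[i, j]):
                continue
            neigh = dg[max(0, i - 1): i + 2, max(0, j - 1): j + 2]
            finite = neigh[np.isfinite(neigh)]
            if np.any(finite < dg[i, j]):
                continue
            centre = np.array([c1[i], c2[j]])
            d = np.linalg.norm(proj.coordinates[:, :2] - centre, axis=1)
            minima.append(
                {
                    "bin": (i, j),
                    "delta_g": float(dg[i, j]),
                    "frame": int(np.argmin(d)),
                    "pc1": float(c1[i]),
                    "pc2": float(c2[j]),
                }
            )
    minima.sort(key=lambda m: m["delta_g"])
    return minima
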