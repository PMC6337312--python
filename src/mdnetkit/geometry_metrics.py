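"""Classical per-trajectory geometry metrics.

RMSD/RMSF/Rg/COM-distance/hydrogen-bond series and gromos conformational
clustering — the standard descriptive statistics computed on a molecular
dynamics ensemble before any network analysis.  All lengths are Å internally;
use ``to_nm`` for reporting in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import Frame, Selection, Trajectory

__all__ = [
    "SeriesMetric",
    "ResidueProfile",
    "ClusterResult",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "rg_series",
    "com_distance_series",
    "hbond_series",
    "gromos_cluster",
    "pairwise_rmsd_matrix",
    "to_nm",
]


def to_nm(values):
    """Convert Å to nm (reporting convenience; internals stay in Å)."""
    return np.asarray(values, dtype=float) / 10.0


@dataclass
class SeriesMetric:
    """A per-frame scalar series (units documented per metric)."""

    times: np.ndarray  # ps
    values: np.ndarray
    name: str = ""
    units: str = "angstrom"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class ResidueProfile:
    """A per-residue scalar profile with optional per-residue SDs.

    Undefined entries (e.g. metrics of fully isolated residues) are NaN and
    additionally listed in ``undefined_mask`` — they are never silent zeros.
    """

    residue_labels: list[tuple[str, int, str]]
    values: np.ndarray
    sd: np.ndarray | None = None
    name: str = ""
    units: str = "angstrom"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_labels) != len(self.values):
            raise ValueError("labels and values must be parallel")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.values.shape:
                raise ValueError("sd must parallel values")

    @property
    def undefined_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ClusterResult:
    """gromos clustering output: frame-index clusters plus their centroids,
    ordered by decreasing size (ties broken by lower centroid index)."""

    clusters: list[set[int]]
    centroids: list[int]

    def labels(self, n_frames: int) -> np.ndarray:
        lab = np.full(n_frames, -1, dtype=int)
        for c, members in enumerate(self.clusters):
            for m in members:
                lab[m] = c
        return lab


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates and the post-fit RMSD (Å).
    The rotation is the Kabsch solution: SVD of the weighted covariance with
    a determinant correction so only proper rotations are returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms of 3-D coordinates")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(mobile),) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    h = (w[:, None] * mob_c).T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    fitted = mob_c @ rot.T + (w[:, None] * reference).sum(axis=0)
    rmsd = float(np.sqrt((w * ((fitted - reference) ** 2).sum(axis=1)).sum()))
    return fitted, rmsd


def _fitted_coordinates(
    traj: Trajectory, selection: Selection, fit: bool
) -> np.ndarray:
    """(n_frames, n_sel, 3) selected coordinates, two-pass fitted to the mean.

    Pass 1 fits every frame to frame 0 and takes the mean structure; pass 2
    refits every frame to that mean.  Shared by RMSF and the covariance
    builder so their cross-identity (sum of squared RMSFs = covariance trace)
    holds exactly.
    """
    coords = traj.coordinates(selection.indices)
    if not fit:
        return coords
    ref = coords[0]
    pass1 = np.stack([kabsch_superpose(x, ref)[0] for x in coords])
    mean = pass1.mean(axis=0)
    return np.stack([kabsch_superpose(x, mean)[0] for x in coords])


# ---------------------------------------------------------------------------
# Series metrics
# ---------------------------------------------------------------------------

def rmsd_series(
    traj: Trajectory,
    reference: Frame,
    selection: Selection,
    fit: bool = True,
) -> SeriesMetric:
    """Per-frame RMSD (Å) over selected atoms, optionally Kabsch-fitted."""
    ref = reference.coordinates[selection.indices]
    vals = []
    for fr in traj.frames:
        x = fr.coordinates[selection.indices]
        if fit:
            _, r = kabsch_superpose(x, ref)
        else:
            r = float(np.sqrt(((x - ref) ** 2).sum(axis=1).mean()))
        vals.append(r)
    return SeriesMetric(traj.times, np.asarray(vals), name="rmsd")


def rmsf_per_residue(
    traj: Trajectory, selection: Selection, fit: bool = True
) -> ResidueProfile:
    """Root-mean-square fluctuation (Å) of each representative atom about its
    mean position, after two-pass fitting to the mean structure when ``fit``."""
    if len(traj) < 2:
        raise ValueError("RMSF is undefined for a single frame")
    coords = _fitted_coordinates(traj, selection, fit)
    mean = coords.mean(axis=0)
    sq = ((coords - mean[None]) ** 2).sum(axis=2).mean(axis=0)
    return ResidueProfile(
        selection.residue_labels, np.sqrt(sq), name="rmsf"
    )


def rg_series(
    traj: Trajectory, selection: Selection, mass_weighted: bool = False
) -> SeriesMetric:
    """Radius of gyration (Å) per frame over the selection."""
    w = selection.mass_array if mass_weighted else np.ones(len(selection))
    if w.sum() == 0:
        raise ValueError("selection carries no mass")
    w = w / w.sum()
    coords = traj.coordinates(selection.indices)
    com = (w[None, :, None] * coords).sum(axis=1, keepdims=True)
    rg = np.sqrt((w[None, :] * ((coords - com) ** 2).sum(axis=2)).sum(axis=1))
    return SeriesMetric(traj.times, rg, name="rg")


def com_distance_series(
    traj: Trajectory,
    selection_a: Selection,
    selection_b: Selection,
    mass_weighted: bool = True,
) -> SeriesMetric:
    """Distance (Å) between the centres of mass of two disjoint selections."""
    if set(selection_a.indices) & set(selection_b.indices):
        raise ValueError("selections overlap")
    if len(selection_a) == 0 or len(selection_b) == 0:
        raise ValueError("both selections must be non-empty")

    def com(sel: Selection) -> np.ndarray:
        w = sel.mass_array if mass_weighted else np.ones(len(sel))
        w = w / w.sum()
        return (w[None, :, None] * traj.coordinates(sel.indices)).sum(axis=1)

    d = np.linalg.norm(com(selection_a) - com(selection_b), axis=1)
    return SeriesMetric(traj.times, d, name="com_distance")


def hbond_series(
    traj: Trajectory,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    r_max: float = 3.5,
    theta_max: float = 30.0,
) -> SeriesMetric:
    """Count hydrogen bonds per frame with the geometric criterion
    |D−A| ≤ ``r_max`` Å and angle(H−D−A) ≤ ``theta_max`` degrees.

    ``donors`` are (donor, hydrogen) atom-index pairs with explicit hydrogen
    positions; ``acceptors`` are atom indices.
    """
    if not donors or not acceptors:
        raise ValueError("need at least one donor pair and one acceptor")
    d_idx = np.asarray([d for d, _ in donors], dtype=int)
    h_idx = np.asarray([h for _, h in donors], dtype=int)
    a_idx = np.asarray(acceptors, dtype=int)
    cos_max = np.cos(np.deg2rad(theta_max))
    counts = []
    for fr in traj.frames:
        xyz = fr.coordinates
        d_pos, h_pos, a_pos = xyz[d_idx], xyz[h_idx], xyz[a_idx]
        da = a_pos[None, :, :] - d_pos[:, None, :]  # (nd, na, 3)
        dist = np.linalg.norm(da, axis=2)
        dh = h_pos - d_pos  # (nd, 3)
        dh_norm = np.linalg.norm(dh, axis=1)
        if np.any(dh_norm == 0):
            raise ValueError("donor and hydrogen coincide; no D-H direction")
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (da * dh[:, None, :]).sum(axis=2) / (
                dist * dh_norm[:, None]
            )
        ok = (dist <= r_max) & (dist > 0) & (cosang >= cos_max)
        # exclude the donor acting as its own acceptor
        same = d_idx[:, None] == a_idx[None, :]
        counts.append(int(np.sum(ok & ~same)))
    return SeriesMetric(traj.times, np.asarray(counts, dtype=float),
                        name="hbonds", units="count")


# ---------------------------------------------------------------------------
# gromos clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(
    traj: Trajectory, selection: Selection, fit: bool = True
) -> np.ndarray:
    """Symmetric frame-pair RMSD matrix (Å) over the selection."""
    coords = traj.coordinates(selection.indices)
    m = len(coords)
    mat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if fit:
                _, r = kabsch_superpose(coords[j], coords[i])
            else:
                r = float(np.sqrt(((coords[j] - coords[i]) ** 2).sum(axis=1).mean()))
            mat[i, j] = mat[j, i] = r
    return mat


def gromos_cluster(distance_matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy neighbour-counting conformational clustering.

    Repeatedly takes the frame with the most neighbours within ``cutoff``
    (ties broken by lowest frame index) as a centroid, removes it and its
    neighbours as one cluster, and recurses on the remainder.  Output
    clusters are ordered by decreasing size, ties by lower centroid index.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    remaining = np.ones(n, dtype=bool)
    clusters: list[set[int]] = []
    centroids: list[int] = []
    adj = d <= cutoff
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = set(np.where(adj[centre] & remaining)[0].tolist())
        members.add(centre)
        clusters.append(members)
        centroids.append(centre)
        remaining[list(members)] = False
    order = sorted(
        range(len(clusters)), key=lambda k: (-len(clusters[k]), centroids[k])
    )
    return ClusterResult(
        clusters=[clusters[k] for k in order],
        centroids=[centroids[k] for k in order],
    )
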