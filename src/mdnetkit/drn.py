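"""Dynamic residue network (DRN) analysis.

A residue interaction network (RIN) is built per trajectory frame: nodes are
residue representative atoms (Cβ, with Cα standing in for glycine) and an
undirected, unweighted edge joins every pair within a distance cutoff
(6.7 Å by convention, inclusive).  Two per-residue metrics are computed on
each frame's graph and then averaged over frames:

* **L**, the average shortest path — the mean hop count from a residue to
  every other reachable residue.  Low L marks residues highly accessible for
  signal propagation.
* **BC**, betweenness centrality — the fraction of all shortest paths
  between residue pairs that pass through a residue, normalised to [0, 1]
  by 2/((N−1)(N−2)).  High BC marks communication bottlenecks.

On top of the averaged profiles the module provides standard-deviation hub
detection (residues beyond mean ± k·SD; conventionally k = 1 below the mean
for L and k = 2 above it for BC), ligand-free-minus-bound difference
profiles, joint min–max normalisation of a free/bound pair onto [0, 1], and
Pearson comparisons between metrics (optionally on inverted values).

Disconnected graphs: L averages over the residue's reachable set only, and
the reachable fraction is recorded per residue; a fully isolated residue has
undefined (NaN) L.  No large constant is ever imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .geometry_metrics import ResidueProfile
from .trajectory_io import Frame, Selection, Trajectory

__all__ = [
    "DEFAULT_CUTOFF",
    "ContactGraph",
    "DRNProfile",
    "HubSet",
    "DeltaProfile",
    "NormalizedPair",
    "build_contact_graph",
    "shortest_path_profile",
    "betweenness_profile",
    "average_profiles",
    "detect_hubs",
    "delta_profile",
    "joint_minmax_normalize",
    "pearson_compare",
    "combine_runs",
]

DEFAULT_CUTOFF = 6.7  # Å, inclusive edge threshold

ContactGraph = nx.Graph  # nodes: integer residue positions, attr "label"


def build_contact_graph(
    frame: Frame,
    selection: Selection,
    cutoff: float = DEFAULT_CUTOFF,
    exclude_backbone_neighbours: bool = False,
) -> ContactGraph:
    """Residue interaction network of one frame.

    Nodes are the selection's residues (integer positions carrying a
    ``label`` attribute); an edge joins residues whose representative atoms
    are within ``cutoff`` Å (inclusive).  With
    ``exclude_backbone_neighbours`` the trivially contacting (i, i±1) pairs
    on the same chain are omitted.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = frame.coordinates[selection.indices]
    n = len(selection)
    g = nx.Graph()
    for i, lab in enumerate(selection.residue_labels):
        g.add_node(i, label=lab)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    ii, jj = np.where(np.triu(d <= cutoff, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        if exclude_backbone_neighbours:
            ci, ri, _ = selection.residue_labels[i]
            cj, rj, _ = selection.residue_labels[j]
            if ci == cj and abs(ri - rj) == 1:
                continue
        g.add_edge(i, j)
    return g


def shortest_path_profile(graph: ContactGraph) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue average shortest path L and reachable fraction.

    L(i) is the sum of hop-count shortest-path lengths from i to every
    reachable node, divided by the number of reachable nodes; the fraction
    of the other N−1 nodes reached is returned alongside.  Isolated nodes
    get NaN.
    """
    n = graph.number_of_nodes()
    L = np.full(n, np.nan)
    reach = np.zeros(n)
    if n < 2:
        return L, reach
    for i in graph.nodes:
        lengths = nx.single_source_shortest_path_length(graph, i)
        n_reach = len(lengths) - 1  # exclude self
        reach[i] = n_reach / (n - 1)
        if n_reach > 0:
            L[i] = sum(lengths.values()) / n_reach
    return L, reach


def betweenness_profile(graph: ContactGraph) -> np.ndarray:
    """Normalised betweenness centrality per residue, in [0, 1].

    Brandes pair-dependency accumulation with fractional credit over equal
    shortest paths, scaled by 2/((N−1)(N−2)); for N < 3 every value is 0.
    """
    n = graph.number_of_nodes()
    if n < 3:
        return np.zeros(n)
    bc = nx.betweenness_centrality(graph, normalized=True)
    return np.asarray([bc[i] for i in range(n)])


def edge_table(graph: ContactGraph, frame_index: int = 0):
    """Contact edges as a DataFrame with columns frame,chain_i,resid_i,
    chain_j,resid_j (CSV-ready edge-list export)."""
    import pandas as pd

    rows = []
    for i, j in sorted(graph.edges):
        ci, ri, _ = graph.nodes[i]["label"]
        cj, rj, _ = graph.nodes[j]["label"]
        rows.append({"frame": frame_index, "chain_i": ci, "resid_i": ri,
                     "chain_j": cj, "resid_j": rj})
    return pd.DataFrame(rows, columns=["frame", "chain_i", "resid_i",
                                       "chain_j", "resid_j"])


@dataclass
class DRNProfile:
    """Frame-averaged L and BC with per-residue sample SDs.

    ``unreachable_fraction`` is 1 − (mean reachable fraction) per residue;
    residues that were isolated in every frame have NaN avg_L.
    """

    residue_labels: list[tuple[str, int, str]]
    avg_L: np.ndarray
    sd_L: np.ndarray
    avg_BC: np.ndarray
    sd_BC: np.ndarray
    n_frames: int
    unreachable_fraction: np.ndarray

    def profile(self, metric: str) -> ResidueProfile:
        """View one metric ('L' or 'BC') as a ResidueProfile."""
        if metric == "L":
            return ResidueProfile(self.residue_labels, self.avg_L,
                                  sd=self.sd_L, name="avg_L", units="hops")
        if metric == "BC":
            return ResidueProfile(self.residue_labels, self.avg_BC,
                                  sd=self.sd_BC, name="avg_BC", units="")
        raise ValueError(f"unknown metric {metric!r}")


def average_profiles(
    traj: Trajectory,
    selection: Selection,
    cutoff: float = DEFAULT_CUTOFF,
    window: Trajectory | None = None,
    exclude_backbone_neighbours: bool = False,
) -> DRNProfile:
    """Frame-averaged DRN profile.

    Computes the per-frame L and BC profiles on ``window`` (default: the
    whole of ``traj``) and returns per-residue means and sample SDs
    (n−1 divisor).  Per-frame NaN L values (isolated residues) are excluded
    from that residue's statistics.
    """
    frames = window if window is not None else traj
    if len(frames) == 0:
        raise ValueError("empty frame window")
    n = len(selection)
    L_rows, bc_rows, reach_rows = [], [], []
    for fr in frames:
        g = build_contact_graph(fr, selection, cutoff, exclude_backbone_neighbours)
        L, reach = shortest_path_profile(g)
        L_rows.append(L)
        bc_rows.append(betweenness_profile(g))
        reach_rows.append(reach)
    L_mat = np.vstack(L_rows)
    bc_mat = np.vstack(bc_rows)
    reach_mat = np.vstack(reach_rows)
    m = L_mat.shape[0]
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        avg_L = np.nanmean(L_mat, axis=0)
        sd_L = np.nanstd(L_mat, axis=0, ddof=1) if m > 1 else np.zeros(n)
    avg_BC = bc_mat.mean(axis=0)
    sd_BC = bc_mat.std(axis=0, ddof=1) if m > 1 else np.zeros(n)
    return DRNProfile(
        residue_labels=list(selection.residue_labels),
        avg_L=avg_L,
        sd_L=sd_L,
        avg_BC=avg_BC,
        sd_BC=sd_BC,
        n_frames=m,
        unreachable_fraction=1.0 - reach_mat.mean(axis=0),
    )


@dataclass
class HubSet:
    """Residues whose metric lies beyond mean ± k·SD."""

    metric: str
    direction: str  # "low" | "high"
    k_sd: float
    threshold: float
    members: list[tuple[str, int, str]]
    member_indices: list[int]


def detect_hubs(
    profile: ResidueProfile | np.ndarray,
    k_sd: float,
    direction: str,
    residue_labels: list[tuple[str, int, str]] | None = None,
    metric: str = "",
) -> HubSet:
    """Flag residues beyond ``mean ± k_sd·SD`` of the profile.

    ``direction="high"`` flags values ≥ mean + k·SD (the BC convention,
    k = 2); ``direction="low"`` flags values ≤ mean − k·SD (the L
    convention, k = 1).  Undefined (NaN) entries are excluded from both the
    statistics and the membership.  Comparisons are inclusive.  A constant
    profile (SD = 0) yields an empty hub set with a warning.
    """
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    if isinstance(profile, ResidueProfile):
        values = profile.values
        labels = profile.residue_labels
        metric = metric or profile.name
    else:
        values = np.asarray(profile, dtype=float)
        labels = residue_labels or [("A", i + 1, "UNK") for i in range(len(values))]
    defined = np.isfinite(values)
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined values")
    v = values[defined]
    mean, sd = float(v.mean()), float(v.std(ddof=1))
    if sd == 0:
        import warnings

        warnings.warn("constant profile: no hubs at any k_sd", stacklevel=2)
    if direction == "high":
        threshold = mean + k_sd * sd
        mask = defined & (values >= threshold) & (sd > 0)
    else:
        threshold = mean - k_sd * sd
        mask = defined & (values <= threshold) & (sd > 0)
    idx = np.where(mask)[0].tolist()
    return HubSet(
        metric=metric,
        direction=direction,
        k_sd=float(k_sd),
        threshold=threshold,
        members=[labels[i] for i in idx],
        member_indices=idx,
    )


@dataclass
class DeltaProfile:
    """Per-residue free − bound metric differences on the common label set."""

    residue_labels: list[tuple[str, int, str]]
    values: np.ndarray
    metric: str
    dropped_free: list[tuple[str, int, str]]
    dropped_bound: list[tuple[str, int, str]]


def delta_profile(
    free: DRNProfile, bound: DRNProfile, metric: str = "L"
) -> DeltaProfile:
    """Ligand-free minus ligand-bound per-residue differences.

    Labels are intersected explicitly (order follows the free profile) and
    dropped labels are reported; a residue undefined on either side has an
    undefined (NaN) delta.
    """
    free_p, bound_p = free.profile(metric), bound.profile(metric)
    bound_map = {lab: bound_p.values[i] for i, lab in enumerate(bound_p.residue_labels)}
    common, deltas = [], []
    for i, lab in enumerate(free_p.residue_labels):
        if lab in bound_map:
            common.append(lab)
            deltas.append(free_p.values[i] - bound_map[lab])
    if not common:
        raise ValueError("free and bound profiles share no residue labels")
    common_set = set(common)
    return DeltaProfile(
        residue_labels=common,
        values=np.asarray(deltas),
        metric=metric,
        dropped_free=[l for l in free_p.residue_labels if l not in common_set],
        dropped_bound=[l for l in bound_p.residue_labels if l not in common_set],
    )


@dataclass
class NormalizedPair:
    """Free/bound value pair rescaled jointly onto [0, 1].

    Z_A = (A − min(A,B)) / (max(A,B) − min(A,B)) and likewise Z_B, with the
    min and max taken over the union of both vectors, so the joint minimum
    maps to 0 and the joint maximum to 1.
    """

    Z_A: np.ndarray
    Z_B: np.ndarray
    joint_min: float
    joint_max: float


def joint_minmax_normalize(A: np.ndarray, B: np.ndarray) -> NormalizedPair:
    """Normalise a ligand-free vector A and ligand-bound vector B onto [0, 1]
    using their joint min and max."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    pool = np.concatenate([A[np.isfinite(A)], B[np.isfinite(B)]])
    if pool.size == 0:
        raise ValueError("no finite values to normalise")
    lo, hi = float(pool.min()), float(pool.max())
    if hi == lo:
        raise ValueError("all values equal across A and B: zero denominator")
    return NormalizedPair((A - lo) / (hi - lo), (B - lo) / (hi - lo), lo, hi)


@dataclass
class PearsonResult:
    r: float
    n_used: int
    n_excluded: int
    transform_x: str
    transform_y: str


def pearson_compare(
    x: np.ndarray,
    y: np.ndarray,
    transform_x: str = "identity",
    transform_y: str = "identity",
) -> PearsonResult:
    """Pearson correlation between two per-residue metric vectors.

    Either vector may be inverted first (``transform="inverse"``, used for
    the L⁻¹-vs-BC and RMSF⁻¹-vs-BC comparisons); residues where an inverse
    hits zero or either value is undefined are excluded and counted.
    """
    def apply(v: np.ndarray, tf: str) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if tf == "identity":
            return v
        if tf == "inverse":
            with np.errstate(divide="ignore"):
                out = np.where(v != 0, 1.0 / v, np.nan)
            return out
        raise ValueError(f"unknown transform {tf!r}")

    tx, ty = apply(x, transform_x), apply(y, transform_y)
    if tx.shape != ty.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(tx) & np.isfinite(ty)
    n_used = int(ok.sum())
    if n_used < 3:
        raise ValueError("fewer than 3 usable residue pairs")
    if tx[ok].std() == 0 or ty[ok].std() == 0:
        raise ValueError("zero variance in a compared vector")
    r, _ = stats.pearsonr(tx[ok], ty[ok])
    return PearsonResult(
        r=float(r),
        n_used=n_used,
        n_excluded=int(len(tx) - n_used),
        transform_x=transform_x,
        transform_y=transform_y,
    )


def combine_runs(profiles: list[DRNProfile]) -> DRNProfile:
    """Average duplicate-run profiles per residue (explicit combine step).

    All runs must share the residue label list; means are averaged, SDs are
    pooled as the root-mean-square of the per-run SDs, and the frame count
    is summed.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    labels = profiles[0].residue_labels
    for p in profiles[1:]:
        if p.residue_labels != labels:
            raise ValueError("profiles have differing residue labels")
    k = len(profiles)
    return DRNProfile(
        residue_labels=labels,
        avg_L=np.mean([p.avg_L for p in profiles], axis=0),
        sd_L=np.sqrt(np.mean([p.sd_L ** 2 for p in profiles], axis=0)),
        avg_BC=np.mean([p.avg_BC for p in profiles], axis=0),
        sd_BC=np.sqrt(np.mean([p.sd_BC ** 2 for p in profiles], axis=0)),
        n_frames=sum(p.n_frames for p in profiles),
        unreachable_fraction=np.mean(
            [p.unreachable_fraction for p in profiles], axis=0
        ),
    )
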