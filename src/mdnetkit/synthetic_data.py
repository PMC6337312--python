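"""Seeded synthetic trajectories with known ground truth.

Real chaperone trajectories are far too large to regenerate at desk scale, so
every analysis stage in this package is exercised against synthetic ensembles
whose generating parameters are known exactly:

* a two-domain bead protein (compact domain A, flexible linker, compact
  domain B) whose interdomain centre-of-mass separation follows a prescribed
  per-frame schedule and whose beads carry per-residue isotropic Gaussian
  positional noise — so RMSF, COM-distance and covariance estimators can be
  checked against closed forms;
* a single-frame "planted bridge" structure whose contact graph at the
  standard 6.7 Å cutoff is, by construction, two cliques joined through one
  bridge residue — so betweenness-based hub detection has a known answer.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a given
spec + seed reproduces output bit for bit across platforms.

One bead serves as the whole residue.  Beads are emitted as glycine α-carbons
so that both the ``CA`` and the ``CB_with_CA_for_GLY`` selection schemes
resolve to the same (only) atom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .trajectory_io import AtomRecord, Frame, Trajectory, mass_of_element

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "GenerationError",
    "generate_two_domain_trajectory",
    "generate_planted_bridge_structure",
    "add_positional_noise",
    "constant_schedule",
    "ramp_schedule",
]

DEFAULT_CONTACT_CUTOFF = 6.7  # Å, residue-network edge threshold


class GenerationError(RuntimeError):
    """Geometric placement failed after bounded retries."""


def constant_schedule(distance: float, n_frames: int) -> np.ndarray:
    """COM-separation schedule held constant at ``distance`` Å."""
    return np.full(n_frames, float(distance))


def ramp_schedule(d0: float, d1: float, n_frames: int) -> np.ndarray:
    """Linear COM-separation ramp from ``d0`` to ``d1`` Å over the run."""
    return np.linspace(float(d0), float(d1), n_frames)


@dataclass
class SyntheticSpec:
    """Parameters of the two-domain bead-protein generator.

    Defaults describe the reference study system: 50 residues split
    20 (domain A) / 10 (linker) / 20 (domain B), 0.5 Å isotropic positional
    noise per residue, a constant 25 Å interdomain separation, 2000 frames
    stored every 2 ps.
    """

    n_domain_a: int = 20
    n_domain_b: int = 20
    n_linker: int = 10
    bead_spacing: float = 3.8  # Å, Cα-Cα virtual bond length
    sigma_profile: np.ndarray | None = None  # per-residue noise SD, Å
    com_schedule: np.ndarray | None = None  # per-frame COM separation, Å
    n_frames: int = 2000
    dt: float = 2.0  # ps
    seed: int = 0

    def __post_init__(self):
        if min(self.n_domain_a, self.n_domain_b, self.n_linker) < 1:
            raise ValueError("all residue counts must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        n = self.n_residues
        if self.sigma_profile is None:
            self.sigma_profile = np.full(n, 0.5)
        self.sigma_profile = np.asarray(self.sigma_profile, dtype=float)
        if self.sigma_profile.shape != (n,):
            raise ValueError(f"sigma_profile must have length {n}")
        if np.any(self.sigma_profile < 0):
            raise ValueError("sigma values must be >= 0")
        if self.com_schedule is None:
            self.com_schedule = constant_schedule(25.0, self.n_frames)
        self.com_schedule = np.asarray(self.com_schedule, dtype=float)
        if self.com_schedule.shape != (self.n_frames,):
            raise ValueError(f"com_schedule must have length {self.n_frames}")

    @property
    def n_residues(self) -> int:
        return self.n_domain_a + self.n_linker + self.n_domain_b


@dataclass
class GroundTruth:
    """What the generator actually put into a synthetic ensemble."""

    sigma_profile: np.ndarray | None = None
    com_schedule: np.ndarray | None = None
    bridge_residue: tuple[str, int, str] | None = None
    base_contact_edges: set[tuple[int, int]] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sigma_profile": None if self.sigma_profile is None
            else list(map(float, self.sigma_profile)),
            "com_schedule": None if self.com_schedule is None
            else list(map(float, self.com_schedule)),
            "bridge_residue": list(self.bridge_residue)
            if self.bridge_residue else None,
            "base_contact_edges": sorted(map(list, self.base_contact_edges)),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            sigma_profile=None if d["sigma_profile"] is None
            else np.asarray(d["sigma_profile"]),
            com_schedule=None if d["com_schedule"] is None
            else np.asarray(d["com_schedule"]),
            bridge_residue=tuple(d["bridge_residue"])
            if d["bridge_residue"] else None,
            base_contact_edges={tuple(e) for e in d["base_contact_edges"]},
        )


def _bead_frame(coords: np.ndarray, chains: list[str], time: float = 0.0) -> Frame:
    mass = mass_of_element("C")
    atoms = [
        AtomRecord("CA", "GLY", i + 1, chains[i], "C",
                   (float(x), float(y), float(z)), mass)
        for i, (x, y, z) in enumerate(coords)
    ]
    return Frame(atoms, time=time)


def _compact_cluster(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """n beads on a jittered cubic lattice, centred on their mean."""
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                pts.append((i, j, k))
                if len(pts) == n:
                    break
            if len(pts) == n:
                break
        if len(pts) == n:
            break
    lattice = np.asarray(pts, dtype=float) * spacing
    lattice += rng.uniform(-0.1 * spacing, 0.1 * spacing, size=lattice.shape)
    return lattice - lattice.mean(axis=0)


def generate_two_domain_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, GroundTruth]:
    """Generate the two-domain bead trajectory described by ``spec``.

    Frame ``t`` rigidly translates domain B along +x so that the B-A
    centre-of-mass separation equals ``spec.com_schedule[t]`` exactly in the
    noise-free reference; linker beads interpolate between the two domain
    anchors.  Every bead then receives independent isotropic Gaussian noise
    with its per-residue SD per coordinate.  With zero noise every frame's
    measured COM separation reproduces the schedule to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    n_a, n_l, n_b = spec.n_domain_a, spec.n_linker, spec.n_domain_b
    n = spec.n_residues
    dom_a = _compact_cluster(n_a, spec.bead_spacing, rng)  # COM at origin
    dom_b_local = _compact_cluster(n_b, spec.bead_spacing, rng)  # COM at origin
    chains = ["A"] * n_a + ["L"] * n_l + ["B"] * n_b

    radius_a = float(np.linalg.norm(dom_a, axis=1).max())
    radius_b = float(np.linalg.norm(dom_b_local, axis=1).max())
    min_sep = float(np.min(spec.com_schedule))
    if min_sep < radius_a + radius_b:
        import warnings

        warnings.warn(
            f"com_schedule minimum {min_sep:.2f} Å is below the domain radii "
            f"sum {radius_a + radius_b:.2f} Å; domains will overlap",
            stacklevel=2,
        )

    # fixed anchors for the linker ends: outermost bead of each domain along x
    anchor_a = dom_a[np.argmax(dom_a[:, 0])]

    noise = rng.normal(
        0.0, 1.0, size=(spec.n_frames, n, 3)
    ) * spec.sigma_profile[None, :, None]

    frames = []
    for t in range(spec.n_frames):
        sep = spec.com_schedule[t]
        offset = np.array([sep, 0.0, 0.0])
        dom_b = dom_b_local + offset
        anchor_b = dom_b[np.argmin(dom_b_local[:, 0])]
        frac = (np.arange(1, n_l + 1) / (n_l + 1))[:, None]
        linker = anchor_a[None, :] * (1 - frac) + anchor_b[None, :] * frac
        ref = np.vstack([dom_a, linker, dom_b])
        coords = ref + noise[t]
        frames.append(_bead_frame(coords, chains, time=t * spec.dt))

    truth = GroundTruth(
        sigma_profile=spec.sigma_profile.copy(),
        com_schedule=spec.com_schedule.copy(),
    )
    return Trajectory(frames, dt=spec.dt), truth


def _contact_edges(coords: np.ndarray, cutoff: float) -> set[tuple[int, int]]:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    ii, jj = np.where((d <= cutoff) & (d > 0))
    return {(int(i), int(j)) for i, j in zip(ii, jj) if i < j}


def generate_planted_bridge_structure(
    m: int = 10, seed: int = 0, cutoff: float = DEFAULT_CONTACT_CUTOFF,
    max_retries: int = 200,
) -> tuple[Frame, GroundTruth]:
    """Single frame whose contact graph is two ``m``-cliques plus one bridge.

    Bead layout: bridge residue at the origin; one "gateway" bead per clique
    at ±4.5 Å on x (2.2 Å inside the cutoff, so the two bridge edges — the
    only contacts whose loss could disconnect the cliques — survive thermal
    jitter); the remaining ``m - 1`` beads of each clique packed in a
    1.5 Å-radius ball centred at ±9.0 Å (outside the cutoff from the bridge,
    inside it from their gateway and from each other).  The resulting graph
    has exactly ``2·C(m,2) + 2`` edges and the bridge carries every
    inter-clique shortest path.
    """
    if m < 3:
        raise ValueError("community size m must be >= 3")
    rng = np.random.default_rng(seed)
    gateway = 4.5
    ball_centre = 9.0
    ball_radius = 1.5

    def sample_ball(centre: np.ndarray, k: int) -> np.ndarray:
        pts = []
        tries = 0
        while len(pts) < k:
            tries += 1
            if tries > max_retries * k:
                raise GenerationError(
                    "could not place clique beads within retry budget"
                )
            v = rng.normal(size=3)
            v *= (rng.uniform() ** (1 / 3)) * ball_radius / np.linalg.norm(v)
            p = centre + v
            if any(np.linalg.norm(p - q) < 0.8 for q in pts):
                continue  # keep beads sterically distinct
            pts.append(p)
        return np.asarray(pts)

    bridge = np.zeros((1, 3))
    gw_a = np.array([[-gateway, 0.0, 0.0]])
    gw_b = np.array([[+gateway, 0.0, 0.0]])
    ball_a = sample_ball(np.array([-ball_centre, 0.0, 0.0]), m - 1)
    ball_b = sample_ball(np.array([+ball_centre, 0.0, 0.0]), m - 1)
    # residue order: clique A (gateway first), bridge, clique B (gateway first)
    coords = np.vstack([gw_a, ball_a, bridge, gw_b, ball_b])
    chains = ["A"] * m + ["L"] + ["B"] * m

    edges = _contact_edges(coords, cutoff)
    expected = 2 * (m * (m - 1) // 2) + 2
    if len(edges) != expected:
        raise GenerationError(
            f"planted graph has {len(edges)} edges, expected {expected}"
        )
    frame = _bead_frame(coords, chains)
    bridge_idx = m  # position of the bridge residue in the bead order
    label = (chains[bridge_idx], bridge_idx + 1, "GLY")
    truth = GroundTruth(bridge_residue=label, base_contact_edges=edges)
    return frame, truth


def add_positional_noise(
    frame: Frame,
    sigma_profile: np.ndarray | float,
    n_frames: int,
    seed: int = 0,
    dt: float = 2.0,
) -> Trajectory:
    """``n_frames`` independent noisy copies of ``frame``.

    Every frame is perturbed (frame 0 is not the clean reference), so
    fluctuation estimators computed on the result are unbiased.  The frame is
    assumed to hold one bead per residue; ``sigma_profile`` is per residue, Å.
    """
    n = len(frame)
    sigma = np.broadcast_to(np.asarray(sigma_profile, dtype=float), (n,))
    if np.any(sigma < 0):
        raise ValueError("sigma values must be >= 0")
    rng = np.random.default_rng(seed)
    base = frame.coordinates
    frames = []
    for t in range(n_frames):
        noisy = base + rng.normal(0.0, 1.0, size=(n, 3)) * sigma[:, None]
        frames.append(frame.with_coordinates(noisy, time=t * dt))
    return Trajectory(frames, dt=dt)
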