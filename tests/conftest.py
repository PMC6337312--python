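import numpy as np
import pytest

from mdnetkit import (
    AtomRecord, Frame, Trajectory, SyntheticSpec,
    generate_two_domain_trajectory, select_representatives,
)


def make_frame(coords, time=0.0, names=None, resnames=None, chains=None):
    """Frame of one-atom residues at the given coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or ["CA"] * n
    resnames = resnames or ["GLY"] * n
    chains = chains or ["A"] * n
    atoms = [
        AtomRecord(names[i], resnames[i], i + 1, chains[i], "C",
                   tuple(coords[i]), 12.011)
        for i in range(n)
    ]
    return Frame(atoms, time=time)


def make_trajectory(coord_sets, dt=2.0, **kw):
    return Trajectory(
        [make_frame(c, time=i * dt, **kw) for i, c in enumerate(coord_sets)],
        dt=dt,
    )


@pytest.fixture
def tripeptide_frame():
    """ALA-GLY-LEU with backbone + CB atoms (GLY has no CB)."""
    atoms = []
    spec = [
        ("ALA", ["N", "CA", "CB", "C"]),
        ("GLY", ["N", "CA", "C"]),
        ("LEU", ["N", "CA", "CB", "C"]),
    ]
    x = 0.0
    for ri, (resname, atom_names) in enumerate(spec):
        for an in atom_names:
            atoms.append(
                AtomRecord(an, resname, ri + 1, "A", an[0],
                           (x, 0.0, 0.0), 12.011)
            )
            x += 1.5
    return Frame(atoms)


@pytest.fixture(scope="session")
def small_synthetic():
    """50-residue two-domain trajectory, 200 frames, sigma 0.5 Å."""
    spec = SyntheticSpec(n_frames=200, seed=11)
    traj, truth = generate_two_domain_trajectory(spec)
    sel = select_representatives(traj)
    return traj, truth, sel
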