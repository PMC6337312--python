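"""Generate a synthetic two-domain trajectory and recover its ground truth.

The generator builds a 50-residue bead protein (domain A, flexible linker,
domain B) with 0.5 Å isotropic positional noise per residue and a prescribed
interdomain centre-of-mass separation per frame.  Because the noise model is
known exactly, the RMSF estimator should converge to sigma * sqrt(3) and the
COM-distance series should track the schedule.
"""

import numpy as np

import mdnetkit as mk
from mdnetkit.trajectory_io import Selection

spec = mk.SyntheticSpec(n_frames=2000, seed=7)
traj, truth = mk.generate_two_domain_trajectory(spec)
sel = mk.select_representatives(traj)

rmsf = mk.rmsf_per_residue(traj, sel, fit=False)
expected = np.sqrt(3) * truth.sigma_profile
rel = np.abs(rmsf.values - expected) / expected
print(f"residues: {len(sel)}, frames: {len(traj)}")
print(f"RMSF (first 5 residues, Å): {np.round(rmsf.values[:5], 3)}")
print(f"expected sigma*sqrt(3) (Å): {np.round(expected[:5], 3)}")
print(f"median relative error: {np.median(rel):.3%}")
# The agreement shows the fluctuation estimator is unbiased at this depth.

rg = mk.rg_series(traj, sel)
print(f"radius of gyration: mean {rg.values.mean():.2f} Å "
      f"(compactness of the whole two-domain assembly)")


def chain_sel(ch):
    keep = [i for i, l in enumerate(sel.residue_labels) if l[0] == ch]
    return Selection([sel.indices[i] for i in keep],
                     [sel.residue_labels[i] for i in keep],
                     [sel.masses[i] for i in keep])


com = mk.com_distance_series(traj, chain_sel("A"), chain_sel("B"))
print(f"interdomain COM distance: mean {com.values.mean():.2f} Å "
      f"(schedule holds it at {truth.com_schedule[0]:.1f} Å; "
      f"noise adds the spread of {com.values.std():.2f} Å)")
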