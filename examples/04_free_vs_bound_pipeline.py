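"""Full ligand-free vs ligand-bound comparison on synthetic inputs.

Emulates the standard workflow: the "bound" ensemble carries a planted
network bridge (as if ligand binding created a new communication bottleneck)
while the "free" ensemble lacks it.  The pipeline computes per-condition DRN
profiles, free-minus-bound deltas, joint [0,1] normalisation and metric
correlations, and writes deterministic CSV tables.
"""

import tempfile
from pathlib import Path

import numpy as np

import mdnetkit as mk
from mdnetkit.pipeline import RunConfig, run_compare_pipeline, write_report_tables

tmp = Path(tempfile.mkdtemp())

bound_frame, truth = mk.generate_planted_bridge_structure(m=10, seed=1)
sel0 = mk.select_representatives(bound_frame)
bridge_pos = sel0.residue_labels.index(truth.bridge_residue)

free_coords = bound_frame.coordinates.copy()
free_coords[bridge_pos] = (0.0, 60.0, 0.0)  # no bridge in the free state
free_frame = bound_frame.with_coordinates(free_coords)

mk.write_multimodel_pdb(mk.add_positional_noise(free_frame, 0.15, 20, seed=2),
                        tmp / "free.pdb")
mk.write_multimodel_pdb(mk.add_positional_noise(bound_frame, 0.15, 20, seed=3),
                        tmp / "bound.pdb")

cfg = RunConfig(
    free_paths=[str(tmp / "free.pdb")],
    bound_paths=[str(tmp / "bound.pdb")],
    window_fraction=0.9, stride_ps=2.0,
    outdir=str(tmp / "out"),
)
report = run_compare_pipeline(cfg)

d = report.delta_BC.values
print(f"residues compared: {len(d)}")
print(f"most negative delta BC (free - bound): {d.min():.4f} at position "
      f"{int(np.argmin(d))} (bridge is {bridge_pos})")
# Negative free-minus-bound BC marks centrality GAINED on binding: the
# planted bridge shows up as the strongest gain, as designed.

for c in report.correlations:
    if c["condition"] == "bound":
        print(f"bound: {c['x']}({c['transform_x']}) vs "
              f"{c['y']}({c['transform_y']}): r = {c['r']:.3f} "
              f"(n = {c['n_used']})")

manifest = write_report_tables(report, tmp / "tables")
print(f"wrote {len(manifest['files'])} CSV tables to {tmp/'tables'} "
      f"(rerunning the same config reproduces them byte for byte)")
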