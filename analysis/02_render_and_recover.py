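#!/usr/bin/env python
"""Render one fully exiting wild-type replica into the toy exit tunnel and
re-analyze the resulting 3D trajectory with the kinetics module: the
round-trip must recover every per-residue release time within one frame,
and the covered CV distance of a complete exit equals the full 12.5 nm span.

Writes results/roundtrip_wt.csv and results/traj_wt.xyz.
"""

from pathlib import Path

import pandas as pd

from arrestkin.core import AP_RESIDUES, AnalysisConfig
from arrestkin.io import write_xyz_trajectory
from arrestkin.kinetics import covered_distance, events_from_trajectory
from arrestkin.synth import (
    default_tunnel,
    default_variant_configs,
    render_trajectory,
    sample_ensemble,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

DT = 0.5  # ns per rendered frame
configs = default_variant_configs()
events = next(t for t in sample_ensemble(configs["WT"], master_seed=1)
              if t.exited)
tunnel = default_tunnel()
analysis = AnalysisConfig()
traj = render_trajectory(events, tunnel, dt=DT, analysis=analysis)
write_xyz_trajectory(traj, OUT / "traj_wt.xyz")

point = tunnel.virtual_point(analysis.cv_target_distance)
recovered = events_from_trajectory(traj, analysis, virtual_point=point)

rows = [{"residue": r, "t_true_ns": events.t_release[r],
         "t_recovered_ns": recovered.t_release[r]} for r in AP_RESIDUES]
table = pd.DataFrame(rows)
table["error_ns"] = table.t_recovered_ns - table.t_true_ns
table.to_csv(OUT / "roundtrip_wt.csv", index=False)

print(f"rendered {traj.n_frames} frames at dt = {DT} ns "
      f"({traj.topology.n_atoms} atoms)")
print(f"max release-time recovery error: {table.error_ns.max():.3f} ns "
      f"(one frame = {DT} ns)")
print(f"detach recovered {recovered.t_detach_M260:.1f} ns "
      f"(true {events.t_detach_M260:.2f}), extraction "
      f"{recovered.extraction_time_T:.1f} ns (true "
      f"{events.extraction_time_T:.2f})")
D = covered_distance(traj, point)
print(f"covered distance of the full exit: {D:.6f} nm (CV span 12.5 nm)")
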