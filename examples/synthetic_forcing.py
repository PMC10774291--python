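"""Build the idealised shelf scenario and inspect its structure.

The generator produces a piecewise-linear shelf profile (200 m edge at
60 km offshore), a seasonal density gradient, episodic offshore bottom
pulses, and a kelp-probability raster vanishing beyond ~50 m depth.
"""

import numpy as np

import kelpflux as kf

cfg = kf.ShelfScenarioConfig(n_days=31)  # January, warm season
scenario = kf.make_scenario(cfg)
b, f = scenario.bathymetry, scenario.fields

print(f"grid: {b.shape[1]} x {b.shape[0]} nodes at {cfg.grid_spacing:.0f} m")
print(f"depth at shelf edge ({cfg.shelf_edge_distance / 1e3:.0f} km): "
      f"{b.depth_at(cfg.shelf_edge_distance, 10e3):.0f} m")
print(f"offshore boundary depth: {b.depth[0, -1]:.0f} m")

shelf = b.wet & (b.depth <= 200.0)
print(f"January mean cross-shore bottom velocity on the shelf: "
      f"{f.u[:, shelf].mean():+.3f} m/s (negative = onshore)")

kelp_area = (scenario.kelp_prob > 0).sum()
print(f"kelp habitat: {kelp_area} cells, max probability "
      f"{scenario.kelp_prob.max():.2f}, none deeper than "
      f"{b.depth[scenario.kelp_prob > 0].max():.0f} m")

# Cold-season forcing carries offshore pulses instead:
may = kf.make_forcing(cfg.replace(start_date="2017-05-01"), b)
print(f"May mean cross-shore bottom velocity on the shelf: "
      f"{may.u[:, shelf].mean():+.3f} m/s (positive = offshore)")
print(f"May peak offshore speed: {may.u.max():.2f} m/s (pulse speed "
      f"{cfg.pulse_speed} m/s)")

# Write the scenario as CF-style NetCDF for the file-based CLI stages:
#   kf.save_scenario("scenario.nc", scenario)
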