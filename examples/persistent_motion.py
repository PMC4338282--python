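"""Persistent cell motion as a biased random walk.

A lone cell gets a target direction; extensions aligned with it are favoured
(acceptance ~ exp(-dH/T + mu cos zeta)), and every s MCS the target
direction is reset to the direction the cell actually moved.  Raising mu (or
s) lengthens the straight stretches of the walk and the emergent speed --
the cell-level knob that later amplifies tissue extension.
"""

import numpy as np

from segcpm import (AdhesionTable, Persistence, SimConfig, TissueSpec,
                    build_segmented_tissue)
from segcpm.engine import Simulation
from segcpm import metrics

spec = TissueSpec(n_segments=1, segment_rows=1, segment_cols=1,
                  cell_target_area=100)
adhesion = AdhesionTable.uniform(J_cm=12, J_cc=18)

print("single cell, 25,000 MCS, centroid sampled every 1000 MCS")
for mu, s in [(None, None), (0.5, 10), (2.0, 10)]:
    pers = Persistence(mu=mu, s=s) if mu is not None else None
    state = build_segmented_tissue(spec, field=(260, 260))
    sim = Simulation(state, adhesion, SimConfig(duration=25_000, seed=4),
                     persistence=pers)
    res = sim.run()
    speed = metrics.mean_cell_speed(res.tracks, t_start=5000)
    tr = res.tracks
    net = float(np.hypot(tr.x.iloc[-1] - tr.x.iloc[0],
                         tr.y.iloc[-1] - tr.y.iloc[0]))
    label = "no persistence " if mu is None else f"mu={mu}, s={s}    "
    print(f"  {label}: speed {speed:.3f} sites/MCS, net path {net:5.1f} sites")

print("""
Without persistence the centroid only jitters thermally; with mu = 2 the
self-reinforcing target direction turns the jitter into sustained migration,
an order of magnitude faster.""")
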