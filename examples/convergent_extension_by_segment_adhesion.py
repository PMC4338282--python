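"""Convergent extension driven by segment-specific adhesion alone.

A tissue of four segments (alternating red/green identity) evolves under
nothing but differential adhesion: cells prefer neighbours of their own
segment type (gamma_rg > 0) while the cell-medium tension keeps the tissue
compact.  The intersegment interface contracts, segments round up, and the
stack narrows and lengthens -- convergent extension without any imposed
directional cue.  Desk scale: reduced cell size (area 64) and a short run,
so the fold stays below the equilibrium value; see docs/methods.md.
"""

from segcpm import (AdhesionTable, SimConfig, TissueSpec,
                    build_segmented_tissue)
from segcpm.engine import Simulation
from segcpm import metrics
from segcpm.render import render_snapshot

spec = TissueSpec(n_segments=4, segment_rows=3, segment_cols=10,
                  cell_target_area=64)
state = build_segmented_tissue(spec, field=(220, 125))
adhesion = AdhesionTable.from_tensions(gamma_rg=10, gamma_cm=6)
sim = Simulation(state, adhesion, SimConfig(duration=60_000, seed=0))
result = sim.run()

init = result.initial_long_axis(5000)
final = result.final_long_axis(tail=0.2)
mixing, strays = metrics.segment_integrity(sim.state)
print(f"long axis after inflation (MCS 5000): {init:.1f} sites")
print(f"long axis at the end (tail mean):     {final:.1f} sites")
print(f"elongation fold: {final / init:.2f}")
print(f"stray cells: {strays}, boundary-row mixing fraction: {mixing:.2f}")
render_snapshot(sim.state, path="extension_final.png")
print("snapshot written to extension_final.png")
print("""
The fold > 1 shows the tissue lengthened along the segment-stacking axis
while narrowing; strays stay low because cells rarely pay the gamma_rg
penalty of sitting inside the other segment type.""")
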