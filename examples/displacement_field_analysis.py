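"""Per-cell displacement vectors, rotation correction and neighbourhood
coherence.

The analysis pipeline behind every vector plot: centroids are tracked every
1000 MCS; the vector of each cell runs from its position at MCS 5000 (after
inflation) to the end of the run; the field is corrected for net
whole-tissue rotation via the unwrapped principal-angle series; each vector
is coloured by its mean absolute angle to the vectors starting within 30
sites.  Convergent extension shows up as inward-pointing lateral vectors and
outward-pointing anterior/posterior ones, with high local coherence.
"""

import numpy as np

from segcpm import (AdhesionTable, SimConfig, TissueSpec,
                    build_segmented_tissue)
from segcpm.engine import Simulation
from segcpm import metrics
from segcpm.render import render_vectors

spec = TissueSpec(n_segments=4, segment_rows=3, segment_cols=10,
                  cell_target_area=64)
state = build_segmented_tissue(spec, field=(220, 125))
adhesion = AdhesionTable.from_tensions(gamma_rg=10, gamma_cm=6)
sim = Simulation(state, adhesion, SimConfig(duration=50_000, seed=1))
result = sim.run()

vectors = metrics.displacement_vectors(result.tracks, t_start=5000)
corrected = metrics.rotation_correct(vectors, result.shapes)
coherence = metrics.neighbour_angle_coherence(corrected, radius=30)

lengths = np.hypot(corrected.dx, corrected.dy)
print(f"{len(corrected)} displacement vectors "
      f"({vectors.attrs['excluded']} cells retired before the end)")
print(f"net tissue rotation removed: {corrected.attrs['net_rotation']:+.3f} rad")
print(f"mean vector length: {lengths.mean():.1f} sites")
print(f"mean neighbour angle: {np.nanmean(coherence):.2f} rad "
      "(0 = locally parallel, pi/2 = random)")

# anterior/posterior thirds move apart along y; the middle converges
y0 = corrected.y0
top = corrected.dy[y0 < y0.quantile(0.33)].mean()
bottom = corrected.dy[y0 > y0.quantile(0.67)].mean()
print(f"mean dy of anterior third {top:+.1f}, posterior third {bottom:+.1f} "
      "(opposite signs = extension)")
render_vectors(corrected, coherence, path="displacement_field.png")
print("vector plot written to displacement_field.png")
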