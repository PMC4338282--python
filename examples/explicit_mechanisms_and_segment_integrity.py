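"""An imposed convergent-extension mechanism mixes segments unless
segment-specific adhesion guards them.

Graded adhesion imposes a static Gaussian of cell-cell adhesion strength
across the field x-axis: contacts near the x-centre are cheaper, so the
tissue funnels into the centre column and extends along y -- an explicit,
externally-directed mechanism.  Run on a tissue whose red/green segments
adhere indiscriminately (gamma_rg = 0), the extension shuffles cells across
segment boundaries; a small positive gamma_rg preserves the pattern without
sacrificing extension.  The same comparison holds for the orientation-based
(axial) mechanism.
"""

from segcpm import (AdhesionTable, GradedAdhesion, SimConfig, TissueSpec,
                    build_segmented_tissue)
from segcpm.engine import Simulation
from segcpm import metrics

spec = TissueSpec(n_segments=4, segment_rows=3, segment_cols=6,
                  cell_target_area=64)
for label, table in [
    ("gamma_rg = 0 (indiscriminate)", AdhesionTable.uniform(J_cm=10, J_cc=16)),
    ("gamma_rg = 4 (segment-specific)",
     AdhesionTable.segmented(J_cm=10, J_rr=12, J_rg=16)),
]:
    state = build_segmented_tissue(spec, field=(200, 110))
    sim = Simulation(state, table, SimConfig(duration=50_000, seed=3),
                     mechanism=GradedAdhesion(w=11, c=7))
    res = sim.run()
    mixing, strays = metrics.segment_integrity(sim.state)
    print(f"{label}: fold {res.elongation_fold(tail=0.2):.2f}, "
          f"boundary mixing {mixing:.2f}, strays {strays}")

print("""
Both tissues extend under the imposed gradient, but only the tissue with
segment-specific adhesion keeps its boundary-row mixing near zero --
differential adhesion maintains the pattern the extension would otherwise
destroy.""")
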