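"""Axial sorting and extension from two opposing adhesion-protein gradients.

Instead of discrete segments, every cell carries concentrations of two
adhesion proteins A and B with A + B = 1; the lower of the two cells'
concentrations of each protein sets the bond strength
(J' = J - mm * (min(A_i, A_j) + min(B_i, B_j))), so similar cells stick
together and intermediate cells bridge the extremes.  From a sorted start
the tissue elongates modestly; from a randomly mixed start the tissue sorts
along its axis, which is quantified by the sorting index (|rank correlation|
between B and axial position).
"""

from segcpm import (AdhesionTable, GradientAdhesion, Persistence, SimConfig,
                    TissueSpec, build_gradient_tissue)
from segcpm.engine import Simulation
from segcpm import metrics

adhesion = AdhesionTable.gradient_tissue(J_cm=15, J_max=28)
mech = GradientAdhesion(mm=18)

spec = TissueSpec(n_segments=1, segment_rows=10, segment_cols=5,
                  cell_target_area=200, pattern="gradient_sorted")
state = build_gradient_tissue(spec, field=(260, 130))
print(f"sorted start: sorting index {metrics.sorting_index(state):.3f}")
sim = Simulation(state, adhesion, SimConfig(duration=80_000, seed=2),
                 mechanism=mech, persistence=Persistence(mu=0.5, s=5))
res = sim.run()
print(f"after 80,000 MCS: sorting index "
      f"{metrics.sorting_index(sim.state):.3f}, "
      f"elongation fold {res.elongation_fold(tail=0.2):.2f}")

spec_rand = TissueSpec(n_segments=1, segment_rows=10, segment_cols=5,
                       cell_target_area=200, pattern="gradient_random")
state = build_gradient_tissue(spec_rand, field=(260, 130), rng=2)
print(f"\nmixed start:  sorting index {metrics.sorting_index(state):.3f}")
sim = Simulation(state, adhesion, SimConfig(duration=80_000, seed=2),
                 mechanism=mech, persistence=Persistence(mu=2.0, s=30))
sim.run()
print(f"after 80,000 MCS with strong persistence (mu=2, s=30): "
      f"sorting index {metrics.sorting_index(sim.state):.3f}")
print("""
The sorted tissue stretches while its gradient slowly erodes (its index
drops below 1 as rows wander).  At this small tissue size the strong
persistence churns the mixed tissue without global ordering -- the sorting
route to axial order needs far larger tissues and much longer runs than
this demo (see the reduced-scale discussion in docs/methods.md).""")
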