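# segcpm

Cellular Potts simulations of **convergent extension in pre-segmented
tissues** — for computational developmental biologists studying how a
tissue that has already been patterned into segments of distinct identity
can narrow and lengthen without destroying that pattern, and how the
pattern itself can drive the movement.

## The model in brief

The tissue is a 2D Cellular Potts Model (CPM): cells are sets of lattice
sites sharing an identity σ, and the configuration energy

```
H = Σ_neighbour pairs J(τ, τ′) · [σ ≠ σ′]  +  λ_a Σ_cells (a − A)²
```

combines contact energies J between cell types τ (lower J = stronger
adhesion) with a quadratic area constraint.  Dynamics are Metropolis copy
attempts (accept if ΔH ≤ 0, else with probability exp(−ΔH/T)).  Adhesion
preferences are read through surface tensions γ_ij = J_ij − (J_ii+J_jj)/2:
a positive red–green tension γ_rg makes cells prefer their own segment
type, which contracts the interfaces between segments and — balanced
against the cell–medium tension γ_cm — narrows and lengthens the whole
tissue.  A stack of n segments of area A_s each is predicted to equilibrate
at intersegment contact length

```
L* = sqrt( 2 γ_cm n A_s / ((n−1) γ_rg + 2 γ_cm) )
```

(tissue ≈ L* wide by n·A_s/L* long).  The package also implements graded
adhesion (Gaussian in the field x), axial adhesion (orientation-dependent),
opposing adhesion-protein gradients, persistent cell motion, a blocked
anterior boundary, and the full measurement pipeline (tissue axes,
displacement-vector fields with rotation correction, neighbour coherence,
cell speeds, segment integrity, segment merging, sorting index).

## Worked example

```python
from segcpm import (AdhesionTable, SimConfig, TissueSpec,
                    build_segmented_tissue)
from segcpm.engine import Simulation
from segcpm import metrics

spec = TissueSpec(n_segments=4, segment_rows=3, segment_cols=10,
                  cell_target_area=100)
state = build_segmented_tissue(spec, field=(270, 150))
adhesion = AdhesionTable.from_tensions(gamma_rg=10, gamma_cm=6)
sim = Simulation(state, adhesion, SimConfig(duration=120_000, seed=0))
result = sim.run()

print(round(result.initial_long_axis(5000), 1))        # 145.9
print(round(result.final_long_axis(tail=0.2), 1))      # 208.8
print(round(result.elongation_fold(tail=0.2), 2))      # 1.43
print(metrics.segment_integrity(sim.state))            # (0.0, 0)
```

A four-segment tissue (120 cells) under segment-specific adhesion alone
(γ_rg = 10, γ_cm = 6) lengthens from 146 to 209 lattice sites — a 1.43-fold
extension, close to the 1.5-fold the rectangle-energy balance predicts for
these tensions — while zero cells stray from their segment (the integrity
tuple is mixing fraction, stray count).  No directional cue was imposed
anywhere: the orientation of the segment interfaces alone decides the
extension axis.

The `examples/` directory holds one short script per capability (tension
arithmetic and shape prediction, convergent extension, persistent motion,
displacement-field analysis, gradient sorting); each prints the numbers it
computes and says what they mean.  `segcpm.experiments` provides named
presets for every published experiment family and writes reproducible run
directories (tracks, shapes, manifest, snapshots).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from scratch — the elongation folds of
the 4-segment and 8-segment benchmark tissues under segment-specific
adhesion, the emergent cell speeds of the uniform-adhesion and stiff
persistent tissues, and the extension of the stiff tissue with persistent
motion — by building each tissue, running the Monte Carlo engine and
measuring the resulting tracks and shape series (reduced scale where the
physics permits; see `docs/methods.md`).  Runtime is ~20 minutes on one
core; results land in the JSON file given by `--out`.
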