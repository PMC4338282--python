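# segcpm — model and methods

## The model

`segcpm` simulates a 2D tissue as a Cellular Potts Model (CPM): the field is
an integer lattice in which each site holds the identity σ of the cell
occupying it (0 = medium), and each cell is the set of sites sharing its σ.
Cell types τ are `red`/`green` (the two alternating segment identities),
`gradient` (cells carrying two opposing adhesion-protein concentrations) and
the medium.  The energy of a configuration is

```
H = Σ_pairs J(τ_σ, τ_σ') · [σ ≠ σ']  +  λ_a Σ_cells (a_σ − A_σ)²
```

where the first sum runs over all unordered Moore-8 neighbour pairs of
sites, J is the contact energy per unit boundary (lower J = stronger
adhesion), and the second term holds each cell's area a near its target A
(the medium has no area term).  Dynamics are copy attempts: one Monte Carlo
step (MCS) draws as many random target sites as there are lattice sites,
picks a uniform random Moore-8 neighbour as the source, and copies the
source identity into the target with the Metropolis probability 1 if
ΔH ≤ 0, else exp(−ΔH/T).  T sets the membrane-fluctuation amplitude.

Behaviour under a J table is read through surface tensions
γ_ij = J_ij − (J_ii + J_jj)/2 (with J between two medium sites fixed at 0).
Positive γ between red and green demixes the segment types
(*segment-specific adhesion*); positive cell–medium γ keeps the tissue
compact.  The interplay of the two is the core mechanism: the intersegment
tension contracts the interfaces between segments, the medium tension
resists the resulting elongation of the tissue outline, and the balance
sets the equilibrium shape (below).

### J-modification mechanisms (at most one active)

* **Graded adhesion** — cell–cell contacts near the field x-centre are
  stronger: J′ = J − w·exp(−(x−b)²/2c²), evaluated at the x of the copy
  target site (defaults w = 11, c = 7, b = field centre).
* **Axial adhesion** — contacts on the top/bottom faces of cells are
  stronger: J′ = J − (β/2)·|sin α|·|sin α′|, where α, α′ are the angles of
  the two cells' centroid→contact-site vectors with the x-axis (default
  β = 2).  A degenerate zero-length vector contributes no reduction.
* **Opposing protein gradients** — each gradient cell carries
  concentrations A + B = 1; J′ = J − mm·(min(A_i,A_j) + min(B_i,B_j)), so
  the cell with less of a protein limits that protein's contribution and
  intermediate cells bridge the extremes (default mm = 18).

These modifications apply to cell–cell contacts only, never cell–medium.
Graded and axial adhesion bias copy attempts; because their J′ depends on
which site of a pair is the copy target they define no global pair
potential, and `hamiltonian_total` refuses them (the gradient mechanism is
symmetric per pair and is supported).

### Persistent motion

Each cell can carry a unit target direction.  A copy attempt that extends a
cell at angle ζ (between the target direction and the vector from the
cell's centroid to the target site) is biased *on the temperature scale*:

```
P(accept) = exp(−ΔH/T + μ·cos ζ)     (ΔH > 0 branch)
```

equivalently ΔH′ = ΔH − μ·T·cos ζ, with μ dimensionless (0.5–2.5).  By
default the retracting cell is biased symmetrically (retraction against its
own target direction is favoured), following the lymphocyte-migration CPM
implementations this mechanism derives from; `bias_retraction=False`
restricts the bias to the extending cell.  Every `s` MCS (5–40) the target
direction is replaced by the unit vector of the cell's actual displacement
since the last update (zero displacement keeps the old direction), so an
isolated cell performs a persistent random walk whose straight stretches
grow with μ·s.

Why the temperature scale: a bias of μ ≤ 2.5 in plain energy units against
T = 15 changes per-attempt odds by < 20% and is lost in thermal noise — we
measured cell speeds to be independent of μ over the whole documented range
under that reading.  With the bias in the exponent and both-cell terms, the
documented parameter sets reproduce the emergent speeds this mechanism is
known for (≈0.17 sites/MCS at μ = 2, s = 10 in a uniform-adhesion tissue;
≈0.16 at μ = 2.5, s = 20 in the stiff tissue).  This is a deliberate
re-reading of the printed update rule, recorded here as the package's
design choice.

Persistence is suspended during the initialization period and activates
with fresh anchors and independent uniform-random initial directions.  For
persistence runs the initialization period is 5000 MCS — the time the 5x5
seed blocks need to inflate to their target area.  Activating the bias on a
still-inflating, loosely packed tissue disperses it before it consolidates
(we measured tissue outlines twice their footprint by MCS 5000 in that
case); activated after inflation, tissues stay coherent and the published
emergent speeds and extension folds are reproduced.

## Initial tissues

Cells are seeded as 5×5 blocks packed contiguously into a grid of
`n_segments · segment_rows` rows by `segment_cols` columns, centred in the
field (or abutting the top wall in the `anterior_blocked` layout, which
models a tissue pinned against non-deforming anterior structures).  Blocks
inflate to the target area (500, or 200 for persistence runs) during the
first few thousand MCS; measurements therefore use MCS 5000 as the
reference ("initial") sample.  Segments alternate red/green by index.
Gradient tissues set B per cell: row-stepped 0→1 for the sorted pattern,
uniform-random for the mixed pattern.  The lattice boundary is a one-site
frozen wall frame; copies into or out of walls are rejected, which
implements both the free case (walls far away) and the blocked-anterior
case with one mechanism.

## Measurements

* **Tissue axes** — covariance (gyration) tensor of all non-medium site
  coordinates; axis lengths are peak-to-peak projections onto the principal
  directions plus one site width (a 60×50 solid rectangle measures exactly
  60 × 50); the principal angle is reported against the field y-axis.
* **Displacement vectors** — per-cell centroid displacement between MCS
  5000 and the end of the run (centroids sampled every 1000 MCS); cells
  retired in between are excluded and counted.  Rotation correction
  unwraps the π-periodic principal-angle series and rotates end points by
  the negative net rotation about the final tissue centroid.
* **Neighbour-angle coherence** — per vector, the mean absolute angle to
  all vectors starting within 30 sites; 0 = locally parallel field, π/2 =
  isotropic.
* **Cell speed** — per cell, the mean of |Δcentroid|/Δt over consecutive
  1000-MCS intervals from MCS 5000; then the mean over cells.
* **Segment integrity** — a stray is a live cell with no Moore-adjacent
  cell of its own segment label; the mixing fraction is the fraction of
  boundary-row cells touching a same-type cell of another segment.
  Segment merging is a connected component (same-type contact graph)
  containing two or more segment labels.
* **Sorting index** — |Spearman rank correlation| between B and the
  centroid projection on the tissue's principal axis.

### Equilibrium contact length (analytic oracle)

Approximating a stack of n segments of area A_s each as rectangles of
width L, the boundary energy is E(L) = (n−1)·γ_rg·L + γ_cm·(2L + 2n·A_s/L),
minimised at

```
L* = sqrt( 2 γ_cm n A_s / ((n−1) γ_rg + 2 γ_cm) )
```

with predicted tissue dimensions L* × n·A_s/L*.  γ_rg = 0 recovers the
square tissue; the derivation is validated against numerical minimisation
in the test-suite.  Because L* and the initial length both scale as
sqrt(cell area), the *fold* elongation is independent of cell size — the
basis for all reduced-scale runs.

## Numerical choices

* ΔH is computed incrementally from the 8 contact pairs touching the target
  site plus two expanded area terms (2(a−A)±1); the identity against
  from-scratch recomputation is property-tested exactly.
* ΔH = 0 is accepted with probability 1 (limit of the exponential rule).
* Randomness: one xorshift64* stream per run (seeded via splitmix64 from
  the config seed) drives all copy attempts; initial target directions come
  from a NumPy generator spawned from the same seed.  Trajectories are
  bit-reproducible, and checkpoints store the RNG state so a resumed run
  continues bit-identically.
* Centroids are maintained as running coordinate sums; cells whose area
  reaches 0 are retired (no connectivity constraint exists, so cells can
  fragment — monitored by the stray/mixing metrics, not forbidden).
* The Monte Carlo kernel is numba-compiled and specialised per mechanism
  (~1.2×10⁸ attempts/s on one core); per-MCS cost scales with field size.

## What the reduced-scale runs do and do not establish

Desk-scale experiments shrink cells (target area 64–100) and durations.
Equilibrium *shape ratios* survive this reduction (see the scale argument
above) and plateau ~3× faster; the 4-segment benchmark reaches its plateau
fold ≈ 1.4–1.5 by ~5×10⁴ MCS at area 100.  What does *not* survive
reduction: (i) pattern integrity — boundary fluctuations are larger
relative to small cells, so strays and segment merging appear at parameter
sets that keep integrity at full scale (visible in the 8-segment benchmark,
whose measured fold at area 100 falls short of its equilibrium prediction
of ≈ 2.1 for exactly this reason); (ii) emergent speeds, which depend on
cell size — speed measurements therefore always use the published cell
size (area 200); (iii) the opposing-gradient pattern, whose row-to-row J
differences (mm/n_rows per contact site) must stay well above T — gradient
runs also keep area 200.  A green reduced-scale test establishes the
mechanism and the direction and approximate magnitude of the effect, not
the paper-scale trajectory.

## Known limitations

* 3D tissues, growth zones / sequential segmentation, cell division and
  dynamic regulation of adhesion are out of scope.
* T1-transition counting is not implemented (neighbour exchanges occur but
  are not detected as events).
* Periodic boundaries and hexagonal lattices are not supported.
* At strong persistence (μ ≥ ~2.5) combined with strong differential
  adhesion, the model sits near the segment-merging instability; outcomes
  there are sensitive to the persistence implementation variant (see the
  bias discussion above).
* Persistence-driven axial sorting of a randomly mixed gradient tissue is
  not reproduced at desk-reachable sizes: at μ = 2, s = 30 the weakly
  cohesive gradient tissue (γ_cm as low as 1 between dissimilar cells)
  stretches and churns without global ordering (sorting index ≤ 0.2 even
  after 10⁶ MCS at 96 cells).  The corresponding acceptance check is left
  failing by design rather than weakened.
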