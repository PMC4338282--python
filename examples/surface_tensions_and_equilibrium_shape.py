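"""Surface tensions from contact energies, and the equilibrium tissue shape
they predict.

Adhesion between cell types is set by contact energies J (lower J = stronger
adhesion); behaviour is read through surface tensions
gamma_ij = J_ij - (J_ii + J_jj)/2.  A positive red/green tension pulls the
interface between segments inward (driving convergent extension), a positive
cell/medium tension pulls the tissue outline toward a circle.  Balancing the
two in a rectangle approximation predicts the equilibrium intersegment
contact length L* and hence the final tissue aspect ratio.
"""

from segcpm import AdhesionTable, RED, GREEN, MEDIUM
from segcpm.metrics import equilibrium_contact_length, predicted_axis_lengths

for label, J_cm, J_rr, J_rg in [
    ("weak segment adhesion", 10, 12, 16),
    ("tension-grid maximum ", 10, 8, 18),
    ("stiff tissue         ", 24, 32, 44),
]:
    t = AdhesionTable.segmented(J_cm=J_cm, J_rr=J_rr, J_rg=J_rg)
    print(f"{label}: J_cm={J_cm:>2} J_rr={J_rr:>2} J_rg={J_rg:>2}"
          f"  -> gamma_rg={t.gamma(RED, GREEN):4.1f}"
          f"  gamma_cm={t.gamma(RED, MEDIUM):4.1f}")

print()
n, cell_area, cells_per_segment = 4, 100, 30
A_s = cell_area * cells_per_segment
for gamma_rg in (0, 4, 10):
    L = equilibrium_contact_length(n, A_s, gamma_rg, gamma_cm=6)
    long, short = predicted_axis_lengths(n, A_s, gamma_rg, gamma_cm=6)
    print(f"gamma_rg={gamma_rg:>2}, gamma_cm=6: L*={L:6.1f} sites, "
          f"predicted tissue {long:.0f} x {short:.0f} "
          f"(aspect {long/short:4.2f})")

print("""
At gamma_rg = 0 the tissue is square (no force opposes the medium tension);
raising the intersegment tension narrows the predicted interface L* and
stretches the stack of segments perpendicular to it.""")
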