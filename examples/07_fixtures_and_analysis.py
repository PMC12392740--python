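"""Planted configurations and the cluster analytics that recover them.

Fixtures have ground truth by construction: a dangler is a 12-subunit
shell with one misoriented subunit (26 of 30 bonds); a packed condensate
holds complete capsids on an FCC lattice at a chosen packing fraction.
"""

import math

from condcap.analysis import compute_yields, detect_bonds, find_clusters, off_target_fraction
from condcap.fixtures import packed_condensate, planted_dangler
from condcap.geometry import build_dodecahedron_subunit

template = build_dodecahedron_subunit(1.0)

dangler = planted_dangler(template, L=80.0, seed=0)
g = detect_bonds(dangler, template)
rep = find_clusters(g, state=dangler, template=template)
print(f"dangler fixture: {dangler.n} subunits, {g.number_of_edges()} bonds "
      f"-> complete={rep.n_complete}, danglers={rep.n_danglers}")
print(f"off-target fraction: {off_target_fraction(rep, dangler.n):.2f}")

R_c, eta = 16.0, 0.5
packed = packed_condensate(template, eta=eta, R_c=R_c, sigma_cap=5.1, seed=1)
g = detect_bonds(packed, template)
rep = find_clusters(g, state=packed, template=template, R_c=R_c + 5.1)
V = packed.box_L**3
V_c = 4.0 / 3.0 * math.pi * (R_c + 5.1) ** 3
f_c, f_c_c, f_c_bg = compute_yields(rep, packed.n, V, V_c)
print(f"\npacked condensate at eta={eta}: {packed.n // 12} capsids, "
      f"all complete: {rep.n_complete == packed.n // 12}")
print(f"yields: f_c={f_c:.3f} = f_c(condensate) {f_c_c:.3f} + f_c(background) {f_c_bg:.3f}")
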