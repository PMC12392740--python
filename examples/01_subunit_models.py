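"""Build the two capsid subunit models and inspect their geometry.

The dodecahedron model is a pentagonal subunit (5 vertex attractors, one
top and one bottom repulsive sphere); twelve of them close into a
dodecahedral shell with 30 bonds.  The icosahedron model is a triangular
subunit (45 excluders, 6 edge attractors); twenty close into a T=1
icosahedral shell.
"""

from condcap.geometry import (
    assemble_reference_capsid,
    build_dodecahedron_subunit,
    build_icosahedron_subunit,
    build_interaction_table,
    capsid_attraction_energy,
    estimate_capsid_diameter,
    min_bond_energy,
)

dodeca = build_dodecahedron_subunit(1.0)
table = build_interaction_table("dodecahedron", eps_ss=6.0)
capsid = assemble_reference_capsid("dodecahedron", dodeca)

print("dodecahedron subunit:")
print(f"  pseudoatoms: {dict((r, dodeca.roles.count(r)) for r in set(dodeca.roles))}")
print(f"  per-bond well depth at eps_ss=6: {-min_bond_energy(table):.2f} kT")
print(f"  capsid: {capsid.n_cap} subunits, {capsid.n_bonds_complete} bonds")
print(f"  capsid attraction energy: {capsid_attraction_energy(capsid, dodeca, table):.1f} kT")
print(f"  capsid circumscribed diameter: {estimate_capsid_diameter(capsid, dodeca):.2f} l0")

ico = build_icosahedron_subunit(1.0)
cap_i = assemble_reference_capsid("icosahedron", ico)
print("\nicosahedron subunit:")
print(f"  excluders: {ico.roles.count('EXC')}, attractors: {sum(1 for r in ico.roles if r != 'EXC')}")
print(f"  subunit diameter: {ico.shape_diameter:.2f} sigma")
print(f"  capsid: {cap_i.n_cap} subunits, {cap_i.n_bonds_complete} bonds")

# The per-bond energy sets the assembly regime: productive self-assembly
# needs bonds of roughly 8-10 kT; much stronger bonds trap malformed
# aggregates, much weaker ones never nucleate.
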