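"""Iterative-core superposition on a chain with a planted mobile domain.

Builds a 100-residue CA trace and a copy whose last 40 residues are rigidly
swung away (rotated 90° and shifted 20 Å), then lets the core-trimming
superposition find the conserved part.
"""

from p4ring import iterative_core_superpose
from p4ring.synthetic import two_domain_pair

a, b = two_domain_pair(n_core=60, n_displaced=40, displacement=20.0, seed=0)
sup = iterative_core_superpose(a, b)

print(f"residues equivalenced : {sup.n_equivalent} / {sup.n_min}")
print(f"fraction equivalenced : {sup.fraction_equivalent:.2f}")
print(f"core RMSD             : {sup.rmsd_core:.3f} A")
print(f"all-pair RMSD         : {sup.rmsd_all:.3f} A")
print(f"iterations            : {sup.iterations}")

# The fraction 0.60 and ~0 core RMSD mean the algorithm recovered exactly
# the 60 conserved residues and ignored the displaced domain; the all-pair
# RMSD stays large because it still includes the 40 moved residues.
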