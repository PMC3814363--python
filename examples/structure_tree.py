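"""Structure-based tree from all-vs-all superpositions.

Two structural "families" are simulated from two related folds (the second
fold has its C-terminal third shifted by 3 Å); every member gets its own
random orientation and 0.3 Å coordinate noise.  The pipeline superposes
all pairs, converts each superposition to a penalized-RMSD distance, and
builds a neighbor-joining tree.
"""

import numpy as np

from p4ring import build_matrix, nj_tree, to_newick
from p4ring.synthetic import PerturbationTruth, ca_trace, perturb, random_rotation

rng = np.random.default_rng(99)
base = ca_trace(60, seed=12)
base2 = ca_trace(60, seed=12)
for res in base2.chains[0].residues[40:]:
    res.atoms[0].coords = res.atoms[0].coords + np.array([3.0, 0.0, 0.0])

entries = []
for i in range(4):
    entries.append((f"fam{i}", perturb(
        base, PerturbationTruth(random_rotation(rng), rng.normal(0, 5, 3), 0.3),
        seed=100 + i)))
for i in range(3):
    entries.append((f"out{i}", perturb(
        base2, PerturbationTruth(random_rotation(rng), rng.normal(0, 5, 3), 0.3),
        seed=200 + i)))

matrix = build_matrix(entries, seed_mode="index")
print("distance matrix (penalized core RMSD, A):")
print(matrix.to_tsv())
tree = nj_tree(matrix)
print("NJ tree:", to_newick(tree))
print("fam clade recovered:", tree.is_monophyletic({"fam0", "fam1", "fam2", "fam3"}))

# Within-family distances (~0.7 A) are clearly below the between-family
# ones (~1.1 A), so the four fam leaves separate from the out leaves by a
# single edge — the clade-level signal the tree stage is designed to expose.
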