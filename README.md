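# p4ring

Structural comparison toolkit for hexameric ring NTPases — the packaging
motors of dsRNA bacteriophages and their RecA-type relatives — and for ring
oligomers generally.

Viral genome-packaging NTPases of the P4 family form hexameric rings that
translocate single-stranded RNA through a central channel. Homologues from
different phages share almost no sequence identity (often ~10–20%), so
comparing them is a structure-first problem: which parts of two folds are
equivalent, how far apart are the folds, how stable is the ring, how wide
is the channel, and which regions exchange fastest in solution. `p4ring`
implements that comparison pipeline as a tested Python library with a thin
CLI:

- **Rigid-body superposition with iterative core trimming**
  (`p4ring.superpose`). The engine is the Kabsch closed-form least-squares
  rotation; on top of it, residue pairs whose CA–CA distance exceeds a
  cutoff (default 3.8 Å) are iteratively trimmed until the structurally
  conserved core is stable. Reports core RMSD, the fraction of residues
  equivalenced, f = n_eq / n_min, and structure-based sequence identity
  over the core.
- **Structure-based phylogeny** (`p4ring.phylo`). All-vs-all
  superpositions are condensed to a distance matrix with the penalized
  RMSD d = RMSD_core · n_min / n_eq, and a neighbor-joining tree is built
  (deterministic tie-breaks, negative branches clamped, exact on additive
  matrices). Newick in/out.
- **Interface analysis** (`p4ring.interface`). Shrake–Rupley SASA over
  Bondi radii; buried interface area BSA = (SASA_A + SASA_B − SASA_AB)/2;
  hydrogen-bond, salt-bridge and hydrophobic contact inventories on heavy
  atoms; and the ring-stability statistic **polar-contact density** =
  (H-bonds + salt bridges) / BSA, per Å².
- **Channel geometry** (`p4ring.channel`). Symmetry-axis detection from CA
  inertia, slab-wise pore-radius profile r(z) = min_atoms (d_axis − r_vdW),
  constriction and external diameters.
- **HDX mapping** (`p4ring.hdx`). Peptide-level hydrogen–deuterium
  exchange rates averaged onto residues (average-rate colouring), ordinal
  slow→fast classes, condition differences, and painting onto the PDB
  B-factor column.
- **Synthetic ground truth** (`p4ring.synthetic`). Cn-symmetric rings,
  perturbed copies with known rotation/translation/noise, planted
  two-domain chains, toy contact geometries, additive distance matrices
  from known trees, and overlapping-peptide HDX tables — every stage is
  testable without downloading anything.

## Worked example

Recover a planted conserved core:

```python
from p4ring import iterative_core_superpose
from p4ring.synthetic import two_domain_pair

a, b = two_domain_pair(n_core=60, n_displaced=40, displacement=20.0, seed=0)
sup = iterative_core_superpose(a, b)
print(sup.fraction_equivalent, round(sup.rmsd_core, 3), round(sup.rmsd_all, 3))
```

prints

```
0.6 0.0 20.01
```

Exactly the 60 conserved residues were equivalenced (fraction 0.60) with a
core RMSD of 0; the all-pair RMSD stays at ~20 Å because it includes the
40 residues that were rigidly swung away. The scripts in `examples/` walk
through each capability the same way (tree building, interface density,
channel profiling, HDX mapping) and print what the numbers mean.

From a shell, the same stages are available as subcommands:

```sh
p4ring simulate --out ring.pdb --ring-radius 10
p4ring channel ring.pdb --out profile.tsv
# min_channel_diameter=16.60 external_diameter=23.40 z_of_constriction=-10.00
```

(6 tube subunits at 10 Å from the axis, carbon vdW 1.7 Å: pore radius
10 − 1.7 = 8.3 Å, so the channel diameter is 16.6 Å and the external
diameter 2 × (10 + 1.7) = 23.4 Å.)

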