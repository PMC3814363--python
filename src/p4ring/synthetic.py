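"""Synthetic fixtures with known ground truth for every pipeline stage.

Generators cover: Cn-symmetric rings built from a subunit template (the
hexamer-with-central-channel architecture), rigidly perturbed copies with
the perturbation returned alongside, CA-trace chains for superposition
tests, two-domain chains with a planted rigid displacement, toy inter-chain
contact geometries, additive distance matrices derived from known trees,
and overlapping-peptide HDX tables.

Everything is deterministic under a fixed seed, and no attempt is made to
produce stereochemically valid proteins — the toys are built so geometry
oracles are closed-form (single-radius carbon pseudo-atoms, vdW 1.7 Å).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import skbio

from .model import Atom, Chain, Residue, StructureModel
from .phylo import DistanceMatrix

AA20 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]

CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class RingSpec:
    """Specification for a Cn-symmetric ring of template copies."""

    n_subunits: int = 6
    ring_radius: float = 25.0  # Å, axis → template local origin
    subunit_template: StructureModel | str = "tube"
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ValueError("n_subunits must be ≥ 3")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise ValueError("axis must be a non-zero vector")
        self.axis = self.axis / norm


@dataclass
class PerturbationTruth:
    """Known rigid perturbation plus coordinate noise level."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-10) \
                or abs(np.linalg.det(self.rotation) - 1.0) > 1e-10:
            raise ValueError("rotation must be orthonormal with det +1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# Subunit templates (local frame: +x points away from the ring axis,
# +z along the axis)

def single_atom_template() -> StructureModel:
    """One carbon pseudo-atom at the local origin."""
    atom = Atom("CA", "C", np.zeros(3))
    res = Residue(1, "ALA", atoms=[atom])
    return StructureModel("single", [Chain("T", [res])])


def tube_template(length: float = 20.0, n_atoms: int = 11) -> StructureModel:
    """Carbon pseudo-atoms on a line along local z (a tube wall segment)."""
    zs = np.linspace(-length / 2, length / 2, n_atoms)
    residues = [Residue(i + 1, "ALA", atoms=[Atom("CA", "C", np.array([0.0, 0.0, z]))])
                for i, z in enumerate(zs)]
    return StructureModel("tube", [Chain("T", residues)])


def ca_trace(n_residues: int, seed: int = 0, chain_id: str = "A",
             start_number: int = 1, jitter: float = 1.0) -> StructureModel:
    """CA-only trace with a seeded random sequence.

    α-helix CA geometry (radius 2.3 Å, 100° twist, 1.5 Å rise, ~3.8 Å
    consecutive spacing) plus seeded Gaussian jitter.  The jitter breaks
    the helix's screw self-similarity so superpositions onto the trace
    have a unique optimum; non-collinear by construction.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be ≥ 1")
    rng = np.random.default_rng(seed)
    names = rng.choice(AA20, size=n_residues)
    offsets = rng.normal(0.0, jitter, (n_residues, 3)) if jitter > 0 else np.zeros((n_residues, 3))
    residues = []
    for i in range(n_residues):
        ang = np.radians(100.0 * i)
        pos = np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i]) + offsets[i]
        residues.append(Residue(start_number + i, str(names[i]),
                                atoms=[Atom("CA", "C", pos)]))
    return StructureModel(f"trace{n_residues}", [Chain(chain_id, residues)])


def _resolve_template(template: StructureModel | str) -> StructureModel:
    if isinstance(template, StructureModel):
        return template
    if template == "tube":
        return tube_template()
    if template == "single":
        return single_atom_template()
    if template == "trace":
        return ca_trace(30)
    raise ValueError(f"unknown template name {template!r}")


def _frame(axis: np.ndarray) -> np.ndarray:
    """Orthonormal frame with third column = axis."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return np.column_stack([u, v, a])


def make_ring(spec: RingSpec) -> StructureModel:
    """Cn-symmetric ring: template copies every 360°/n about the axis.

    The template's local frame is mapped so local +x points radially
    outward; each chain k is the template placed at ``ring_radius`` and
    rotated by k·360/n.  Deterministic given the spec.
    """
    template = _resolve_template(spec.subunit_template)
    if template.n_atoms() == 0:
        raise ValueError("template has no atoms")
    F = _frame(spec.axis)  # columns u, v, axis
    chains = []
    for k in range(spec.n_subunits):
        Rk = rotation_about(spec.axis, 360.0 * k / spec.n_subunits)
        residues = []
        for tmpl_chain in template.chains:
            for res in tmpl_chain.residues:
                atoms = []
                for a in res.atoms:
                    local = a.coords + np.array([spec.ring_radius, 0.0, 0.0])
                    atoms.append(Atom(a.name, a.element, Rk @ (F @ local),
                                      a.occupancy, a.b_factor, a.altloc))
                residues.append(Residue(res.number, res.name, res.icode, atoms, res.het))
        chains.append(Chain(CHAIN_IDS[k % len(CHAIN_IDS)], residues))
    return StructureModel(f"ring{spec.n_subunits}", chains,
                          {"generator": "make_ring", "seed": str(spec.seed)})


def perturb(model: StructureModel, truth: PerturbationTruth,
            seed: int = 0) -> StructureModel:
    """Apply coords' = R·x + t + N(0, σ²) i.i.d. per Cartesian coordinate."""
    rng = np.random.default_rng(seed)
    out = model.transformed(truth.rotation, truth.translation)
    if truth.noise_sigma > 0:
        for c in out.chains:
            for r in c.residues:
                for a in r.atoms:
                    a.coords = a.coords + rng.normal(0.0, truth.noise_sigma, 3)
    out.metadata["perturbed"] = "true"
    return out


def two_domain_pair(n_core: int = 60, n_displaced: int = 40,
                    displacement: float = 20.0, domain_rotation_deg: float = 90.0,
                    seed: int = 0) -> tuple[StructureModel, StructureModel]:
    """A chain and a copy whose second domain is rigidly displaced.

    Residues 1..n_core match exactly; residues n_core+1..n_core+n_displaced
    of the copy are rigidly moved — rotated about their centroid and
    shifted by ``displacement`` Å.  Ground truth for iterative core
    trimming: the conserved core is exactly the first domain, so the
    expected fraction equivalenced is n_core / (n_core + n_displaced).
    """
    a = ca_trace(n_core + n_displaced, seed=seed)
    b = ca_trace(n_core + n_displaced, seed=seed)
    moved = b.chains[0].residues[n_core:]
    pts = np.array([res.atoms[0].coords for res in moved])
    centroid = pts.mean(axis=0)
    R = rotation_about([0.0, 1.0, 0.0], domain_rotation_deg)
    shift = np.array([displacement, 0.0, 0.0])
    for res in moved:
        for atom in res.atoms:
            atom.coords = R @ (atom.coords - centroid) + centroid + shift
    b.id = a.id + "_displaced"
    return a, b


# ---------------------------------------------------------------------------
# Toy contact geometries

_SIDECHAIN_STUB = {
    "SER": "OG", "ASP": "OD1", "GLU": "OE1", "LYS": "NZ", "ARG": "NH1",
    "LEU": "CD1", "ALA": "CB", "ASN": "OD1", "GLN": "NE2", "THR": "OG1",
}


def _contact_residue(name: str, atom_name: str, anchor: np.ndarray,
                     direction: float, number: int) -> Residue:
    """Residue whose named atom sits at ``anchor``; backbone stubs behind it."""
    d = np.array([direction, 0.0, 0.0])
    atoms = [
        Atom(atom_name, "", anchor.astype(float)),
        Atom("CA", "C", anchor + 3.0 * d),
        Atom("N", "N", anchor + 3.0 * d + np.array([0.0, 1.5, 0.0])),
        Atom("C", "C", anchor + 3.0 * d + np.array([0.0, -1.5, 0.0])),
        Atom("O", "O", anchor + 4.5 * d + np.array([0.0, -1.5, 0.0])),
    ]
    if atom_name in ("N", "CA", "C", "O"):
        atoms = [a for a in atoms if a.name != atom_name or a is atoms[0]]
    return Residue(number, name, atoms=atoms)


def contact_pair_model(res_a: tuple[str, str], res_b: tuple[str, str],
                       distance: float) -> StructureModel:
    """Two single-residue chains with the named atoms exactly ``distance`` apart.

    All other atoms point away from the interface so only the constructed
    pair can satisfy contact criteria.
    """
    name_a, atom_a = res_a
    name_b, atom_b = res_b
    ra = _contact_residue(name_a, atom_a, np.zeros(3), direction=-1.0, number=1)
    rb = _contact_residue(name_b, atom_b, np.array([distance, 0.0, 0.0]),
                          direction=+1.0, number=1)
    return StructureModel("contact_pair",
                          [Chain("A", [ra]), Chain("B", [rb])],
                          {"constructed_distance": f"{distance:g}"})


def slab_interface_model(n_per_side: int = 16, gap: float = 4.0,
                         spacing: float = 3.0) -> StructureModel:
    """Two parallel square slabs of apolar carbons facing each other.

    A touching two-chain fixture for buried-area tests: the slabs sit
    ``gap`` Å apart so removal of either fully exposes the facing surface.
    """
    side = int(round(np.sqrt(n_per_side)))
    chains = []
    for ci, x in enumerate([0.0, gap]):
        residues = []
        num = 1
        for i in range(side):
            for j in range(side):
                pos = np.array([x, i * spacing, j * spacing])
                residues.append(Residue(num, "LEU",
                                        atoms=[Atom("CD1", "C", pos)]))
                num += 1
        chains.append(Chain("AB"[ci], residues))
    return StructureModel("slabs", chains)


# ---------------------------------------------------------------------------
# Additive distance matrices from known trees

def make_additive_matrix(newick: str) -> DistanceMatrix:
    """Additive distance matrix: entry (i,j) = leaf-to-leaf path length.

    By additivity, neighbor-joining on this matrix recovers the source
    topology and branch lengths exactly — the main oracle for the tree
    machinery.
    """
    try:
        tree = skbio.TreeNode.read(io.StringIO(newick))
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    tips = list(tree.tips())
    if len(tips) < 3:
        raise ValueError(f"tree has {len(tips)} leaves; need at least 3")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length in input tree")
    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    return DistanceMatrix(labels, np.asarray(dm.data), metric="path")


def random_additive_tree(n_leaves: int, rng: np.random.Generator,
                         min_len: float = 0.3, max_len: float = 2.0) -> str:
    """Random unrooted binary tree as Newick, branch lengths ≥ min_len.

    Lengths are bounded away from zero so the generating topology is the
    unique additive fit and exact recovery is well-posed.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    items = [f"L{i+1}" for i in range(n_leaves)]

    def blen() -> float:
        return float(rng.uniform(min_len, max_len))

    while len(items) > 3:
        idx = rng.choice(len(items), size=2, replace=False)
        i, j = sorted(int(x) for x in idx)
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a}:{blen():.4f},{b}:{blen():.4f})")
    return (f"({items[0]}:{blen():.4f},{items[1]}:{blen():.4f},"
            f"{items[2]}:{blen():.4f});")


# ---------------------------------------------------------------------------
# HDX peptide fixtures

def make_hdx_fixture(n_residues: int,
                     peptides: list[tuple[int, int, float]],
                     seed: int = 0,
                     condition: str = "apo") -> str:
    """TSV peptide table (start, end, rate, condition), one row per peptide.

    Overlapping peptides are the tested case, never an error.
    """
    lines = ["start\tend\trate\tcondition"]
    for start, end, rate in peptides:
        if not (1 <= start <= end <= n_residues):
            raise ValueError(f"peptide ({start}, {end}) outside 1..{n_residues}")
        if rate < 0:
            raise ValueError(f"negative rate {rate}")
        lines.append(f"{start}\t{end}\t{rate:g}\t{condition}")
    return "\n".join(lines) + "\n"


def hdx_gradient_fixture(n_residues: int = 60, peptide_len: int = 8,
                         step: int = 4, base_rate: float = 0.05,
                         slope: float = 0.01, seed: int = 0,
                         condition: str = "apo") -> str:
    """Overlapping peptides whose rates increase toward the C-terminus.

    Emulates a protein whose C-terminal region exchanges fastest; the
    derived per-residue map must be monotone non-decreasing along the chain.
    """
    peptides = []
    start = 1
    while start + peptide_len - 1 <= n_residues:
        end = start + peptide_len - 1
        peptides.append((start, end, base_rate + slope * start))
        start += step
    return make_hdx_fixture(n_residues, peptides, seed=seed, condition=condition)
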