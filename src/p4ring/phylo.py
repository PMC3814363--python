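"""Structure-based phylogeny: distance matrices from superpositions and
neighbor-joining trees.

The all-vs-all superposition of a set of comparison cores is condensed to a
symmetric structural-distance matrix and an unrooted NJ tree.  The default
distance is an SAS-like penalized RMSD, ``rmsd_core · n_min / n_equivalent``
— core RMSD inflated by the unaligned fraction — chosen because it is zero
exactly for identical fully-equivalenced structures and grows with both
divergence and loss of alignable core.  The metric is pluggable and its
name is recorded in output metadata so distances stay comparable.

Neighbor-joining is implemented here (rather than delegated) to guarantee
deterministic tie-breaking by label order and explicit clamping of negative
branch lengths with the clamped deficit recorded on the tree; NJ is exact
on additive matrices, which is the main test oracle.
"""

from __future__ import annotations

import io
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .model import StructureModel
from .superpose import AlignmentPair, SuperpositionResult, iterative_core_superpose, seed_alignment

logger = logging.getLogger(__name__)

METRICS = ("sas", "rmsd")


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray
    metric: str = "sas"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-8):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-8):
            raise ValueError("matrix diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise ValueError("matrix contains negative distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    def to_tsv(self, path=None) -> str:
        df = pd.DataFrame(self.d, index=self.labels, columns=self.labels)
        text = df.to_csv(sep="\t", float_format="%.6g")
        if path is not None:
            with open(path, "w") as fh:
                fh.write(f"# metric={self.metric}\n")
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        """Read a labelled TSV matrix (or square PHYLIP) back."""
        with open(path) as fh:
            lines = fh.readlines()
        metric = "sas"
        body = []
        for ln in lines:
            if ln.startswith("#"):
                if "metric=" in ln:
                    metric = ln.split("metric=")[1].strip()
                continue
            if ln.strip():
                body.append(ln)
        first = body[0].split()
        if len(first) == 1 and first[0].isdigit():
            # PHYLIP square: count line, then "label d d d ..."
            n = int(first[0])
            labels, rows = [], []
            for ln in body[1:n + 1]:
                parts = ln.split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
            return cls(labels, np.array(rows), metric)
        df = pd.read_csv(io.StringIO("".join(body)), sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float), metric)


@dataclass
class PhyloTree:
    """Unrooted tree (stored rooted at a degree-3 node) with leaf labels."""

    root: skbio.TreeNode
    labels: list[str]
    clamped_deficit: float = 0.0
    method: str = "nj"

    def tip_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (rooting-independent)."""
        dm = self.root.tip_tip_distances()
        order = list(dm.ids)
        mat = np.asarray(dm.data)
        idx = [order.index(l) for l in self.labels]
        return DistanceMatrix(self.labels, mat[np.ix_(idx, idx)], metric="path")

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (each as the smaller-side label set)."""
        all_tips = frozenset(self.labels)
        out = set()
        for node in self.root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_tips) - 1:
                other = all_tips - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def is_monophyletic(self, group: set[str]) -> bool:
        """True if the group is separated from the rest by a single edge."""
        group = frozenset(group)
        if not group <= set(self.labels):
            raise ValueError("group contains labels not in the tree")
        if len(group) <= 1 or len(group) >= len(self.labels) - 1:
            return True  # trivial splits always exist on an unrooted tree
        rest = frozenset(self.labels) - group
        key = min(group, rest, key=lambda s: (len(s), sorted(s)))
        return key in self.bipartitions()


def structural_distance(sup: SuperpositionResult, metric: str = "sas") -> float:
    """Scalar structural distance from a converged superposition.

    ``sas``: rmsd_core × n_min / n_equivalent — RMSD penalized by the
    fraction of the smaller structure that could not be equivalenced.
    ``rmsd``: plain core RMSD.
    """
    if sup.n_equivalent == 0:
        raise ValueError("superposition has no equivalenced residues")
    if metric == "sas":
        return sup.rmsd_core * sup.n_min / sup.n_equivalent
    if metric == "rmsd":
        return sup.rmsd_core
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def build_matrix(entries: list[tuple[str, StructureModel]],
                 metric: str = "sas",
                 cutoff: float = 3.8,
                 seed_mode: str = "sequence",
                 max_iter: int = 50) -> DistanceMatrix:
    """All-vs-all iterative-core superposition → symmetric distance matrix.

    Each entry is (label, core region model), e.g. structures already
    truncated to a common comparison core with
    :func:`p4ring.model.extract_region`.  Both directions of every pair are
    superposed and the two distances averaged, which symmetrizes the small
    direction dependence of core trimming.
    """
    if len(entries) < 3:
        raise ValueError("need at least 3 entries for a distance matrix")
    labels = [lab for lab, _ in entries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate entry labels")
    n = len(entries)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        la, ma = entries[i]
        lb, mb = entries[j]
        try:
            sup_ab = iterative_core_superpose(
                ma, mb, seed_alignment(ma, mb, mode=seed_mode),
                cutoff=cutoff, max_iter=max_iter)
            sup_ba = iterative_core_superpose(
                mb, ma, seed_alignment(mb, ma, mode=seed_mode),
                cutoff=cutoff, max_iter=max_iter)
        except ValueError as exc:
            raise ValueError(f"pair ({la}, {lb}): {exc}") from exc
        d_ab = structural_distance(sup_ab, metric)
        d_ba = structural_distance(sup_ba, metric)
        d[i, j] = d[j, i] = 0.5 * (d_ab + d_ba)
    return DistanceMatrix(labels, d, metric)


def nj_tree(m: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix.

    Standard Saitou–Nei NJ with deterministic tie-breaking by label order
    and negative branch lengths clamped to zero (total clamped length
    recorded as ``clamped_deficit`` and logged).  Exact on additive
    matrices.  The returned tree is unrooted, represented with a degree-3
    root.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError(f"need at least 3 labels for a tree, got {n}")
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    nodes: list[skbio.TreeNode] = [skbio.TreeNode(name=lab) for lab in m.labels]
    D = m.d.copy()
    active = list(range(n))

    while len(active) > 3:
        na = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic: first (row-major over label order) minimal Q
        flat = np.argmin(q)
        ai, aj = np.unravel_index(flat, q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (na - 2))
        lj = dij - li
        li, lj = clamp(li), clamp(lj)
        parent = skbio.TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # new distances to remaining nodes
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final 3-star: closed-form branch lengths
    i, j, k = active
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    root = skbio.TreeNode()
    nodes[i].length = li
    nodes[j].length = lj
    nodes[k].length = lk
    root.extend([nodes[i], nodes[j], nodes[k]])
    if deficit > 0:
        logger.info("nj_tree: clamped %.6g of negative branch length to 0", deficit)
    return PhyloTree(root, list(m.labels), clamped_deficit=deficit, method="nj")


def upgma_tree(m: DistanceMatrix) -> PhyloTree:
    """UPGMA alternative (rooted ultrametric clustering), for comparison."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    if len(m.labels) < 3:
        raise ValueError("need at least 3 labels for a tree")
    z = hierarchy.average(squareform(m.d, checks=False))
    sk = skbio.TreeNode.from_linkage_matrix(z, m.labels)
    return PhyloTree(sk, list(m.labels), method="upgma")


def _newick_of(node: skbio.TreeNode) -> str:
    if node.is_tip():
        body = node.name or ""
    else:
        body = "(" + ",".join(_newick_of(c) for c in node.children) + ")"
        if node.name:
            body += node.name
    if node.length is not None:
        body += f":{node.length:.6g}"
    return body


def to_newick(t: PhyloTree, path=None) -> str:
    """Serialize with branch lengths at 6 significant digits."""
    text = _newick_of(t.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def from_newick(text: str) -> PhyloTree:
    """Parse a Newick string (round-trip partner of :func:`to_newick`)."""
    root = skbio.TreeNode.read(io.StringIO(text))
    labels = [t.name for t in root.tips()]
    if len(labels) < 3:
        raise ValueError(f"tree has {len(labels)} leaves; need at least 3")
    return PhyloTree(root, labels)
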