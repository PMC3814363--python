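"""Subunit-interface analysis: solvent accessibility, buried area, contact
inventories and polar-contact density.

The stability of a hexameric ring does not track buried interface area; it
tracks how polar the interface is.  The statistic computed here is the
polar-contact density — (hydrogen bonds + salt bridges) per buried Å² —
for each adjacent chain pair of a ring.

SASA is a Shrake–Rupley sphere-point sampler over Bondi vdW radii with a
water-sized probe; hydrogens and waters are excluded from both the surface
and the occlusion set.  Contact detection is heavy-atom only with
inclusive distance cutoffs (3.5 Å H-bond, 4.0 Å salt bridge, 4.5 Å
apolar carbon–carbon), since crystal structures at typical resolution carry
no hydrogens.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import chemistry
from .chemistry import VDW_TABLE_NAME, vdw_radius
from .model import StructureModel

HBOND_CUTOFF = 3.5
SALT_BRIDGE_CUTOFF = 4.0
HYDROPHOBIC_CUTOFF = 4.5


@dataclass
class SASAResult:
    per_atom: np.ndarray  # Å², aligned with `atoms`
    atoms: list[tuple[str, int, str, str]]  # (chain, resnum, icode, atom name)
    probe_radius: float
    n_points: int
    radii_set: str = VDW_TABLE_NAME

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass
class ContactRecord:
    kind: str  # hbond | salt_bridge | hydrophobic
    atom_a: tuple[str, int, str, str, str]  # chain, resnum, icode, resname, atom
    atom_b: tuple[str, int, str, str, str]
    distance: float


@dataclass
class InterfaceReport:
    chain_a: str
    chain_b: str
    bsa: float  # Å², per-side average by default
    n_hbonds: int
    n_salt_bridges: int
    n_hydrophobic: int
    n_polar_unique: int  # hbond ∪ salt-bridge atom pairs, double-counts removed
    polar_density: float  # n_polar_unique / bsa, per Å²
    bsa_convention: str = "per-side-average"


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _sasa_atoms(model: StructureModel):
    out = []
    for c, r, a in model.atoms(include_waters=False, include_hydrogens=False):
        out.append((c.id, r.number, r.icode, a.name, a.element, a.coords))
    return out


def sasa(model: StructureModel, probe: float = 1.4,
         n_points: int = 960) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area, per atom.

    Each atom's accessible area is the fraction of ``n_points`` sphere
    points (at radius vdW + probe) not inside any neighbour's expanded
    sphere, times the expanded-sphere area.  Raises for elements missing
    from the radius table, naming the element.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be ≥ 100 for a usable estimate")
    atoms = _sasa_atoms(model)
    if not atoms:
        raise ValueError("no non-water heavy atoms in model")
    coords = np.array([a[5] for a in atoms])
    radii = np.array([vdw_radius(a[4]) + probe for a in atoms])
    unit = _sphere_points(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                 if j != i]
        if neigh:
            nc = coords[neigh]
            nr = radii[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr ** 2)[None, :] - 1e-12).any(axis=1)
            free = np.count_nonzero(~buried)
        else:
            free = n_points
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * free / n_points
    return SASAResult(per_atom=areas,
                      atoms=[(a[0], a[1], a[2], a[3]) for a in atoms],
                      probe_radius=probe, n_points=n_points)


def buried_area(model: StructureModel, chain_a: str, chain_b: str,
                probe: float = 1.4, n_points: int = 960,
                halved: bool = True) -> float:
    """Buried surface area between two chains, Å².

    bsa = SASA(A alone) + SASA(B alone) − SASA(A+B complex), halved by
    default (per-side average) so the value reads as "interface size".
    All chains other than A and B are removed first.  Non-contacting
    chains give ≈ 0, not an error.
    """
    sa = sasa(model.subset_chains([chain_a]), probe, n_points).total
    sb = sasa(model.subset_chains([chain_b]), probe, n_points).total
    sab = sasa(model.subset_chains([chain_a, chain_b]), probe, n_points).total
    delta = sa + sb - sab
    return 0.5 * delta if halved else delta


def _typed_atoms(model: StructureModel, chain_id: str):
    """(address, coords) lists per role for one chain, heavy atoms only."""
    donors, acceptors, basic, acidic, apolar = [], [], [], [], []
    chain = model.chain(chain_id)
    for r in chain.residues:
        if r.is_water:
            continue
        for a in r.atoms:
            if a.element.upper() == "H":
                continue
            addr = (chain.id, r.number, r.icode, r.name, a.name)
            entry = (addr, a.coords)
            if chemistry.is_hbond_donor(r.name, a.name):
                donors.append(entry)
            if chemistry.is_hbond_acceptor(r.name, a.name):
                acceptors.append(entry)
            if chemistry.is_salt_bridge_basic(r.name, a.name):
                basic.append(entry)
            if chemistry.is_salt_bridge_acidic(r.name, a.name):
                acidic.append(entry)
            if chemistry.is_apolar_carbon(r.name, a.name, a.element):
                apolar.append(entry)
    return {"donor": donors, "acceptor": acceptors, "basic": basic,
            "acidic": acidic, "apolar": apolar}


def _cross_pairs(list_a, list_b, cutoff):
    """Atom pairs from two typed lists within an inclusive distance cutoff."""
    if not list_a or not list_b:
        return []
    ca = np.array([e[1] for e in list_a])
    cb = np.array([e[1] for e in list_b])
    tree = cKDTree(cb)
    out = []
    for i, hits in enumerate(tree.query_ball_point(ca, cutoff + 1e-9)):
        for j in hits:
            d = float(np.linalg.norm(ca[i] - cb[j]))
            if d <= cutoff + 1e-9:
                out.append((list_a[i][0], list_b[j][0], d))
    return out


def find_contacts(model: StructureModel, chain_a: str, chain_b: str,
                  kind: str,
                  hbond_cutoff: float = HBOND_CUTOFF,
                  salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
                  hydrophobic_cutoff: float = HYDROPHOBIC_CUTOFF,
                  ) -> list[ContactRecord]:
    """Inter-chain contacts of one kind, each atom pair reported once.

    hbond: donor heavy atom of one chain to acceptor heavy atom of the
    other, ≤ 3.5 Å (both directions considered).  salt_bridge: Lys NZ /
    Arg NE,NH* / His ND1,NE2 to Asp OD* / Glu OE*, ≤ 4.0 Å.  hydrophobic:
    apolar carbon to apolar carbon, ≤ 4.5 Å.  Cutoffs inclusive.
    """
    if kind not in ("hbond", "salt_bridge", "hydrophobic"):
        raise ValueError(f"unknown contact kind {kind!r}")
    ta = _typed_atoms(model, chain_a)
    tb = _typed_atoms(model, chain_b)
    seen: dict[tuple, float] = {}
    if kind == "hbond":
        raw = (_cross_pairs(ta["donor"], tb["acceptor"], hbond_cutoff)
               + [(a, b, d) for b, a, d in
                  _cross_pairs(tb["donor"], ta["acceptor"], hbond_cutoff)])
    elif kind == "salt_bridge":
        raw = (_cross_pairs(ta["basic"], tb["acidic"], salt_bridge_cutoff)
               + [(a, b, d) for b, a, d in
                  _cross_pairs(tb["basic"], ta["acidic"], salt_bridge_cutoff)])
    else:
        raw = _cross_pairs(ta["apolar"], tb["apolar"], hydrophobic_cutoff)
    for addr_a, addr_b, d in raw:
        key = (addr_a, addr_b)
        if key not in seen:
            seen[key] = d
    return [ContactRecord(kind, a, b, d) for (a, b), d in sorted(seen.items())]


def interface_report(model: StructureModel, chain_a: str, chain_b: str,
                     probe: float = 1.4, n_points: int = 960,
                     halved: bool = True) -> InterfaceReport:
    """Full per-interface report with the polar-contact-density statistic.

    Atom pairs qualifying as both hydrogen bond and salt bridge are counted
    in both inventories but only once in the polar numerator.
    """
    hb = find_contacts(model, chain_a, chain_b, "hbond")
    sb = find_contacts(model, chain_a, chain_b, "salt_bridge")
    hp = find_contacts(model, chain_a, chain_b, "hydrophobic")
    polar_pairs = {(c.atom_a, c.atom_b) for c in hb} | {(c.atom_a, c.atom_b) for c in sb}
    bsa = buried_area(model, chain_a, chain_b, probe, n_points, halved)
    if bsa <= 1.0 and polar_pairs:
        raise ValueError(
            f"inconsistent geometry: polar contacts present between chains "
            f"{chain_a}/{chain_b} but buried area is ~0 ({bsa:.2f} Å²)")
    density = len(polar_pairs) / bsa if bsa > 0 else 0.0
    return InterfaceReport(
        chain_a=chain_a, chain_b=chain_b, bsa=bsa,
        n_hbonds=len(hb), n_salt_bridges=len(sb), n_hydrophobic=len(hp),
        n_polar_unique=len(polar_pairs), polar_density=density,
        bsa_convention="per-side-average" if halved else "full")


def ring_interfaces(model: StructureModel, probe: float = 1.4,
                    n_points: int = 960, halved: bool = True
                    ) -> list[InterfaceReport]:
    """Reports for all adjacent chain pairs of a ring (A:B, B:C, …, last:A)."""
    ids = model.chain_ids()
    if len(ids) < 3:
        raise ValueError("ring must have at least 3 chains")
    reports = []
    for a, b in zip(ids, ids[1:] + ids[:1]):
        reports.append(interface_report(model, a, b, probe, n_points, halved))
    return reports


def mean_polar_density(reports: list[InterfaceReport]) -> float:
    return float(np.mean([r.polar_density for r in reports]))
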