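"""Hierarchical structure model: StructureModel → Chain → Residue → Atom.

Every downstream stage (superposition, interfaces, channel geometry, HDX
mapping) consumes only this representation.  Parsing of PDB and mmCIF is
delegated to gemmi; writing uses a fixed-column PDB writer so the B-factor
column can be controlled exactly.

Conventions: author residue numbering is authoritative and never changed;
residue ranges are inclusive; of alternate-location duplicates only the
highest-occupancy conformer is kept (ties broken alphabetically by altloc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

from .chemistry import STANDARD_AA, THREE_TO_ONE, WATER_NAMES, infer_element


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0,1]")
        if not self.element.strip():
            self.element = infer_element(self.name)


@dataclass
class Residue:
    number: int
    name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False  # waters and non-polymer heteroatoms are flagged, not dropped

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.name in STANDARD_AA

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number}{self.icode}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"chain {self.id}: duplicate (number, icode) residue keys")

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"chain {self.id}: no residue {number}{icode}")

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.het and not r.is_water]

    def ca_residues(self) -> list[Residue]:
        return [r for r in self.polymer_residues() if r.has_atom("CA")]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.ca_residues())


@dataclass
class StructureModel:
    id: str
    chains: list[Chain] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"structure {self.id}: duplicate chain ids")
        if not any(len(c) > 0 for c in self.chains):
            raise ValueError(f"structure {self.id}: no chain with at least one residue")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"structure {self.id}: no chain {chain_id!r}")

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def atoms(self, include_het: bool = True, include_waters: bool = True,
              include_hydrogens: bool = True) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                if r.is_water and not include_waters:
                    continue
                if r.het and not r.is_water and not include_het:
                    continue
                for a in r.atoms:
                    if a.element.upper() == "H" and not include_hydrogens:
                        continue
                    yield c, r, a

    def coords(self, **kwargs) -> np.ndarray:
        pts = [a.coords for _, _, a in self.atoms(**kwargs)]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with coords' = R·coords + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_chains = []
        for c in self.chains:
            new_res = []
            for r in c.residues:
                new_atoms = [Atom(a.name, a.element, R @ a.coords + t,
                                  a.occupancy, a.b_factor, a.altloc)
                             for a in r.atoms]
                new_res.append(Residue(r.number, r.name, r.icode, new_atoms, r.het))
            new_chains.append(Chain(c.id, new_res))
        return StructureModel(self.id, new_chains, dict(self.metadata))

    def subset_chains(self, chain_ids: Iterable[str]) -> "StructureModel":
        keep = set(chain_ids)
        chains = [c for c in self.chains if c.id in keep]
        missing = keep - {c.id for c in chains}
        if missing:
            raise KeyError(f"structure {self.id}: no chain(s) {sorted(missing)}")
        return StructureModel(self.id, chains, dict(self.metadata))


# ---------------------------------------------------------------------------
# Reading

def _dedup_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep, per atom name, the highest-occupancy altloc (ties → first alphabetically)."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        out.append(best)
    return out


def read_structure(source: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file (or raw text) into a StructureModel.

    Parameters
    ----------
    source
        File path, or the file content itself as text.
    fmt
        ``"pdb"`` or ``"mmcif"``; inferred from the file suffix when a path
        is given and fmt is None.

    Only model 1 of multi-model files is used.  Waters and non-polymer
    heteroatoms are retained but flagged ``het``; hydrogens are kept.
    """
    text: str | None = None
    label = "structure"
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        path = Path(source)
        label = path.stem
        text = path.read_text()
        if fmt is None:
            suffix = path.suffix.lower()
            fmt = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"
    else:
        text = str(source)
        if fmt is None:
            fmt = "pdb"

    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        elif fmt == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ParseError(f"unknown format {fmt!r}; expected 'pdb' or 'mmcif'")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {fmt} input: {exc}") from exc

    if st.name:
        label = st.name.lower() if fmt == "pdb" else st.name
    if len(st) == 0:
        raise ParseError("file contains no models")
    st.setup_entities()
    model = st[0]

    chains = []
    for gchain in model:
        residues = []
        for gres in gchain:
            atoms = []
            for ga in gres:
                el = ga.element.name if ga.element and ga.element.name != "X" else ""
                atoms.append(Atom(
                    name=ga.name,
                    element=el,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    b_factor=ga.b_iso,
                    altloc=(ga.altloc if ga.altloc != "\x00" else ""),
                ))
            atoms = _dedup_altlocs(atoms)
            het = gres.het_flag == "H"
            residues.append(Residue(
                number=gres.seqid.num,
                name=gres.name,
                icode=(gres.seqid.icode.strip() if gres.seqid.icode else ""),
                atoms=atoms,
                het=het,
            ))
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains or not any(len(c) for c in chains):
        raise ParseError("parsed model is empty (no chains with residues)")
    return StructureModel(label, chains, {"format": fmt})


# ---------------------------------------------------------------------------
# Region extraction

def extract_region(model: StructureModel, chain_id: str,
                   first: int, last: int) -> StructureModel:
    """Extract residues ``first..last`` (inclusive, author numbering) of a chain.

    Used to truncate entries to a common comparison core before
    superposition and tree building.
    """
    if first > last:
        raise ValueError(f"invalid range: first ({first}) > last ({last})")
    chain = model.chain(chain_id)
    selected = [r for r in chain.residues if first <= r.number <= last]
    if not selected:
        numbers = [r.number for r in chain.residues]
        raise ValueError(
            f"empty selection {first}-{last} in chain {chain_id}; "
            f"available residue numbers span {min(numbers)}-{max(numbers)}")
    return StructureModel(f"{model.id}_{chain_id}{first}-{last}",
                          [Chain(chain_id, selected)],
                          dict(model.metadata))


# ---------------------------------------------------------------------------
# Writing

def _format_atom_name(name: str, element: str) -> str:
    """PDB atom-name alignment: 1-letter elements start in column 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"[:4]


def write_pdb(model: StructureModel, path: str | Path | None = None) -> str:
    """Serialize to PDB text (ATOM/HETATM/TER/END); optionally write to path."""
    lines = []
    serial = 1
    for chain in model.chains:
        last_polymer = None
        for res in chain.residues:
            record = "HETATM" if (res.het or res.is_water) else "ATOM  "
            for a in res.atoms:
                if not (-999.999 <= min(a.coords) and max(a.coords) <= 9999.999):
                    raise ValueError(f"coordinate out of PDB field range: {a.coords}")
                if not (-99.99 <= a.b_factor <= 999.99):
                    raise ValueError(
                        f"B-factor {a.b_factor} not representable in the PDB "
                        f"B-factor field (width 6, 2 decimals)")
                name4 = _format_atom_name(a.name, a.element)
                lines.append(
                    f"{record}{serial % 100000:5d} {name4}{a.altloc or ' ':1s}"
                    f"{res.name:>3s} {chain.id[:1]:1s}{res.number:4d}"
                    f"{res.icode or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.b_factor:6.2f}          "
                    f"{a.element.strip().upper():>2s}")
                serial += 1
            if not res.het and not res.is_water:
                last_polymer = res
        if last_polymer is not None:
            lines.append(
                f"TER   {serial % 100000:5d}      {last_polymer.name:>3s} "
                f"{chain.id[:1]:1s}{last_polymer.number:4d}{last_polymer.icode or ' ':1s}")
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_with_bfactor(model: StructureModel,
                       values: Mapping[tuple[str, int, str], float],
                       default: float = 0.0,
                       path: str | Path | None = None) -> str:
    """Write PDB text with per-residue values in the B-factor column.

    ``values`` is keyed by ``(chain_id, residue_number, icode)``; every atom
    of an uncovered residue carries ``default``.  All other columns are
    unchanged.  The typical use is painting per-residue HDX exchange rates
    onto a structure for rendering in a molecular viewer.
    """
    for key, v in values.items():
        if not (-99.99 <= v <= 999.99):
            raise ValueError(f"value {v} for residue {key} not representable "
                             f"in the PDB B-factor field")
    if not (-99.99 <= default <= 999.99):
        raise ValueError(f"default {default} not representable in the PDB B-factor field")
    new_chains = []
    for c in model.chains:
        new_res = []
        for r in c.residues:
            v = values.get((c.id, r.number, r.icode), default)
            atoms = [Atom(a.name, a.element, a.coords.copy(), a.occupancy, v, a.altloc)
                     for a in r.atoms]
            new_res.append(Residue(r.number, r.name, r.icode, atoms, r.het))
        new_chains.append(Chain(c.id, new_res))
    painted = StructureModel(model.id, new_chains, dict(model.metadata))
    return write_pdb(painted, path)
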