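"""Declarative pipeline: one YAML config → superpositions, distance matrix
and tree, interface reports, channel profiles, HDX maps.

The config is validated fully before any computation starts (fail-fast on
missing files), every output carries a provenance header (tool version,
config hash, metric/convention names), and identical config + seed yields
byte-identical text outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .channel import channel_profile, ring_metrics
from .hdx import paint_structure, read_peptides, residue_rates
from .interface import ring_interfaces
from .model import StructureModel, extract_region, read_structure
from .phylo import build_matrix, nj_tree, to_newick

VALID_TASKS = ("phylo", "interface", "channel", "hdx")


@dataclass
class RunConfig:
    entries: list[dict]  # label, path, optional chain, optional core [first,last]
    tasks: list[str]
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "p4ring_out"
    hdx_tables: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            entries=raw.get("entries", []),
            tasks=raw.get("tasks", []),
            parameters=raw.get("parameters", {}) or {},
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "p4ring_out")),
            hdx_tables=raw.get("hdx_tables", []) or [],
        )

    def validate(self) -> None:
        if not self.tasks:
            raise ValueError("config lists no tasks")
        for t in self.tasks:
            if t not in VALID_TASKS:
                raise ValueError(f"unknown task {t!r}; valid: {VALID_TASKS}")
        labels = [e.get("label") for e in self.entries]
        if len(labels) != len(set(labels)):
            raise ValueError("entry labels must be unique")
        for e in self.entries:
            if "label" not in e or "path" not in e:
                raise ValueError(f"entry missing label/path: {e}")
            if not Path(e["path"]).exists():
                raise FileNotFoundError(f"structure file not found: {e['path']}")
        if "phylo" in self.tasks and len(self.entries) < 3:
            raise ValueError("phylo task needs at least 3 entries")
        if "hdx" in self.tasks:
            if not self.hdx_tables:
                raise ValueError("hdx task needs hdx_tables in the config")
            for p in self.hdx_tables:
                if not Path(p).exists():
                    raise FileNotFoundError(f"HDX peptide table not found: {p}")

    def digest(self) -> str:
        blob = json.dumps({
            "entries": self.entries, "tasks": self.tasks,
            "parameters": self.parameters, "seed": self.seed,
            "hdx_tables": self.hdx_tables,
        }, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _header(config: RunConfig, extra: dict | None = None) -> str:
    lines = [f"# p4ring {__version__}", f"# config_sha256={config.digest()}",
             f"# seed={config.seed}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _load_entry(entry: dict) -> StructureModel:
    model = read_structure(entry["path"])
    if entry.get("chain"):
        model = model.subset_chains([entry["chain"]])
    return model


def _core_region(entry: dict, model: StructureModel) -> StructureModel:
    if entry.get("core"):
        first, last = entry["core"]
        chain = entry.get("chain") or model.chain_ids()[0]
        base = read_structure(entry["path"])
        return extract_region(base, chain, int(first), int(last))
    return model


def run(config: RunConfig) -> dict[str, str]:
    """Execute the configured tasks; returns a manifest name → file path."""
    config.validate()
    p = config.parameters
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    models = {e["label"]: _load_entry(e) for e in config.entries}

    if "phylo" in config.tasks:
        cores = [(e["label"], _core_region(e, models[e["label"]]))
                 for e in config.entries]
        metric = p.get("metric", "sas")
        dm = build_matrix(cores, metric=metric,
                          cutoff=float(p.get("cutoff", 3.8)),
                          seed_mode=p.get("seed_mode", "sequence"))
        dist_path = outdir / "dist.tsv"
        with open(dist_path, "w") as fh:
            fh.write(_header(config, {"metric": metric}))
            fh.write(dm.to_tsv())
        manifest["distance_matrix"] = str(dist_path)
        tree = nj_tree(dm)
        tree_path = outdir / "tree.nwk"
        with open(tree_path, "w") as fh:
            fh.write(to_newick(tree) + "\n")
        manifest["tree"] = str(tree_path)

    if "interface" in config.tasks:
        rows = ["label\tchain_a\tchain_b\tbsa\tn_hbonds\tn_salt_bridges"
                "\tn_hydrophobic\tpolar_density"]
        for e in config.entries:
            model = models[e["label"]]
            if len(model.chains) < 3:
                continue
            for rep in ring_interfaces(model,
                                       probe=float(p.get("probe", 1.4)),
                                       n_points=int(p.get("n_points", 960)),
                                       halved=bool(p.get("halved_bsa", True))):
                rows.append(f"{e['label']}\t{rep.chain_a}\t{rep.chain_b}"
                            f"\t{rep.bsa:.1f}\t{rep.n_hbonds}"
                            f"\t{rep.n_salt_bridges}\t{rep.n_hydrophobic}"
                            f"\t{rep.polar_density:.6g}")
        path = outdir / "interfaces.tsv"
        conv = "per-side-average" if p.get("halved_bsa", True) else "full"
        path.write_text(_header(config, {"bsa_convention": conv})
                        + "\n".join(rows) + "\n")
        manifest["interfaces"] = str(path)

    if "channel" in config.tasks:
        rows = ["label\tz\tpore_radius\tn_atoms_in_slab"]
        metrics_rows = ["label\tmin_channel_diameter\texternal_diameter"
                        "\tz_of_constriction"]
        for e in config.entries:
            model = models[e["label"]]
            prof = channel_profile(model,
                                   step=float(p.get("step", 1.0)),
                                   slab=float(p.get("slab", 2.0)))
            met = ring_metrics(prof, model)
            for z, r, n in zip(prof.z, prof.pore_radius, prof.n_atoms_in_slab):
                rows.append(f"{e['label']}\t{z:.2f}\t{r:.3f}\t{n}")
            metrics_rows.append(f"{e['label']}\t{met.min_channel_diameter:.2f}"
                                f"\t{met.external_diameter:.2f}"
                                f"\t{met.z_of_constriction:.2f}")
        prof_path = outdir / "channel_profile.tsv"
        prof_path.write_text(_header(config, {"convention": "vdw-surface-min"})
                             + "\n".join(rows) + "\n")
        met_path = outdir / "channel_metrics.tsv"
        met_path.write_text(_header(config, {"convention": "vdw-surface-min"})
                            + "\n".join(metrics_rows) + "\n")
        manifest["channel_profile"] = str(prof_path)
        manifest["channel_metrics"] = str(met_path)

    if "hdx" in config.tasks:
        for table in config.hdx_tables:
            peptides = read_peptides(Path(table))
            rmap = residue_rates(peptides)
            stem = Path(table).stem
            map_path = outdir / f"hdx_{stem}_residues.tsv"
            with open(map_path, "w") as fh:
                fh.write(_header(config, {"condition": rmap.condition}))
                fh.write(rmap.to_tsv())
            manifest[f"hdx_map_{stem}"] = str(map_path)
            if config.entries:
                first = config.entries[0]
                pdb_path = outdir / f"hdx_{stem}_painted.pdb"
                paint_structure(models[first["label"]], rmap, path=pdb_path)
                manifest[f"hdx_painted_{stem}"] = str(pdb_path)

    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest"] = str(man_path)
    return manifest
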