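"""Optional fetch-by-accession helper (network required, never used by tests).

Downloads deposited coordinate files from the Protein Data Bank so the
replication workflow (:mod:`p4ring.replicate`) can run on the real
structures.  Kept strictly separate from the analysis code: everything
else in the package operates on local files only.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

PDB_URL = "https://files.rcsb.org/download/{accession}.pdb"


def fetch_pdb(accession: str, dest_dir: str | Path = ".",
              timeout: float = 60.0) -> Path:
    """Download ``{accession}.pdb`` into dest_dir; returns the file path."""
    acc = accession.strip().upper()
    if len(acc) != 4 or not acc[0].isdigit():
        raise ValueError(f"not a PDB accession: {accession!r}")
    dest = Path(dest_dir) / f"{acc}.pdb"
    if dest.exists():
        return dest
    dest.parent.mkdir(parents=True, exist_ok=True)
    url = PDB_URL.format(accession=acc)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest


def fetch_all(accessions: list[str], dest_dir: str | Path = ".") -> list[Path]:
    return [fetch_pdb(a, dest_dir) for a in accessions]
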