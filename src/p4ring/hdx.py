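"""Peptide-level hydrogen–deuterium exchange rates → per-residue maps.

HDX-MS reports exchange rates on overlapping proteolytic peptides.  For
structure colouring, each residue is assigned the arithmetic mean of the
rates of all peptides covering it ("average rate colouring"); uncovered
residues are flagged, never defaulted to zero.  The map can be binned into
ordinal classes (slow → fast) and written onto a structure's B-factor
column for rendering, and two conditions (e.g. apo vs +RNA) can be
differenced to localize exposure changes.

Deliberate simplifications, exposed as such: the mean is unweighted by
peptide length, no back-exchange correction is applied, and the N-terminal
residue of each peptide is included (common HDX practice excludes it
because the first amide's deuterium is lost during digestion).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import StructureModel, write_with_bfactor


@dataclass
class PeptideExchange:
    start: int
    end: int  # inclusive
    rate: float  # 1/time, units as supplied
    condition: str = "apo"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"peptide start {self.start} > end {self.end}")
        if self.rate < 0:
            raise ValueError(f"negative exchange rate {self.rate}")


@dataclass
class ResidueRateMap:
    """Per-residue mean exchange rate with coverage counts."""

    rates: dict[int, float]
    coverage: dict[int, int]
    condition: str = "apo"

    def __post_init__(self) -> None:
        if set(self.rates) != set(self.coverage):
            raise ValueError("rates and coverage must cover the same residues")
        if any(n < 1 for n in self.coverage.values()):
            raise ValueError("coverage counts must be ≥ 1 where a mean is defined")

    def residues(self) -> list[int]:
        return sorted(self.rates)

    def to_frame(self) -> pd.DataFrame:
        res = self.residues()
        return pd.DataFrame({"residue": res,
                             "mean_rate": [self.rates[r] for r in res],
                             "n_peptides": [self.coverage[r] for r in res]})

    def to_tsv(self, path=None) -> str:
        text = self.to_frame().to_csv(sep="\t", index=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def read_peptides(source: str | Path) -> list[PeptideExchange]:
    """Read a peptide table (TSV with start, end, rate[, condition])."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        df = pd.read_csv(source, sep="\t")
    else:
        df = pd.read_csv(io.StringIO(str(source)), sep="\t")
    if "condition" not in df.columns:
        df["condition"] = "apo"
    return [PeptideExchange(int(r.start), int(r.end), float(r.rate), str(r.condition))
            for r in df.itertuples()]


def residue_rates(peptides: list[PeptideExchange]) -> ResidueRateMap:
    """Average peptide rates onto residues.

    Each residue covered by ≥ 1 peptide gets the arithmetic mean of the
    covering peptides' rates (inclusive boundaries).  An empty peptide
    list yields an empty map; mixed conditions are an error.
    """
    conditions = {p.condition for p in peptides}
    if len(conditions) > 1:
        raise ValueError(f"mixed conditions in one map: {sorted(conditions)}")
    condition = conditions.pop() if conditions else "apo"
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for p in peptides:
        for res in range(p.start, p.end + 1):
            sums[res] = sums.get(res, 0.0) + p.rate
            counts[res] = counts.get(res, 0) + 1
    rates = {res: sums[res] / counts[res] for res in sums}
    return ResidueRateMap(rates, counts, condition)


def rate_classes(rate_map: ResidueRateMap, n_classes: int = 5,
                 scale: str = "linear",
                 uncovered_class: int = -1) -> dict[int, int]:
    """Bin residues into ordinal exchange classes (0 = slowest).

    Equal-width bins between the observed min and max on the chosen scale
    (``linear`` or ``log``); the fastest residue lands in the top class.
    With all rates identical every residue is class 0.  Only covered
    residues appear; callers paint ``uncovered_class`` elsewhere.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be ≥ 2")
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    if not rate_map.rates:
        return {}
    values = dict(rate_map.rates)
    if scale == "log":
        if any(v <= 0 for v in values.values()):
            raise ValueError("log scale requires strictly positive rates")
        values = {r: float(np.log(v)) for r, v in values.items()}
    lo = min(values.values())
    hi = max(values.values())
    if hi - lo < 1e-300:
        return {r: 0 for r in values}
    width = (hi - lo) / n_classes
    return {r: min(int((v - lo) / width), n_classes - 1) for r, v in values.items()}


def delta_map(a: ResidueRateMap, b: ResidueRateMap) -> ResidueRateMap:
    """Per-residue rate difference b − a over residues covered in both.

    Coverage of the delta is the minimum of the two coverages; residues
    covered in only one condition are absent.  Used to localize exposure
    changes between conditions (e.g. +RNA vs apo).
    """
    common = set(a.rates) & set(b.rates)
    rates = {r: b.rates[r] - a.rates[r] for r in common}
    coverage = {r: min(a.coverage[r], b.coverage[r]) for r in common}
    return ResidueRateMap(rates, coverage,
                          condition=f"{b.condition}-{a.condition}")


def paint_structure(model: StructureModel, rate_map: ResidueRateMap,
                    chain_id: str | None = None, default: float = 0.0,
                    path=None) -> str:
    """Write the rate map into the structure's B-factor column (PDB text).

    Rates are applied to every chain unless ``chain_id`` narrows the
    target; uncovered residues carry ``default``.
    """
    targets = [chain_id] if chain_id else model.chain_ids()
    values = {(cid, res, ""): rate
              for cid in targets for res, rate in rate_map.rates.items()}
    return write_with_bfactor(model, values, default=default, path=path)
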