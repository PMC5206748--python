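"""Epitope calling from mutant binding-level panels.

The mapping experiment measures, for each antibody, the SPR binding level
of a panel of antigen mutant sets relative to wild type (WT = 1.0).  A
mutant set whose binding level falls *below* a threshold fraction of WT
(default 0.20, strict inequality) marks its mutated positions as epitope
residues for that antibody; the called epitope is the union over such
mutant sets.  Mutant sets that knock out binding to more than one antibody
are flagged as possible fold disruptions but still counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import XdcError

DEFAULT_THRESHOLD = 0.20


@dataclass
class MutantPanel:
    """mutant_id → (mutated positions, binding level per antibody).

    ``levels`` is a DataFrame indexed by mutant_id with one column per
    antibody, values as fractions of the WT signal; ``positions`` maps
    mutant_id → list of mutated residue positions (author numbering).
    A WT row (empty position list, level 1.0 everywhere) anchors the scale.
    """

    levels: pd.DataFrame
    positions: dict[str, list[int]]

    def __post_init__(self) -> None:
        if (self.levels.to_numpy() < 0).any():
            raise ValueError("binding levels must be >= 0")
        missing = set(self.levels.index) - set(self.positions)
        if missing:
            raise ValueError(f"mutants without position lists: {sorted(missing)}")

    @property
    def antibodies(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def wt_id(self) -> str | None:
        for mid, pos in self.positions.items():
            if not pos and mid in self.levels.index:
                return mid
        return None

    @classmethod
    def from_csv(cls, path: str | Path) -> "MutantPanel":
        """Read ``mutant_id, positions, level_<Ab>...`` CSV.

        ``positions`` is a semicolon-separated residue list (empty for WT);
        levels may be given as fractions or percentages (auto-detected from
        the WT row).
        """
        df = pd.read_csv(path, dtype={"positions": str})
        df["positions"] = df["positions"].fillna("")
        level_cols = [c for c in df.columns if c.startswith("level_")]
        if not level_cols:
            raise XdcError(f"{path}: no level_* columns")
        positions = {
            str(r.mutant_id): [int(p) for p in str(r.positions).split(";") if p]
            for r in df.itertuples()
        }
        levels = df.set_index("mutant_id")[level_cols].astype(float)
        levels.columns = [c.removeprefix("level_") for c in levels.columns]
        levels.index = levels.index.astype(str)
        wt_rows = [m for m, p in positions.items() if not p]
        if wt_rows and levels.loc[wt_rows[0]].max() > 2.0:  # percentages
            levels = levels / 100.0
        return cls(levels, positions)


@dataclass
class EpitopeCall:
    """Called epitopes plus the evidence behind each call."""

    epitopes: dict[str, frozenset[int]]  # antibody → residue positions
    supporting_mutants: dict[str, list[str]]  # antibody → mutant ids
    threshold: float
    suspect_mutants: list[str] = field(default_factory=list)  # lost >1 antibody


def call_epitopes(panel: MutantPanel, threshold: float = DEFAULT_THRESHOLD) -> EpitopeCall:
    """Assign each antibody the union of positions of its knocked-out mutants.

    A mutant is knocked out for an antibody when its binding level is
    strictly below ``threshold`` (WT-relative fraction).
    """
    if panel.levels.empty:
        raise XdcError("empty panel")
    if panel.wt_id is None:
        raise XdcError("panel has no WT reference row (empty position list)")
    epitopes: dict[str, set[int]] = {ab: set() for ab in panel.antibodies}
    supporting: dict[str, list[str]] = {ab: [] for ab in panel.antibodies}
    suspect: list[str] = []
    for mid in sorted(panel.levels.index):
        pos = panel.positions[mid]
        if not pos:
            continue
        lost = [ab for ab in panel.antibodies if panel.levels.at[mid, ab] < threshold]
        if len(lost) > 1:
            suspect.append(mid)
        for ab in lost:
            epitopes[ab].update(pos)
            supporting[ab].append(mid)
    return EpitopeCall(
        epitopes={ab: frozenset(s) for ab, s in epitopes.items()},
        supporting_mutants=supporting,
        threshold=threshold,
        suspect_mutants=suspect,
    )


def epitope_overlap_report(
    callA: frozenset[int] | set[int], callB: frozenset[int] | set[int]
) -> dict[str, list[int]]:
    """Set algebra between two epitope calls (same numbering scheme)."""
    a, b = set(callA), set(callB)
    return {
        "shared": sorted(a & b),
        "unique_A": sorted(a - b),
        "unique_B": sorted(b - a),
    }
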