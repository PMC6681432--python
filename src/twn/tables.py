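"""Per-residue atom-class count tables.

The aggregate of ring assignments is a table with atom-class rows
(O, N, C, S), a Total row, and ratio rows (O,N)/Total, C/Total and
S/Total, one column per residue type.  Columns are ordered by the
Kyte-Doolittle hydropathy scale, most hydrophobic (Ile) first, so
hydrophobic and hydrophilic residues group visually.

Rendering conventions: zero counts print as blank cells; a ratio
prints only when its numerator is non-zero; ratios are rounded
half-up to two decimals (e.g. 215/344 -> 0.63).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

ATOM_CLASSES = ("O", "N", "C", "S")
RATIO_ROWS = ("O,N/Total", "C/Total", "S/Total")
SCOPES = ("combined", "backbone", "sidechain")

#: Kyte-Doolittle hydropathy order, most hydrophobic first.  His
#: tautomer names (HSD/HSE) slot where His sits on the scale.
KD_ORDER = (
    "ILE", "VAL", "LEU", "PHE", "CYS", "MET", "ALA", "GLY", "THR",
    "TRP", "SER", "TYR", "PRO", "HSD", "HSE", "HIS", "GLN", "ASP",
    "ASN", "GLU", "LYS", "ARG",
)

_DISPLAY = {name: name.capitalize() for name in KD_ORDER}


def residue_display(residue_name: str) -> str:
    """Three-letter display form (ILE -> Ile); unknown names pass through."""
    return _DISPLAY.get(residue_name.upper(), residue_name)


def ordered_columns(residues) -> list[str]:
    """Sort residue names: Kyte-Doolittle order first, others appended
    alphabetically."""
    rank = {name: i for i, name in enumerate(KD_ORDER)}
    known = sorted((r for r in residues if r.upper() in rank), key=lambda r: rank[r.upper()])
    other = sorted(r for r in residues if r.upper() not in rank)
    return known + other


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.625 -> 0.63), as in printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CountsTable:
    """Residue x atom-class counts for one ring size and scope.

    ``counts`` is indexed by atom class (O, N, C, S) with one column
    per residue type.
    """

    counts: pd.DataFrame
    scope: str = "combined"
    ring_size: int = 3
    criterion_tag: str = "energy"
    policy: str = "chordless"

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        counts = self.counts.reindex(list(ATOM_CLASSES)).fillna(0).astype(int)
        counts = counts[ordered_columns(counts.columns)]
        self.counts = counts

    @classmethod
    def from_class_counts(
        cls,
        per_residue: dict[str, dict[str, int]],
        scope: str = "combined",
        ring_size: int = 3,
        **kw,
    ) -> "CountsTable":
        """Build from {residue: {atom_class: count}} mappings."""
        df = pd.DataFrame(per_residue).reindex(list(ATOM_CLASSES)).fillna(0).astype(int)
        return cls(counts=df, scope=scope, ring_size=ring_size, **kw)

    @property
    def totals(self) -> pd.Series:
        """Column totals: O + N + C + S per residue."""
        return self.counts.sum(axis=0)

    def ratios(self) -> pd.DataFrame:
        """Unrounded ratio rows; NaN where the column total is zero."""
        tot = self.totals.astype(float)
        on = (self.counts.loc["O"] + self.counts.loc["N"]) / tot
        c = self.counts.loc["C"] / tot
        s = self.counts.loc["S"] / tot
        return pd.DataFrame({"O,N/Total": on, "C/Total": c, "S/Total": s}).T

    def rounded_ratios(self) -> pd.DataFrame:
        """Ratio rows rounded half-up to 2 decimals (printed form)."""
        return self.ratios().map(
            lambda v: round_half_up(v) if pd.notna(v) else float("nan")
        )

    def add(self, other: "CountsTable") -> "CountsTable":
        """Cell-wise sum (e.g. backbone + sidechain = combined)."""
        if other.ring_size != self.ring_size:
            raise ValueError("ring sizes differ")
        summed = self.counts.add(other.counts, fill_value=0).astype(int)
        return CountsTable(
            counts=summed,
            scope="combined",
            ring_size=self.ring_size,
            criterion_tag=self.criterion_tag,
            policy=self.policy,
        )

    # -- rendering ---------------------------------------------------------

    def render(self) -> pd.DataFrame:
        """Printable table: class rows, Total, ratio rows, blanks for
        zero counts / undefined ratios."""
        cols = list(self.counts.columns)
        out = pd.DataFrame(index=list(ATOM_CLASSES) + ["Total"] + list(RATIO_ROWS),
                           columns=[residue_display(c) for c in cols], dtype=object)
        tot = self.totals
        ratios = self.rounded_ratios()
        numerators = {
            "O,N/Total": self.counts.loc["O"] + self.counts.loc["N"],
            "C/Total": self.counts.loc["C"],
            "S/Total": self.counts.loc["S"],
        }
        for col in cols:
            disp = residue_display(col)
            if tot[col] == 0:
                out[disp] = ""
                continue
            for cls_row in ATOM_CLASSES:
                v = self.counts.at[cls_row, col]
                out.at[cls_row, disp] = str(v) if v else ""
            out.at["Total", disp] = str(int(tot[col]))
            for rrow in RATIO_ROWS:
                if numerators[rrow][col] > 0:
                    out.at[rrow, disp] = f"{ratios.at[rrow, col]:.2f}"
                else:
                    out.at[rrow, disp] = ""
        return out.fillna("")

    def to_tsv(self, path) -> None:
        self.render().to_csv(path, sep="\t", index_label="")

    @classmethod
    def read_tsv(cls, path, scope: str = "combined", ring_size: int = 3) -> "CountsTable":
        """Re-parse a rendered TSV back into a CountsTable (counts only)."""
        df = pd.read_csv(path, sep="\t", index_col=0).fillna("")
        display_to_name = {v: k for k, v in _DISPLAY.items()}
        counts = {}
        for disp in df.columns:
            name = display_to_name.get(disp, disp)
            counts[name] = {
                c: int(df.at[c, disp]) if str(df.at[c, disp]).strip() else 0
                for c in ATOM_CLASSES
            }
        return cls.from_class_counts(counts, scope=scope, ring_size=ring_size)

    def validate(self) -> None:
        """Check internal arithmetic: Total = O+N+C+S and the ratio rows
        sum to 1 (before rounding) wherever the total is non-zero."""
        tot = self.totals
        recomputed = self.counts.sum(axis=0)
        if not (tot == recomputed).all():
            raise AssertionError("Total row does not match column sums")
        ratios = self.ratios()
        nonzero = tot[tot > 0].index
        s = ratios[nonzero].sum(axis=0)
        if not ((s - 1.0).abs() < 1e-12).all():
            raise AssertionError("ratio rows do not sum to 1")
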