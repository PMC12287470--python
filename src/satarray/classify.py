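"""Variable-region extraction, four-type unit classification, consensus and logos.

Units share conserved 5' (25 bp, anchor-led) and 3' (16 bp) blocks; the
mid-unit variable region between them differs in motif and width, defining
four types of nominal length 47/49/50/53 bp. Dash placeholders in the printed
motifs denote weakly conserved positions and are matched as wildcards, so a
type's variable-region width is the motif width and its nominal length is
41 + width.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .segmentation import RepeatUnit, UnitAlignment

VAR_START = 25  # 0-based offset where the variable region begins
SCAFFOLD_3PRIME_LEN = 16
SCAFFOLD_LEN = VAR_START + SCAFFOLD_3PRIME_LEN  # 41 bp shared by all types

_GAP_CHARS = "-–—."  # ASCII dash, en/em dash, dot all mean wildcard


@dataclass(frozen=True)
class UnitType:
    """One variable-region class: display motif, wildcard positions, length."""

    name: str
    variable_motif: str  # printed form, dashes = wildcard positions
    nominal_length: int
    default_fill: str = ""

    def __post_init__(self) -> None:
        if self.nominal_length != SCAFFOLD_LEN + self.width:
            raise ValueError(
                f"{self.name}: nominal length {self.nominal_length} != "
                f"{SCAFFOLD_LEN} + motif width {self.width}"
            )

    @property
    def pattern(self) -> str:
        """Motif with every wildcard placeholder normalized to '.'."""
        return "".join("." if c in _GAP_CHARS else c for c in self.variable_motif)

    @property
    def width(self) -> int:
        return len(self.pattern)

    def mismatches(self, region: str) -> int | None:
        """Mismatch count at non-wildcard positions, or None on width mismatch."""
        if len(region) != self.width:
            return None
        return sum(p != "." and p != c for p, c in zip(self.pattern, region))

    def consensus_region(self) -> str:
        """The motif with wildcards filled by ``default_fill``."""
        it = iter(self.default_fill)
        return "".join(next(it) if c == "." else c for c in self.pattern)


def load_types(path=None) -> list[UnitType]:
    """Load the unit-type table (the packaged default, or a user YAML)."""
    if path is None:
        source = importlib.resources.files("satarray.data").joinpath("unit_types.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return [
        UnitType(
            name=t["name"],
            variable_motif=str(t["motif"]),
            nominal_length=int(t["nominal_length"]),
            default_fill=str(t.get("default_fill", "") or ""),
        )
        for t in raw["types"]
    ]


def load_scaffolds(path=None) -> tuple[str, str]:
    if path is None:
        source = importlib.resources.files("satarray.data").joinpath("unit_types.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return str(raw["scaffold_5prime"]), str(raw["scaffold_3prime"])


def extract_variable_region(
    unit: RepeatUnit | str,
    var_start: int = VAR_START,
    scaffold_3prime_len: int = SCAFFOLD_3PRIME_LEN,
) -> str:
    """The mid-unit subsequence between the conserved 5' and 3' blocks.

    Returns ``seq[var_start : len - scaffold_3prime_len]``; empty for units at
    or below the scaffold length (no variable bases to classify).
    """
    seq = unit if isinstance(unit, str) else unit.sequence
    if len(seq) <= var_start + scaffold_3prime_len:
        return ""
    return seq[var_start : len(seq) - scaffold_3prime_len]


def classify(
    unit: RepeatUnit | str,
    types: list[UnitType] | None = None,
    max_mismatch: int = 1,
    var_start: int = VAR_START,
) -> str:
    """Assign a unit to a type, or "unassigned".

    The primary key is length: the variable-region width must equal a type's
    motif width (equivalently unit length = nominal length). The candidate is
    accepted when the region differs from the motif at no more than
    ``max_mismatch`` non-wildcard positions.
    """
    types = types if types is not None else load_types()
    region = extract_variable_region(unit, var_start)
    if not region:
        return "unassigned"
    for t in types:
        mm = t.mismatches(region)
        if mm is not None and mm <= max_mismatch:
            return t.name
    return "unassigned"


@dataclass
class LogoMatrix:
    """Per-column base frequencies and information content of an alignment."""

    frequencies: pd.DataFrame  # columns A,C,G,T; one row per match column
    information: np.ndarray  # bits, in [0, 2]

    def __len__(self) -> int:
        return len(self.frequencies)


def consensus_and_logo(aln: UnitAlignment) -> tuple[str, LogoMatrix]:
    """Majority-rule consensus plus an information-content logo matrix.

    Gaps are excluded from the frequencies (depth renormalized per column);
    IC_col = 2 + sum_b p_b log2 p_b with 0 log 0 = 0. Ties in the consensus
    break toward the alphabetically first base.
    """
    if aln.depth == 0:
        raise ValueError("empty alignment")
    cols = aln.match_columns()
    freqs = np.zeros((len(cols), 4))
    for j, c in enumerate(cols):
        col = aln.column(c)
        counts = np.array([col.count(b) for b in "ACGT"], float)
        depth = counts.sum()
        freqs[j] = counts / depth if depth else 0.25
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    logo = LogoMatrix(
        frequencies=pd.DataFrame(freqs, columns=list("ACGT")),
        information=ic,
    )
    return aln.consensus(), logo


def type_census(
    units_by_element: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-type counts of elements (by modal type) and units.

    ``units_by_element`` maps element id -> list of per-unit type names
    (including "unassigned"). An element counts toward the type most frequent
    among its assigned units; "unassigned" never wins an element.
    """
    rows: dict[str, dict] = {}
    for element_id, labels in units_by_element.items():
        assigned = [t for t in labels if t != "unassigned"]
        for t in labels:
            if t == "unassigned":
                continue
            r = rows.setdefault(t, {"type": t, "n_elements": 0, "n_units": 0})
            r["n_units"] += 1
        if assigned:
            counts = {t: assigned.count(t) for t in set(assigned)}
            modal = max(sorted(counts), key=lambda t: counts[t])
            rows[modal]["n_elements"] += 1
    if not rows:
        return pd.DataFrame(columns=["type", "n_elements", "n_units"])
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["type"])).reset_index(
        drop=True
    )
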