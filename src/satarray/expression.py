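"""Element-level expression: count aggregation, CPM, stage summaries, group tests.

Read counting and mapping are upstream concerns; this module consumes
per-interval count tables (one row per annotated interval, one column per
sample), sums them over consolidated elements (member intervals plus reclaimed
decoy intervals, since an element is transcribed as one continuous region),
normalizes to counts per million (CPM) or log2(CPM + 1), summarizes by
developmental stage, and compares sample groups with Student's t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consolidate import Element

logger = logging.getLogger(__name__)

# human embryonic stage order used for summaries and heatmap-ready output
DEFAULT_STAGE_ORDER = ("GV", "MI", "MII", "PN", "CL", "MO", "IC", "TP")


@dataclass
class CountTable:
    """Feature x sample raw counts with explicit per-sample library sizes.

    ``library_size`` defaults to the per-sample column sum, which is only a
    lower bound on the true mapped-read total; pass the real totals when the
    table is a subset of the full quantification.
    """

    counts: pd.DataFrame
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        self.library_size = self.library_size.reindex(self.counts.columns)
        if self.library_size.isna().any():
            raise ValueError("library_size missing for some samples")
        if (self.library_size + 1e-9 < self.counts.sum(axis=0)).any():
            raise ValueError("library_size smaller than column sum")


@dataclass
class ExpressionMatrix:
    """Normalized feature x sample values plus the transform that produced them."""

    values: pd.DataFrame
    transform: str  # "cpm" or "log2_cpm1"
    stage_map: pd.Series | None = None


def aggregate_counts(
    interval_counts: pd.DataFrame, elements: list[Element]
) -> CountTable:
    """Sum per-interval counts over elements.

    ``interval_counts`` needs ``chrom``/``start``/``end`` columns followed by
    sample columns. An interval belongs to the element whose envelope contains
    it (member and reclaimed intervals both qualify); intervals matching no
    element are dropped with a logged count.
    """
    meta = {"chrom", "start", "end"}
    missing = meta - set(interval_counts.columns)
    if missing:
        raise ValueError(f"interval_counts lacks columns {sorted(missing)}")
    samples = [c for c in interval_counts.columns if c not in meta]

    rows = {}
    dropped = 0
    for el in elements:
        rows[el.id] = np.zeros(len(samples))
    for _, rec in interval_counts.iterrows():
        owners = [
            el
            for el in elements
            if el.chrom == rec["chrom"] and el.start <= rec["start"] and rec["end"] <= el.end
        ]
        if not owners:
            dropped += 1
            continue
        if len(owners) > 1:
            raise ValueError(
                f"interval {rec['chrom']}:{rec['start']}-{rec['end']} maps to "
                f"{len(owners)} elements"
            )
        rows[owners[0].id] += rec[samples].to_numpy(dtype=float)
    if dropped:
        logger.info("aggregate_counts: dropped %d unassigned intervals", dropped)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return CountTable(counts)


def cpm(table: CountTable, log2_transform: bool = False) -> ExpressionMatrix:
    """Counts per million: count / library_size * 1e6, optionally log2(x + 1)."""
    if (table.library_size <= 0).any():
        raise ValueError("library_size must be positive for every sample")
    vals = table.counts / table.library_size * 1e6
    transform = "cpm"
    if log2_transform:
        vals = np.log2(vals + 1.0)
        transform = "log2_cpm1"
    return ExpressionMatrix(values=vals, transform=transform)


def inverse_cpm(mat: ExpressionMatrix, library_size: pd.Series) -> pd.DataFrame:
    """Recover raw counts from a CPM or log2(CPM+1) matrix."""
    vals = mat.values
    if mat.transform == "log2_cpm1":
        vals = np.exp2(vals) - 1.0
    return vals * library_size / 1e6


def stage_summary(
    mat: ExpressionMatrix,
    stage_map: pd.Series | dict,
    stat: str = "mean",
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER,
) -> pd.DataFrame:
    """Per-feature per-stage mean (or median) of the transformed values."""
    stage_map = pd.Series(stage_map)
    unmapped = set(mat.values.columns) - set(stage_map.index)
    if unmapped:
        raise ValueError(f"samples without a stage: {sorted(unmapped)}")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    grouped = mat.values.T.groupby(stage_map.reindex(mat.values.columns))
    out = (grouped.mean() if stat == "mean" else grouped.median()).T
    ordered = [s for s in stage_order if s in out.columns]
    extra = [s for s in out.columns if s not in stage_order]
    return out[ordered + sorted(extra)]


_P_FLOOR = float(np.finfo(float).tiny)


def group_compare(
    values_a: np.ndarray | list,
    values_b: np.ndarray | list,
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance) between two sample groups.

    With ``paired=True`` the test is computed on per-pair differences. Two
    degenerate cases get explicit conventions: zero variance everywhere with
    equal means reports (0, 1); zero variance with unequal means reports an
    infinite statistic and a p-value at the floating-point floor.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length groups")
        if len(a) < 2:
            raise ValueError("paired test needs at least 2 pairs")
        diffs = a - b
        if np.ptp(diffs) == 0:
            if diffs[0] == 0:
                return 0.0, 1.0
            return float(np.sign(diffs[0]) * np.inf), _P_FLOOR
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return float(np.sign(a[0] - b[0]) * np.inf), _P_FLOOR
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (helper; no correction is applied by default)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]
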