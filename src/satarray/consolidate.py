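"""Consolidation of fragmented repeat annotations into tandem-repeat elements.

Repeat annotators tend to shatter a long tandem array into many short copies,
both at diverged stretches and wherever an unrelated insertion (e.g. an
MLT2B4-derived fragment) interrupts the array. Copies of one family that sit
within a small genomic distance of each other are therefore merged into a
single *element*; copies separated by more than a threshold (default 1000 bp)
are treated as distinct elements. Decoy-family annotations that fall entirely
inside an element envelope are recorded on the element as reclaimed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import RepeatAnnotation

DEFAULT_GAP_THRESHOLD = 1000


@dataclass
class Element:
    """A consolidated tandem-repeat cluster.

    Ids are ``<chrom>#<k>`` with k numbered 1..n per chromosome in coordinate
    order. ``start``/``end`` are the 0-based half-open envelope of the member
    annotations; ``reclaimed`` holds decoy intervals recovered from inside the
    envelope (their bases are candidate unit territory for segmentation).
    """

    id: str
    chrom: str
    start: int
    end: int
    family: str
    members: list[RepeatAnnotation] = field(default_factory=list)
    reclaimed: list[RepeatAnnotation] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def member_bp(self) -> int:
        return sum(m.length for m in self.members)


def consolidate(
    annots: list[RepeatAnnotation],
    family: str | None = None,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
) -> list[Element]:
    """Merge same-family annotations separated by at most ``gap_threshold`` bp.

    The gap between consecutive copies on one chromosome is
    ``next.start - prev.end``; a gap strictly greater than the threshold starts
    a new element. Strand is ignored for merging. Input must be sorted by
    (chrom, start); pass ``family`` to filter a mixed annotation set.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be >= 0")
    if family is not None:
        annots = [a for a in annots if a.family == family]
    if not annots:
        return []
    key = [(a.chrom, a.start, a.end) for a in annots]
    if key != sorted(key):
        raise ValueError("annotations must be sorted by (chrom, start)")
    families = {a.family for a in annots}
    if len(families) > 1:
        raise ValueError(
            f"mixed families {sorted(families)}; pass family= to filter"
        )
    fam = annots[0].family

    clusters: list[list[RepeatAnnotation]] = []
    for a in annots:
        if (
            clusters
            and a.chrom == clusters[-1][-1].chrom
            and a.start - max(m.end for m in clusters[-1]) <= gap_threshold
        ):
            clusters[-1].append(a)
        else:
            clusters.append([a])

    elements: list[Element] = []
    per_chrom: dict[str, int] = {}
    for members in clusters:
        chrom = members[0].chrom
        k = per_chrom.get(chrom, 0) + 1
        per_chrom[chrom] = k
        elements.append(
            Element(
                id=f"{chrom}#{k}",
                chrom=chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                family=fam,
                members=list(members),
            )
        )
    return elements


def reconcile_decoys(
    elements: list[Element],
    other_annots: list[RepeatAnnotation],
    decoy_family: str,
) -> list[Element]:
    """Attach decoy-family annotations contained in element envelopes.

    A decoy interval fully inside an envelope is recorded on that element as a
    reclaimed interval; decoys outside every envelope are left untouched. The
    element envelope never changes (it already spans interior decoys).
    """
    by_chrom: dict[str, list[Element]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el)
    for a in other_annots:
        if a.family != decoy_family:
            continue
        for el in by_chrom.get(a.chrom, ()):
            if el.start <= a.start and a.end <= el.end:
                el.reclaimed.append(a)
                break
    return elements


def element_length_summary(elements: list[Element]) -> pd.DataFrame:
    """Per-chromosome copy counts, summed member lengths, and genome fraction."""
    if not elements:
        return pd.DataFrame(
            columns=["chrom", "n_copies", "total_bp", "fraction_of_total"]
        )
    rows: dict[str, dict] = {}
    for el in elements:
        r = rows.setdefault(el.chrom, {"chrom": el.chrom, "n_copies": 0, "total_bp": 0})
        r["n_copies"] += len(el.members)
        r["total_bp"] += el.member_bp
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["chrom"]))
    df["fraction_of_total"] = df["total_bp"] / df["total_bp"].sum()
    return df
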