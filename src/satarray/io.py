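"""Readers and writers for the formats the pipeline touches.

Internal convention: all coordinates are 0-based half-open on the + strand
of the reference. Conversions happen only at format boundaries (RepeatMasker
``.out`` files are 1-based inclusive and use ``C`` for the minus strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_IUPAC_DNA = set("ACGTN")


@dataclass(frozen=True, order=True)
class RepeatAnnotation:
    """One annotated repeat copy interval with a family label."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    family: str = ""
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.name!r}")
        bad = set(self.residues) - _IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into uppercase :class:`SequenceRecord`s.

    Names are the first whitespace token of each header. Duplicate names and
    non-IUPAC residues (including RNA ``U``) are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise ValueError(f"duplicate FASTA record name {name!r} in {path}")
        seen.add(name)
        records.append(SequenceRecord(name, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.name, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# --- RepeatMasker .out dialect -------------------------------------------------
#
# Layout: 3 header lines, then whitespace-separated columns
#   SW_score div del ins query begin end (left) strand repeat class/family ...
# Coordinates are 1-based inclusive; strand is "+" or "C" (complement).

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching repeat\n"
    "score  div. del. ins.  sequence  begin end    (left)  repeat   class/family\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file into sorted annotations.

    Coordinates are converted to 0-based half-open and strand ``C`` to ``-``.
    """
    annots: list[RepeatAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3 or not line.strip():
            continue
        fields = line.split()
        try:
            score = float(fields[0])
            chrom = fields[4]
            begin = int(fields[5])
            end = int(fields[6])
            strand = fields[8]
            family = fields[9]
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path}: malformed RepeatMasker row at line {lineno}: {line.rstrip()!r}"
            ) from exc
        if strand not in ("+", "C"):
            raise ValueError(
                f"{path}: bad strand {strand!r} at line {lineno}"
            )
        annots.append(
            RepeatAnnotation(
                chrom=chrom,
                start=begin - 1,
                end=end,
                strand="-" if strand == "C" else "+",
                family=family,
                score=score,
            )
        )
    annots.sort(key=lambda a: (a.chrom, a.start, a.end))
    return annots


def write_repeatmasker_out(annots: Iterable[RepeatAnnotation], path: str | Path) -> None:
    """Write annotations back out in the ``.out`` column layout."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for a in annots:
            strand = "C" if a.strand == "-" else "+"
            score = a.score if a.score is not None else 0.0
            fh.write(
                f"{score:7.1f}  0.0  0.0  0.0  {a.chrom}  {a.start + 1}  {a.end}  "
                f"(0)  {strand}  {a.family}  Satellite\n"
            )


# --- BED6 ---------------------------------------------------------------------


def write_bed(items: Sequence, path: str | Path) -> None:
    """Write objects bearing chrom/start/end (+ optional id/name, strand) as BED6."""
    with open(path, "w") as fh:
        for it in items:
            start, end = it.start, it.end
            if start >= end:
                raise ValueError(f"invalid BED interval {start}-{end}")
            name = getattr(it, "id", None) or getattr(it, "name", None) or getattr(
                it, "family", "."
            )
            strand = getattr(it, "strand", "+")
            fh.write(f"{it.chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


@dataclass(frozen=True, order=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"


def read_bed(path: str | Path) -> list[BedInterval]:
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            out.append(
                BedInterval(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                    score=float(f[4]) if len(f) > 4 else 0.0,
                    strand=f[5] if len(f) > 5 else "+",
                )
            )
    out.sort()
    return out


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
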