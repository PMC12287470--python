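"""Anchor-motif segmentation of tandem arrays into repeat units.

Units of the target family share a conserved 5' 5-mer anchor (``CAGCT``, with
tolerated variants such as ``CAGCC`` and ``CATGT``). Segmentation cuts an
element sequence at anchor occurrences, yielding one unit per anchor; a
refinement loop then aligns the units, derives a consensus, and uses it to
rescue anchors that substitution noise or interrupting insertions hid from the
plain motif scan — a deterministic form of the manual cut / align / correct
cycle such arrays are traditionally curated with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

ANCHOR_PRIMARY = "CAGCT"
ANCHOR_VARIANTS = ("CAGCC", "CATGT")
DEFAULT_MIN_LEN = 40
DEFAULT_MAX_LEN = 70

# affine scheme used for all pairwise alignments in the package
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN_SCORE = -3
GAP_EXTEND_SCORE = -1


def make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    return aligner


@dataclass(frozen=True)
class AnchorSpec:
    """The anchor motif scan set: a primary 5-mer plus explicit variants.

    ``max_hamming`` additionally admits any 5-mer within that Hamming distance
    of the primary motif (default 0: explicit list only).
    """

    primary: str = ANCHOR_PRIMARY
    variants: tuple[str, ...] = ANCHOR_VARIANTS
    max_hamming: int = 0

    def __post_init__(self) -> None:
        for m in (self.primary, *self.variants):
            if len(m) != len(self.primary):
                raise ValueError(f"anchor motifs must all be length {len(self.primary)}")

    @property
    def width(self) -> int:
        return len(self.primary)

    @property
    def scan_set(self) -> frozenset[str]:
        return frozenset((self.primary, *self.variants))


@dataclass(frozen=True)
class RepeatUnit:
    """One segmented unit (element-local, 0-based half-open coordinates).

    ``flags`` is one of {"ok"}, {"irregular_short"}, {"irregular_long"},
    {"fragment"}, optionally together with "contains_N". Only plain "ok" units
    enter alignment and consensus building; the others are retained so that
    concatenating all pieces reproduces the input sequence.
    """

    element_id: str
    start: int
    end: int
    sequence: str
    anchor_offset: int = 0
    flags: frozenset[str] = frozenset({"ok"})

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("unit coordinates do not match sequence length")

    @property
    def ok(self) -> bool:
        return self.flags == frozenset({"ok"})

    @property
    def id(self) -> str:
        return f"{self.element_id}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return len(self.sequence)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def scan_anchors(seq: str, spec: AnchorSpec | None = None) -> list[int]:
    """All 0-based positions whose 5-mer is in the anchor scan set.

    Overlapping hits are all reported; conflict resolution happens in
    :func:`segment`.
    """
    spec = spec or AnchorSpec()
    w = spec.width
    scan = spec.scan_set
    hits = []
    for p in range(len(seq) - w + 1):
        kmer = seq[p : p + w]
        if kmer in scan or (
            spec.max_hamming > 0 and hamming(kmer, spec.primary) <= spec.max_hamming
        ):
            hits.append(p)
    return hits


def _flags_for(seq: str, min_len: int, max_len: int) -> frozenset[str]:
    flags: set[str] = set()
    if len(seq) < min_len:
        flags.add("irregular_short")
    elif len(seq) > max_len:
        flags.add("irregular_long")
    if "N" in seq:
        flags.add("contains_N")
    return frozenset(flags or {"ok"})


def segment(
    seq: str,
    spec: AnchorSpec | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    element_id: str = "",
    extra_anchors: tuple[int, ...] | frozenset[int] = (),
) -> list[RepeatUnit]:
    """Cut ``seq`` at anchors: unit i spans [anchor_i, anchor_{i+1}).

    Anchors closer than ``min_len`` to the previously accepted one are skipped
    (greedy left to right). The last unit runs to the end of the sequence;
    sequence before the first anchor is emitted as a "fragment" entry, not a
    unit. Units outside [min_len, max_len] are kept but flagged irregular.
    """
    spec = spec or AnchorSpec()
    anchors = sorted(set(scan_anchors(seq, spec)) | set(extra_anchors))
    if not anchors:
        if not seq:
            return []
        return [
            RepeatUnit(element_id, 0, len(seq), seq, flags=frozenset({"fragment"}))
        ]

    accepted: list[int] = []
    for p in anchors:
        if not accepted or p - accepted[-1] >= min_len:
            accepted.append(p)

    pieces: list[RepeatUnit] = []
    if accepted[0] > 0:
        lead = seq[: accepted[0]]
        pieces.append(
            RepeatUnit(element_id, 0, accepted[0], lead, flags=frozenset({"fragment"}))
        )
    bounds = accepted + [len(seq)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        sub = seq[s:e]
        pieces.append(
            RepeatUnit(element_id, s, e, sub, flags=_flags_for(sub, min_len, max_len))
        )
    return pieces


# --- anchor-pinned iterative consensus alignment --------------------------------


@dataclass
class UnitAlignment:
    """A gapped alignment of units; every row degaps to its unit sequence."""

    unit_ids: list[str]
    rows: list[str]
    units: list[RepeatUnit] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def depth(self) -> int:
        return len(self.rows)

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.rows)

    def column_depths(self) -> list[int]:
        return [sum(ch != "-" for ch in self.column(c)) for c in range(self.ncols)]

    def match_columns(self) -> list[int]:
        """Columns with fewer than 50% gaps (the consensus coordinate system)."""
        half = self.depth / 2
        return [
            c
            for c in range(self.ncols)
            if sum(ch != "-" for ch in self.column(c)) >= half
        ]

    def consensus(self) -> str:
        """Majority-rule consensus over match columns; ties break A<C<G<T."""
        out = []
        for c in self.match_columns():
            col = self.column(c)
            counts = {b: col.count(b) for b in "ACGT"}
            out.append(max("ACGT", key=lambda b: (counts[b], -ord(b))))
        return "".join(out)


def _gapped_pair(aligner: Align.PairwiseAligner, center: str, other: str) -> tuple[str, str]:
    aln = aligner.align(center, other)[0]
    return str(aln[0]), str(aln[1])


def _project_onto_center(gc: str, gu: str, center_len: int) -> tuple[list[str], list[str]]:
    """Split a pairwise alignment into per-center-position inserts and matches.

    Returns (inserts, matched): ``inserts[c]`` are unit characters falling
    before center position c (index center_len = trailing), ``matched[c]`` is
    the unit character (or '-') aligned to center position c.
    """
    inserts = [""] * (center_len + 1)
    matched = ["-"] * center_len
    c = 0
    for cc, uc in zip(gc, gu):
        if cc == "-":
            if uc != "-":
                inserts[c] += uc
        else:
            matched[c] = uc
            c += 1
    return inserts, matched


def _center_star(units: list[RepeatUnit], center: str, pin: int) -> UnitAlignment:
    """Align every unit to ``center``, pinning the first ``pin`` columns.

    The anchor occupies the first ``pin`` positions of every unit and of the
    center, so those columns are fixed 1:1 and only the suffixes are aligned.
    Insert columns from different units are merged per center position
    (left-justified, padded to the maximum insert length), which makes the
    result independent of unit order.
    """
    aligner = make_aligner("global")
    ctail = center[pin:]
    clen = len(ctail)
    projections = []
    for u in units:
        gc, gu = _gapped_pair(aligner, ctail, u.sequence[pin:])
        projections.append(_project_onto_center(gc, gu, clen))

    ins_len = [0] * (clen + 1)
    for inserts, _ in projections:
        for c, s in enumerate(inserts):
            ins_len[c] = max(ins_len[c], len(s))

    rows = []
    for u, (inserts, matched) in zip(units, projections):
        parts = [u.sequence[:pin]]
        for c in range(clen):
            parts.append(inserts[c].ljust(ins_len[c], "-"))
            parts.append(matched[c])
        parts.append(inserts[clen].ljust(ins_len[clen], "-"))
        rows.append("".join(parts))
    return UnitAlignment([u.id for u in units], rows, units=list(units))


def _initial_center(units: list[RepeatUnit]) -> str:
    lengths = sorted(len(u) for u in units)
    counts = {L: lengths.count(L) for L in set(lengths)}
    modal = max(counts, key=lambda L: (counts[L], -L))
    return min(u.sequence for u in units if len(u) == modal)


def align_units(units: list[RepeatUnit], max_rounds: int = 10) -> UnitAlignment:
    """Anchor-pinned iterative consensus alignment of ok units.

    Starts from a deterministic center (modal-length unit, lexicographically
    smallest), aligns every unit to it with the package's affine scheme, then
    realigns everything against the majority consensus until the consensus is
    a fixed point (or ``max_rounds``). The result is invariant to unit order.
    """
    ok = [u for u in units if u.ok]
    if len(ok) < 2:
        raise ValueError("align_units needs at least 2 ok units")
    ok = sorted(ok, key=lambda u: (u.element_id, u.start))
    pin = 5
    center = _initial_center(ok)
    aln = _center_star(ok, center, pin)
    for _ in range(max_rounds):
        cons = aln.consensus()
        if cons == center:
            break
        center = cons
        aln = _center_star(ok, center, pin)
    return aln


# --- refinement loop -------------------------------------------------------------


def _rescue_anchors(
    seq: str,
    pieces: list[RepeatUnit],
    consensus: str,
    spec: AnchorSpec,
    min_identity: float = 0.8,
) -> set[int]:
    """Anchor candidates inside irregular regions, guided by the consensus.

    Two rescue rules, both confined to flagged fragments and irregular_long
    pieces so that noise inside clean units can never inject anchors:
    (a) positions whose 5-mer is within 1 mismatch of the consensus anchor
    window; (b) positions where the full consensus matches the sequence at
    ``min_identity`` or better (recovers units whose anchor is too diverged
    for rule (a)).
    """
    w = spec.width
    window = consensus[:w]
    ncons = len(consensus)
    found: set[int] = set()
    for piece in pieces:
        if piece.ok or "irregular_short" in piece.flags:
            continue
        s, e = piece.start, piece.end
        for p in range(s, e - w + 1):
            if hamming(seq[p : p + w], window) <= 1:
                found.add(p)
        if ncons >= w:
            for p in range(s, e - ncons + 1):
                ident = sum(a == b for a, b in zip(seq[p : p + ncons], consensus))
                if ident / ncons >= min_identity:
                    found.add(p)
    return found


def refine(
    seq: str,
    spec: AnchorSpec | None = None,
    rounds: int = 3,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    element_id: str = "",
) -> tuple[list[RepeatUnit], UnitAlignment | None, str]:
    """Iterate segment -> align -> consensus-guided re-segmentation.

    Each round derives a majority consensus from the current ok units and adds
    rescue anchors found inside irregular regions; stops when the unit set is
    unchanged (fixed point) or after ``rounds`` rounds. With ``rounds=0`` this
    is exactly :func:`segment`. Returns (units, alignment, consensus); the
    alignment is None when fewer than 2 ok units exist.
    """
    spec = spec or AnchorSpec()
    extra: set[int] = set()
    pieces = segment(seq, spec, min_len, max_len, element_id)
    for _ in range(rounds):
        ok = [u for u in pieces if u.ok]
        if len(ok) < 2:
            break
        aln = align_units(ok)
        cons = aln.consensus()
        new = _rescue_anchors(seq, pieces, cons, spec) - extra
        if not new:
            break
        extra |= new
        new_pieces = segment(
            seq, spec, min_len, max_len, element_id, extra_anchors=frozenset(extra)
        )
        if [(p.start, p.end) for p in new_pieces] == [
            (p.start, p.end) for p in pieces
        ]:
            break
        pieces = new_pieces

    ok = [u for u in pieces if u.ok]
    if len(ok) >= 2:
        aln = align_units(ok)
        cons = aln.consensus()
    elif len(ok) == 1:
        aln, cons = None, ok[0].sequence
    else:
        aln, cons = None, ""
    return pieces, aln, cons
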