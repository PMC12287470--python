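"""Synthetic tandem-array genomes and stage-structured count tables with truth.

The generator emulates the study conditions the pipeline is built for: arrays
of ~47-53 bp units sharing a 5' CAGCT anchor, per-base substitution noise,
decoy insertions (~100 bp MLT2B4-like fragments) that shatter the annotation
of an array into pieces, and negative-binomial count matrices whose focal
feature is highly expressed before the cleavage stage and low after it. Every
output records the seed and full ground truth, so pipeline recovery can be
asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import UnitType, load_scaffolds, load_types
from .expression import DEFAULT_STAGE_ORDER, CountTable
from .io import RepeatAnnotation, SequenceRecord

DEFAULT_FAMILY = "D20S16"
DEFAULT_DECOY_FAMILY = "MLT2B4"
_BASES = np.array(list("ACGT"))

_TYPES = {t.name: t for t in load_types()}
SCAFFOLD_5PRIME, SCAFFOLD_3PRIME = load_scaffolds()

_ANCHOR_SET = ("CAGCT", "CAGCC", "CATGT")


def type_consensus_unit(unit_type: str | UnitType) -> str:
    """The noise-free unit sequence of a type: 5' scaffold + motif + 3' scaffold."""
    t = _TYPES[unit_type] if isinstance(unit_type, str) else unit_type
    return SCAFFOLD_5PRIME + t.consensus_region() + SCAFFOLD_3PRIME


def _substitute(seq: str, rate: float, rng: np.random.Generator, protect: range | None) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    if protect is not None:
        hit[protect.start : protect.stop] = False
    for i in np.flatnonzero(hit):
        options = [b for b in "ACGT" if b != chars[i]]
        chars[i] = options[rng.integers(3)]
    return "".join(chars)


def gen_unit(
    unit_type: str | UnitType,
    rng: np.random.Generator,
    substitution: float = 0.0,
    anchor_protection: bool = True,
) -> str:
    """One unit of the type's nominal length with per-base substitution noise.

    The 5-bp anchor at the unit start is exempt from substitution when
    ``anchor_protection`` is set.
    """
    base = type_consensus_unit(unit_type)
    protect = range(0, 5) if anchor_protection else None
    return _substitute(base, substitution, rng, protect)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(4, size=n)])


def _anchor_free_seq(n: int, rng: np.random.Generator) -> str:
    """Random sequence with no anchor-motif occurrence (rejection by mutation)."""
    chars = list(_random_seq(n, rng))
    for _ in range(100):
        dirty = False
        for p in range(n - 4):
            if "".join(chars[p : p + 5]) in _ANCHOR_SET:
                chars[p + 2] = {"G": "C", "T": "A"}.get(chars[p + 2], "T")
                dirty = True
        if not dirty:
            return "".join(chars)
    raise RuntimeError("could not generate anchor-free sequence")


@dataclass(frozen=True)
class TruthUnit:
    chrom: str
    start: int
    end: int
    name: str  # type name


@dataclass
class ArrayConfig:
    """One synthetic tandem array: composition, noise, decoys, flanks, seed."""

    unit_type: str = "L53"
    n_units: int = 50
    substitution: float = 0.0
    anchor_protection: bool = True
    n_decoys: int = 0
    decoy_length: int = 100
    decoy_seq: str | None = None
    flank: int = 500
    chrom: str = "chr20"
    family: str = DEFAULT_FAMILY
    decoy_family: str = DEFAULT_DECOY_FAMILY
    seed: int = 0
    mid_unit_decoys: bool = False  # robustness mode: insertions may split a unit

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution <= 1.0:
            raise ValueError("substitution rate must be in [0, 1]")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_decoys >= self.n_units:
            raise ValueError("need fewer decoys than units")


@dataclass
class TruthSet:
    """Everything the generator knows about one array (local coordinates)."""

    units: list[TruthUnit]
    element: tuple[str, int, int]
    decoys: list[RepeatAnnotation]
    annotations: list[RepeatAnnotation]  # fragmented family intervals
    seed: int
    sequence_name: str = ""

    def shifted(self, offset: int, chrom: str) -> "TruthSet":
        def mv(a: RepeatAnnotation) -> RepeatAnnotation:
            return RepeatAnnotation(chrom, a.start + offset, a.end + offset, a.strand, a.family)

        return TruthSet(
            units=[TruthUnit(chrom, u.start + offset, u.end + offset, u.name) for u in self.units],
            element=(chrom, self.element[1] + offset, self.element[2] + offset),
            decoys=[mv(a) for a in self.decoys],
            annotations=[mv(a) for a in self.annotations],
            seed=self.seed,
            sequence_name=chrom,
        )


def gen_array(
    cfg: ArrayConfig, rng: np.random.Generator | None = None
) -> tuple[SequenceRecord, TruthSet]:
    """Flank + units (with decoys between whole units) + flank, plus truth.

    The fragmented annotation set splits the array at every decoy, the way an
    annotator confused by the insertions would emit it; decoy gaps are well
    under the 1000 bp merge threshold, so consolidation must re-merge them.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    units = [
        gen_unit(cfg.unit_type, rng, cfg.substitution, cfg.anchor_protection)
        for _ in range(cfg.n_units)
    ]
    junctions = (
        sorted(rng.choice(np.arange(1, cfg.n_units), size=cfg.n_decoys, replace=False))
        if cfg.n_decoys
        else []
    )
    decoy_of = {
        j: (cfg.decoy_seq or _anchor_free_seq(cfg.decoy_length, rng)) for j in junctions
    }

    pos = cfg.flank
    parts = [_random_seq(cfg.flank, rng)]
    truth_units: list[TruthUnit] = []
    decoys: list[RepeatAnnotation] = []
    fragments: list[RepeatAnnotation] = []
    frag_start = pos
    tname = _type_name(cfg.unit_type)
    for i, u in enumerate(units):
        if i in decoy_of and not cfg.mid_unit_decoys:
            d = decoy_of[i]
            fragments.append(RepeatAnnotation(cfg.chrom, frag_start, pos, "+", cfg.family))
            decoys.append(
                RepeatAnnotation(cfg.chrom, pos, pos + len(d), "+", cfg.decoy_family)
            )
            parts.append(d)
            pos += len(d)
            frag_start = pos
        if i in decoy_of and cfg.mid_unit_decoys:
            # robustness mode: the decoy lands inside unit i, splitting it
            d = decoy_of[i]
            cut = len(u) // 2
            parts.append(u[:cut])
            truth_units.append(TruthUnit(cfg.chrom, pos, pos + cut, f"{tname}_split"))
            pos += cut
            fragments.append(RepeatAnnotation(cfg.chrom, frag_start, pos, "+", cfg.family))
            decoys.append(
                RepeatAnnotation(cfg.chrom, pos, pos + len(d), "+", cfg.decoy_family)
            )
            parts.append(d)
            pos += len(d)
            frag_start = pos
            parts.append(u[cut:])
            truth_units.append(
                TruthUnit(cfg.chrom, pos, pos + len(u) - cut, f"{tname}_split")
            )
            pos += len(u) - cut
            continue
        parts.append(u)
        truth_units.append(TruthUnit(cfg.chrom, pos, pos + len(u), tname))
        pos += len(u)
    fragments.append(RepeatAnnotation(cfg.chrom, frag_start, pos, "+", cfg.family))
    parts.append(_random_seq(cfg.flank, rng))

    seq = "".join(parts)
    truth = TruthSet(
        units=truth_units,
        element=(cfg.chrom, cfg.flank, pos),
        decoys=decoys,
        annotations=fragments,
        seed=cfg.seed,
        sequence_name=cfg.chrom,
    )
    return SequenceRecord(cfg.chrom, seq), truth


def _type_name(t: str | UnitType) -> str:
    return t if isinstance(t, str) else t.name


@dataclass
class GenomeTruth:
    arrays: list[TruthSet]
    seed: int

    @property
    def units(self) -> list[TruthUnit]:
        return [u for t in self.arrays for u in t.units]

    @property
    def elements(self) -> list[tuple[str, int, int]]:
        return [t.element for t in self.arrays]


def gen_genome(
    configs: list[ArrayConfig],
    intergap: int = 2000,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[RepeatAnnotation], GenomeTruth]:
    """Multiple arrays per chromosome, separated by more than the merge threshold.

    Arrays are placed in config order within each chromosome, with ``intergap``
    random bases between consecutive arrays (on top of their flanks), so each
    array consolidates to exactly one element. When ``seed`` is given it
    overrides the per-array seeds deterministically.
    """
    if intergap <= 1000:
        raise ValueError("intergap must exceed the 1000 bp merge threshold")
    if seed is not None:
        children = np.random.SeedSequence(seed).spawn(len(configs) + 1)
        rngs = [np.random.default_rng(c) for c in children[:-1]]
        gap_rng = np.random.default_rng(children[-1])
        eff_seed = seed
    else:
        rngs = [None] * len(configs)
        gap_rng = np.random.default_rng(0)
        eff_seed = 0

    by_chrom: dict[str, list[tuple[ArrayConfig, np.random.Generator | None]]] = {}
    for cfg, rng in zip(configs, rngs):
        by_chrom.setdefault(cfg.chrom, []).append((cfg, rng))

    records: list[SequenceRecord] = []
    annotations: list[RepeatAnnotation] = []
    truths: list[TruthSet] = []
    for chrom, items in by_chrom.items():
        seq_parts: list[str] = []
        offset = 0
        for i, (cfg, rng) in enumerate(items):
            if i > 0:
                seq_parts.append(_random_seq(intergap, gap_rng))
                offset += intergap
            rec, truth = gen_array(cfg, rng)
            seq_parts.append(rec.residues)
            shifted = truth.shifted(offset, chrom)
            truths.append(shifted)
            annotations.extend(shifted.annotations)
            annotations.extend(shifted.decoys)
            offset += len(rec.residues)
        records.append(SequenceRecord(chrom, "".join(seq_parts)))
    annotations.sort(key=lambda a: (a.chrom, a.start, a.end))
    return records, annotations, GenomeTruth(arrays=truths, seed=eff_seed)


@dataclass
class CountConfig:
    """Stage-structured count simulation: per-feature per-stage means, NB noise.

    The default profile mirrors the focal element's developmental dynamics:
    high from GV through CL, low from MO through TP, against flat background
    features. ``dispersion`` is the negative-binomial size parameter r (with
    variance m + m^2/r); ``None`` means Poisson.
    """

    stages: tuple[str, ...] = DEFAULT_STAGE_ORDER
    stage_means: dict[str, dict[str, float]] = field(default_factory=dict)
    n_samples_per_stage: int = 3
    library_size: float = 1_000_000.0
    dispersion: float | None = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stage_means:
            high = {s: 300.0 for s in ("GV", "MI", "MII", "PN", "CL")}
            low = {s: 15.0 for s in ("MO", "IC", "TP")}
            self.stage_means = {
                "chr20#4": {**high, **low},
                "chr20#1": {s: 40.0 for s in self.stages},
                "chr3#1": {s: 40.0 for s in self.stages},
            }
        for feat, means in self.stage_means.items():
            if any(m < 0 for m in means.values()):
                raise ValueError(f"negative mean for {feat}")


def gen_counts(cfg: CountConfig) -> tuple[CountTable, pd.Series]:
    """Draw a CountTable plus a sample->stage map from a CountConfig."""
    rng = np.random.default_rng(cfg.seed)
    samples = [f"{s}_{i + 1}" for s in cfg.stages for i in range(cfg.n_samples_per_stage)]
    stage_map = pd.Series({name: name.rsplit("_", 1)[0] for name in samples})
    data = {}
    for feat, means in cfg.stage_means.items():
        vals = []
        for name in samples:
            m = means[stage_map[name]]
            if m == 0:
                vals.append(0)
            elif cfg.dispersion is None or not np.isfinite(cfg.dispersion):
                vals.append(int(rng.poisson(m)))
            else:
                r = cfg.dispersion
                vals.append(int(rng.negative_binomial(r, r / (r + m))))
        data[feat] = vals
    counts = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    lib = pd.Series(cfg.library_size, index=samples)
    return CountTable(counts, lib), stage_map
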