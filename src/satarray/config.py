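"""Pipeline configuration and the end-to-end workflow runner.

The defaults collect the workflow's operating constants in one place: the
1000 bp consolidation gap, the CAGCT anchor with its CAGCC/CATGT variants,
unit length bounds 40-70 bp bracketing the 47-53 bp types, profile search at
E < 0.01, the variable region from unit offset 25, and the consensus columns
26-37 used for trees. Every run writes its resolved configuration and a log
with seeds and versions next to the outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    VAR_START,
    classify as classify_unit,
    consensus_and_logo,
    load_types,
    type_census,
)
from .consolidate import (
    DEFAULT_GAP_THRESHOLD,
    consolidate,
    element_length_summary,
    reconcile_decoys,
)
from .expression import DEFAULT_STAGE_ORDER, aggregate_counts, cpm, stage_summary
from .io import (
    RepeatAnnotation,
    SequenceRecord,
    read_bed,
    read_fasta,
    read_repeatmasker_out,
    revcomp,
    write_bed,
    write_fasta,
)
from .phylo import PHYLO_END, PHYLO_START, distance_matrix, extract_phylo_region, nj_tree, to_newick
from .profile import annotation_delta, build_profile, calibrate, search
from .segmentation import (
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    AnchorSpec,
    align_units,
    refine,
)

logger = logging.getLogger("satarray")


@dataclass
class PipelineConfig:
    family: str = "D20S16"
    decoy_family: str = "MLT2B4"
    gap_threshold: int = DEFAULT_GAP_THRESHOLD
    anchor_primary: str = "CAGCT"
    anchor_variants: tuple[str, ...] = ("CAGCC", "CATGT")
    anchor_max_hamming: int = 0
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    refine_rounds: int = 3
    pseudocount: float = 0.25
    evalue_max: float = 0.01
    calibration_n: int = 5000
    calibration_len: int = 200
    var_start: int = VAR_START
    max_mismatch: int = 1
    phylo_start: int = PHYLO_START
    phylo_end: int = PHYLO_END
    tree_max_taxa: int = 60
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    log2_transform: bool = True
    seed: int = 7
    types_path: str | None = None

    @property
    def anchor_spec(self) -> AnchorSpec:
        return AnchorSpec(
            primary=self.anchor_primary,
            variants=tuple(self.anchor_variants),
            max_hamming=self.anchor_max_hamming,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("anchor_variants", "stage_order"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["anchor_variants"] = list(d["anchor_variants"])
        d["stage_order"] = list(d["stage_order"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _read_annotations(path: str | Path) -> list[RepeatAnnotation]:
    path = Path(path)
    if path.suffix == ".bed":
        return [
            RepeatAnnotation(b.chrom, b.start, b.end, b.strand, b.name)
            for b in read_bed(path)
        ]
    return read_repeatmasker_out(path)


def _element_sequence(el, genomes: dict[str, str]) -> str:
    """Element envelope sequence, reverse-complemented for minus-majority elements."""
    seq = genomes[el.chrom][el.start : el.end]
    minus = sum(m.strand == "-" for m in el.members)
    return revcomp(seq) if minus > len(el.members) / 2 else seq


def _unit_global(el, unit, minus: bool) -> tuple[int, int]:
    if minus:
        return el.end - unit.end, el.end - unit.start
    return el.start + unit.start, el.start + unit.end


def run_pipeline(
    config: PipelineConfig,
    fasta: str | Path,
    annotations: str | Path,
    outdir: str | Path,
    counts: str | Path | None = None,
    stage_map: str | Path | None = None,
) -> Path:
    """Run consolidation -> segmentation/refinement -> profile rescue ->
    classification -> (expression) -> tree, writing all tabular outputs.

    Reruns with identical inputs and seeds produce byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("satarray %s; seed=%d", __version__, config.seed)

    try:
        genomes = {r.name: r.residues for r in read_fasta(fasta)}
        try:
            annots = _read_annotations(annotations)
        except ValueError as exc:
            raise RuntimeError(f"stage consolidate: {exc}") from exc

        # --- consolidate ------------------------------------------------------
        fam = [a for a in annots if a.family == config.family]
        if not fam:
            raise RuntimeError(
                f"stage consolidate: no {config.family} annotations in {annotations}"
            )
        elements = consolidate(fam, config.family, config.gap_threshold)
        decoys = [a for a in annots if a.family == config.decoy_family]
        elements = reconcile_decoys(elements, decoys, config.decoy_family)
        write_bed(elements, outdir / "elements.bed")
        element_length_summary(elements).to_csv(
            outdir / "summary.tsv", sep="\t", index=False
        )
        logger.info("consolidated %d annotations into %d elements", len(fam), len(elements))

        # --- segmentation + refinement ---------------------------------------
        types = load_types(config.types_path)
        spec = config.anchor_spec
        all_units = []  # (element, unit, minus, type_name)
        unit_seqs: list[SequenceRecord] = []
        (outdir / "logos").mkdir(exist_ok=True)
        consensus_records: list[SequenceRecord] = []
        for el in elements:
            if el.chrom not in genomes:
                raise RuntimeError(f"stage segment: {el.chrom} missing from FASTA")
            minus = sum(m.strand == "-" for m in el.members) > len(el.members) / 2
            seq = _element_sequence(el, genomes)
            units, aln, cons = refine(
                seq,
                spec,
                rounds=config.refine_rounds,
                min_len=config.min_len,
                max_len=config.max_len,
                element_id=el.id,
            )
            for u in units:
                tname = (
                    classify_unit(u, types, config.max_mismatch, config.var_start)
                    if u.ok
                    else "unassigned"
                )
                all_units.append((el, u, minus, tname))
                if u.ok:
                    unit_seqs.append(SequenceRecord(u.id.replace("#", "_"), u.sequence))
            if cons:
                consensus_records.append(
                    SequenceRecord(el.id.replace("#", "_"), cons)
                )
            if aln is not None:
                _, logo = consensus_and_logo(aln)
                logo_df = logo.frequencies.copy()
                logo_df["information_bits"] = logo.information
                logo_df.to_csv(
                    outdir / "logos" / f"{el.id.replace('#', '_')}.tsv",
                    sep="\t",
                    index_label="column",
                )

        units_df = pd.DataFrame(
            [
                {
                    "element": el.id,
                    "start": u.start,
                    "end": u.end,
                    "global_start": _unit_global(el, u, minus)[0],
                    "global_end": _unit_global(el, u, minus)[1],
                    "length": len(u),
                    "flags": ",".join(sorted(u.flags)),
                    "type": tname,
                }
                for el, u, minus, tname in all_units
            ]
        )
        units_df.to_csv(outdir / "units.tsv", sep="\t", index=False)
        write_fasta(unit_seqs, outdir / "units.fa")
        write_fasta(consensus_records, outdir / "consensus.fa")

        ok_units = [u for _, u, _, _ in all_units if u.ok]
        logger.info("segmented %d units (%d ok)", len(all_units), len(ok_units))

        # --- profile build / calibrate / search --------------------------------
        if len(ok_units) >= 2:
            global_aln = align_units(ok_units)
            # gapped FASTA: write literal rows (gaps as '-') without validation
            with open(outdir / "units.aln.fa", "w") as fh:
                for uid, row in zip(global_aln.unit_ids, global_aln.rows):
                    fh.write(f">{uid}\n{row}\n")
            model = build_profile(global_aln, pseudocount=config.pseudocount)
            calibrate(
                model,
                n_random=config.calibration_n,
                len_random=config.calibration_len,
                seed=config.seed,
            )
            model.to_json(outdir / "model.json")
            seq_records = [SequenceRecord(n, s) for n, s in genomes.items()]
            hits = search(model, seq_records, evalue_max=config.evalue_max)
            write_bed(
                [
                    RepeatAnnotation(h.chrom, h.start, h.end, "+", config.family, h.bitscore)
                    for h in hits
                ],
                outdir / "hits.bed",
            )
            logger.info("profile search: %d hits at E<%g", len(hits), config.evalue_max)
            added, removed = annotation_delta(fam, hits)
            pd.DataFrame(
                [{"added_bp": added, "removed_bp": removed}]
            ).to_csv(outdir / "delta.tsv", sep="\t", index=False)
        else:
            global_aln = None
            logger.warning("fewer than 2 ok units; skipping profile stage")

        # --- classification census ---------------------------------------------
        by_element: dict[str, list[str]] = {}
        for el, u, _, tname in all_units:
            if u.ok:
                by_element.setdefault(el.id, []).append(tname)
        census = type_census(by_element)
        census.to_csv(outdir / "types.tsv", sep="\t", index=False)

        # --- expression ---------------------------------------------------------
        if counts is not None:
            icounts = pd.read_csv(counts, sep="\t")
            table = aggregate_counts(icounts, elements)
            mat = cpm(table, log2_transform=config.log2_transform)
            mat.values.to_csv(outdir / "expression.tsv", sep="\t", index_label="element")
            if stage_map is not None:
                smap = pd.read_csv(stage_map, sep="\t", index_col=0).iloc[:, 0]
                stage_summary(mat, smap, stage_order=tuple(config.stage_order)).to_csv(
                    outdir / "stage_summary.tsv", sep="\t", index_label="element"
                )

        # --- variable-region tree ------------------------------------------------
        if global_aln is not None and len(global_aln.match_columns()) >= config.phylo_end:
            ids = global_aln.unit_ids
            regions = extract_phylo_region(global_aln, config.phylo_start, config.phylo_end)
            if len(ids) > config.tree_max_taxa:
                stride = -(-len(ids) // config.tree_max_taxa)
                keep = list(range(0, len(ids), stride))
                ids = [ids[i] for i in keep]
                regions = [regions[i] for i in keep]
            if len(ids) >= 3 and len(set(ids)) == len(ids):
                dm = distance_matrix(regions, ids)
                (outdir / "tree.nwk").write_text(to_newick(nj_tree(dm)) + "\n")

        config.to_yaml(outdir / "run_config.yaml")
        return outdir
    finally:
        logger.removeHandler(handler)
        handler.close()
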