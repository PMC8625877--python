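"""Pipeline orchestration and report bundling.

run_all executes detection -> characterization -> chimera screening and
writes a bundle of BED/TSV/JSON outputs whose sections mirror the standard
NUMT-survey readout: per-genome count/total bp/genome fraction, length
histogram, per-gene origin counts, flank AT summary (with the
upstream-vs-downstream comparison), position-class counts, and the
fused-NUMT (chimera) count.  Every threshold that influenced the run is
echoed verbatim into the report's provenance block; outputs contain no
timestamps, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from numtforge.aligner import ScoringScheme
from numtforge.characterize import (
    flank_at,
    flank_at_summary,
    classify_position,
    genes_of_origin,
    length_histogram,
    origin_counts,
    pearson_test,
    position_class_counts,
)
from numtforge.chimera import build_chimera_queries, chimera_summary, detect_chimeras
from numtforge.genome_io import (
    AnnotatedGenome,
    GenomicInterval,
    Mitogenome,
    mitogenome_summary,
    read_fasta,
    read_gff3_genes,
    read_mito_annotation,
    write_bed,
)
from numtforge.numt_detect import DetectionConfig, NumtRecord, detect_numts

logger = logging.getLogger("numtforge")


class StageError(Exception):
    """A pipeline stage failed; .stage names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a full run.

    Threshold defaults are the strict published NUMT-survey settings:
    detection E <= 6e-14, 100 bp composition flanks, 2 kb gene flanks, and
    the chimera rule (60 bp query flanks, E <= 1e-10, identity >= 0.98,
    >= 50 contiguous flank bases).
    """

    genome_fasta: str = ""
    genome_gff3: Optional[str] = None
    mito_fasta: str = ""
    mito_gff3: Optional[str] = None
    transcripts_fasta: Optional[str] = None
    out_dir: str = "numtforge_out"
    seed: int = 0
    evalue_max: float = 6e-14
    end_margin: int = 0
    merge: bool = True
    flank: int = 100
    gene_flank: int = 2000
    min_origin_overlap: int = 1
    bin_width: int = 200
    tail_from: int = 2000
    chimera_flank: int = 60
    chimera_evalue: float = 1e-10
    chimera_identity: float = 0.98
    chimera_min_flank: int = 50
    mito_circular: bool = True

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def load_inputs(config: PipelineConfig):
    scaffolds = read_fasta(config.genome_fasta)
    genome = AnnotatedGenome(scaffolds=scaffolds)
    if config.genome_gff3:
        genome = AnnotatedGenome(
            scaffolds=scaffolds, genes=read_gff3_genes(config.genome_gff3, genome)
        )
    mito_seq = read_fasta(config.mito_fasta)[0].sequence
    if config.mito_gff3:
        mito = read_mito_annotation(
            config.mito_gff3, mito_seq, circular=config.mito_circular
        )
    else:
        mito = Mitogenome(sequence=mito_seq, circular=config.mito_circular)
    transcripts = (
        read_fasta(config.transcripts_fasta) if config.transcripts_fasta else None
    )
    return genome, mito, transcripts


def hits_to_frame(hits) -> pd.DataFrame:
    """Raw alignment-hit table with stable columns."""
    return pd.DataFrame(
        [
            {
                "query_start": h.query_start,
                "query_end": h.query_end,
                "scaffold": h.scaffold_id,
                "subject_start": h.subject_start,
                "subject_end": h.subject_end,
                "strand": h.strand,
                "score": h.raw_score,
                "identity": round(h.identity, 6),
                "evalue": h.evalue,
            }
            for h in hits
        ],
        columns=[
            "query_start", "query_end", "scaffold", "subject_start",
            "subject_end", "strand", "score", "identity", "evalue",
        ],
    )


def numts_to_frame(
    numts: Sequence[NumtRecord],
    genome: AnnotatedGenome,
    mito: Mitogenome,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-NUMT characterization table (one row per locus)."""
    rows = []
    for r in numts:
        origins = genes_of_origin(r, mito, config.min_origin_overlap)
        fp = flank_at(r, genome, config.flank)
        pc = classify_position(r, genome.genes, config.gene_flank)
        rows.append(
            {
                "numt_id": r.numt_id,
                "scaffold": r.locus.scaffold_id,
                "start": r.locus.start,
                "end": r.locus.end,
                "length": r.length,
                "best_evalue": r.best_evalue,
                "mean_identity": round(r.mean_identity, 6),
                "support_hits": r.support_hits,
                "mito_intervals": ";".join(
                    f"{a}-{b}:{st}" for (a, b, st) in r.mito_intervals
                ),
                "origin_genes": ",".join(f"{g}:{ov}" for g, ov in origins),
                "upstream_at": _rnd(fp.upstream_at),
                "downstream_at": _rnd(fp.downstream_at),
                "combined_at": _rnd(fp.combined_at),
                "position_class": pc.position_class,
                "nearest_gene": pc.nearest_gene_id or "",
                "distance_bp": -1 if pc.distance_bp is None else pc.distance_bp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "numt_id", "scaffold", "start", "end", "length", "best_evalue",
            "mean_identity", "support_hits", "mito_intervals", "origin_genes",
            "upstream_at", "downstream_at", "combined_at", "position_class",
            "nearest_gene", "distance_bp",
        ],
    )


def _rnd(x, nd: int = 6):
    return None if x is None else round(x, nd)


def frame_to_numts(df: pd.DataFrame) -> list[NumtRecord]:
    """Rebuild NumtRecords from a numts.tsv table (inverse of
    numts_to_frame for the detection fields)."""
    out = []
    for row in df.itertuples(index=False):
        ivs = []
        if isinstance(row.mito_intervals, str) and row.mito_intervals:
            for part in row.mito_intervals.split(";"):
                rng, st = part.rsplit(":", 1)
                a, b = rng.split("-")
                ivs.append((int(a), int(b), st))
        out.append(
            NumtRecord(
                numt_id=row.numt_id,
                locus=GenomicInterval(row.scaffold, int(row.start), int(row.end), "."),
                mito_intervals=ivs,
                best_evalue=float(row.best_evalue),
                mean_identity=float(row.mean_identity),
                support_hits=int(row.support_hits),
            )
        )
    return out


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict and writes
    numts.bed, numts.tsv, chimera_evidence.tsv (if transcripts given) and
    report.json under config.out_dir.  On a stage failure all partial
    outputs of this run are removed and StageError is raised."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        try:
            genome, mito, transcripts = load_inputs(config)
        except Exception as exc:  # noqa: BLE001
            raise StageError("load", exc) from exc

        report: dict = {"provenance": {"config": config.echo()}}
        try:
            det_cfg = DetectionConfig(
                evalue_max=config.evalue_max,
                end_margin=config.end_margin,
                merge=config.merge,
            )
            logger.info(
                "detect: genome %d bp (%d scaffolds), mito %d bp, E<=%g",
                genome.total_length, len(genome.scaffolds), mito.length,
                config.evalue_max,
            )
            numts, det_summary = detect_numts(mito, genome, det_cfg)
            logger.info("detect: %d loci from %d hits", len(numts), det_summary["n_hits"])
            report["mitogenome"] = mitogenome_summary(mito)
            report["detection"] = det_summary
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("detect", exc) from exc

        try:
            hist = length_histogram(numts, config.bin_width, config.tail_from)
            report["length_histogram"] = [
                {"lo": lo, "hi": hi, "count": c} for (lo, hi, c) in hist
            ]
            report["origin_counts"] = origin_counts(
                numts, mito, config.min_origin_overlap
            )
            report["flank_at"] = flank_at_summary(numts, genome, config.flank)
            report["position_classes"] = position_class_counts(
                numts, genome.genes, config.gene_flank
            )
            logger.info(
                "characterize: %d loci, classes %s",
                len(numts), report["position_classes"],
            )
            table = numts_to_frame(numts, genome, mito, config)
        except Exception as exc:  # noqa: BLE001
            raise StageError("characterize", exc) from exc

        try:
            if transcripts is None:
                report["chimera"] = {"status": "skipped", "reason": "no transcripts input"}
                evidence = None
            else:
                queries = build_chimera_queries(numts, genome, config.chimera_flank)
                evidence = detect_chimeras(
                    queries,
                    transcripts,
                    evalue_max=config.chimera_evalue,
                    identity_min=config.chimera_identity,
                    min_flank=config.chimera_min_flank,
                )
                summ = chimera_summary(evidence)
                summ["status"] = "ok"
                report["chimera"] = summ
                logger.info(
                    "chimera: %d evidence rows, %d fused NUMTs",
                    len(evidence), summ["fused_numt_count"],
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("chimera", exc) from exc

        bed_path = out_dir / "numts.bed"
        write_bed(numts, bed_path)
        written.append(bed_path)
        tsv_path = out_dir / "numts.tsv"
        table.to_csv(tsv_path, sep="\t", index=False)
        written.append(tsv_path)
        if evidence is not None:
            ev_path = out_dir / "chimera_evidence.tsv"
            pd.DataFrame(
                [
                    {
                        "numt_id": e.numt_id,
                        "transcript_id": e.transcript_id,
                        "evalue": e.evalue,
                        "identity": round(e.identity, 6),
                        "flank_bases": e.flank_bases_covered,
                        "side": e.side,
                    }
                    for e in evidence
                ],
                columns=[
                    "numt_id", "transcript_id", "evalue", "identity",
                    "flank_bases", "side",
                ],
            ).to_csv(ev_path, sep="\t", index=False)
            written.append(ev_path)
        json_path = out_dir / "report.json"
        json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(json_path)
        return report
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def run_correlate(
    counts: Sequence[float],
    genome_sizes: Sequence[float],
    total_numt_bp: Optional[Sequence[float]] = None,
) -> dict:
    """Pearson tests across cohorts: NUMT count vs nuclear genome size and,
    when given, total NUMT bp vs genome size."""
    if len(counts) < 3 or len(genome_sizes) < 3:
        raise ValueError("need at least 3 cohorts to correlate")
    res = pearson_test(genome_sizes, counts)
    out = {"count_vs_genome_size": dataclasses.asdict(res)}
    if total_numt_bp is not None:
        res2 = pearson_test(genome_sizes, total_numt_bp)
        out["numt_bp_vs_genome_size"] = dataclasses.asdict(res2)
    return out
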