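"""NUMT calling: E-value filter, scaffold-end filter, locus merging.

A NUMT locus is the union of overlapping or bookended (gap 0) alignment
hits on a scaffold, merged regardless of strand: a single insertion
fragmented into several HSPs by indels or decayed patches is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from numtforge.aligner import (
    AlignmentHit,
    KarlinParams,
    ScoringScheme,
    align_circular_query,
)
from numtforge.genome_io import AnnotatedGenome, GenomicInterval, Mitogenome


@dataclass
class DetectionConfig:
    """Thresholds of the detection stage.

    evalue_max: strict E-value cutoff applied to every hit (6e-14, chosen to
        minimize false positives in AT-rich genomes).
    end_margin: a hit within this many bp of a scaffold end is discarded
        (0 = touches the terminal base).
    merge: merge overlapping/bookended hits into loci; with merge off every
        hit becomes its own single-support locus (exposes the HSP-vs-locus
        counting ambiguity).
    count_n_in_genome_fraction: denominator of the genome-fraction summary
        includes N bases (full assembly length) when true.
    """

    evalue_max: float = 6e-14
    end_margin: int = 0
    merge: bool = True
    count_n_in_genome_fraction: bool = True
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    gap_trigger: Optional[int] = None


@dataclass
class NumtRecord:
    """A merged nuclear locus of mitochondrial origin."""

    numt_id: str
    locus: GenomicInterval
    mito_intervals: list[tuple[int, int, str]]  # (start, end, strand) on mito
    best_evalue: float
    mean_identity: float
    support_hits: int

    @property
    def length(self) -> int:
        return len(self.locus)


def filter_evalue(hits: Sequence[AlignmentHit], threshold: float = 6e-14):
    """Keep hits with evalue <= threshold (inclusive); order preserved."""
    if threshold < 0:
        raise ValueError("E-value threshold must be non-negative")
    return [h for h in hits if h.evalue <= threshold]


def filter_scaffold_ends(
    hits: Sequence[AlignmentHit], genome: AnnotatedGenome, margin: int = 0
):
    """Remove hits at scaffold ends, where alignment artifacts concentrate.

    A hit is removed iff subject_start <= margin or
    subject_end >= scaffold_length - margin; the default margin of 0 removes
    hits touching the first or last base.
    """
    out = []
    for h in hits:
        L = genome.scaffold(h.scaffold_id).length  # raises on unknown scaffold
        if h.subject_start <= margin or h.subject_end >= L - margin:
            continue
        out.append(h)
    return out


def merge_hits_to_loci(hits: Sequence[AlignmentHit]) -> list[NumtRecord]:
    """Merge same-scaffold hits whose subject intervals overlap or are
    bookended (gap 0) into loci, regardless of strand.

    locus = union span; best_evalue = min over members; mean_identity =
    aligned-column-weighted mean; mito_intervals = member query intervals;
    numt_id = "NUMT_<scaffold>_<start>".  Already-merged input (disjoint,
    non-bookended loci) passes through unchanged.
    """
    ordered = sorted(hits, key=lambda h: (h.scaffold_id, h.subject_start, h.subject_end))
    records: list[NumtRecord] = []
    cluster: list[AlignmentHit] = []

    def _flush():
        if not cluster:
            return
        start = min(h.subject_start for h in cluster)
        end = max(h.subject_end for h in cluster)
        scaf = cluster[0].scaffold_id
        cols = sum(h.aligned_columns for h in cluster)
        matches = sum(h.matches for h in cluster)
        records.append(
            NumtRecord(
                numt_id=f"NUMT_{scaf}_{start}",
                locus=GenomicInterval(scaf, start, end, "."),
                mito_intervals=[
                    (h.query_start, h.query_end, h.strand) for h in cluster
                ],
                best_evalue=min(h.evalue for h in cluster),
                mean_identity=matches / cols if cols else 0.0,
                support_hits=len(cluster),
            )
        )

    for h in ordered:
        if (
            cluster
            and h.scaffold_id == cluster[0].scaffold_id
            and h.subject_start <= max(x.subject_end for x in cluster)
        ):
            cluster.append(h)
        else:
            _flush()
            cluster = [h]
    _flush()
    records.sort(key=lambda r: (r.locus.scaffold_id, r.locus.start, r.locus.end))
    return records


def detect_numts(
    mito: Mitogenome,
    genome: AnnotatedGenome,
    config: Optional[DetectionConfig] = None,
    karlin: Optional[KarlinParams] = None,
) -> tuple[list[NumtRecord], dict]:
    """Full detection: align (circular-aware) -> E-value filter ->
    scaffold-end filter -> merge.  Returns (records, summary) where summary
    reports count, total bp and the fraction of the nuclear genome covered
    by NUMTs."""
    config = config or DetectionConfig()
    hits = align_circular_query(
        mito,
        genome,
        scoring=config.scoring,
        karlin=karlin,
        evalue_max=config.evalue_max,
        gap_trigger=config.gap_trigger,
    )
    hits = filter_evalue(hits, config.evalue_max)
    hits = filter_scaffold_ends(hits, genome, config.end_margin)
    if config.merge:
        records = merge_hits_to_loci(hits)
    else:
        records = [
            NumtRecord(
                numt_id=f"NUMT_{h.scaffold_id}_{h.subject_start}_{i}",
                locus=GenomicInterval(
                    h.scaffold_id, h.subject_start, h.subject_end, "."
                ),
                mito_intervals=[(h.query_start, h.query_end, h.strand)],
                best_evalue=h.evalue,
                mean_identity=h.identity,
                support_hits=1,
            )
            for i, h in enumerate(hits)
        ]
    total_bp = sum(r.length for r in records)
    if config.count_n_in_genome_fraction:
        denom = genome.total_length
    else:
        denom = sum(
            s.length - s.sequence.count("N") for s in genome.scaffolds
        )
    summary = {
        "numt_count": len(records),
        "total_numt_bp": total_bp,
        "genome_length": denom,
        "genome_fraction": total_bp / denom if denom else 0.0,
        "n_hits": len(hits),
    }
    return records, summary
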