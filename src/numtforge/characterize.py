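"""Characterization of NUMT cohorts.

Length spectrum, mitochondrial gene of origin, insertion-site flank AT
content, position relative to nuclear gene models, and the Pearson
correlation test used to relate per-genome NUMT counts to genome size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import betainc

from numtforge.genome_io import AnnotatedGenome, GeneModel, Mitogenome
from numtforge.numt_detect import NumtRecord


@dataclass
class FlankProfile:
    """AT content of the sequence immediately flanking one NUMT.

    Flanks are truncated (not discarded) at scaffold edges; an AT value is
    None only when a flank has zero non-N bases.  combined_at is the
    base-weighted mean over the available flank bases.
    """

    numt_id: str
    upstream_at: Optional[float]
    downstream_at: Optional[float]
    combined_at: Optional[float]
    upstream_len: int
    downstream_len: int


@dataclass
class PositionClass:
    numt_id: str
    position_class: str  # exonic | intronic | flank2kb | intergenic
    nearest_gene_id: Optional[str]
    distance_bp: Optional[int]


@dataclass
class CorrelationResult:
    n: int
    r: float
    r_squared: float
    t_stat: float
    p_value: float


def length_histogram(
    numts: Sequence[NumtRecord], bin_width: int = 200, tail_from: int = 2000
) -> list[tuple[int, Optional[int], int]]:
    """Counts of NUMT lengths per half-open bin [k*bin, (k+1)*bin) up to
    tail_from, plus one open tail bin [tail_from, inf).  Returned as
    (lo, hi_or_None, count) triples covering all bins; counts sum to the
    cohort size."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if tail_from % bin_width:
        tail_from = (tail_from // bin_width) * bin_width
    n_bins = tail_from // bin_width
    counts = [0] * (n_bins + 1)
    for r in numts:
        L = r.length
        if L >= tail_from:
            counts[-1] += 1
        else:
            counts[L // bin_width] += 1
    out: list[tuple[int, Optional[int], int]] = [
        (k * bin_width, (k + 1) * bin_width, counts[k]) for k in range(n_bins)
    ]
    out.append((tail_from, None, counts[-1]))
    return out


def _modular_segments(start: int, end: int, L: int) -> list[tuple[int, int]]:
    """Split a possibly origin-wrapping interval (end may exceed L) into
    linear segments on [0, L)."""
    if end <= L:
        return [(start, end)]
    return [(start, L), (0, end - L)]


def genes_of_origin(
    numt: NumtRecord, mito: Mitogenome, min_overlap: int = 1
) -> list[tuple[str, int]]:
    """Mitochondrial protein-coding genes overlapped by the NUMT's source
    interval(s), with overlap in bp; empty if the NUMT derives only from
    non-PCG mtDNA.  A NUMT spanning a gene junction reports every gene it
    overlaps by >= min_overlap."""
    L = mito.length
    per_gene: dict[str, int] = {}
    for (qs, qe, _strand) in numt.mito_intervals:
        for (a, b) in _modular_segments(qs, qe, L):
            for g in mito.pcgs():
                ov = max(0, min(b, g.end) - max(a, g.start))
                if ov > 0:
                    per_gene[g.name] = per_gene.get(g.name, 0) + ov
    return sorted(
        ((name, ov) for name, ov in per_gene.items() if ov >= min_overlap),
        key=lambda x: (-x[1], x[0]),
    )


def origin_counts(
    numts: Sequence[NumtRecord], mito: Mitogenome, min_overlap: int = 1
) -> dict[str, int]:
    """Per-gene tally over a cohort: a NUMT increments every PCG it
    overlaps; NUMTs overlapping no PCG fall in a separate 'non_PCG' bucket
    (so counts are conserved but per-gene bars may sum to more than the
    cohort size)."""
    counts = {g.name: 0 for g in mito.pcgs()}
    counts["non_PCG"] = 0
    for r in numts:
        hit_genes = genes_of_origin(r, mito, min_overlap)
        if not hit_genes:
            counts["non_PCG"] += 1
        for (name, _ov) in hit_genes:
            counts[name] += 1
    return counts


def _at_content(seq: str) -> tuple[Optional[float], int]:
    """(AT fraction ignoring Ns or None if empty, total length used)."""
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    if at + gc == 0:
        return None, len(seq)
    return at / (at + gc), len(seq)


def flank_at(numt: NumtRecord, genome: AnnotatedGenome, flank: int = 100) -> FlankProfile:
    """AT content of the up-to-`flank` bp immediately upstream and
    downstream of the locus (in scaffold orientation), Ns ignored."""
    scaf = genome.scaffold(numt.locus.scaffold_id)
    up_start = max(0, numt.locus.start - flank)
    up = scaf.sequence[up_start : numt.locus.start]
    down = scaf.sequence[numt.locus.end : numt.locus.end + flank]
    up_at, up_len = _at_content(up)
    down_at, down_len = _at_content(down)
    both = up + down
    combined_at, _ = _at_content(both)
    return FlankProfile(
        numt_id=numt.numt_id,
        upstream_at=up_at,
        downstream_at=down_at,
        combined_at=combined_at,
        upstream_len=len(up),
        downstream_len=len(down),
    )


def genome_at(genome: AnnotatedGenome) -> float:
    """Genome-wide AT fraction over all scaffolds, Ns excluded."""
    at = gc = 0
    for s in genome.scaffolds:
        at += s.sequence.count("A") + s.sequence.count("T")
        gc += s.sequence.count("G") + s.sequence.count("C")
    if at + gc == 0:
        raise ValueError("genome has no unambiguous bases; AT content undefined")
    return at / (at + gc)


def flank_at_summary(
    numts: Sequence[NumtRecord], genome: AnnotatedGenome, flank: int = 100
) -> dict:
    """Cohort flank-composition summary: pooled-base AT of upstream,
    downstream and combined flanks, the genome baseline, and the paired
    upstream-minus-downstream comparison (mean difference and sign counts;
    reported descriptively, no hypothesis test)."""
    profiles = [flank_at(r, genome, flank) for r in numts]
    pools = {"upstream": [0, 0], "downstream": [0, 0]}
    diffs = []
    for r, p in zip(numts, profiles):
        scaf = genome.scaffold(r.locus.scaffold_id)
        up = scaf.sequence[max(0, r.locus.start - flank) : r.locus.start]
        down = scaf.sequence[r.locus.end : r.locus.end + flank]
        for key, seq in (("upstream", up), ("downstream", down)):
            pools[key][0] += seq.count("A") + seq.count("T")
            pools[key][1] += seq.count("G") + seq.count("C")
        if p.upstream_at is not None and p.downstream_at is not None:
            diffs.append(p.upstream_at - p.downstream_at)

    def _pool_at(key):
        at, gc = pools[key]
        return at / (at + gc) if at + gc else None

    up_at, down_at = _pool_at("upstream"), _pool_at("downstream")
    at_tot = pools["upstream"][0] + pools["downstream"][0]
    gc_tot = pools["upstream"][1] + pools["downstream"][1]
    mean_combined = (
        float(np.mean([p.combined_at for p in profiles if p.combined_at is not None]))
        if any(p.combined_at is not None for p in profiles)
        else None
    )
    return {
        "n": len(numts),
        "upstream_at": up_at,
        "downstream_at": down_at,
        "combined_at": (at_tot / (at_tot + gc_tot)) if at_tot + gc_tot else None,
        "mean_combined_at_per_numt": mean_combined,
        "genome_at": genome_at(genome),
        "mean_upstream_minus_downstream": float(np.mean(diffs)) if diffs else None,
        "n_upstream_higher": sum(d > 0 for d in diffs),
        "n_downstream_higher": sum(d < 0 for d in diffs),
    }


def classify_position(
    numt: NumtRecord, genes: Sequence[GeneModel], flank: int = 2000
) -> PositionClass:
    """Assign one positional class with precedence exonic > intronic >
    flank2kb > intergenic.

    Exonic: overlaps any exon by >= 1 bp.  Intronic: else overlaps a gene
    span.  flank2kb: else within `flank` bp of a gene span (inclusive
    bound).  Intergenic otherwise.  The nearest gene and its distance
    (0 for genic overlap) are always reported; None when the scaffold has
    no genes."""
    locus = numt.locus
    same = [g for g in genes if g.scaffold_id == locus.scaffold_id]
    if not same:
        return PositionClass(numt.numt_id, "intergenic", None, None)
    best_gene = None
    best_dist = None
    exonic = intronic = False
    for g in same:
        # distance = number of bases between locus and gene span (0 when
        # overlapping or bookended)
        if locus.start < g.end and g.start < locus.end:
            dist = 0
            if any(locus.start < b and a < locus.end for (a, b) in g.exons):
                exonic = True
            else:
                intronic = True
        elif locus.end <= g.start:
            dist = g.start - locus.end
        else:
            dist = locus.start - g.end
        if best_dist is None or (dist, g.gene_id) < (best_dist, best_gene):
            best_dist, best_gene = dist, g.gene_id
    if exonic:
        cls = "exonic"
    elif intronic:
        cls = "intronic"
    elif best_dist <= flank:
        cls = "flank2kb"
    else:
        cls = "intergenic"
    return PositionClass(numt.numt_id, cls, best_gene, best_dist)


def position_class_counts(
    numts: Sequence[NumtRecord], genes: Sequence[GeneModel], flank: int = 2000
) -> dict[str, int]:
    counts = {"exonic": 0, "intronic": 0, "flank2kb": 0, "intergenic": 0}
    for r in numts:
        counts[classify_position(r, genes, flank).position_class] += 1
    return counts


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value.

    r from the product-moment formula; t = r*sqrt((n-2)/(1-r^2)); the
    two-sided p comes from the Student-t distribution with n-2 df evaluated
    through the regularized incomplete beta function,
    p = I_{df/(df+t^2)}(df/2, 1/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(np.dot(xm, xm))
    syy = float(np.dot(ym, ym))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("constant input vector: correlation undefined")
    r = float(np.dot(xm, ym) / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = math.inf
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return CorrelationResult(n=n, r=r, r_squared=r * r, t_stat=t, p_value=p)
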