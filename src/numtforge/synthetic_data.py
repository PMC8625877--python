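"""Synthetic genomes with planted NUMTs and machine-readable ground truth.

The generator emulates the statistical structure the analysis targets:

* an AT-rich nuclear genome (default 65% AT) with window-scale composition
  heterogeneity, so insertion-site bias toward AT-rich windows has signal;
* a circular, very AT-rich (80%) mitogenome carrying the 13 canonical
  protein-coding genes, 2 rRNAs and 22 tRNAs in a typical insect order;
* planted mitogenome copies whose source intervals are biased toward COX1,
  whose lengths concentrate below 400 bp with a tail past 2 kb, whose
  insertion sites prefer AT-rich windows (probability ~ window-AT^beta),
  and which are decayed by substitutions and short indels;
* a transcriptome containing background (exonic) transcripts, chimeric
  transcripts that retain a NUMT plus genomic flank, and pure-mitochondrial
  decoy transcripts.

Insertion is performed by sequence splicing with coordinate lifting of gene
models, so detection faces realistic coordinates; planted sites keep >=1 kb
from scaffold ends and a minimum mutual separation so truth loci stay
distinct after merging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from numtforge.genome_io import (
    AnnotatedGenome,
    GeneModel,
    GenomicInterval,
    MitoGene,
    Mitogenome,
    Scaffold,
)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENC = {c: i for i, c in enumerate("ACGTN")}


class SimulationError(Exception):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.  Defaults put the cohort inside
    the ranges observed for bumblebee-like genomes: ~50 NUMTs per genome,
    COX1-weighted origins, AT-biased insertion sites, a length spectrum
    dominated by <400 bp copies, and ~2% sequence decay."""

    seed: int = 0
    mito_length: int = 16500
    mito_at: float = 0.80
    n_scaffolds: int = 10
    scaffold_length: int = 2_000_000
    nuclear_at: float = 0.65
    at_window: int = 2000
    at_window_sd: float = 0.12
    n_numts: int = 50
    cox1_weight: float = 5.0
    gene_weights: Optional[dict] = None  # full per-PCG override
    length_short_fraction: float = 0.8
    length_short_range: tuple[int, int] = (100, 400)
    length_long_range: tuple[int, int] = (400, 3000)
    site_at_bias: float = 4.0
    site_window: int = 200
    min_end_distance: int = 1000
    min_site_separation: int = 3000
    sub_rate: float = 0.02
    indel_rate: float = 0.002
    n_background_transcripts: int = 20
    n_chimeric_transcripts: int = 8
    n_decoy_transcripts: int = 12
    chimera_flank_retained: int = 60

    def source_gene_weights(self) -> dict[str, float]:
        from numtforge.genome_io import CANONICAL_PCGS

        if self.gene_weights is not None:
            return {g: float(self.gene_weights.get(g, 0.0)) for g in CANONICAL_PCGS}
        return {g: (self.cox1_weight if g == "COX1" else 1.0) for g in CANONICAL_PCGS}


@dataclass
class PlantedCopy:
    """Ground truth for one planted insertion (final coordinates)."""

    plant_id: str
    site: GenomicInterval
    source_start: int  # on the mitogenome; end may exceed its length (wrap)
    source_end: int
    source_strand: str
    realized_length: int
    divergence_applied: float
    chimeric_transcript_ids: list[str] = field(default_factory=list)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_sequence(n: int, at: float, rng: np.random.Generator) -> str:
    u = rng.random(n)
    codes = np.empty(n, dtype=np.uint8)
    half = at / 2.0
    codes[:] = 2  # G
    codes[u < half] = 0  # A
    codes[(u >= half) & (u < 2 * half)] = 3  # T
    codes[(u >= 2 * half) & (u < 2 * half + (1 - at) / 2)] = 1  # C
    return _DECODE[codes].tobytes().decode("ascii")


# Typical insect mitochondrial gene order (Drosophila-like arrangement).
_MITO_PLAN = [
    ("trnI", "tRNA", "+"), ("trnQ", "tRNA", "-"), ("trnM", "tRNA", "+"),
    ("ND2", "PCG", "+"), ("trnW", "tRNA", "+"), ("trnC", "tRNA", "-"),
    ("trnY", "tRNA", "-"), ("COX1", "PCG", "+"), ("trnL2", "tRNA", "+"),
    ("COX2", "PCG", "+"), ("trnK", "tRNA", "+"), ("trnD", "tRNA", "+"),
    ("ATP8", "PCG", "+"), ("ATP6", "PCG", "+"), ("COX3", "PCG", "+"),
    ("trnG", "tRNA", "+"), ("ND3", "PCG", "+"), ("trnA", "tRNA", "+"),
    ("trnR", "tRNA", "+"), ("trnN", "tRNA", "+"), ("trnS1", "tRNA", "+"),
    ("trnE", "tRNA", "+"), ("trnF", "tRNA", "-"), ("ND5", "PCG", "-"),
    ("trnH", "tRNA", "-"), ("ND4", "PCG", "-"), ("ND4L", "PCG", "-"),
    ("trnT", "tRNA", "+"), ("trnP", "tRNA", "-"), ("ND6", "PCG", "+"),
    ("CYTB", "PCG", "+"), ("trnS2", "tRNA", "+"), ("ND1", "PCG", "-"),
    ("trnL1", "tRNA", "-"), ("rrnL", "rRNA", "-"), ("trnV", "tRNA", "-"),
    ("rrnS", "rRNA", "-"),
]

_PCG_SIZES = {
    "COX1": 1539, "COX2": 684, "COX3": 786, "CYTB": 1140, "ND1": 936,
    "ND2": 1026, "ND3": 354, "ND4": 1344, "ND4L": 288, "ND5": 1719,
    "ND6": 522, "ATP6": 678, "ATP8": 162,
}
_RRNA_SIZES = {"rrnL": 1300, "rrnS": 780}


def simulate_mitogenome(config: SimulationConfig, rng=None) -> Mitogenome:
    """Circular mitogenome at 80% AT with 13 PCGs + 2 rRNA + 22 tRNA tiled
    without overlap; gene sizes are drawn within +/-10% of typical insect
    values and the slack is distributed as intergenic spacers."""
    rng = _rng(config.seed if rng is None else rng)
    sizes = []
    for (name, cls, _strand) in _MITO_PLAN:
        if cls == "PCG":
            base = _PCG_SIZES[name]
        elif cls == "rRNA":
            base = _RRNA_SIZES[name]
        else:
            base = 68
        lo, hi = int(base * 0.9), int(base * 1.1)
        sizes.append(int(rng.integers(lo, hi + 1)))
    required = sum(sizes)
    slack = config.mito_length - required
    if slack < 0:
        raise SimulationError(
            f"mito_length {config.mito_length} too small to tile the "
            f"{len(_MITO_PLAN)} genes ({required} bp required)"
        )
    # distribute slack over the len(plan)+1 spacer slots
    cuts = np.sort(rng.integers(0, slack + 1, size=len(_MITO_PLAN)))
    spacers = np.diff(np.concatenate(([0], cuts, [slack])))
    seq = _random_sequence(config.mito_length, config.mito_at, rng)
    genes = []
    pos = int(spacers[0])
    for (name, cls, strand), size, sp in zip(_MITO_PLAN, sizes, spacers[1:]):
        genes.append(MitoGene(name=name, gene_class=cls, start=pos, end=pos + size, strand=strand))
        pos += size + int(sp)
    return Mitogenome(sequence=seq, circular=True, genes=genes)


def simulate_nuclear_genome(config: SimulationConfig, rng=None) -> AnnotatedGenome:
    """AT-rich scaffolds with window-level composition heterogeneity plus
    sparse gene models (2-8 exons) covering roughly a third of the genome.

    Window AT levels are Beta-distributed around nuclear_at with standard
    deviation at_window_sd; bases are i.i.d. within a window.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    mu, sd = config.nuclear_at, config.at_window_sd
    nu = mu * (1 - mu) / sd ** 2 - 1
    if nu <= 0:
        raise SimulationError("at_window_sd too large for nuclear_at")
    a, b = mu * nu, (1 - mu) * nu
    scaffolds = []
    genes = []
    for si in range(config.n_scaffolds):
        L = config.scaffold_length
        n_win = (L + config.at_window - 1) // config.at_window
        at_w = np.clip(rng.beta(a, b, n_win), 0.05, 0.95)
        atv = np.repeat(at_w, config.at_window)[:L]
        u = rng.random(L)
        codes = np.full(L, 2, dtype=np.uint8)  # G
        codes[u < atv / 2] = 0  # A
        codes[(u >= atv / 2) & (u < atv)] = 3  # T
        codes[(u >= atv) & (u < atv + (1 - atv) / 2)] = 1  # C
        sid = f"scaf{si + 1}"
        scaffolds.append(Scaffold(id=sid, sequence=_DECODE[codes].tobytes().decode("ascii")))
        pos = 0
        gi = 0
        while True:
            gap = int(rng.integers(4000, 12001))
            glen = int(rng.integers(1500, 6001))
            start = pos + gap
            end = start + glen
            if end > L - 1000:
                break
            n_ex = int(rng.integers(2, 9))
            cuts = np.sort(
                rng.choice(np.arange(1, glen - 1), size=2 * (n_ex - 1), replace=False)
            )
            bounds = np.concatenate(([0], cuts, [glen]))
            exons = [
                (start + int(bounds[k]), start + int(bounds[k + 1]))
                for k in range(0, 2 * n_ex - 1, 2)
            ]
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene_{sid}_{gi}",
                    scaffold_id=sid,
                    strand="+" if rng.random() < 0.5 else "-",
                    start=start,
                    end=end,
                    exons=exons,
                )
            )
            pos = end
    return AnnotatedGenome(scaffolds=scaffolds, genes=genes)


def mutate_sequence(seq: str, sub_rate: float, indel_rate: float, seed=0) -> str:
    """Decay a sequence: per-base substitution to a uniformly chosen
    different base with probability sub_rate, and insertions/deletions at
    indel_rate per base with geometric lengths (mean 2)."""
    out, _stats = _mutate_with_stats(seq, sub_rate, indel_rate, _rng(seed))
    return out


def _mutate_with_stats(seq: str, sub_rate: float, indel_rate: float, rng):
    if not (0 <= sub_rate <= 1 and 0 <= indel_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = np.full(len(arr), 4, dtype=np.int64)
    for c, i in _ENC.items():
        codes[arr == ord(c)] = i
    subable = codes < 4
    hit = (rng.random(len(arr)) < sub_rate) & subable
    n_sub = int(hit.sum())
    if n_sub:
        shift = rng.integers(1, 4, size=n_sub)
        codes[hit] = (codes[hit] + shift) % 4
    mutated = _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")

    n_indel = 0
    if indel_rate > 0:
        sites = np.nonzero(rng.random(len(mutated)) < indel_rate)[0]
        pieces = list(mutated)
        for p in sites[::-1]:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion before position p
                ins = _random_sequence(length, 0.65, rng)
                pieces[p:p] = list(ins)
            else:  # deletion starting at p
                del pieces[p : p + length]
            n_indel += 1
        mutated = "".join(pieces)
    stats = {
        "n_sub": n_sub,
        "n_indel": n_indel,
        "sub_fraction": n_sub / len(seq) if seq else 0.0,
    }
    return mutated, stats


def sample_insertion_sites(
    genome: AnnotatedGenome,
    n: int,
    beta: float,
    rng,
    window: int = 200,
    min_end_distance: int = 1000,
    min_separation: int = 3000,
    stride: int = 25,
) -> list[tuple[str, int]]:
    """Sample n insertion points with probability proportional to the AT
    content of the surrounding `window` bp raised to beta (beta=0 gives the
    uniform null).  Weighted sampling without replacement uses the Gumbel
    top-k device; candidates violating the end-distance or separation
    constraints are skipped.  Raises if n sites cannot be placed.
    """
    rng = _rng(rng)
    cand_scaf: list[str] = []
    cand_pos: list[np.ndarray] = []
    logw: list[np.ndarray] = []
    half = window // 2
    for s in genome.scaffolds:
        if s.length < 2 * min_end_distance + window:
            continue
        arr = np.frombuffer(s.sequence.encode("ascii"), dtype=np.uint8)
        is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(np.int64)
        not_n = (arr != ord("N")).astype(np.int64)
        cs_at = np.concatenate(([0], np.cumsum(is_at)))
        cs_ok = np.concatenate(([0], np.cumsum(not_n)))
        pos = np.arange(min_end_distance, s.length - min_end_distance, stride)
        lo = np.maximum(0, pos - half)
        hi = np.minimum(s.length, pos + half)
        denom = cs_ok[hi] - cs_ok[lo]
        at = np.where(denom > 0, (cs_at[hi] - cs_at[lo]) / np.maximum(denom, 1), 0.0)
        cand_scaf.extend([s.id] * len(pos))
        cand_pos.append(pos)
        with np.errstate(divide="ignore"):
            logw.append(beta * np.log(np.maximum(at, 1e-12)))
    if not cand_pos:
        raise SimulationError("no scaffold long enough to host insertion sites")
    pos_all = np.concatenate(cand_pos)
    logw_all = np.concatenate(logw)
    scaf_all = np.array(cand_scaf)
    gumbel = -np.log(-np.log(rng.random(len(pos_all))))
    order = np.argsort(-(logw_all + gumbel), kind="stable")
    chosen: dict[str, list[int]] = {}
    out: list[tuple[str, int]] = []
    for idx in order:
        sid = scaf_all[idx]
        p = int(pos_all[idx])
        near = chosen.get(sid, [])
        if any(abs(p - q) < min_separation for q in near):
            continue
        chosen.setdefault(sid, []).append(p)
        out.append((sid, p))
        if len(out) == n:
            break
    if len(out) < n:
        raise SimulationError(
            f"could only place {len(out)} of {n} insertion sites under the "
            "separation constraints"
        )
    out.sort()
    return out


def _sample_source(mito: Mitogenome, config: SimulationConfig, rng) -> tuple[int, int]:
    """Source interval on the mitogenome: a PCG is chosen by weight and the
    interval midpoint falls inside it; origin wrap is allowed."""
    weights = config.source_gene_weights()
    pcgs = mito.pcgs()
    w = np.array([weights.get(g.name, 1.0) for g in pcgs])
    if w.sum() <= 0 or (w < 0).any():
        raise SimulationError("source gene weights must be non-negative, not all zero")
    gene = pcgs[int(rng.choice(len(pcgs), p=w / w.sum()))]
    if rng.random() < config.length_short_fraction:
        lo, hi = config.length_short_range
    else:
        lo, hi = config.length_long_range
    length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    length = min(max(length, lo), hi, mito.length)
    mid = int(rng.integers(gene.start, gene.end))
    start = mid - length // 2
    if start < 0:
        if mito.circular:
            start += mito.length
        else:
            start = 0
    end = start + length  # may exceed mito.length (wrap)
    if not mito.circular and end > mito.length:
        start = mito.length - length
        end = mito.length
    return start, end


def plant_numts(
    genome: AnnotatedGenome,
    mito: Mitogenome,
    config: SimulationConfig,
    rng=None,
) -> tuple[AnnotatedGenome, list[PlantedCopy]]:
    """Plant n_numts decayed mitogenome copies into the genome.

    Sources are weighted toward COX1, lengths follow the short/long mixture,
    sites prefer AT-rich windows (site_at_bias), copies are mutated and
    inserted on a random strand, and gene-model coordinates are lifted
    across every insertion point.  Truth is returned in final coordinates.
    """
    rng = _rng(config.seed + 2 if rng is None else rng)
    sites = sample_insertion_sites(
        genome,
        config.n_numts,
        config.site_at_bias,
        rng,
        window=config.site_window,
        min_end_distance=config.min_end_distance,
        min_separation=config.min_site_separation,
    )
    doubled = mito.sequence * 2
    inserts: dict[str, list[tuple[int, str, dict]]] = {}
    for k, (sid, pos) in enumerate(sites):
        src_start, src_end = _sample_source(mito, config, rng)
        raw = doubled[src_start:src_end]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from numtforge.aligner import reverse_complement

            raw = reverse_complement(raw)
        seq, stats = _mutate_with_stats(raw, config.sub_rate, config.indel_rate, rng)
        meta = {
            "plant_id": f"PLANT_{k + 1}",
            "source_start": src_start,
            "source_end": src_end,
            "source_strand": strand,
            "divergence_applied": stats["sub_fraction"],
        }
        inserts.setdefault(sid, []).append((pos, seq, meta))

    new_scaffolds = []
    truth: list[PlantedCopy] = []
    all_points: dict[str, list[tuple[int, int]]] = {}
    for scaf in genome.scaffolds:
        items = sorted(inserts.get(scaf.id, []))
        parts = []
        prev = 0
        offset = 0
        pts = []
        for (pos, seq, meta) in items:
            parts.append(scaf.sequence[prev:pos])
            parts.append(seq)
            final_start = pos + offset
            truth.append(
                PlantedCopy(
                    plant_id=meta["plant_id"],
                    site=GenomicInterval(
                        scaf.id, final_start, final_start + len(seq), meta["source_strand"]
                    ),
                    source_start=meta["source_start"],
                    source_end=meta["source_end"],
                    source_strand=meta["source_strand"],
                    realized_length=len(seq),
                    divergence_applied=meta["divergence_applied"],
                )
            )
            pts.append((pos, len(seq)))
            offset += len(seq)
            prev = pos
        parts.append(scaf.sequence[prev:])
        new_scaffolds.append(Scaffold(id=scaf.id, sequence="".join(parts)))
        all_points[scaf.id] = pts

    lifted_genes = []
    for g in genome.genes:
        pts = all_points.get(g.scaffold_id, [])
        shift_start = sum(l for (p, l) in pts if p <= g.start)
        shift_end = sum(l for (p, l) in pts if p < g.end)
        exons = []
        for (a, b) in g.exons:
            ea = a + sum(l for (p, l) in pts if p <= a)
            eb = b + sum(l for (p, l) in pts if p < b)
            exons.append((ea, eb))
        lifted_genes.append(
            GeneModel(
                gene_id=g.gene_id,
                scaffold_id=g.scaffold_id,
                strand=g.strand,
                start=g.start + shift_start,
                end=g.end + shift_end,
                exons=exons,
            )
        )
    truth.sort(key=lambda t: (t.site.scaffold_id, t.site.start))
    return AnnotatedGenome(scaffolds=new_scaffolds, genes=lifted_genes), truth


def simulate_transcriptome(
    genome: AnnotatedGenome,
    truth: Sequence[PlantedCopy],
    mito: Mitogenome,
    config: SimulationConfig,
    rng=None,
) -> tuple[list[Scaffold], dict]:
    """Background exonic transcripts, chimeric transcripts retaining a NUMT
    with `chimera_flank_retained` bp of genomic flank on each side, and
    pure-mitochondrial decoy transcripts.

    Returns (transcripts, chimera_truth); chimera_truth lists which planted
    copies are detectably chimeric (flank retained >= 50 bp).
    """
    rng = _rng(config.seed + 3 if rng is None else rng)
    if config.n_chimeric_transcripts > 0 and not truth:
        raise SimulationError("chimeric transcripts requested but no planted truth")
    transcripts: list[Scaffold] = []
    from numtforge.aligner import reverse_complement

    # background genes must not host a planted copy: an exonic NUMT would
    # make its gene's transcript a genuine chimera outside the planted truth
    sites: dict[str, list[tuple[int, int]]] = {}
    for t in truth:
        sites.setdefault(t.site.scaffold_id, []).append((t.site.start, t.site.end))
    eligible = [
        i
        for i, g in enumerate(genome.genes)
        if not any(
            a < g.end and g.start < b for (a, b) in sites.get(g.scaffold_id, [])
        )
    ]
    if eligible and config.n_background_transcripts > 0:
        pick = rng.choice(
            np.array(eligible),
            size=min(config.n_background_transcripts, len(eligible)),
            replace=False,
        )
        for j, gidx in enumerate(sorted(int(i) for i in pick), 1):
            g = genome.genes[gidx]
            seq = "".join(
                genome.scaffold(g.scaffold_id).sequence[a:b] for (a, b) in g.exons
            )
            if g.strand == "-":
                seq = reverse_complement(seq)
            transcripts.append(Scaffold(id=f"TX_BG_{j}", sequence=seq))

    f = config.chimera_flank_retained
    chimeric_ids: list[str] = []
    n_chim = min(config.n_chimeric_transcripts, len(truth))
    if n_chim > 0:
        pick = rng.choice(len(truth), size=n_chim, replace=False)
        for j, tidx in enumerate(sorted(int(i) for i in pick), 1):
            t = truth[tidx]
            scaf = genome.scaffold(t.site.scaffold_id)
            a = max(0, t.site.start - f)
            b = min(scaf.length, t.site.end + f)
            tx_id = f"TX_CHIM_{j}"
            transcripts.append(Scaffold(id=tx_id, sequence=scaf.sequence[a:b]))
            t.chimeric_transcript_ids.append(tx_id)
            chimeric_ids.append(t.plant_id)

    doubled = mito.sequence * 2
    for j in range(1, config.n_decoy_transcripts + 1):
        length = int(rng.integers(200, 1501))
        start = int(rng.integers(0, mito.length))
        transcripts.append(
            Scaffold(id=f"TX_MITO_{j}", sequence=doubled[start : start + length])
        )

    chimera_truth = {
        "chimeric_plants": sorted(chimeric_ids),
        "detectable_plants": sorted(chimeric_ids) if f >= 50 else [],
        "flank_retained": f,
    }
    return transcripts, chimera_truth


def score_detection(
    records,
    truth: Sequence[PlantedCopy],
    min_reciprocal: float = 0.5,
) -> dict:
    """Match called loci to planted truth by reciprocal overlap and report
    sensitivity and precision.

    A call matches a truth site when each covers >= min_reciprocal of the
    other; matching is greedy one-to-one by descending overlap.
    """
    pairs = []
    for t in truth:
        for r in records:
            iv = r.locus
            if iv.scaffold_id != t.site.scaffold_id:
                continue
            ov = max(0, min(iv.end, t.site.end) - max(iv.start, t.site.start))
            if ov <= 0:
                continue
            if ov >= min_reciprocal * len(iv) and ov >= min_reciprocal * (
                t.site.end - t.site.start
            ):
                pairs.append((ov, t.plant_id, r.numt_id))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t: set[str] = set()
    used_r: set[str] = set()
    matches = []
    for (_ov, tid, rid) in pairs:
        if tid in used_t or rid in used_r:
            continue
        used_t.add(tid)
        used_r.add(rid)
        matches.append((tid, rid))
    sens = len(matches) / len(truth) if truth else float("nan")
    prec = len(matches) / len(records) if records else float("nan")
    return {
        "n_truth": len(truth),
        "n_called": len(records),
        "n_matched": len(matches),
        "sensitivity": sens,
        "precision": prec,
        "matches": sorted(matches),
    }


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    mito: Mitogenome
    genome: AnnotatedGenome
    truth: list[PlantedCopy]
    transcripts: list[Scaffold]
    chimera_truth: dict


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end deterministic simulation: mitogenome, nuclear genome,
    planted NUMTs, transcriptome.  All randomness derives from config.seed."""
    mito = simulate_mitogenome(config)
    genome = simulate_nuclear_genome(config)
    planted, truth = plant_numts(genome, mito, config)
    transcripts, chimera_truth = simulate_transcriptome(planted, truth, mito, config)
    return SimulatedDataset(
        config=config,
        mito=mito,
        genome=planted,
        truth=truth,
        transcripts=transcripts,
        chimera_truth=chimera_truth,
    )
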