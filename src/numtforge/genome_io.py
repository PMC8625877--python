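"""Sequence/annotation data model and file I/O.

Single home for coordinate conventions: every interval inside the package is
0-based half-open.  GFF3 (1-based inclusive) is converted at the read/write
boundary; BED6 is native.  Sequences are uppercase DNA over {A,C,G,T,N};
IUPAC ambiguity codes collapse to N at read time (the aligner treats N as
never matching, so ambiguous assembly positions can neither seed nor extend
an alignment).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

# The 13 canonical animal mitochondrial protein-coding genes.
CANONICAL_PCGS = (
    "COX1", "COX2", "COX3", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "ATP6", "ATP8",
)

_VALID = set("ACGTN")
_CLEAN = str.maketrans(
    {c: ("N" if c not in _VALID else c) for c in map(chr, range(65, 91))}
)


class GenomeIOError(Exception):
    """Base class for I/O and validation failures in this module."""


class EmptyFileError(GenomeIOError):
    pass


class DuplicateIdError(GenomeIOError):
    pass


class FastaFormatError(GenomeIOError):
    pass


class AnnotationError(GenomeIOError):
    """GFF3 feature inconsistent with the genome or its parent feature."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named scaffold; strand in {+,-,.}."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Scaffold:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A nuclear gene: span plus sorted, disjoint exon intervals within it.

    Introns are the set difference span minus exons.  Genes lacking exon
    features are modelled as single-exon (exon == span) so positional
    classification stays total.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = None
        for (a, b) in self.exons:
            if not (self.start <= a < b <= self.end):
                raise AnnotationError(
                    f"exon [{a},{b}) outside gene span of {self.gene_id}"
                )
            if prev_end is not None and a < prev_end:
                raise AnnotationError(f"overlapping exons in {self.gene_id}")
            prev_end = b

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        prev = self.start
        for (a, b) in self.exons:
            if a > prev:
                out.append((prev, a))
            prev = b
        if self.end > prev:
            out.append((prev, self.end))
        return out


@dataclass
class AnnotatedGenome:
    """Ordered scaffolds plus gene models; the nuclear search subject."""

    scaffolds: list[Scaffold]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.id for s in self.scaffolds]
        if len(ids) != len(set(ids)):
            raise DuplicateIdError("duplicate scaffold ids in genome")
        self._by_id = {s.id: s for s in self.scaffolds}
        for g in self.genes:
            scaf = self._by_id.get(g.scaffold_id)
            if scaf is None:
                raise AnnotationError(
                    f"gene {g.gene_id} on unknown scaffold {g.scaffold_id}"
                )
            if not (0 <= g.start < g.end <= scaf.length):
                raise AnnotationError(
                    f"gene {g.gene_id} outside scaffold bounds"
                )

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.scaffolds)

    def scaffold(self, scaffold_id: str) -> Scaffold:
        try:
            return self._by_id[scaffold_id]
        except KeyError:
            raise KeyError(f"unknown scaffold {scaffold_id!r}") from None

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._by_id


@dataclass(frozen=True)
class MitoGene:
    name: str
    gene_class: str  # PCG | rRNA | tRNA
    start: int
    end: int
    strand: str = "+"


@dataclass
class Mitogenome:
    """Circular mitochondrial genome with named gene intervals."""

    sequence: str
    circular: bool = True
    genes: list[MitoGene] = field(default_factory=list)

    def __post_init__(self):
        L = len(self.sequence)
        for g in self.genes:
            if not (0 <= g.start < g.end <= L):
                raise AnnotationError(
                    f"mito gene {g.name} interval outside [0,{L})"
                )
            if g.gene_class not in ("PCG", "rRNA", "tRNA"):
                raise AnnotationError(
                    f"mito gene {g.name} has unknown class {g.gene_class!r}"
                )
            if g.gene_class == "PCG" and g.name not in CANONICAL_PCGS:
                raise AnnotationError(
                    f"{g.name!r} is not one of the 13 canonical PCG names"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def pcgs(self) -> list[MitoGene]:
        return [g for g in self.genes if g.gene_class == "PCG"]


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse any non-ACGTN character to N."""
    return seq.upper().translate(_CLEAN)


def read_fasta(path) -> list[Scaffold]:
    """Read a FASTA file into an ordered list of scaffolds.

    Sequences are uppercased and ambiguity codes collapsed to N.  Distinct
    exceptions signal an empty file, duplicate record ids, and non-FASTA
    content.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyFileError(f"{path} is empty")
    if not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path} does not look like FASTA")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise FastaFormatError(f"{path} contains no FASTA records")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} in {path} has no sequence")
        out.append(Scaffold(id=rec.id, sequence=seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3_genes(path, genome: AnnotatedGenome) -> list[GeneModel]:
    """Read gene/exon features from GFF3 into 0-based half-open GeneModels.

    GFF3 coordinates (1-based inclusive) are converted at this boundary.
    Exons are grouped under their parent genes; a gene without exons becomes
    single-exon.  Errors name the offending feature.
    """
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    gene_ids: set[str] = set()
    for g in db.features_of_type("gene"):
        if g.seqid not in genome:
            raise AnnotationError(f"gene {g.id} on unknown scaffold {g.seqid}")
        gene_ids.add(g.id)
        exons = []
        for e in db.children(g, featuretype="exon"):
            if not (g.start <= e.start and e.end <= g.end):
                raise AnnotationError(
                    f"exon {e.id or '(anonymous)'} outside span of gene {g.id}"
                )
            exons.append((e.start - 1, e.end))
        genes.append(
            GeneModel(
                gene_id=g.id,
                scaffold_id=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                start=g.start - 1,
                end=g.end,
                exons=exons,
            )
        )
    # orphan exons: exon features whose Parent is not a known gene
    for e in db.features_of_type("exon"):
        parents = e.attributes.get("Parent", [])
        if not parents or any(p not in gene_ids for p in parents):
            raise AnnotationError(
                f"orphan exon feature {e.id or e.start} with parent {parents}"
            )
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + exon rows, 1-based inclusive)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold_id, g.start, g.gene_id)):
            fh.write(
                f"{g.scaffold_id}\tnumtforge\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold_id}\tnumtforge\texon\t{a + 1}\t{b}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def _bed_score(evalue: float) -> int:
    """-log10(E) capped at 1000; E of zero (underflow) maps to the cap."""
    import math

    if evalue <= 0:
        return 1000
    return int(min(1000, max(0, round(-math.log10(evalue)))))


def write_bed(records, path) -> None:
    """Write BED6.  Records need .locus (GenomicInterval)-like fields, a name
    and an E-value; ordering is deterministic (scaffold, start, end, name).
    Accepts any object with attributes (numt_id|name, locus|interval) or
    plain (GenomicInterval, name, evalue) triples.
    """
    rows = []
    for rec in records:
        if isinstance(rec, tuple):
            iv, name, ev = rec
        else:
            iv = getattr(rec, "locus", None) or getattr(rec, "interval")
            name = getattr(rec, "numt_id", None) or getattr(rec, "name")
            ev = getattr(rec, "best_evalue", None)
            if ev is None:
                ev = getattr(rec, "evalue", 1.0)
        rows.append(
            (iv.scaffold_id, iv.start, iv.end, name, _bed_score(ev), iv.strand)
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with Path(path).open("w") as fh:
        for r in rows:
            strand = r[5] if r[5] in "+-" else "."
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]}\t{strand}\n")


def read_bed(path) -> list[tuple[GenomicInterval, str, int]]:
    """Read BED6 back as (interval, name, score) for round-trip checks."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        out.append(
            (
                GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else "."),
                f[3] if len(f) > 3 else ".",
                int(f[4]) if len(f) > 4 else 0,
            )
        )
    return out


def write_mito_annotation(mito: Mitogenome, path) -> None:
    """Write mitogenome gene annotation as GFF3 with a gene_class attribute."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(mito.genes, key=lambda g: (g.start, g.name)):
            fh.write(
                f"MT\tnumtforge\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.name};gene_class={g.gene_class}\n"
            )


def read_mito_annotation(path, sequence: str, circular: bool = True) -> Mitogenome:
    """Read a mitogenome annotation written by write_mito_annotation (or any
    GFF3 whose gene rows carry ID and optionally gene_class).  Without a
    gene_class attribute, names are classified by convention: trn* -> tRNA,
    rrn* -> rRNA, canonical PCG names -> PCG."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        name = attrs.get("ID") or attrs.get("Name")
        if name is None:
            raise AnnotationError(f"mito gene row without ID: {line}")
        cls = attrs.get("gene_class")
        if cls is None:
            if name.lower().startswith("trn"):
                cls = "tRNA"
            elif name.lower().startswith("rrn"):
                cls = "rRNA"
            elif name in CANONICAL_PCGS:
                cls = "PCG"
            else:
                raise AnnotationError(f"cannot classify mito gene {name!r}")
        genes.append(
            MitoGene(
                name=name,
                gene_class=cls,
                start=int(f[3]) - 1,
                end=int(f[4]),
                strand=f[6] if f[6] in "+-" else "+",
            )
        )
    return Mitogenome(sequence=sequence, circular=circular, genes=genes)


def mitogenome_summary(mito: Mitogenome) -> dict:
    """Total length and PCG/rRNA/tRNA gene counts (entries, not unique names);
    duplicate gene names are flagged, not collapsed."""
    counts = {"PCG": 0, "rRNA": 0, "tRNA": 0}
    seen: set[str] = set()
    duplicates: list[str] = []
    for g in mito.genes:
        counts[g.gene_class] += 1
        if g.name in seen:
            duplicates.append(g.name)
        seen.add(g.name)
    return {
        "total_length": mito.length,
        "n_pcg": counts["PCG"],
        "n_rrna": counts["rRNA"],
        "n_trna": counts["tRNA"],
        "duplicate_names": sorted(set(duplicates)),
    }
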