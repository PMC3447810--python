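"""Genome and annotation handling.

Reads a (bacterial) genome from FASTA and its gene annotation from GFF3,
extracts the upstream regions used to build promoter motif models, and
computes intergenic spans used to classify promoter hits.

Coordinate conventions: all internal coordinates are 0-based half-open
intervals; GFF3 at the I/O boundary is 1-based inclusive; BED output is
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Genome",
    "Gene",
    "UpstreamRegion",
    "read_genome",
    "read_annotation",
    "extract_upstream_regions",
    "intergenic_spans",
    "merge_intervals",
    "write_genes_gff3",
    "write_regions_fasta",
    "write_spans_bed",
]

_VALID = set("ACGTN")

# feature types retained from a GFF3 file; anything else (region, exon, ...)
# is ignored.  CDS/gene count as protein coding unless a biotype says not.
_KEPT_TYPES = {"gene", "CDS", "tRNA", "rRNA", "ncRNA", "tmRNA", "misc_RNA"}
_CODING_TYPES = {"gene", "CDS"}


@dataclass(frozen=True)
class Genome:
    """A single linear chromosome."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        s = self.sequence[start:end]
        if strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


@dataclass(frozen=True)
class Gene:
    id: str
    start: int
    end: int
    strand: str
    protein_coding: bool = True

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gene span [{self.start},{self.end}) for {self.id}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class UpstreamRegion:
    gene_id: str
    start: int
    end: int
    strand: str
    sequence: str  # strand-oriented, 5'->3' of the gene

    @property
    def length(self) -> int:
        return self.end - self.start


def read_genome(path, record_id: str | None = None) -> Genome:
    """Read a genome from FASTA.

    A single-record file is read directly; for multi-record files a
    ``record_id`` must name the chromosome to use.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if record_id is None:
        if len(records) > 1:
            raise ValueError(
                f"{path}: {len(records)} records present; pass record_id to select one"
            )
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"{path}: record {record_id!r} not found")
        rec = matches[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{path}: non-nucleotide characters {sorted(bad)}")
    if not seq:
        raise ValueError(f"{path}: empty sequence")
    return Genome(id=rec.id, sequence=seq)


def read_annotation(path, genome: Genome) -> list[Gene]:
    """Read gene features from GFF3 (1-based inclusive -> 0-based half-open)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for feat in db.all_features(order_by=("start",)):
        if feat.featuretype not in _KEPT_TYPES:
            continue
        if feat.strand not in ("+", "-"):
            raise ValueError(f"feature {feat.id or feat.featuretype}: strand is required")
        start = feat.start - 1  # GFF3 is 1-based inclusive
        end = feat.end
        if end > genome.length:
            raise ValueError(
                f"feature {feat.id or feat.featuretype} [{feat.start},{feat.end}] "
                f"exceeds genome length {genome.length}"
            )
        coding = feat.featuretype in _CODING_TYPES
        biotype = feat.attributes.get("gene_biotype") or feat.attributes.get("biotype")
        if coding and biotype and biotype[0] != "protein_coding":
            coding = False
        gid = feat.id or feat.attributes.get("ID", [f"{feat.featuretype}_{feat.start}"])[0]
        genes.append(Gene(id=gid, start=start, end=end, strand=feat.strand, protein_coding=coding))
    genes.sort(key=lambda g: (g.start, g.end, g.id))
    return genes


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals, merged and sorted."""
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def extract_upstream_regions(
    genome: Genome,
    genes: list[Gene],
    window: int = 100,
    min_len: int = 25,
) -> list[UpstreamRegion]:
    """Extract the <= ``window`` nt immediately 5' of each protein-coding gene.

    The window is truncated at the nearest gene body on either strand so
    that only intergenic sequence remains; regions shorter than
    ``min_len`` are dropped.  Minus-strand regions are reverse-complemented
    so every returned sequence reads 5'->3' of its gene.
    """
    if window < min_len:
        raise ValueError("window must be >= min_len")
    bodies = merge_intervals((g.start, g.end) for g in genes)
    out: list[UpstreamRegion] = []
    for g in genes:
        if not g.protein_coding:
            continue
        if g.strand == "+":
            lo, hi = max(0, g.start - window), g.start
            # any gene body intruding into [lo, hi) pushes lo right
            for a, b in bodies:
                if a >= hi:
                    break
                if b > lo:
                    lo = hi if b >= hi else max(lo, b)
            strand = "+"
        else:
            lo, hi = g.end, min(genome.length, g.end + window)
            # any gene body intruding into [lo, hi) pulls hi left
            for a, b in bodies:
                if a >= hi:
                    break
                if b > lo:
                    hi = lo if a <= lo else min(hi, a)
            strand = "-"
        if hi - lo >= min_len:
            out.append(UpstreamRegion(g.id, lo, hi, strand, genome.subseq(lo, hi, strand)))
    return out


def intergenic_spans(genome: Genome, genes: list[Gene]):
    """Complement of the union of gene bodies.

    Returns ``(spans, fraction)`` where fraction is total intergenic nt
    divided by genome length.
    """
    bodies = merge_intervals((g.start, g.end) for g in genes)
    spans: list[tuple[int, int]] = []
    pos = 0
    for a, b in bodies:
        if a > pos:
            spans.append((pos, a))
        pos = max(pos, b)
    if pos < genome.length:
        spans.append((pos, genome.length))
    total = sum(b - a for a, b in spans)
    return spans, total / genome.length


# ---------------------------------------------------------------- writers

def write_genes_gff3(genes: list[Gene], path, seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "gene" if g.protein_coding else "ncRNA"
            fh.write(
                f"{seqid}\tpromotile\t{ftype}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id}\n"
            )


def write_regions_fasta(regions: list[UpstreamRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.gene_id} {r.start}-{r.end}({r.strand})\n{r.sequence}\n")


def write_spans_bed(spans, path, seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        for a, b in spans:
            fh.write(f"{seqid}\t{a}\t{b}\n")
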