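"""Gene annotations and strand-aware 5'/3' half-gene regions.

Genes are loaded from GFF3, GTF or BED and held as simple genomic spans in
0-based half-open coordinates (BED convention; GFF3/GTF's 1-based inclusive
starts are converted on read). Each gene is bisected at its midpoint into a
5' half containing the TSS-proximal base and a 3' half containing the
poly(A)-proximal base, with strand deciding which genomic side is which.
Half-gene regions feed fragment counting and half-specific differential
testing downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GeneModel",
    "HalfRegion",
    "AnnotationError",
    "read_annotation",
    "bisect_gene",
    "bisect_all",
    "write_bed",
]

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


class AnnotationError(ValueError):
    """Raised for unparsable annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: genomic span, strand and identifier.

    Coordinates are 0-based half-open; ``length = end - start``. Unstranded
    genes are rejected because 5'/3' orientation is meaningless without a
    strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HalfRegion:
    """One 5' or 3' gene half, with provenance to its parent gene."""

    parent_gene_id: str
    half: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.half not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"half must be {FIVE_PRIME!r} or {THREE_PRIME!r}, got {self.half!r}")
        if self.end <= self.start:
            raise ValueError(f"half region {self.region_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"half region {self.region_id}: invalid strand {self.strand!r}")

    @property
    def region_id(self) -> str:
        return f"{self.parent_gene_id}:{self.half}"

    @property
    def length(self) -> int:
        return self.end - self.start


def _parse_gff_attributes(attr: str, fmt: str) -> dict:
    out = {}
    if fmt == "gff3":
        for field in attr.strip().rstrip(";").split(";"):
            if "=" in field:
                k, _, v = field.partition("=")
                out[k.strip()] = v.strip()
    else:  # gtf
        for field in attr.strip().rstrip(";").split(";"):
            field = field.strip()
            if not field:
                continue
            k, _, v = field.partition(" ")
            out[k.strip()] = v.strip().strip('"')
    return out


def read_annotation(path, fmt: str = "gff3") -> list[GeneModel]:
    """Read gene records from a GFF3/GTF (feature type ``gene``) or BED file.

    All coordinates are converted to 0-based half-open. Records without a
    usable strand are rejected; the number rejected is reported through a
    single :class:`UserWarning`. An unparsable line raises
    :class:`AnnotationError` naming the line number.
    """
    if fmt not in ("gff3", "gtf", "bed"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (fmt == "bed" and line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 3:
                        raise ValueError("fewer than 3 BED columns")
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    gene_id = fields[3] if len(fields) > 3 and fields[3] != "." else f"bed_{lineno}"
                    strand = fields[5] if len(fields) > 5 else "."
                else:
                    if len(fields) != 9:
                        raise ValueError(f"expected 9 {fmt.upper()} columns, got {len(fields)}")
                    if fields[2] != "gene":
                        continue
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])  # 1-based inclusive -> 0-based half-open
                    strand = fields[6]
                    attrs = _parse_gff_attributes(fields[8], fmt)
                    gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
                    if gene_id is None:
                        raise ValueError("no ID/gene_id attribute")
                if end <= start:
                    raise ValueError(f"empty or inverted span [{start}, {end})")
            except ValueError as exc:
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                n_rejected += 1
                continue
            if gene_id in seen:
                raise AnnotationError(f"{path}: line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand))
    if n_rejected:
        warnings.warn(f"{path}: rejected {n_rejected} record(s) without strand", stacklevel=2)
    return genes


def bisect_gene(gene: GeneModel) -> tuple[HalfRegion, HalfRegion]:
    """Split a gene at its midpoint into (5' half, 3' half).

    For odd lengths the extra base goes to the 5' half, so the 5' half spans
    ``ceil(L/2)`` bases. On the + strand the 5' half is the left (lower
    coordinate) side; on the - strand it is the right side.
    """
    L = gene.length
    if L < 2:
        raise ValueError(f"gene {gene.gene_id} too short to bisect (length {L})")
    half5 = (L + 1) // 2  # ceil(L/2) bases to the 5' half
    if gene.strand == "+":
        mid = gene.start + half5
        five = HalfRegion(gene.gene_id, FIVE_PRIME, gene.chrom, gene.start, mid, "+")
        three = HalfRegion(gene.gene_id, THREE_PRIME, gene.chrom, mid, gene.end, "+")
    else:
        mid = gene.start + (L - half5)  # floor(L/2) bases to the 3' (left) side
        five = HalfRegion(gene.gene_id, FIVE_PRIME, gene.chrom, mid, gene.end, "-")
        three = HalfRegion(gene.gene_id, THREE_PRIME, gene.chrom, gene.start, mid, "-")
    return five, three


def bisect_all(genes: Iterable[GeneModel], min_length: int = 2) -> list[HalfRegion]:
    """Bisect every gene of length >= ``min_length``; shorter genes are skipped
    with a warning tally."""
    halves: list[HalfRegion] = []
    n_short = 0
    for g in genes:
        if g.length < max(min_length, 2):
            n_short += 1
            continue
        halves.extend(bisect_gene(g))
    if n_short:
        warnings.warn(f"skipped {n_short} gene(s) shorter than {max(min_length, 2)} bases", stacklevel=2)
    return halves


def write_bed(regions: Sequence[HalfRegion | GeneModel], path) -> None:
    """Write regions as 6-column BED (name = ``gene_id:half`` for halves)."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.region_id if isinstance(r, HalfRegion) else r.gene_id
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t.\t{r.strand}\n")
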