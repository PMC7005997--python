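"""Genome and annotation data model with FASTA/GFF3/GenBank readers and writers.

All coordinates are 0-based half-open internally; on-disk formats keep their
native conventions (GFF3 and GenBank are 1-based inclusive). Sequences are
upper-case DNA over the alphabet ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = frozenset({"CDS", "tRNA", "rRNA", "pseudogene", "mobile_element"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an upper-case ACGTN string (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


class SeqFormatError(ValueError):
    """Raised for malformed sequence or annotation input."""


@dataclass
class GeneAnnotation:
    """A single annotated feature on a genome.

    ``start``/``end`` are 0-based half-open; ``strand`` is '+' or '-';
    ``cog_category`` holds zero or more one-letter COG codes (e.g. "P", "EP")
    or None when unassigned.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    feature_kind: str = "CDS"
    product: str = ""
    cog_category: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise SeqFormatError(
                f"annotation {self.locus_tag}: start {self.start} >= end {self.end}"
            )
        if self.feature_kind not in FEATURE_KINDS:
            raise SeqFormatError(
                f"annotation {self.locus_tag}: unknown feature_kind {self.feature_kind!r}"
            )
        if self.feature_kind == "CDS" and self.strand not in "+-":
            raise SeqFormatError(
                f"annotation {self.locus_tag}: CDS requires strand '+' or '-'"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class Genome:
    """A (possibly circular) chromosome with its feature annotations."""

    genome_id: str
    sequence: str
    circular: bool = False
    annotations: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise SeqFormatError(f"genome {self.genome_id}: empty sequence")
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        seen: set[str] = set()
        for ann in self.annotations:
            if ann.end > len(self.sequence):
                raise SeqFormatError(
                    f"genome {self.genome_id}: annotation {ann.locus_tag} "
                    f"end {ann.end} exceeds sequence length {len(self.sequence)}"
                )
            if ann.locus_tag in seen:
                raise SeqFormatError(
                    f"genome {self.genome_id}: duplicate locus_tag {ann.locus_tag}"
                )
            seen.add(ann.locus_tag)

    def genes(self, kinds: Iterable[str] = ("CDS",)) -> list[GeneAnnotation]:
        kindset = set(kinds)
        return [a for a in self.annotations if a.feature_kind in kindset]

    def feature_sequence(self, ann: GeneAnnotation) -> str:
        seq = self.sequence[ann.start : ann.end]
        return reverse_complement(seq) if ann.strand == "-" else seq


def _validate_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper()
    for pos, base in enumerate(seq):
        if base not in VALID_BASES:
            raise SeqFormatError(
                f"record {record_id}: invalid character {base!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path) -> list[Genome]:
    """Read genome skeletons (no annotations) from a FASTA file.

    Sequences are case-folded to upper; characters outside ACGTN are rejected
    with the 0-based offending position reported.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqFormatError(f"{path}: no FASTA records found")
    genomes: list[Genome] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SeqFormatError(f"{path}: duplicate record id {rec.id}")
        seen.add(rec.id)
        circular = "circular=true" in rec.description.lower()
        genomes.append(
            Genome(rec.id, _validate_sequence(str(rec.seq), rec.id), circular=circular)
        )
    return genomes


def write_fasta(genomes: Iterable[Genome] | Genome, path: str | Path, width: int = 70) -> None:
    """Write genomes as FASTA, sequence wrapped at ``width`` columns."""
    if isinstance(genomes, Genome):
        genomes = [genomes]
    with open(path, "w") as fh:
        for g in genomes:
            desc = " circular=true" if g.circular else ""
            fh.write(f">{g.genome_id}{desc}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise SeqFormatError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "pseudogene": "pseudogene",
    "mobile_genetic_element": "mobile_element",
    "mobile_element": "mobile_element",
}


def read_gff3(path: str | Path, genome: Genome) -> Genome:
    """Attach GFF3 features to ``genome``, converting 1-based inclusive
    coordinates to internal 0-based half-open ones.

    Lines whose seqid does not match ``genome.genome_id`` and feature types
    outside the supported set are ignored; features beyond the sequence end
    are rejected.
    """
    annotations: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise SeqFormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if seqid != genome.genome_id or ftype not in _GFF_TYPE_MAP:
                continue
            start_1, end_1 = int(start_s), int(end_s)
            if end_1 < start_1:
                raise SeqFormatError(f"{path}:{lineno}: end {end_1} < start {start_1}")
            attrs = _parse_gff_attributes(attr_s)
            locus = attrs.get("locus_tag") or attrs.get("ID")
            if locus is None:
                raise SeqFormatError(f"{path}:{lineno}: feature lacks locus_tag/ID")
            ann = GeneAnnotation(
                locus_tag=locus,
                start=start_1 - 1,
                end=end_1,
                strand=strand if strand in "+-" else "+",
                feature_kind=_GFF_TYPE_MAP[ftype],
                product=attrs.get("product", ""),
                cog_category=attrs.get("cog_category") or None,
            )
            if ann.end > len(genome.sequence):
                raise SeqFormatError(
                    f"{path}:{lineno}: feature {locus} end {end_1} exceeds "
                    f"sequence length {len(genome.sequence)}"
                )
            annotations.append(ann)
    result = Genome(
        genome.genome_id, genome.sequence, circular=genome.circular, annotations=annotations
    )
    return result


_GFF_TYPE_OUT = {v: k for k, v in _GFF_TYPE_MAP.items() if k != "mobile_element"}


def write_gff3(genome: Genome, path: str | Path) -> None:
    """Write annotations as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome.sequence)}\n")
        for ann in sorted(genome.annotations, key=lambda a: (a.start, a.locus_tag)):
            attrs = [f"ID={ann.locus_tag}", f"locus_tag={ann.locus_tag}"]
            if ann.product:
                attrs.append(f"product={ann.product}")
            if ann.cog_category:
                attrs.append(f"cog_category={ann.cog_category}")
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        "cladecompare",
                        _GFF_TYPE_OUT[ann.feature_kind],
                        str(ann.start + 1),
                        str(ann.end),
                        ".",
                        ann.strand,
                        "0" if ann.feature_kind == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_genbank(path: str | Path) -> Genome:
    """Read a GenBank flat file into a Genome with CDS/tRNA/rRNA annotations."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise SeqFormatError(f"{path}: no GenBank records found")
    if len(records) > 1:
        warnings.warn(f"{path}: {len(records)} records; using the first")
    rec = records[0]
    circular = rec.annotations.get("topology", "") == "circular"
    annotations: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        locus = feat.qualifiers.get("locus_tag", [None])[0]
        if locus is None or locus in seen:
            continue
        seen.add(locus)
        annotations.append(
            GeneAnnotation(
                locus_tag=locus,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
                feature_kind=feat.type,
                product=feat.qualifiers.get("product", [""])[0],
            )
        )
    return Genome(
        rec.id,
        _validate_sequence(str(rec.seq), rec.id),
        circular=circular,
        annotations=annotations,
    )
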