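"""Readers and writers for the standard formats the pipeline touches.

Every parser normalizes to a single internal coordinate convention:
0-based, half-open intervals.  GFF3 (1-based inclusive) and VCF (1-based
positions) are converted at the boundary; BED is already 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = {"+", "-", "."}

#: Default 1000 Genomes phase-3 population allele-frequency INFO keys.
DEFAULT_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")


class FormatError(ValueError):
    """A line of an input file violates its format contract."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def five_prime(self) -> int:
        """Strand-aware 5' coordinate (point, 0-based)."""
        return self.start if self.strand != "-" else self.end - 1


@dataclasses.dataclass(frozen=True)
class NcRnaLocus:
    """An annotated ncRNA gene copy: the atomic unit of all evidence."""

    interval: GenomicInterval
    species: str
    family: str
    locus_id: str
    biotype: str = ""

    def __post_init__(self) -> None:
        if not self.family:
            raise FormatError(f"locus {self.locus_id}: empty family")

    @property
    def tss(self) -> int:
        return self.interval.five_prime()


@dataclasses.dataclass(frozen=True)
class CmHit:
    """Best covariance-model bit score for one locus."""

    locus_id: str
    cm_score: float
    family: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.cm_score):
            raise FormatError(f"non-finite CM score for {self.locus_id}")


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """A small variant with per-population allele frequencies."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    pop_af: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"VCF position {self.pos} < 1")
        for pop, af in self.pop_af.items():
            if not (0.0 <= af <= 1.0):
                raise FormatError(f"allele frequency {af} for {pop} outside [0,1]")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def parse_bed_line(line: str, line_number: int | None = None):
    """Parse one BED line -> (GenomicInterval, name, score).

    BED is 0-based half-open.  Fields beyond the third are optional; a
    missing strand becomes ".".
    """
    where = f" (line {line_number})" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FormatError(f"BED line has <3 fields{where}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"non-integer BED coordinates{where}") from exc
    name = fields[3] if len(fields) > 3 else ""
    score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else 0.0
    strand = fields[5] if len(fields) > 5 else "."
    try:
        iv = GenomicInterval(chrom, start, end, strand)
    except FormatError as exc:
        raise FormatError(f"{exc}{where}") from exc
    return iv, name, score


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(parse_bed_line(line, line_number=i))
    return out


def write_bed(path: str | Path, entries: Iterable[tuple[GenomicInterval, str, float]]) -> None:
    with open(path, "w") as fh:
        for iv, name, score in entries:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def parse_gff3_record(
    line: str,
    species: str,
    family_key: str = "family",
    line_number: int | None = None,
) -> NcRnaLocus:
    """Parse a GFF3 feature line into a locus.

    GFF3 coordinates are 1-based inclusive and are converted to the internal
    0-based half-open convention (start-1, end).
    """
    where = f" (line {line_number})" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise FormatError(f"GFF3 record needs 9 columns{where}")
    chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
    try:
        start1, end1 = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"non-integer GFF3 coordinates{where}") from exc
    attrs = _parse_gff3_attributes(attr_s)
    if "ID" not in attrs:
        raise FormatError(f"GFF3 record without ID attribute{where}")
    family = attrs.get(family_key, "")
    iv = GenomicInterval(chrom, start1 - 1, end1, strand if strand in VALID_STRANDS else ".")
    return NcRnaLocus(
        interval=iv,
        species=species,
        family=family,
        locus_id=attrs["ID"],
        biotype=attrs.get("biotype", ftype),
    )


def read_gff3(path: str | Path, species: str, family_key: str = "family") -> list[NcRnaLocus]:
    loci = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            locus = parse_gff3_record(line, species=species, family_key=family_key, line_number=i)
            if locus.locus_id in seen:
                raise FormatError(f"duplicate locus ID {locus.locus_id} in {path}")
            seen.add(locus.locus_id)
            loci.append(locus)
    return loci


def write_gff3(path: str | Path, loci: Iterable[NcRnaLocus], source: str = "urnafate") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            iv = loc.interval
            attrs = f"ID={loc.locus_id};family={loc.family}"
            if loc.biotype:
                attrs += f";biotype={loc.biotype}"
            fh.write(
                f"{iv.chrom}\t{source}\tncRNA_gene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Infernal tblout
# ---------------------------------------------------------------------------

#: Infernal 1.1 cmsearch --tblout column indices (0-based).
TBLOUT_COLUMNS = {"target": 0, "query": 2, "score": 14}


def parse_infernal_tblout_row(
    line: str, columns: Mapping[str, int] = TBLOUT_COLUMNS
) -> CmHit | None:
    """Parse a cmsearch --tblout row; comment lines return None.

    Targets are locus sequences (locus id), queries the family covariance
    model.  A locus with several rows is resolved to its maximum score by
    :func:`read_tblout`.
    """
    if line.startswith("#") or not line.strip():
        return None
    fields = line.split()
    needed = max(columns.values())
    if len(fields) <= needed:
        raise FormatError(f"tblout row has {len(fields)} fields, need > {needed}")
    try:
        score = float(fields[columns["score"]])
    except ValueError as exc:
        raise FormatError(f"non-numeric tblout score {fields[columns['score']]!r}") from exc
    return CmHit(
        locus_id=fields[columns["target"]],
        cm_score=score,
        family=fields[columns["query"]],
    )


def read_tblout(path: str | Path, columns: Mapping[str, int] = TBLOUT_COLUMNS) -> dict[str, CmHit]:
    """Read a tblout file keeping, per locus, the hit with the maximum score."""
    best: dict[str, CmHit] = {}
    with open(path) as fh:
        for line in fh:
            hit = parse_infernal_tblout_row(line, columns=columns)
            if hit is None:
                continue
            prev = best.get(hit.locus_id)
            if prev is None or hit.cm_score > prev.cm_score:
                best[hit.locus_id] = hit
    return best


def write_tblout(path: str | Path, hits: Iterable[CmHit]) -> None:
    """Write hits in Infernal 1.1 --tblout column order (dummy mdl columns)."""
    with open(path, "w") as fh:
        fh.write(
            "#target name\taccession\tquery name\taccession\tmdl\tmdl from\tmdl to\t"
            "seq from\tseq to\tstrand\ttrunc\tpass\tgc\tbias\tscore\tE-value\tinc\t"
            "description of target\n"
        )
        for h in hits:
            fh.write(
                f"{h.locus_id} - {h.family} - cm 1 100 1 150 + no 1 0.45 0.0 "
                f"{h.cm_score:.1f} 1e-20 ! -\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def parse_vcf_record(
    line: str,
    populations: Iterable[str] = DEFAULT_POPULATIONS,
    af_suffix: str = "_AF",
) -> VariantRecord:
    """Parse a VCF 4.x body line, extracting per-population allele frequencies.

    A population whose INFO key is absent gets frequency 0.  Multi-allelic
    AF values keep the first alternate allele.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        raise FormatError("VCF body line needs >=8 columns")
    chrom, pos_s, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
    info_s = fields[7]
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise FormatError(f"non-integer VCF position {pos_s!r}") from exc
    info: dict[str, str] = {}
    for item in info_s.split(";"):
        if not item or item == ".":
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            info[key] = value
        else:
            info[item] = ""
    pop_af: dict[str, float] = {}
    for pop in populations:
        raw = info.get(f"{pop}{af_suffix}")
        if raw is None or raw == "":
            pop_af[pop] = 0.0
            continue
        try:
            af = float(raw.split(",")[0])
        except ValueError as exc:
            raise FormatError(f"malformed allele frequency {raw!r} for {pop}") from exc
        pop_af[pop] = af
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, pop_af=pop_af)


def read_vcf(
    path: str | Path,
    populations: Iterable[str] = DEFAULT_POPULATIONS,
    af_suffix: str = "_AF",
) -> list[VariantRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            records.append(parse_vcf_record(line, populations=populations, af_suffix=af_suffix))
    return records


def write_vcf(path: str | Path, records: Iterable[VariantRecord], af_suffix: str = "_AF") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            info = ";".join(f"{pop}{af_suffix}={af:g}" for pop, af in sorted(rec.pop_af.items()))
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# FASTA / matrices
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a name -> sequence mapping (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a loci x samples TSV count matrix (first column = locus id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_count_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Read alignment tables (SAM text or simplified TSV)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ReadAlignmentRecord:
    """A (possibly multi-mapped) short-read alignment.

    ``n_hits`` is the number of equally valid mapping locations for the read
    (the SAM ``NH`` tag); unique mappers have ``n_hits == 1``.
    """

    read_id: str
    interval: GenomicInterval
    n_hits: int
    sample: str = "s1"

    def __post_init__(self) -> None:
        if self.n_hits < 1:
            raise FormatError(f"read {self.read_id}: n_hits {self.n_hits} < 1")


def read_alignment_tsv(path: str | Path) -> list[ReadAlignmentRecord]:
    """Read a per-read hit table: read_id, sample, chrom, start, end, n_hits."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < len(idx):
                continue
            records.append(
                ReadAlignmentRecord(
                    read_id=f[idx["read_id"]],
                    sample=f[idx["sample"]] if "sample" in idx else "s1",
                    interval=GenomicInterval(
                        f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]]), "."
                    ),
                    n_hits=int(f[idx["n_hits"]]),
                )
            )
    return records


def write_alignment_tsv(path: str | Path, records: Iterable[ReadAlignmentRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample\tchrom\tstart\tend\tn_hits\n")
        for rec in records:
            iv = rec.interval
            fh.write(f"{rec.read_id}\t{rec.sample}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.n_hits}\n")


def read_sam(path: str | Path, sample: str = "s1") -> list[ReadAlignmentRecord]:
    """Read SAM text into alignment records; NH tag gives n_hits (default 1)."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
            records.append(
                ReadAlignmentRecord(
                    read_id=aln.query_name,
                    sample=sample,
                    interval=GenomicInterval(
                        aln.reference_name, aln.reference_start, aln.reference_end, "."
                    ),
                    n_hits=int(n_hits),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_newick_rooted(path_or_string: str | Path):
    """Read a rooted Newick tree (dendropy).

    A tree flagged unrooted (``[&U]``) or with a basal polytomy and no
    explicit rooting statement is rejected rather than silently rooted.
    """
    import dendropy

    src = str(path_or_string)
    if Path(src).exists():
        data = Path(src).read_text()
    else:
        data = src
    tree = dendropy.Tree.get(data=data, schema="newick", suppress_internal_node_taxa=False)
    if tree.is_rooted is not True and "[&R]" not in data:
        if len(tree.seed_node.child_nodes()) > 2:
            raise ValueError(
                "tree appears unrooted (basal polytomy, no [&R]); supply a rooted tree"
            )
    tree.is_rooted = True
    return tree


def iter_tsv(path: str | Path) -> Iterator[list[str]]:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                yield line.rstrip("\n").split("\t")
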