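"""Retrotransposition hallmarks: downstream poly-A remnants and repeat flanks.

LINE/L1-mediated retrotransposition leaves a 3' poly-A stretch directly
downstream of the inserted copy; the A fraction of the 30 bp downstream
flank, in transcript orientation, is the tractable signature.  A second,
independent hallmark is a LINE/L1 repeat annotation overlapping the 100 bp
flanking regions of a locus.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomicInterval, NcRnaLocus

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_POLYA_FLANK = 30
DEFAULT_POLYA_THRESHOLD = 0.5
DEFAULT_REPEAT_FLANK = 100


class DataError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PolyASignature:
    locus_id: str
    flank_len: int
    a_fraction: float
    flagged: bool
    truncated: bool = False


@dataclasses.dataclass(frozen=True)
class RepeatFlankCall:
    locus_id: str
    flank_len: int
    overlapping_repeat_classes: frozenset[str]
    line_l1_flanked: bool


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    seq = genome[chrom]
    # pyfaidx.Fasta records and plain strings both support slicing
    return str(seq[start:end])


def polya_fraction(
    genome: Mapping[str, str],
    locus: NcRnaLocus,
    flank_len: int = DEFAULT_POLYA_FLANK,
    threshold: float = DEFAULT_POLYA_THRESHOLD,
    strand_aware: bool = True,
) -> PolyASignature:
    """Adenosine fraction of the transcript-orientation downstream flank.

    For a + strand locus the flank is [end, end+flank_len) read as-is; for a
    - strand locus it is [start-flank_len, start) reverse-complemented.
    ``N`` never counts as adenosine.  Flanks truncated by a contig end use
    the truncated length as denominator.  The flag is strict: a_fraction
    must exceed ``threshold`` (default 0.5, i.e. >50% of bases).
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    iv = locus.interval
    if iv.chrom not in genome:
        raise DataError(f"chromosome {iv.chrom!r} absent from genome")
    chrom_len = len(genome[iv.chrom])
    minus = strand_aware and iv.strand == "-"
    if minus:
        start = max(0, iv.start - flank_len)
        flank = _fetch(genome, iv.chrom, start, iv.start)
        flank = reverse_complement(flank)
    else:
        end = min(chrom_len, iv.end + flank_len)
        flank = _fetch(genome, iv.chrom, iv.end, end)
    flank = flank.upper()
    denom = len(flank)
    truncated = denom < flank_len
    a_fraction = (flank.count("A") / denom) if denom else 0.0
    return PolyASignature(
        locus_id=locus.locus_id,
        flank_len=denom if truncated else flank_len,
        a_fraction=a_fraction,
        flagged=a_fraction > threshold,
        truncated=truncated,
    )


def repeat_flank_overlap(
    locus: NcRnaLocus,
    repeats: Iterable[tuple[GenomicInterval, str]],
    flank_len: int = DEFAULT_REPEAT_FLANK,
    line_l1_class: str = "LINE/L1",
) -> RepeatFlankCall:
    """Repeat classes overlapping either flank of a locus by >=1 bp.

    Only the flanks count: a repeat entirely inside the locus body records
    nothing.  ``line_l1_flanked`` is true iff a repeat of class
    ``line_l1_class`` overlaps a flank.
    """
    if flank_len < 0:
        raise ValueError("flank_len must be non-negative")
    iv = locus.interval
    flanks = []
    if flank_len > 0:
        left_start = max(0, iv.start - flank_len)
        if left_start < iv.start:
            flanks.append((left_start, iv.start))
        flanks.append((iv.end, iv.end + flank_len))
    classes: set[str] = set()
    for rep_iv, rep_class in repeats:
        if rep_iv.chrom != iv.chrom:
            continue
        for fs, fe in flanks:
            if rep_iv.start < fe and fs < rep_iv.end:
                classes.add(rep_class)
                break
    return RepeatFlankCall(
        locus_id=locus.locus_id,
        flank_len=flank_len,
        overlapping_repeat_classes=frozenset(classes),
        line_l1_flanked=line_l1_class in classes,
    )


def polya_table(
    genome: Mapping[str, str],
    loci: Sequence[NcRnaLocus],
    flank_len: int = DEFAULT_POLYA_FLANK,
    threshold: float = DEFAULT_POLYA_THRESHOLD,
    strand_aware: bool = True,
):
    """Per-locus poly-A signatures as a pandas DataFrame."""
    import pandas as pd

    sigs = [
        polya_fraction(genome, l, flank_len=flank_len, threshold=threshold, strand_aware=strand_aware)
        for l in loci
    ]
    return pd.DataFrame(
        {
            "locus_id": [s.locus_id for s in sigs],
            "a_fraction": [s.a_fraction for s in sigs],
            "polya_flagged": [s.flagged for s in sigs],
        }
    ).set_index("locus_id")
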