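"""Sequence-divergence summaries for ncRNA families.

Two complementary views of within-family divergence: the mean (and SD) of
pairwise nucleotide differences over an aligned family, and the per-locus
load of segregating small variants from population resequencing, counting
only variants whose folded minor allele frequency min(AF, 1-AF) exceeds 0
in at least one requested population.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import NcRnaLocus, VariantRecord

GAP_CHARS = {"-", "."}


class DataError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PairwiseDiffStats:
    family: str
    n_sequences: int
    mean_diff: float
    sd_diff: float


@dataclasses.dataclass(frozen=True)
class LocusVariantLoad:
    locus_id: str
    n_variants: int


def pairwise_differences(seq_a: str, seq_b: str, gap_is_difference: bool = True) -> int:
    """Nucleotide differences between two aligned sequences.

    A gap opposite a base counts as a difference (switchable); a gap
    opposite a gap is ignored.  Case-insensitive.
    """
    if len(seq_a) != len(seq_b):
        raise DataError("aligned sequences differ in length")
    n = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        xg, yg = x in GAP_CHARS, y in GAP_CHARS
        if xg and yg:
            continue
        if xg != yg:
            n += 1 if gap_is_difference else 0
        elif x != y:
            n += 1
    return n


def pairwise_difference_stats(
    alignment: Mapping[str, str] | Sequence[str],
    family: str = "",
    gap_is_difference: bool = True,
) -> PairwiseDiffStats:
    """Mean and population SD of pairwise differences over all n(n-1)/2 pairs."""
    seqs = list(alignment.values()) if isinstance(alignment, Mapping) else list(alignment)
    if len(seqs) < 2:
        raise DataError("need at least 2 sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise DataError("ragged alignment: sequences differ in length")
    diffs = [
        pairwise_differences(a, b, gap_is_difference=gap_is_difference)
        for a, b in combinations(seqs, 2)
    ]
    arr = np.asarray(diffs, dtype=float)
    return PairwiseDiffStats(
        family=family,
        n_sequences=len(seqs),
        mean_diff=float(arr.mean()),
        sd_diff=float(arr.std(ddof=0)),
    )


def variant_is_segregating(
    variant: VariantRecord, populations: Iterable[str] | None = None
) -> bool:
    """True iff the folded MAF min(AF, 1-AF) exceeds 0 in >=1 population.

    A variant fixed for the alternate allele (AF=1.0) everywhere is
    monomorphic within every population and does not count.
    """
    pops = list(populations) if populations is not None else list(variant.pop_af)
    for pop in pops:
        af = variant.pop_af.get(pop, 0.0)
        if min(af, 1.0 - af) > 0.0:
            return True
    return False


def snp_density(
    loci: Sequence[NcRnaLocus],
    variants: Iterable[VariantRecord],
    populations: Iterable[str] | None = None,
) -> list[LocusVariantLoad]:
    """Count qualifying variants overlapping each locus.

    VCF positions are 1-based: position p lies in a locus iff
    start < p <= end in the locus's 0-based half-open coordinates.
    """
    pops = list(populations) if populations is not None else None
    qualifying = [v for v in variants if variant_is_segregating(v, pops)]
    loads = []
    for locus in loci:
        iv = locus.interval
        n = sum(
            1
            for v in qualifying
            if v.chrom == iv.chrom and iv.start < v.pos <= iv.end
        )
        loads.append(LocusVariantLoad(locus_id=locus.locus_id, n_variants=n))
    return loads
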