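"""Expression evidence: pol-II promoter windows, unique-read counting,
RPKM, CAGE peak assignment with ambiguity/sparsity filters, and TMM
normalization to tags-per-million.

Promoter evidence asks whether a pol-II ChIP peak lies within a fixed
window (default 500 bp, inclusive) of a locus's transcription start site in
each probed cell line, and summarizes the boolean vector into three
categories: no site anywhere, a site in at least one cell line, a site in
all cell lines.  ChIP peaks are unstranded, so the distance is
strand-agnostic; the TSS itself is the strand-aware 5' end of the locus.

Short-read quantification is deliberately conservative: only reads with a
single equally valid mapping location are counted, and a unique read
overlapping two or more loci is discarded as ambiguous.  RPKM is
``[reads_at_locus / (mapped_reads / 1e6)] / length_in_kb``.

CAGE evidence assigns a peak to a locus when their strand-matched 5' ends
lie within the window, after excluding peaks near protein-coding TSSs and
peaks assignable to more than one locus; tag counts of peaks assigned to
the same locus are summed per sample.  The resulting matrix is pruned of
samples expressing <2 loci and loci expressed in <2 samples, then scaled
between samples with trimmed-mean-of-M-values (TMM) factors.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, NcRnaLocus, ReadAlignmentRecord

DEFAULT_WINDOW = 500

CATEGORY_NO_SITE = "no_site"
CATEGORY_AT_LEAST_ONE = "at_least_one"
CATEGORY_ALL = "all_cell_lines"


class DataError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PromoterEvidence:
    locus_id: str
    per_cell_line: Mapping[str, bool]
    category: str


@dataclasses.dataclass(frozen=True)
class CagePeak:
    interval: GenomicInterval
    counts: Mapping[str, int]  # sample -> tag count

    @property
    def five_prime_pos(self) -> int:
        return self.interval.five_prime()


@dataclasses.dataclass(frozen=True)
class TmmFactors:
    factors: Mapping[str, float]
    reference_sample: str
    trim_m: float = 0.30
    trim_a: float = 0.05


# ---------------------------------------------------------------------------
# Pol-II promoter windows
# ---------------------------------------------------------------------------

def _point_interval_distance(point: int, iv: GenomicInterval) -> int:
    """bp distance from a point to an interval; 0 if the point is inside."""
    if point < iv.start:
        return iv.start - point
    if point >= iv.end:
        return point - (iv.end - 1)
    return 0


def classify_polii_support(
    locus: NcRnaLocus,
    peaks_by_cell_line: Mapping[str, Sequence[GenomicInterval]],
    window: int = DEFAULT_WINDOW,
) -> PromoterEvidence:
    """Per-cell-line promoter call for one locus; window bound is inclusive."""
    if not peaks_by_cell_line:
        raise ValueError("empty cell-line map")
    tss = locus.tss
    per_line: dict[str, bool] = {}
    for line, peaks in peaks_by_cell_line.items():
        hit = any(
            p.chrom == locus.interval.chrom and _point_interval_distance(tss, p) <= window
            for p in peaks
        )
        per_line[line] = hit
    n_hit = sum(per_line.values())
    if n_hit == 0:
        category = CATEGORY_NO_SITE
    elif n_hit == len(per_line):
        category = CATEGORY_ALL
    else:
        category = CATEGORY_AT_LEAST_ONE
    return PromoterEvidence(locus_id=locus.locus_id, per_cell_line=per_line, category=category)


def promoter_table(
    loci: Sequence[NcRnaLocus],
    peaks_by_cell_line: Mapping[str, Sequence[GenomicInterval]],
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    recs = [classify_polii_support(l, peaks_by_cell_line, window) for l in loci]
    return pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in recs],
            "promoter_category": [r.category for r in recs],
            "n_cell_lines_with_site": [sum(r.per_cell_line.values()) for r in recs],
        }
    ).set_index("locus_id")


# ---------------------------------------------------------------------------
# Unique-read counting and RPKM
# ---------------------------------------------------------------------------

def count_unique_reads(
    alignments: Iterable[ReadAlignmentRecord],
    loci: Sequence[NcRnaLocus],
) -> tuple[pd.DataFrame, pd.Series]:
    """Count uniquely mapped reads per locus and sample.

    A read contributes iff it has exactly one valid mapping location
    (``n_hits == 1``) and overlaps exactly one locus; unique reads touching
    two or more loci are discarded as ambiguous.  The per-sample library
    size counts every unique read genome-wide, counted or not.

    Returns (loci x samples count matrix, per-sample library sizes).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for l in loci:
        iv = l.interval
        trees[iv.chrom][iv.start:iv.end] = l.locus_id

    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    libsize: dict[str, int] = defaultdict(int)
    samples: list[str] = []
    seen_samples: set[str] = set()
    for rec in alignments:
        if rec.n_hits < 1:
            raise DataError(f"read {rec.read_id}: n_hits < 1")
        if rec.sample not in seen_samples:
            seen_samples.add(rec.sample)
            samples.append(rec.sample)
        if rec.n_hits != 1:
            continue
        libsize[rec.sample] += 1
        iv = rec.interval
        hits = trees[iv.chrom][iv.start:iv.end] if iv.chrom in trees else set()
        if len(hits) == 1:
            (hit,) = hits
            counts[hit.data][rec.sample] += 1

    matrix = pd.DataFrame(
        [[counts[l.locus_id].get(s, 0) for s in samples] for l in loci],
        index=[l.locus_id for l in loci],
        columns=samples,
        dtype=int,
    )
    sizes = pd.Series({s: libsize.get(s, 0) for s in samples}, dtype=int)
    return matrix, sizes


def rpkm(count: float, library_size: int, locus_length_bp: int) -> float:
    """Reads per kilobase per million mapped reads, exactly as printed:
    ``[reads_at_locus / (mapped_reads / 1e6)] / length_in_kb``."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if locus_length_bp <= 0:
        raise ValueError("locus length must be positive")
    return (count / (library_size / 1_000_000)) / (locus_length_bp / 1000)


def rpkm_matrix(counts: pd.DataFrame, library_sizes: pd.Series, lengths: Mapping[str, int]) -> pd.DataFrame:
    out = counts.astype(float).copy()
    for sample in out.columns:
        n = int(library_sizes[sample])
        if n <= 0:
            raise ValueError(f"sample {sample}: zero library size")
        for lid in out.index:
            out.loc[lid, sample] = rpkm(counts.loc[lid, sample], n, lengths[lid])
    return out


# ---------------------------------------------------------------------------
# CAGE assignment and filtering
# ---------------------------------------------------------------------------

def assign_cage_peaks(
    peaks: Sequence[CagePeak],
    loci: Sequence[NcRnaLocus],
    pc_tss: Sequence[tuple[str, int, str]] = (),
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Assign CAGE peaks to loci by 5'-end proximity on the same strand.

    1. Peaks on the same strand within ``window`` bp of a protein-coding
       TSS (``pc_tss``: (chrom, pos, strand) points) are excluded.
    2. Candidate loci: same chrom and strand, |peak 5' - locus 5'| <= window.
    3. Peaks with two or more candidate loci are dropped as ambiguous.
    4. Tag counts of peaks assigned to the same locus are summed per sample.
    """
    for l in loci:
        if l.interval.strand not in ("+", "-"):
            raise DataError(f"locus {l.locus_id} has no strand")

    samples: list[str] = []
    for p in peaks:
        for s in p.counts:
            if s not in samples:
                samples.append(s)

    sums: dict[str, dict[str, int]] = {l.locus_id: defaultdict(int) for l in loci}
    for peak in peaks:
        p5 = peak.five_prime_pos
        strand = peak.interval.strand
        chrom = peak.interval.chrom
        if any(
            c == chrom and s == strand and abs(p5 - pos) <= window
            for c, pos, s in pc_tss
        ):
            continue
        candidates = [
            l
            for l in loci
            if l.interval.chrom == chrom
            and l.interval.strand == strand
            and abs(p5 - l.tss) <= window
        ]
        if len(candidates) != 1:
            continue
        lid = candidates[0].locus_id
        for sample, n in peak.counts.items():
            sums[lid][sample] += n

    return pd.DataFrame(
        [[sums[l.locus_id].get(s, 0) for s in samples] for l in loci],
        index=[l.locus_id for l in loci],
        columns=samples,
        dtype=int,
    )


def filter_cage_matrix(matrix: pd.DataFrame, iterate: bool = False) -> pd.DataFrame:
    """Drop sparse samples then sparse loci.

    One pass by default: samples expressing (count>0) fewer than 2 loci are
    removed, then loci expressed in fewer than 2 of the remaining samples.
    ``iterate=True`` repeats both steps to a fixpoint.
    """
    if matrix.empty:
        return matrix
    out = matrix
    while True:
        keep_samples = out.columns[(out > 0).sum(axis=0) >= 2]
        out2 = out[keep_samples]
        keep_loci = out2.index[(out2 > 0).sum(axis=1) >= 2]
        out2 = out2.loc[keep_loci]
        if not iterate or out2.shape == out.shape:
            return out2
        if out2.empty:
            return out2
        out = out2


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference.

    M (log ratio) and A (mean log abundance) are computed over loci with
    positive counts in both libraries; the most extreme 2*trim_m of M and
    2*trim_a of A values are rank-trimmed away, and the factor is the
    precision-weighted mean of the surviving M values, with weights from
    the asymptotic binomial variance.
    """
    mask = (obs > 0) & (ref > 0)
    obs = obs[mask].astype(float)
    ref = ref[mask].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.abs(m).max() < 1e-10:  # identical composition: factor exactly 1
        return 0.0

    n = m.size
    from scipy.stats import rankdata

    rank_m = rankdata(m)
    rank_a = rankdata(a)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep]
    return float(np.sum(m[keep] * inv_w) / np.sum(inv_w))


def tmm_factors(
    matrix: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> TmmFactors:
    """Trimmed-mean-of-M-values scaling factors for a count matrix.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions; factors are renormalized so
    their geometric mean is exactly 1.
    """
    if matrix.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = matrix.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise DataError(f"sample(s) with all-zero counts: {list(zero.index)}")
    f75 = matrix.apply(lambda col: np.quantile(col.to_numpy(), 0.75), axis=0) / lib
    ref_sample = (f75 - f75.mean()).abs().idxmin()
    ref = matrix[ref_sample].to_numpy()
    n_ref = float(lib[ref_sample])

    log_factors = {}
    for sample in matrix.columns:
        if sample == ref_sample:
            log_factors[sample] = 0.0
        else:
            log_factors[sample] = _tmm_pair_factor(
                matrix[sample].to_numpy(), ref, float(lib[sample]), n_ref, trim_m, trim_a
            )
    logf = pd.Series(log_factors)
    logf = logf - logf.mean()  # geometric mean of 2^logf becomes 1
    factors = (2.0 ** logf).to_dict()
    return TmmFactors(factors=factors, reference_sample=ref_sample, trim_m=trim_m, trim_a=trim_a)


def tmm_tpm(matrix: pd.DataFrame, factors: TmmFactors | None = None) -> pd.DataFrame:
    """Tags per million on TMM-scaled effective library sizes:
    ``TPM = count / (factor * library_size) * 1e6``."""
    if factors is None:
        factors = tmm_factors(matrix)
    lib = matrix.sum(axis=0).astype(float)
    out = matrix.astype(float).copy()
    for sample in matrix.columns:
        out[sample] = matrix[sample] / (factors.factors[sample] * lib[sample]) * 1e6
    return out


def expressed_flags(matrix: pd.DataFrame, min_count: float = 0.0) -> pd.Series:
    """Per-locus expression flag: value > min_count in at least one sample."""
    if matrix.empty or matrix.shape[1] == 0:
        return pd.Series(dtype=bool)
    return (matrix > min_count).any(axis=1)
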