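"""Integration of per-locus evidence and summary statistics.

Joins promoter, expression, retrotransposition, covariance-model,
conservation-depth and variant evidence into one record per locus, then
derives the summary views: the per-family promoter-category table with its
percent-formatting rule, the four-way support partition
(promoter+expression / promoter only / expression only / none), and a
two-sample Kolmogorov-Smirnov comparison of CM scores between loci with
and without promoter evidence.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CATEGORY_ALL, CATEGORY_NO_SITE

logger = logging.getLogger(__name__)

SUPPORT_BOTH = "promoter+expression"
SUPPORT_PROMOTER = "promoter_only"
SUPPORT_EXPRESSION = "expression_only"
SUPPORT_NONE = "none"
SUPPORT_BINS = (SUPPORT_BOTH, SUPPORT_PROMOTER, SUPPORT_EXPRESSION, SUPPORT_NONE)


class DataError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class KsResult:
    D: float
    p_value: float
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# Evidence integration
# ---------------------------------------------------------------------------

EVIDENCE_DEFAULTS = {
    "promoter_category": CATEGORY_NO_SITE,
    "expressed_rnaseq": False,
    "expressed_cage": False,
    "polya_flagged": False,
    "line_l1_flanked": False,
    "cm_score": float("nan"),
    "depth_label": "",
    "n_variants": 0,
}


def integrate_evidence(
    annotations: pd.DataFrame,
    promoter: pd.DataFrame | None = None,
    rnaseq_expressed: pd.Series | None = None,
    cage_expressed: pd.Series | None = None,
    polya: pd.DataFrame | None = None,
    repeat_flank: pd.DataFrame | None = None,
    cm_scores: pd.Series | None = None,
    depth_labels: pd.Series | None = None,
    variant_loads: pd.Series | None = None,
) -> pd.DataFrame:
    """Outer-join all evidence onto the annotation table (index: locus_id).

    ``annotations`` must carry a ``family`` column.  Missing evidence is
    filled with conservative defaults (booleans false, category no_site)
    and the gaps are logged.
    """
    if annotations.index.has_duplicates:
        dup = annotations.index[annotations.index.duplicated()].tolist()
        raise DataError(f"duplicate locus_id in annotations: {dup}")
    records = annotations.copy()

    def attach(name: str, values):
        default = EVIDENCE_DEFAULTS[name]
        if values is None:
            records[name] = default
            logger.info("evidence %s absent for all loci; defaulting to %r", name, default)
            return
        series = values if isinstance(values, pd.Series) else values
        aligned = series.reindex(records.index)
        n_missing = aligned.isna().sum()
        if n_missing:
            logger.info("evidence %s missing for %d loci; defaulting", name, n_missing)
        if isinstance(default, bool):
            aligned = aligned.fillna(default).astype(bool)
        elif isinstance(default, int) and not isinstance(default, bool):
            aligned = aligned.fillna(default).astype(int)
        else:
            aligned = aligned.fillna(default) if not isinstance(default, float) or not math.isnan(default) else aligned
        records[name] = aligned

    attach("promoter_category", promoter["promoter_category"] if promoter is not None else None)
    attach("expressed_rnaseq", rnaseq_expressed)
    attach("expressed_cage", cage_expressed)
    attach("polya_flagged", polya["polya_flagged"] if polya is not None else None)
    attach(
        "line_l1_flanked",
        repeat_flank["line_l1_flanked"] if repeat_flank is not None else None,
    )
    attach("cm_score", cm_scores)
    attach("depth_label", depth_labels)
    attach("n_variants", variant_loads)
    return records


# ---------------------------------------------------------------------------
# Table-style promoter summary
# ---------------------------------------------------------------------------

def format_percent(value: float) -> str:
    """Format a percentage: nearest integer when >=2%, one decimal when
    <2%, rounding half away from zero."""
    if value >= 2.0:
        return str(int(math.floor(value + 0.5)))
    return f"{math.floor(value * 10 + 0.5) / 10:g}"


def summarize_promoter_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-family promoter-category counts with formatted percentages.

    Columns report loci with no pol-II site, with a site in at least one
    cell line, and with a site in all cell lines; the all-cell-lines column
    is a subset of at-least-one, and the percentage denominator is
    no_site + at_least_one (i.e. all loci).
    """
    rows = []
    for family, sub in records.groupby("family", sort=True):
        cats = sub["promoter_category"]
        n_all = int((cats == CATEGORY_ALL).sum())
        n_some = int((cats != CATEGORY_NO_SITE).sum())  # includes all_cell_lines
        n_none = int((cats == CATEGORY_NO_SITE).sum())
        denom = n_none + n_some
        if denom == 0:
            logger.warning("family %s has zero loci; omitted from promoter table", family)
            continue
        rows.append(
            {
                "family": family,
                "no_site": n_none,
                "no_site_pct": format_percent(100.0 * n_none / denom),
                "at_least_one": n_some,
                "at_least_one_pct": format_percent(100.0 * n_some / denom),
                "all_cell_lines": n_all,
                "all_cell_lines_pct": format_percent(100.0 * n_all / denom),
            }
        )
    return pd.DataFrame(rows).set_index("family")


def promoter_table_from_counts(counts: Mapping[str, tuple[int, int, int]]) -> pd.DataFrame:
    """Recompute formatted percentages from raw per-family counts.

    ``counts`` maps family -> (no_site, at_least_one, all_cell_lines), with
    at_least_one inclusive of all_cell_lines.
    """
    rows = []
    for family, (n_none, n_some, n_all) in counts.items():
        denom = n_none + n_some
        rows.append(
            {
                "family": family,
                "no_site": n_none,
                "no_site_pct": format_percent(100.0 * n_none / denom),
                "at_least_one": n_some,
                "at_least_one_pct": format_percent(100.0 * n_some / denom),
                "all_cell_lines": n_all,
                "all_cell_lines_pct": format_percent(100.0 * n_all / denom),
            }
        )
    return pd.DataFrame(rows).set_index("family")


# ---------------------------------------------------------------------------
# Four-way support partition
# ---------------------------------------------------------------------------

def summarize_support_categories(records: pd.DataFrame) -> pd.DataFrame:
    """Per-family fractions over the four mutually exclusive support bins.

    Expression evidence is RNA-seq OR CAGE; promoter evidence is any
    category other than no_site.  Fractions sum to 1 within each family.
    """
    promoter = records["promoter_category"] != CATEGORY_NO_SITE
    expression = records["expressed_rnaseq"] | records["expressed_cage"]
    bin_of = np.select(
        [promoter & expression, promoter & ~expression, ~promoter & expression],
        [SUPPORT_BOTH, SUPPORT_PROMOTER, SUPPORT_EXPRESSION],
        default=SUPPORT_NONE,
    )
    df = pd.DataFrame({"family": records["family"], "support": bin_of}, index=records.index)
    rows = []
    for family, sub in df.groupby("family", sort=True):
        n = len(sub)
        frac = {b: float((sub["support"] == b).sum()) / n for b in SUPPORT_BINS}
        frac["family"] = family
        frac["n_loci"] = n
        rows.append(frac)
    return pd.DataFrame(rows).set_index("family")


def support_category_of(records: pd.DataFrame) -> pd.Series:
    """Per-locus support bin (same rule as summarize_support_categories)."""
    promoter = records["promoter_category"] != CATEGORY_NO_SITE
    expression = records["expressed_rnaseq"] | records["expressed_cage"]
    return pd.Series(
        np.select(
            [promoter & expression, promoter & ~expression, ~promoter & expression],
            [SUPPORT_BOTH, SUPPORT_PROMOTER, SUPPORT_EXPRESSION],
            default=SUPPORT_NONE,
        ),
        index=records.index,
        name="support",
    )


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| over the pooled sample points."""
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def _kolmogorov_sf(lam: float) -> float:
    """Survival function of the Kolmogorov distribution, Q(lambda)."""
    if lam <= 0:
        return 1.0
    total = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < 1e-12:
            break
    return float(min(max(total, 0.0), 1.0))


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], method: str = "asymptotic"
) -> KsResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    ``asymptotic`` uses the Kolmogorov distribution with effective sample
    size n1*n2/(n1+n2) and the standard small-sample correction
    lambda = (sqrt(en) + 0.12 + 0.11/sqrt(en)) * D.  ``exact`` enumerates
    all C(n1+n2, n1) assignments of the pooled values (feasible for
    n1+n2 <= ~16) and reports the fraction with D >= observed.  ``auto``
    picks exact when n1+n2 <= 16.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(xa, ya)
    n1, n2 = xa.size, ya.size
    if method == "auto":
        method = "exact" if n1 + n2 <= 16 else "asymptotic"
    if method == "exact":
        p = _ks_exact_p(xa, ya, d)
    elif method == "asymptotic":
        en = math.sqrt(n1 * n2 / (n1 + n2))
        p = _kolmogorov_sf((en + 0.12 + 0.11 / en) * d)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KsResult(D=d, p_value=p, n1=n1, n2=n2)


def _ks_exact_p(x: np.ndarray, y: np.ndarray, d_obs: float) -> float:
    """Exact permutation p-value: P(D >= observed) over all label splits."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    idx = range(pooled.size)
    count = 0
    total = 0
    for combo in combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        d = _ks_statistic(pooled[mask], pooled[~mask])
        if d >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def compare_cm_by_promoter(
    records: pd.DataFrame, family: str, method: str = "asymptotic"
) -> KsResult:
    """KS comparison of CM scores between loci with and without a promoter."""
    sub = records[records["family"] == family].dropna(subset=["cm_score"])
    with_prom = sub.loc[sub["promoter_category"] != CATEGORY_NO_SITE, "cm_score"]
    without = sub.loc[sub["promoter_category"] == CATEGORY_NO_SITE, "cm_score"]
    if with_prom.empty:
        raise DataError(f"family {family}: promoter stratum is empty")
    if without.empty:
        raise DataError(f"family {family}: no-promoter stratum is empty")
    return ks_two_sample(with_prom.to_numpy(), without.to_numpy(), method=method)
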