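"""Composite selection test: DAF-binned empirical p-values for PBS and |nSL|,
merged with the harmonic mean p-value (HMP).

The test targets beneficial alleles still at intermediate derived-allele
frequency (15-50%), where neither differentiation nor haplotype statistics
alone are at their most powerful.  Within 4%-wide DAF bins, each statistic is
converted to an upper-tail empirical p-value; the two (dependent) p-values are
merged with the HMP, which — unlike Fisher's method — remains valid for
dependent tests but is reliable only when the component p-values are below
0.5, so any site with either p > 0.5 is removed rather than combined.  The
smallest 5% of merged values among retained sites are flagged significant.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# removal reasons
DAF_RANGE = "daf_range"
P_GT_HALF = "p_gt_0.5"
UNDEFINED = "undefined"


def assign_daf_bins(
    daf: np.ndarray,
    bin_width: float = 0.04,
    range_low: float = 0.15,
    range_high: float = 0.50,
) -> np.ndarray:
    """DAF bin ids: left-closed/right-open bins from ``range_low``, last closed.

    Bin k covers [low + k*w, low + (k+1)*w); the final (possibly truncated)
    bin is closed at ``range_high``.  DAF outside [low, high] gets bin -1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if range_low >= range_high:
        raise ValueError("range_low must be below range_high")
    daf = np.asarray(daf, dtype=float)
    n_bins = int(math.ceil((range_high - range_low) / bin_width - 1e-9))
    with np.errstate(invalid="ignore"):
        ids = np.floor((daf - range_low) / bin_width + 1e-9)
        ids = np.minimum(ids, n_bins - 1)
        outside = np.isnan(daf) | (daf < range_low) | (daf > range_high)
    return np.where(outside, -1, ids).astype(np.int64)


def intermediate_daf_filter(
    daf: np.ndarray, low: float = 0.15, high: float = 0.50
) -> np.ndarray:
    """Removed mask for sites whose DAF is outside the closed [low, high] window."""
    if low >= high:
        raise ValueError("low must be below high")
    daf = np.asarray(daf, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.isnan(daf) | (daf < low) | (daf > high)


def empirical_pvalues(statistic: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Upper-tail empirical p-values of a statistic within DAF bins.

    Within each bin, ``p_i = #{j in bin : s_j >= s_i} / N_bin`` (self included,
    so p is at least 1/N_bin; ties share the larger p).  Sites with bin -1 or
    an undefined statistic get NaN.  A singleton bin gives p = 1 (no ranking
    information).
    """
    statistic = np.asarray(statistic, dtype=float)
    bins = np.asarray(bins)
    out = np.full(statistic.size, np.nan)
    for b in np.unique(bins):
        if b < 0:
            continue
        in_bin = (bins == b) & np.isfinite(statistic)
        n_bin = int(in_bin.sum())
        if n_bin == 0:
            continue
        if n_bin == 1:
            logger.info("DAF bin %d has a single site; its empirical p is 1", b)
        vals = statistic[in_bin]
        order = np.sort(vals)
        # count >= s_i  =  n_bin - count(< s_i)
        out[in_bin] = (n_bin - np.searchsorted(order, vals, side="left")) / n_bin
    return out


def hmp_combine(
    p_pbs: np.ndarray,
    p_nsl: np.ndarray,
    weights: tuple[float, float] = (0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted harmonic-mean p-value of two dependent tests, per site.

    ``hmp = (w1 + w2) / (w1/p1 + w2/p2)``; with equal weights this is
    ``2*p1*p2 / (p1 + p2)``, always between min(p1, p2) and max(p1, p2).
    Sites where either p exceeds 0.5 (HMP unreliable there) are flagged
    removed and get NaN instead of a merged value.

    Returns ``(hmp, removed_mask)``.
    """
    p1 = np.asarray(p_pbs, dtype=float)
    p2 = np.asarray(p_nsl, dtype=float)
    w1, w2 = weights
    if w1 <= 0 or w2 <= 0:
        raise ValueError("weights must be positive")
    with np.errstate(invalid="ignore"):
        if np.any(p1 <= 0) or np.any(p2 <= 0):
            raise ValueError("p-values must be strictly positive")
        removed = np.isnan(p1) | np.isnan(p2) | (p1 > 0.5) | (p2 > 0.5)
        hmp = (w1 + w2) / (w1 / p1 + w2 / p2)
    return np.where(removed, np.nan, hmp), removed


def top_fraction_significant(hmp: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Flag the smallest ``fraction`` of merged p-values among retained sites.

    Exactly ``ceil(fraction * N)`` sites are flagged unless ties at the cutoff
    pull extra sites in (all cutoff ties are included, with a logged warning).
    NaN entries (removed sites) are never flagged.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    hmp = np.asarray(hmp, dtype=float)
    valid = np.isfinite(hmp)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no retained sites to rank")
    k = int(math.ceil(fraction * n))
    cutoff = np.sort(hmp[valid])[k - 1]
    flagged = valid & (hmp <= cutoff)
    if flagged.sum() > k:
        logger.warning(
            "ties at the significance cutoff: %d sites flagged (nominal %d)",
            int(flagged.sum()), k,
        )
    return flagged


def composite_scan(
    daf: np.ndarray,
    pbs: np.ndarray,
    norm_nsl: np.ndarray,
    daf_low: float = 0.15,
    daf_high: float = 0.50,
    bin_width: float = 0.04,
    p_removal: float = 0.5,
    top_fraction: float = 0.05,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    site_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the full composite test and return one record per site.

    Inputs are aligned per-site arrays: the focal population's DAF, raw PBS,
    and the *normalized* nSL score (its absolute value is ranked here).
    Stages: intermediate-DAF window -> 4% DAF bins -> per-bin empirical
    p-values for PBS and |nSL| -> removal of sites with either p > ``p_removal``
    -> HMP merge -> top-``top_fraction`` flagging.
    """
    daf = np.asarray(daf, dtype=float)
    pbs = np.asarray(pbs, dtype=float)
    abs_nsl = np.abs(np.asarray(norm_nsl, dtype=float))
    n = daf.size

    out_of_window = intermediate_daf_filter(daf, daf_low, daf_high)
    undefined = ~np.isfinite(pbs) | ~np.isfinite(abs_nsl)
    bins = assign_daf_bins(daf, bin_width, daf_low, daf_high)
    bins = np.where(out_of_window | undefined, -1, bins)

    p_pbs = empirical_pvalues(np.where(undefined, np.nan, pbs), bins)
    p_nsl = empirical_pvalues(np.where(undefined, np.nan, abs_nsl), bins)
    hmp, p_removed = _combine_with_cut(p_pbs, p_nsl, p_removal)

    reason = np.full(n, "", dtype=object)
    reason[p_removed] = P_GT_HALF
    reason[undefined] = UNDEFINED
    reason[out_of_window] = DAF_RANGE
    removed = reason != ""

    significant = np.zeros(n, dtype=bool)
    retained = np.isfinite(hmp) & ~removed
    if retained.any():
        significant[retained] = top_fraction_significant(
            np.where(retained, hmp, np.nan), top_fraction
        )[retained]
    else:
        logger.warning("composite scan: no retained sites; nothing flagged")

    return pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else np.full(n, "."),
            "pos": pos if pos is not None else np.arange(n),
            "site_id": site_ids if site_ids is not None else np.arange(n).astype(str),
            "daf": daf,
            "bin": bins,
            "pbs": pbs,
            "abs_norm_nsl": abs_nsl,
            "p_pbs": p_pbs,
            "p_nsl": p_nsl,
            "hmp": hmp,
            "removed_reason": reason,
            "significant": significant,
        }
    )


def _combine_with_cut(p1, p2, p_removal):
    """HMP merge with a configurable removal cut (default 0.5)."""
    with np.errstate(invalid="ignore"):
        removed = np.isnan(p1) | np.isnan(p2) | (p1 > p_removal) | (p2 > p_removal)
        hmp = 1.0 / (0.5 / p1 + 0.5 / p2)
    return np.where(removed, np.nan, hmp), removed
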