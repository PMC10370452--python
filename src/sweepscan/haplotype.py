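"""Shared-haplotype-length selection statistics: nSL and XP-nSL.

Both statistics compare mean pairwise haplotype-sharing lengths around a focal
site, with length measured in segregating sites (no genetic map needed).  For a
pair of haplotypes (i, j), ``SL_ij`` at a focal site is the number of sites in
the maximal contiguous run of identical alleles containing the focal site; the
run extends left and right until the first mismatch or the matrix edge, and the
focal site itself is counted, so ``SL_ij >= 1`` whenever the pair agrees there.

* ``nSL = ln(SL_anc / SL_der)`` within one population, where the means are over
  pairs of ancestral-allele and derived-allele carriers at the focal site.
  A swept derived allele sits on long shared haplotypes, driving SL_der up.
* ``XP-nSL = ln(SL_pop1 / SL_pop2)`` between two populations, with means over
  all within-population pairs (no allele conditioning); positive values mean
  longer haplotypes — candidate selection — in pop1.

Raw scores are standardized within allele-frequency bins (or genome-wide) to
mean 0, sd 1, since expected haplotype lengths depend strongly on frequency.

Conventions (stated so results are reproducible): runs truncate silently at the
matrix edges; sites where either compared haplotype is missing are treated as
matching inside a run but pairs missing at the focal site are excluded from
that site's mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .io import MISSING, HaplotypeMatrix


@njit(cache=True)
def _sl_sums(H, hap_idx):  # pragma: no cover - exercised via wrappers
    """Accumulate pairwise shared-run lengths at every site.

    Returns per-site sums and pair counts for three pair categories at the
    focal site: both-ancestral, both-derived, and all both-called pairs.
    """
    n_sites = H.shape[0]
    n = hap_idx.size
    anc_sum = np.zeros(n_sites, dtype=np.float64)
    der_sum = np.zeros(n_sites, dtype=np.float64)
    all_sum = np.zeros(n_sites, dtype=np.float64)
    anc_n = np.zeros(n_sites, dtype=np.int64)
    der_n = np.zeros(n_sites, dtype=np.int64)
    all_n = np.zeros(n_sites, dtype=np.int64)
    rl = np.empty(n_sites, dtype=np.int64)
    for a in range(n - 1):
        i = hap_idx[a]
        for b in range(a + 1, n):
            j = hap_idx[b]
            s = 0
            while s < n_sites:
                ai = H[s, i]
                aj = H[s, j]
                if ai == aj or ai == -1 or aj == -1:
                    e = s + 1
                    while e < n_sites:
                        bi = H[e, i]
                        bj = H[e, j]
                        if bi == bj or bi == -1 or bj == -1:
                            e += 1
                        else:
                            break
                    run = e - s
                    for t in range(s, e):
                        rl[t] = run
                    s = e
                else:
                    rl[s] = 0
                    s += 1
            for s in range(n_sites):
                ai = H[s, i]
                aj = H[s, j]
                if ai == -1 or aj == -1:
                    continue
                all_sum[s] += rl[s]
                all_n[s] += 1
                if ai == 1 and aj == 1:
                    der_sum[s] += rl[s]
                    der_n[s] += 1
                elif ai == 0 and aj == 0:
                    anc_sum[s] += rl[s]
                    anc_n[s] += 1
    return anc_sum, anc_n, der_sum, der_n, all_sum, all_n


def _means(total: np.ndarray, count: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def pairwise_sl(
    matrix: HaplotypeMatrix, focal_site: int, haplotype_set: np.ndarray
) -> float:
    """Mean pairwise shared-run length at one focal site over a haplotype set.

    Pairs with a missing allele at the focal site are excluded; with fewer than
    2 usable haplotypes the result is undefined (NaN), not an error.
    """
    hap_idx = np.asarray(haplotype_set, dtype=np.int64)
    if hap_idx.size < 2:
        return float("nan")
    _, _, _, _, all_sum, all_n = _sl_sums(matrix.alleles, hap_idx)
    return float(_means(all_sum, all_n)[focal_site])


def _pop_daf(matrix: HaplotypeMatrix, hap_idx: np.ndarray) -> np.ndarray:
    hap = matrix.alleles[:, hap_idx]
    called = (hap != MISSING).sum(axis=1)
    der = (hap == 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(called > 0, der / np.maximum(called, 1), np.nan)


def nsl_scan(
    matrix: HaplotypeMatrix,
    hap_idx: np.ndarray,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Raw nSL at every eligible site for one population's haplotypes.

    A site is eligible when its within-population MAF exceeds ``maf_min``
    (default 0.05) and it has at least two ancestral and two derived carriers;
    other sites get NaN.
    """
    if not matrix.polarized:
        raise ValueError("nSL requires a polarized matrix (1 = derived)")
    hap_idx = np.asarray(hap_idx, dtype=np.int64)
    anc_sum, anc_n, der_sum, der_n, _, _ = _sl_sums(matrix.alleles, hap_idx)
    sl_anc = _means(anc_sum, anc_n)
    sl_der = _means(der_sum, der_n)
    daf = _pop_daf(matrix, hap_idx)
    maf = np.minimum(daf, 1 - daf)
    ok = (maf > maf_min) & (anc_n >= 1) & (der_n >= 1) & (sl_anc > 0) & (sl_der > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(ok, np.log(sl_anc / sl_der), np.nan)
    return pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "pos": matrix.positions,
            "site_id": matrix.site_ids,
            "daf": daf,
            "sl_anc": sl_anc,
            "sl_der": sl_der,
            "raw": raw,
        }
    )


def xpnsl_scan(
    matrix: HaplotypeMatrix,
    hap_idx_pop1: np.ndarray,
    hap_idx_pop2: np.ndarray,
) -> pd.DataFrame:
    """Raw XP-nSL at every site: ln of the pop1/pop2 mean shared-length ratio.

    Undefined (NaN) where either population has no usable pair or a zero mean
    shared length at the focal site.
    """
    hap1 = np.asarray(hap_idx_pop1, dtype=np.int64)
    hap2 = np.asarray(hap_idx_pop2, dtype=np.int64)
    if hap1.size < 2 or hap2.size < 2:
        raise ValueError("XP-nSL needs at least 2 haplotypes per population")
    _, _, _, _, s1, n1 = _sl_sums(matrix.alleles, hap1)
    _, _, _, _, s2, n2 = _sl_sums(matrix.alleles, hap2)
    sl1 = _means(s1, n1)
    sl2 = _means(s2, n2)
    ok = (n1 >= 1) & (n2 >= 1) & (sl1 > 0) & (sl2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(ok, np.log(sl1 / sl2), np.nan)
    return pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "pos": matrix.positions,
            "site_id": matrix.site_ids,
            "daf_pop1": _pop_daf(matrix, hap1),
            "sl_pop1": sl1,
            "sl_pop2": sl2,
            "raw": raw,
        }
    )


def freq_bins(freq: np.ndarray, width: float = 0.02) -> np.ndarray:
    """Allele-frequency bin ids: bin k covers [k*width, (k+1)*width), 1.0 closed.

    NaN frequencies get bin -1.  Default 2%-wide bins.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    freq = np.asarray(freq, dtype=float)
    n_bins = int(np.ceil(1.0 / width - 1e-9))
    with np.errstate(invalid="ignore"):
        ids = np.floor(freq / width + 1e-9).astype(float)
    ids = np.where(np.isnan(freq), -1, np.minimum(ids, n_bins - 1))
    return ids.astype(np.int64)


def normalize_scores(
    raw: np.ndarray,
    bins: np.ndarray | None = None,
    min_per_bin: int = 2,
) -> np.ndarray:
    """Standardize raw scores to mean 0, sd 1 within frequency bins.

    ``bins=None`` is genome-wide normalization (a single bin).  Bins with fewer
    than ``min_per_bin`` defined scores, or zero variance, yield NaN for their
    members (logged as undefined by callers).  Negative bin ids mean "no bin".
    """
    raw = np.asarray(raw, dtype=float)
    if bins is None:
        bins = np.zeros(raw.size, dtype=np.int64)
    bins = np.asarray(bins)
    out = np.full(raw.size, np.nan)
    for b in np.unique(bins):
        if b < 0:
            continue
        in_bin = (bins == b) & np.isfinite(raw)
        if in_bin.sum() < min_per_bin:
            continue
        vals = raw[in_bin]
        sd = vals.std()
        if sd == 0:
            continue
        out[in_bin] = (raw[in_bin] - vals.mean()) / sd
    return out
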