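"""Independent reference implementations used only as test oracles.

Each oracle takes a computational route different from the package code:
the FST oracle goes through the ANOVA mean-squares decomposition instead of
the closed-form variance components; the shared-length oracles enumerate
haplotype pairs and scan runs site by site in pure Python.
"""

from fractions import Fraction

import numpy as np


def wc_fst_anova(genotype_counts_x, genotype_counts_y):
    """Weir-Cockerham FST per site from the ANOVA mean squares.

    ``genotype_counts_*`` are (n_sites, 3) arrays of diploid counts
    (hom-ancestral, het, hom-derived).  Returns the a/(a+b+c) ratio with NaN
    where the denominator is zero.
    """
    out = []
    for gx, gy in zip(genotype_counts_x, genotype_counts_y):
        pops = [gx, gy]
        r = 2
        n = [g.sum() for g in pops]
        p = [(g[1] + 2 * g[2]) / (2 * g.sum()) for g in pops]
        n_tot = sum(n)
        p_bar = sum(2 * ni * pi for ni, pi in zip(n, p)) / (2 * n_tot)
        ssp = sum(2 * ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p))
        msp = ssp / (r - 1)
        ssi = 0.0
        for g, pi in zip(pops, p):
            # individual allele-means are 0, 1/2, 1 for the three genotypes
            ssi += 2 * (0.0 - pi) ** 2 * g[0]
            ssi += 2 * (0.5 - pi) ** 2 * g[1]
            ssi += 2 * (1.0 - pi) ** 2 * g[2]
        msi = ssi / (n_tot - r)
        ssg = sum(g[1] for g in pops) / 2.0
        msg = ssg / n_tot
        n_c = (n_tot - sum(ni**2 for ni in n) / n_tot) / (r - 1)
        c = msg
        b = (msi - msg) / 2.0
        a = (msp - msi) / (2.0 * n_c)
        denom = a + b + c
        out.append(a / denom if denom != 0 else np.nan)
    return np.array(out)


def shared_length(hap_i, hap_j, focal):
    """Run of identical alleles containing ``focal`` (missing matches)."""
    n = len(hap_i)

    def match(s):
        return hap_i[s] == hap_j[s] or hap_i[s] == -1 or hap_j[s] == -1

    if not match(focal):
        return 0
    left = focal
    while left > 0 and match(left - 1):
        left -= 1
    right = focal
    while right < n - 1 and match(right + 1):
        right += 1
    return right - left + 1


def mean_sl_pairs(alleles, focal, hap_idx, condition=None):
    """Mean pairwise shared length at a focal site by exhaustive enumeration.

    ``condition`` restricts pairs by their focal alleles: None (all
    both-called pairs), 0 (both ancestral) or 1 (both derived).
    """
    vals = []
    for a in range(len(hap_idx)):
        for b in range(a + 1, len(hap_idx)):
            i, j = hap_idx[a], hap_idx[b]
            ai, aj = alleles[focal, i], alleles[focal, j]
            if ai == -1 or aj == -1:
                continue
            if condition is not None and not (ai == condition and aj == condition):
                continue
            vals.append(shared_length(alleles[:, i], alleles[:, j], focal))
    return float(np.mean(vals)) if vals else np.nan


def nsl_site(alleles, focal, hap_idx, maf_min=0.05):
    """Raw nSL at one site by exhaustive pair enumeration (NaN if ineligible)."""
    col = alleles[focal, hap_idx]
    called = col[col != -1]
    if called.size == 0:
        return np.nan
    daf = (called == 1).mean()
    maf = min(daf, 1 - daf)
    n_der = int((called == 1).sum())
    n_anc = int((called == 0).sum())
    if maf <= maf_min or n_der < 2 or n_anc < 2:
        return np.nan
    sl_anc = mean_sl_pairs(alleles, focal, hap_idx, condition=0)
    sl_der = mean_sl_pairs(alleles, focal, hap_idx, condition=1)
    if not (sl_anc > 0 and sl_der > 0):
        return np.nan
    return float(np.log(sl_anc / sl_der))


def xpnsl_site(alleles, focal, hap_idx1, hap_idx2):
    """Raw XP-nSL at one site by exhaustive pair enumeration."""
    s1 = mean_sl_pairs(alleles, focal, hap_idx1)
    s2 = mean_sl_pairs(alleles, focal, hap_idx2)
    if not (s1 > 0 and s2 > 0):
        return np.nan
    return float(np.log(s1 / s2))


def daf_bin_exact(daf, width, low, high):
    """Interval-search bin assignment in exact rational arithmetic."""
    d = Fraction(daf)
    lo, w, hi = Fraction(low), Fraction(width), Fraction(high)
    if d < lo or d > hi:
        return -1
    n_bins = -((lo - hi) // w)  # ceil((hi - lo) / w)
    k = 0
    while k < n_bins - 1:
        if lo + k * w <= d < lo + (k + 1) * w:
            return k
        k += 1
    return int(n_bins) - 1


def quantile_by_sort(values, alpha):
    """Smallest value with at most ``alpha`` of the sample strictly above it."""
    vs = sorted(values)
    n = len(vs)
    for v in vs:
        if sum(x > v for x in vs) <= alpha * n:
            return v
    raise AssertionError("unreachable")
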