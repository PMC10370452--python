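"""Allele frequencies, Weir-Cockerham FST, the population branch statistic (PBS),
and empirical genome-wide significance thresholds.

FST uses the Weir & Cockerham (1984) unbiased estimator built from the three
ANOVA variance components: ``a`` (among populations), ``b`` (among individuals
within populations) and ``c`` (within individuals).  The per-site estimate is
``a / (a + b + c)``, clamped to [0, 1].

PBS transforms the three pairwise FST values between a focal population A, a
sister B and an outgroup C into branch lengths ``T = -ln(1 - FST)`` and
measures the length of A's branch since the A/B split::

    PBS_A = (T_AB + T_AC - T_BC) / 2

Large PBS marks allele-frequency differentiation specific to A, the classic
signature of a local selective sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, HaplotypeMatrix, PopulationPartition

PBS_FST_EPS = 1e-12  # cap FST below 1 so -ln(1 - FST) stays finite


@dataclass
class SiteFrequencyTable:
    """Per-site, per-population allele and genotype summaries.

    Haplotype-level counts (``der_count`` / ``called``) use called-allele
    counting: missing haplotype alleles are excluded from the denominator.
    Diploid-level summaries (``n_dip``, ``p_dip``, ``het_count``) are computed
    over samples whose two alleles are both called, as the Weir-Cockerham
    estimator requires complete genotypes.
    """

    populations: list[str]
    der_count: dict[str, np.ndarray]
    called: dict[str, np.ndarray]
    daf: dict[str, np.ndarray]
    maf: dict[str, np.ndarray]
    n_dip: dict[str, np.ndarray]
    p_dip: dict[str, np.ndarray]
    het_count: dict[str, np.ndarray]
    n_sites: int


def site_frequencies(
    matrix: HaplotypeMatrix, partition: PopulationPartition
) -> SiteFrequencyTable:
    """Per-population derived-allele frequencies and heterozygote counts.

    A sample is heterozygous at a site iff its two haplotypes are both called
    and carry different alleles.
    """
    out = SiteFrequencyTable(
        populations=partition.labels,
        der_count={}, called={}, daf={}, maf={},
        n_dip={}, p_dip={}, het_count={},
        n_sites=matrix.n_sites,
    )
    for label in partition.labels:
        samples = partition[label]
        if samples.size == 0:
            raise ValueError(f"population {label!r} has no samples")
        hap = matrix.alleles[:, matrix.sample_haplotype_indices(samples)]
        called = (hap != MISSING).sum(axis=1)
        der = (hap == 1).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            daf = np.where(called > 0, der / np.maximum(called, 1), np.nan)
        a0 = hap[:, 0::2]
        a1 = hap[:, 1::2]
        complete = (a0 != MISSING) & (a1 != MISSING)
        n_dip = complete.sum(axis=1)
        het = (complete & (a0 != a1)).sum(axis=1)
        dip_der = np.where(complete, a0, 0).sum(axis=1) + np.where(complete, a1, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_dip = np.where(n_dip > 0, dip_der / np.maximum(2 * n_dip, 1), np.nan)
        out.der_count[label] = der.astype(np.int64)
        out.called[label] = called.astype(np.int64)
        out.daf[label] = daf
        out.maf[label] = np.minimum(daf, 1 - daf)
        out.n_dip[label] = n_dip.astype(np.int64)
        out.p_dip[label] = p_dip
        out.het_count[label] = het.astype(np.int64)
    return out


@dataclass
class PairwiseFst:
    """Per-site Weir-Cockerham variance components and the clamped FST."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    fst_raw: np.ndarray
    fst: np.ndarray
    defined: np.ndarray


def wc_fst_components(
    n: np.ndarray, p: np.ndarray, het_freq: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) components for ``r`` populations at each site.

    Parameters are stacked population-wise: ``n`` (diploid sample sizes),
    ``p`` (allele frequencies), ``het_freq`` (observed heterozygote
    frequencies), each of shape (r, n_sites).
    """
    r = n.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = n.mean(axis=0)
        n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * het_freq).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    return a, b, c


def wc_fst(freqs: SiteFrequencyTable, pop_x: str, pop_y: str) -> PairwiseFst:
    """Per-site pairwise Weir-Cockerham FST between two populations.

    Sites where either population has fewer than 2 complete diploid genotypes
    are marked undefined.  When ``a + b + c == 0`` — both populations
    monomorphic for the same allele, so the estimator is 0/0 — FST is set to 0
    (no divergence), the convention genome scans need so that sites private to
    a third population keep a defined PBS.  Negative estimates (sampling noise
    around FST = 0) are clamped to 0 and estimates above 1 to 1.
    """
    for label in (pop_x, pop_y):
        if label not in freqs.populations:
            raise KeyError(f"unknown population label {label!r}")
    n = np.vstack([freqs.n_dip[pop_x], freqs.n_dip[pop_y]]).astype(float)
    p = np.vstack([freqs.p_dip[pop_x], freqs.p_dip[pop_y]])
    h = np.vstack(
        [
            freqs.het_count[pop_x] / np.maximum(freqs.n_dip[pop_x], 1),
            freqs.het_count[pop_y] / np.maximum(freqs.n_dip[pop_y], 1),
        ]
    )
    a, b, c = wc_fst_components(n, p, h)
    denom = a + b + c
    defined = (n >= 2).all(axis=0) & np.isfinite(denom)
    no_variation = defined & (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst_raw = np.where(defined & (denom != 0), a / denom, np.nan)
    fst_raw = np.where(no_variation, 0.0, fst_raw)
    fst = np.clip(fst_raw, 0.0, 1.0)
    return PairwiseFst(a=a, b=b, c=c, fst_raw=fst_raw, fst=fst, defined=defined)


def combined_fst(pair: PairwiseFst) -> float:
    """Multi-locus Weir-Cockerham FST: ``sum(a) / sum(a + b + c)`` over defined sites.

    This is the combined ratio Weir & Cockerham recommend for summarizing many
    loci; unlike the mean of per-site ratios it is (nearly) unbiased for the
    model divergence parameter and is used here for calibration summaries.
    Per-site scan outputs remain per-site ratios.
    """
    d = pair.defined & np.isfinite(pair.a)
    num = pair.a[d].sum()
    den = (pair.a + pair.b + pair.c)[d].sum()
    if den == 0:
        raise ValueError("no allelic variation across sites")
    return float(num / den)


@dataclass
class PbsResult:
    t_ab: np.ndarray
    t_ac: np.ndarray
    t_bc: np.ndarray
    pbs: np.ndarray


def branch_length(fst: np.ndarray, eps: float = PBS_FST_EPS) -> np.ndarray:
    """``T = -ln(1 - FST)`` with FST capped at ``1 - eps`` to stay finite."""
    return -np.log1p(-np.minimum(fst, 1.0 - eps))


def pbs(
    fst_ab: np.ndarray, fst_ac: np.ndarray, fst_bc: np.ndarray
) -> PbsResult:
    """Population branch statistic for focal population A from pairwise FST.

    Inputs are aligned per-site FST arrays in [0, 1]; NaN (undefined FST)
    propagates to an undefined PBS.
    """
    fst_ab = np.asarray(fst_ab, dtype=float)
    fst_ac = np.asarray(fst_ac, dtype=float)
    fst_bc = np.asarray(fst_bc, dtype=float)
    if not (fst_ab.shape == fst_ac.shape == fst_bc.shape):
        raise ValueError("FST arrays must have identical length")
    t_ab = branch_length(fst_ab)
    t_ac = branch_length(fst_ac)
    t_bc = branch_length(fst_bc)
    return PbsResult(t_ab=t_ab, t_ac=t_ac, t_bc=t_bc, pbs=(t_ab + t_ac - t_bc) / 2)


def empirical_threshold(values: np.ndarray, alpha: float) -> float:
    """Upper-tail empirical significance threshold.

    Returns the smallest observed value ``v`` such that the fraction of values
    strictly greater than ``v`` is at most ``alpha`` — the (1 - alpha)
    empirical quantile under the "fraction exceeding" convention used for
    genome-wide scan thresholds.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    vs = np.sort(values)
    n = vs.size
    exceed = n - np.searchsorted(vs, vs, side="right")
    idx = int(np.argmax(exceed <= alpha * n))
    return float(vs[idx])


def pbs_table(
    matrix: HaplotypeMatrix,
    partition: PopulationPartition,
) -> pd.DataFrame:
    """Per-site pairwise FST and PBS table for the configured focal/sister/outgroup.

    Sites undefined in any pairwise comparison have NaN PBS.
    """
    freqs = site_frequencies(matrix, partition)
    a_lab = partition.role("focal")
    b_lab = partition.role("sister")
    c_lab = partition.role("outgroup")
    f_ab = wc_fst(freqs, a_lab, b_lab)
    f_ac = wc_fst(freqs, a_lab, c_lab)
    f_bc = wc_fst(freqs, b_lab, c_lab)
    res = pbs(f_ab.fst, f_ac.fst, f_bc.fst)
    return pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "pos": matrix.positions,
            "site_id": matrix.site_ids,
            "daf_focal": freqs.daf[a_lab],
            "fst_ab": f_ab.fst,
            "fst_ac": f_ac.fst,
            "fst_bc": f_bc.fst,
            "pbs": res.pbs,
        }
    )
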