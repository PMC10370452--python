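"""Calibration and power harnesses built on the synthetic generators.

The composite selection test ranks each site against an empirical background;
on real data that background is genome-wide (millions of SNVs).  At simulation
scale the equivalent is a pool of independently simulated neutral regions: one
scanned region contributes its sites to the same DAF bins as the pooled
background, exactly as a candidate locus is ranked against the rest of the
genome.  These helpers produce per-region statistic tables and run the pooled
composite, and are used by both the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import composite as comp_mod
from . import haplotype as hap_mod
from . import popgen
from .io import PopulationPartition
from .simulate import SimParams, WrightFisherResult, merge_matrices, wright_fisher_sim

ROLES = {"focal": "A", "sister": "B", "outgroup": "C"}


def association_recovery(
    seed: int,
    n_replicates: int,
    beta_g: float = 0.20,
    n: int = 290,
    maf: float = 0.09,
    beta_sex: float = 0.37,
    sigma: float = 0.7,
) -> pd.DataFrame:
    """Repeated additive-model fits on simulated cohorts.

    Each replicate draws Hardy-Weinberg dosages at the configured minor-allele
    frequency, simulates a log-scale phenotype with a sex effect and the given
    residual spread, and refits the pipeline's linear model (log transform +
    sex covariate).  Returns one row per replicate with the estimate, CI and
    p-value — the substrate for bias, CI-coverage and type-I-error checks.
    """
    from .association import fit_linear_model, log_transform
    from .simulate import SimParams, simulate_phenotypes

    rng = np.random.default_rng(seed % 2**31)
    params = SimParams(beta_g=beta_g, beta_sex=beta_sex, sigma=sigma)
    rows = []
    for _ in range(n_replicates):
        dosage = rng.binomial(2, maf, n).astype(float)
        while len(np.unique(dosage)) < 2:  # monomorphic draw: redo
            dosage = rng.binomial(2, maf, n).astype(float)
        pheno = simulate_phenotypes(dosage, params, rng=rng)
        y = log_transform(pheno["phenotype"].to_numpy())
        res = fit_linear_model(y, dosage, pheno[["sex"]].to_numpy(dtype=float))
        rows.append(
            {"beta": res.beta, "ci_low": res.ci_low, "ci_high": res.ci_high,
             "p": res.p_value}
        )
    return pd.DataFrame(rows)


def three_pop_partition(result: WrightFisherResult) -> PopulationPartition:
    sizes = [result.matrices[k].n_samples for k in ("A", "B", "C")]
    offsets = np.cumsum([0] + sizes)
    return PopulationPartition(
        groups={
            k: np.arange(offsets[i], offsets[i + 1])
            for i, k in enumerate(("A", "B", "C"))
        },
        roles=dict(ROLES),
    )


def region_statistics(
    result: WrightFisherResult, maf_min: float = 0.05
) -> tuple[pd.DataFrame, int]:
    """Per-site focal DAF, PBS and raw nSL for one simulated region.

    The fixed site grid is first restricted to sites segregating in the pooled
    sample — a variant file contains only variants, and haplotype-length runs
    counted over invariant columns would be inflated for every pair.  Returns
    the statistics table and the focal site's row index on the filtered grid
    (-1 if the focal site is monomorphic in the sample).

    Raw (unnormalized) nSL is returned so that normalization can be applied on
    a pooled multi-region table, mirroring genome-wide practice.
    """
    merged = merge_matrices(result.matrices)
    seg = np.flatnonzero(
        (merged.alleles == 1).any(axis=1) & (merged.alleles == 0).any(axis=1)
    )
    focal_rows = np.flatnonzero(seg == result.focal_site)
    focal_idx = int(focal_rows[0]) if focal_rows.size else -1
    merged = merged.take_sites(seg)
    partition = three_pop_partition(result)
    ptab = popgen.pbs_table(merged, partition)
    haps = merged.sample_haplotype_indices(partition["A"])
    nsl = hap_mod.nsl_scan(merged, haps, maf_min=maf_min)
    frame = pd.DataFrame(
        {
            "daf": nsl["daf"].to_numpy(),
            "pbs": ptab["pbs"].to_numpy(),
            "raw_nsl": nsl["raw"].to_numpy(),
        }
    )
    return frame, focal_idx


def pooled_composite(
    frames: list[pd.DataFrame],
    nsl_bin_width: float = 0.02,
    **composite_kwargs,
) -> pd.DataFrame:
    """Normalize nSL on the pooled table and run the composite scan.

    ``frames`` are region tables from :func:`region_statistics`; rows stay in
    input order, so a site's pooled index is its region offset plus its
    within-region index.
    """
    pooled = pd.concat(frames, ignore_index=True)
    bins = hap_mod.freq_bins(pooled["daf"].to_numpy(), width=nsl_bin_width)
    norm = hap_mod.normalize_scores(pooled["raw_nsl"].to_numpy(), bins)
    return comp_mod.composite_scan(
        daf=pooled["daf"].to_numpy(),
        pbs=pooled["pbs"].to_numpy(),
        norm_nsl=norm,
        **composite_kwargs,
    )


def neutral_background(
    params: SimParams, n_regions: int, seed: int
) -> list[pd.DataFrame]:
    """Statistic tables for independently simulated neutral regions."""
    frames = []
    for i in range(n_regions):
        p = replace(params, seed=(seed + 65_537 * i) % 2**31,
                    wf_s=0.0, wf_condition_daf=None)
        frames.append(region_statistics(wright_fisher_sim(p))[0])
    return frames


def sweep_replicate(
    params: SimParams,
    background: list[pd.DataFrame],
    seed: int,
    **composite_kwargs,
) -> tuple[pd.DataFrame, int, WrightFisherResult]:
    """Run one conditioned sweep replicate against a neutral background pool.

    Returns the pooled composite table, the pooled row index of the sweep
    site, and the simulation result.
    """
    p = replace(params, seed=seed % 2**31)
    result = wright_fisher_sim(p)
    frame, focal_idx = region_statistics(result)
    offset = sum(len(f) for f in background)
    comp = pooled_composite(background + [frame], **composite_kwargs)
    return comp, offset + focal_idx, result
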