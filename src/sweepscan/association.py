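"""Genotype-phenotype association: minor-allele genotype coding, LD pruning,
genotype-matrix PCA for population-structure covariates, and covariate-adjusted
ordinary least squares with confidence intervals and R^2.

The regression is the standard single-variant linear model

    y = b0 + beta * g + b_sex * sex + sum_k gamma_k * PC_k + e

with ``g`` the minor-allele dosage (additive: 0/1/2 copies; dominant: 0/1
carrier indicator) and the phenotype transformed upstream where needed (e.g.
natural log for right-skewed biomarkers such as exhaled nitric oxide).
Complete-case analysis throughout: samples with a missing genotype, phenotype
or covariate are dropped from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

MODELS = ("additive", "dominant")


@dataclass
class AssociationResult:
    model: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    r_squared: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": self.model,
                    "beta": self.beta,
                    "se": self.se,
                    "ci_low": self.ci_low,
                    "ci_high": self.ci_high,
                    "p": self.p_value,
                    "r2": self.r_squared,
                    "n": self.n,
                }
            ]
        )


def minor_allele(genotypes: Sequence[tuple[str, str] | None]) -> str:
    """The less frequent allele among called genotypes in this cohort."""
    counts: dict[str, int] = {}
    for gt in genotypes:
        if gt is None:
            continue
        for a in gt:
            counts[a] = counts.get(a, 0) + 1
    if len(counts) < 2:
        raise ValueError("site is monomorphic in the analyzed cohort")
    if len(counts) > 2:
        raise ValueError(f"more than two alleles observed: {sorted(counts)}")
    # deterministic tie-break: lexicographic
    return min(counts, key=lambda a: (counts[a], a))


def encode_genotype(
    genotypes: Sequence[tuple[str, str] | None],
    model: str,
    minor: str | None = None,
) -> np.ndarray:
    """Minor-allele dosage coding for one site.

    Additive: number of minor-allele copies (0, 1, 2); dominant: minor-allele
    carrier indicator (0, 1).  Missing genotypes (None) become NaN so callers
    can drop those samples (complete-case).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if minor is None:
        minor = minor_allele(genotypes)
    alleles = {a for gt in genotypes if gt is not None for a in gt}
    if len(alleles) < 2:
        raise ValueError("site is monomorphic in the analyzed cohort")
    dosage = np.array(
        [np.nan if gt is None else float(sum(a == minor for a in gt)) for gt in genotypes]
    )
    if model == "dominant":
        with np.errstate(invalid="ignore"):
            dosage = np.where(np.isnan(dosage), np.nan, (dosage > 0).astype(float))
    return dosage


def ld_prune(
    dosage: np.ndarray,
    r2_max: float = 0.8,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Greedy windowed LD pruning on a sites x samples dosage matrix.

    Within each window of ``window`` sites (advanced by ``step``), while any
    retained pair has squared Pearson correlation above ``r2_max``, the later
    site of the first such pair (by position order) is removed.  Returns the
    retained site indices.  Missing dosages are mean-imputed for the
    correlation only.
    """
    if window < 2:
        raise ValueError("window must be at least 2 sites")
    dosage = np.asarray(dosage, dtype=float)
    n_sites = dosage.shape[0]
    filled = dosage.copy()
    for s in range(n_sites):
        row = filled[s]
        m = np.isnan(row)
        if m.any():
            row[m] = np.nanmean(row) if (~m).any() else 0.0
    keep = np.ones(n_sites, dtype=bool)
    for start in range(0, max(n_sites - 1, 1), step):
        idx = [i for i in range(start, min(start + window, n_sites)) if keep[i]]
        changed = True
        while changed and len(idx) > 1:
            changed = False
            for ai in range(len(idx)):
                for bi in range(ai + 1, len(idx)):
                    i, j = idx[ai], idx[bi]
                    xi, xj = filled[i], filled[j]
                    if xi.std() == 0 or xj.std() == 0:
                        continue
                    r = np.corrcoef(xi, xj)[0, 1]
                    if r * r > r2_max:
                        keep[j] = False
                        idx.remove(j)
                        changed = True
                        break
                if changed:
                    break
    return np.flatnonzero(keep)


def compute_pcs(dosage: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k principal components of a samples x sites dosage matrix.

    Each site is centered by ``2*p_hat`` and scaled by ``sqrt(2*p_hat*(1-p_hat))``
    (the standard genotype standardization); missing dosages are mean-imputed,
    zero-variance sites are excluded.  Per-sample coordinates are the scaled
    left singular vectors; each component's sign is fixed so its
    largest-magnitude site loading is positive.
    """
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be below min(n_samples, n_sites)={min(n, m)}")
    p_hat = np.nanmean(dosage, axis=0) / 2.0
    scale = np.sqrt(2 * p_hat * (1 - p_hat))
    usable = scale > 0
    x = dosage[:, usable] - 2 * p_hat[usable]
    x = np.where(np.isnan(x), 0.0, x) / scale[usable]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    for comp in range(k):
        lead = np.argmax(np.abs(vt[comp]))
        if vt[comp, lead] < 0:
            pcs[:, comp] *= -1
    return pcs


def fit_linear_model(
    phenotype: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    model: str = "additive",
) -> AssociationResult:
    """OLS of the (transformed) phenotype on dosage plus covariates.

    Reports the dosage coefficient with its two-sided Wald p-value from the t
    distribution, a 95% CI at the residual-df t quantile, and the full-model
    R^2.  Samples with any missing value are dropped first.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(dosage, dtype=float)
    cols = ["dosage"]
    parts = [g.reshape(-1, 1)]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cols += list(covariates.columns)
            parts.append(covariates.to_numpy(dtype=float))
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov.reshape(-1, 1)
            cols += [f"cov{i}" for i in range(cov.shape[1])]
            parts.append(cov)
    x = np.hstack(parts)
    complete = np.isfinite(y) & np.isfinite(x).all(axis=1)
    y, x = y[complete], x[complete]
    n = int(complete.sum())
    if n <= x.shape[1] + 1:
        raise ValueError(f"only {n} complete cases for {x.shape[1] + 1} parameters")
    design = sm.add_constant(pd.DataFrame(x, columns=cols), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = _collinear_columns(design)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(y, design).fit()
    r_squared = float(fit.rsquared)
    if not np.isfinite(r_squared):  # zero-variance phenotype: no variance explained
        r_squared = 0.0
    ci_low, ci_high = fit.conf_int().loc["dosage"]
    return AssociationResult(
        model=model,
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(fit.pvalues["dosage"]),
        r_squared=r_squared,
        n=n,
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Name columns that do not increase the design rank when added."""
    bad = []
    acc = np.empty((len(design), 0))
    for c in design.columns:
        cand = np.hstack([acc, design[[c]].to_numpy()])
        if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(acc):
            bad.append(c)
        else:
            acc = cand
    return bad


def read_phenotype_table(path: str) -> pd.DataFrame:
    """Read a TSV with at least ``sample_id``, ``sex`` and ``phenotype`` columns
    (optional PC1..PCk); duplicate sample ids are an error."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "sex", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in phenotype table: {dups}")
    return df


def log_transform(values: np.ndarray) -> np.ndarray:
    """Natural-log transform for strictly positive phenotypes (e.g. FeNO in ppb)."""
    values = np.asarray(values, dtype=float)
    if np.any(values[np.isfinite(values)] <= 0):
        raise ValueError("log transform requires strictly positive phenotype values")
    return np.log(values)
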