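"""End-to-end orchestration: QC -> PBS -> nSL/XP-nSL -> composite -> association.

One :class:`PipelineConfig` carries every input path and threshold; defaults
are the standard settings of this scan family (10% missingness, MAF > 0.05 for
nSL, the 15-50% intermediate-DAF window with 4% bins, p > 0.5 HMP removal,
top-5% flagging, alpha = 0.01 empirical thresholds, r^2 > 0.8 LD pruning, five
PCs).  Every run writes the resolved config and a manifest of input checksums
and per-stage row counts beside its outputs, and is deterministic given inputs
and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import composite as comp_mod
from . import haplotype as hap_mod
from . import io as gio
from . import popgen

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    population_map: str = ""
    phenotype_table: str | None = None
    exclusion_list: str | None = None
    ancestral_table: str | None = None
    region: str | None = None
    focal: str = "A"
    sister: str = "B"
    outgroup: str = "C"
    assoc_site: str | None = None
    site_missing_max: float = 0.10
    sample_missing_max: float = 0.10
    maf_min: float = 0.05
    daf_low: float = 0.15
    daf_high: float = 0.50
    daf_bin_width: float = 0.04
    nsl_bin_width: float = 0.02
    p_removal: float = 0.5
    top_fraction: float = 0.05
    alpha: float = 0.01
    r2_max: float = 0.8
    n_pcs: int = 5
    seed: int = 0
    outdir: str = "sweepscan_out"

    def validate(self) -> None:
        if not self.vcf or not self.population_map:
            raise ValueError("config must name a vcf and a population_map")
        for name in ("site_missing_max", "sample_missing_max", "maf_min", "r2_max", "p_removal"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of range: {v}")
        for name in ("top_fraction", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1): {v}")
        if not 0 <= self.daf_low < self.daf_high <= 1:
            raise ValueError("DAF window must satisfy 0 <= low < high <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _ancestral_from_vcf(path: str) -> dict[str, str]:
    """Collect AA INFO tags as a site_id -> ancestral-base table."""
    from cyvcf2 import VCF

    table: dict[str, str] = {}
    for var in VCF(path):
        aa = var.INFO.get("AA")
        if aa:
            sid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
            table[sid] = str(aa)
    return table


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write result tables plus a manifest.

    Returns the output directory.  Any stage error propagates with the stage
    name prepended so failures are attributable.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"inputs": {}, "stages": {}}
    for name in ("vcf", "population_map", "phenotype_table", "exclusion_list", "ancestral_table"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # annotate, re-raise
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    # -- QC ---------------------------------------------------------------
    @stage("qc")
    def matrix():
        m = gio.read_phased_vcf(config.vcf, region=config.region)
        if config.exclusion_list:
            m = m.drop_samples(gio.read_exclusion_list(config.exclusion_list))
        m, report = gio.missingness_filter(
            m, site_max=config.site_missing_max, sample_max=config.sample_missing_max
        )
        if config.ancestral_table:
            aa = gio.read_ancestral_table(config.ancestral_table)
        else:
            aa = _ancestral_from_vcf(config.vcf)
        m = gio.polarize(m, aa)
        manifest["stages"]["qc"] = {
            "n_sites": m.n_sites,
            "n_samples": m.n_samples,
            "removed_samples": report.removed_samples,
            "n_removed_sites": len(report.removed_sites),
        }
        return m

    partition = gio.read_population_map(
        config.population_map,
        matrix.sample_ids,
        roles={"focal": config.focal, "sister": config.sister, "outgroup": config.outgroup},
    )

    # -- PBS --------------------------------------------------------------
    @stage("pbs")
    def pbs_df():
        df = popgen.pbs_table(matrix, partition)
        finite = df["pbs"].dropna()
        if len(finite):
            df.attrs["threshold"] = popgen.empirical_threshold(finite.to_numpy(), config.alpha)
        df.to_csv(outdir / "pbs.tsv", sep="\t", index=False)
        manifest["stages"]["pbs"] = {"n_sites": len(df), "n_defined": int(df["pbs"].notna().sum())}
        return df

    focal_haps = matrix.sample_haplotype_indices(partition[config.focal])
    sister_haps = matrix.sample_haplotype_indices(partition[config.sister])

    # -- nSL --------------------------------------------------------------
    @stage("nsl")
    def nsl_df():
        df = hap_mod.nsl_scan(matrix, focal_haps, maf_min=config.maf_min)
        bins = hap_mod.freq_bins(df["daf"].to_numpy(), width=config.nsl_bin_width)
        df["bin"] = bins
        df["normalized"] = hap_mod.normalize_scores(df["raw"].to_numpy(), bins)
        df.to_csv(outdir / "nsl.tsv", sep="\t", index=False)
        manifest["stages"]["nsl"] = {
            "n_sites": len(df),
            "n_defined": int(df["normalized"].notna().sum()),
        }
        return df

    # -- XP-nSL -----------------------------------------------------------
    @stage("xpnsl")
    def xpnsl_df():
        df = hap_mod.xpnsl_scan(matrix, focal_haps, sister_haps)
        df["normalized"] = hap_mod.normalize_scores(df["raw"].to_numpy())
        finite = df["normalized"].dropna()
        if len(finite):
            df.attrs["threshold"] = popgen.empirical_threshold(finite.to_numpy(), config.alpha)
        df.to_csv(outdir / "xpnsl.tsv", sep="\t", index=False)
        manifest["stages"]["xpnsl"] = {
            "n_sites": len(df),
            "n_defined": int(df["normalized"].notna().sum()),
        }
        return df

    # -- composite --------------------------------------------------------
    @stage("composite")
    def comp_df():
        df = comp_mod.composite_scan(
            daf=nsl_df["daf"].to_numpy(),
            pbs=pbs_df["pbs"].to_numpy(),
            norm_nsl=nsl_df["normalized"].to_numpy(),
            daf_low=config.daf_low,
            daf_high=config.daf_high,
            bin_width=config.daf_bin_width,
            p_removal=config.p_removal,
            top_fraction=config.top_fraction,
            chrom=matrix.chrom,
            pos=matrix.positions,
            site_ids=matrix.site_ids,
        )
        df.to_csv(outdir / "composite.tsv", sep="\t", index=False)
        manifest["stages"]["composite"] = {
            "n_sites": len(df),
            "n_retained": int((df["removed_reason"] == "").sum()),
            "n_significant": int(df["significant"].sum()),
        }
        return df

    # -- association ------------------------------------------------------
    if config.phenotype_table and config.assoc_site:
        @stage("association")
        def assoc_df():
            df = run_association(matrix, partition, config)
            df.to_csv(outdir / "association.tsv", sep="\t", index=False)
            manifest["stages"]["association"] = {"n_models": len(df)}
            return df

    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def run_association(
    matrix: gio.HaplotypeMatrix,
    partition: gio.PopulationPartition,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Additive and dominant association at ``config.assoc_site`` in the focal
    population, adjusting for sex and PCs (from the phenotype table if present,
    else computed from the LD-pruned genotype matrix)."""
    pheno = assoc_mod.read_phenotype_table(config.phenotype_table)
    site = np.flatnonzero(matrix.site_ids == config.assoc_site)
    if site.size != 1:
        raise ValueError(f"assoc_site {config.assoc_site!r} not found (or ambiguous)")
    s = int(site[0])

    focal_samples = partition[config.focal]
    sample_ids = matrix.sample_ids[focal_samples]
    pheno = pheno.set_index("sample_id").reindex(sample_ids)

    a0 = matrix.alleles[s, 2 * focal_samples]
    a1 = matrix.alleles[s, 2 * focal_samples + 1]
    base = {0: matrix.ref[s], 1: matrix.alt[s]}
    genotypes = [
        None if (x < 0 or y < 0) else (base[int(x)], base[int(y)])
        for x, y in zip(a0, a1)
    ]
    pc_cols = [c for c in pheno.columns if c.startswith("PC")]
    if pc_cols:
        pcs = pheno[pc_cols].to_numpy(dtype=float)[:, : config.n_pcs]
    else:
        dosage_all = _diploid_dosage(matrix, focal_samples)
        kept = assoc_mod.ld_prune(dosage_all, r2_max=config.r2_max)
        pcs = assoc_mod.compute_pcs(dosage_all[kept].T, k=config.n_pcs)
    covariates = np.column_stack([pheno["sex"].to_numpy(dtype=float), pcs])
    y = assoc_mod.log_transform(pheno["phenotype"].to_numpy(dtype=float))
    rows = []
    for model in assoc_mod.MODELS:
        dosage = assoc_mod.encode_genotype(genotypes, model)
        rows.append(
            assoc_mod.fit_linear_model(y, dosage, covariates, model=model).to_frame()
        )
    return pd.concat(rows, ignore_index=True)


def _diploid_dosage(matrix: gio.HaplotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    """Sites x samples ALT/derived dosage with NaN where either allele is missing."""
    a0 = matrix.alleles[:, 2 * sample_idx].astype(float)
    a1 = matrix.alleles[:, 2 * sample_idx + 1].astype(float)
    d = a0 + a1
    d[(a0 < 0) | (a1 < 0)] = np.nan
    return d
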