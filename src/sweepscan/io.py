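"""Phased-VCF input/output, ancestral-allele polarization, and missingness QC.

The central container is :class:`HaplotypeMatrix`: a sites x haplotypes matrix of
binary alleles (0/1, -1 for missing) with physical positions, per-site REF/ALT
bases and per-sample metadata.  Haplotypes ``2k`` and ``2k+1`` belong to diploid
sample ``k``.  Before polarization 0 means REF and 1 means ALT; after
:func:`polarize` 0 means ancestral and 1 means derived.

VCF POS is 1-based and kept 1-based throughout; site indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

ROLES = ("focal", "sister", "outgroup")


class GenotypeError(ValueError):
    """Malformed or unsupported genotype data."""


@dataclass
class HaplotypeMatrix:
    """Phased biallelic alleles, sites x haplotypes.

    ``alleles[s, h]`` is the allele of haplotype ``h`` at site ``s``:
    0, 1 or -1 (missing).  ``positions`` are 1-based physical coordinates,
    strictly increasing within each chromosome.
    """

    alleles: np.ndarray
    positions: np.ndarray
    site_ids: np.ndarray
    chrom: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    sample_ids: np.ndarray
    populations: np.ndarray | None = None
    polarized: bool = False

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
        self.validate()

    # -- shape -----------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def haplotype_sample(self, h: int) -> int:
        """Sample index owning haplotype ``h`` (haplotypes 2k, 2k+1 -> sample k)."""
        return h // 2

    def validate(self) -> None:
        n_sites, n_hap = self.alleles.shape
        if n_hap != 2 * self.n_samples:
            raise ValueError(
                f"{n_hap} haplotypes but {self.n_samples} samples (expected 2 per sample)"
            )
        for arr, name in (
            (self.positions, "positions"),
            (self.site_ids, "site_ids"),
            (self.chrom, "chrom"),
            (self.ref, "ref"),
            (self.alt, "alt"),
        ):
            if len(arr) != n_sites:
                raise ValueError(f"{name} has length {len(arr)}, expected {n_sites}")
        bad = ~np.isin(self.alleles, (-1, 0, 1))
        if bad.any():
            raise ValueError("allele values must be in {0, 1, -1}")
        for c in np.unique(self.chrom.astype(str)):
            pos = self.positions[self.chrom.astype(str) == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.populations is not None and len(self.populations) != self.n_samples:
            raise ValueError("populations must have one label per sample")

    # -- subsetting ------------------------------------------------------
    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            alleles=self.alleles[idx],
            positions=self.positions[idx],
            site_ids=self.site_ids[idx],
            chrom=self.chrom[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        hap_idx = np.ravel(np.column_stack((2 * idx, 2 * idx + 1)))
        return replace(
            self,
            alleles=self.alleles[:, hap_idx],
            sample_ids=self.sample_ids[idx],
            populations=None if self.populations is None else self.populations[idx],
        )

    def drop_samples(self, ids: Sequence[str]) -> "HaplotypeMatrix":
        """Remove samples by id (e.g. a relatedness exclusion list)."""
        ids = set(ids)
        keep = np.array([s not in ids for s in self.sample_ids])
        if not keep.any():
            raise ValueError("dropping these samples would leave an empty matrix")
        return self.take_samples(np.flatnonzero(keep))

    def sample_haplotype_indices(self, sample_idx: np.ndarray) -> np.ndarray:
        sample_idx = np.asarray(sample_idx)
        return np.ravel(np.column_stack((2 * sample_idx, 2 * sample_idx + 1)))


@dataclass
class PopulationPartition:
    """Disjoint assignment of sample indices to population labels with scan roles."""

    groups: dict[str, np.ndarray]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, idx in self.groups.items():
            idx = np.asarray(idx, dtype=np.int64)
            self.groups[label] = idx
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"sample indices {sorted(overlap)} assigned to multiple populations")
            seen.update(idx.tolist())
        for role, label in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
            if label not in self.groups:
                raise ValueError(f"role {role!r} names unknown population {label!r}")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.groups[label]

    def role(self, role: str) -> str:
        return self.roles[role]

    @property
    def labels(self) -> list[str]:
        return list(self.groups)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str, region: str | None = None) -> HaplotypeMatrix:
    """Read phased biallelic SNVs from a VCF into a :class:`HaplotypeMatrix`.

    Multi-allelic and non-SNV records are skipped with a logged count.  Any
    retained site with an unphased (``/``-separated) non-missing genotype is an
    error: downstream haplotype statistics are meaningless on unphased data.
    Fully missing genotypes (``.|.`` or ``./.``) become missing alleles.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    positions: list[int] = []
    site_ids: list[str] = []
    chroms: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    n_skipped = 0

    iterator = vcf(region) if region else vcf
    for var in iterator:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        row = np.empty(2 * len(samples), dtype=np.int8)
        for k, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 and a1 < 0:
                row[2 * k] = MISSING
                row[2 * k + 1] = MISSING
                continue
            if not phased:
                raise GenotypeError(
                    f"unphased genotype at {var.CHROM}:{var.POS} for sample {samples[k]}"
                )
            row[2 * k] = MISSING if a0 < 0 else a0
            row[2 * k + 1] = MISSING if a1 < 0 else a1
        rows.append(row)
        positions.append(var.POS)
        site_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNV records in %s", n_skipped, path)
    if not rows:
        raise ValueError(f"no biallelic SNV records found in {path}"
                         + (f" region {region}" if region else ""))
    return HaplotypeMatrix(
        alleles=np.vstack(rows),
        positions=np.array(positions),
        site_ids=np.array(site_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        sample_ids=np.array(samples, dtype=object),
    )


def write_vcf(matrix: HaplotypeMatrix, path: str) -> None:
    """Write a GT-only VCF 4.2.  Round-trips through :func:`read_phased_vcf`.

    If the matrix is polarized, the ancestral base is emitted as an ``AA``
    INFO tag (equal to REF, since polarized matrices store the ancestral base
    as REF).
    """
    pos_key = np.char.add(matrix.chrom.astype(str), matrix.positions.astype(str))
    if len(np.unique(pos_key)) != matrix.n_sites:
        raise ValueError("duplicate chrom:pos among sites (position collision)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(matrix.chrom.astype(str)):
            maxpos = matrix.positions[matrix.chrom.astype(str) == c].max()
            fh.write(f"##contig=<ID={c},length={int(maxpos) + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in matrix.sample_ids)
            + "\n"
        )
        sym = {-1: ".", 0: "0", 1: "1"}
        for s in range(matrix.n_sites):
            info = f"AA={matrix.ref[s]}" if matrix.polarized else "."
            gts = "\t".join(
                f"{sym[int(matrix.alleles[s, 2 * k])]}|{sym[int(matrix.alleles[s, 2 * k + 1])]}"
                for k in range(matrix.n_samples)
            )
            fh.write(
                f"{matrix.chrom[s]}\t{matrix.positions[s]}\t{matrix.site_ids[s]}\t"
                f"{matrix.ref[s]}\t{matrix.alt[s]}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def polarize(matrix: HaplotypeMatrix, ancestral: Mapping[str, str]) -> HaplotypeMatrix:
    """Recode alleles so 1 = derived, given a site_id -> ancestral-base table.

    Sites whose ancestral base matches ALT are bit-flipped (REF/ALT swapped so
    the stored REF is always the ancestral base); sites with an unknown or
    mismatching ancestral base are dropped with a logged count.  Polarizing an
    already-polarized matrix is an error (the operation is not idempotent on
    the flipped sites).
    """
    if matrix.polarized:
        raise ValueError("matrix is already polarized")
    keep: list[int] = []
    flip: list[bool] = []
    for s in range(matrix.n_sites):
        aa = ancestral.get(str(matrix.site_ids[s]))
        if aa == matrix.ref[s]:
            keep.append(s)
            flip.append(False)
        elif aa == matrix.alt[s]:
            keep.append(s)
            flip.append(True)
    n_dropped = matrix.n_sites - len(keep)
    if n_dropped:
        logger.info("polarize: dropped %d sites with unknown/mismatching ancestral state", n_dropped)
    if not keep:
        raise ValueError("no sites with a usable ancestral state")
    out = matrix.take_sites(np.array(keep))
    flip_arr = np.array(flip)
    alleles = out.alleles.copy()
    fl = alleles[flip_arr]
    swapped = np.where(fl == MISSING, MISSING, 1 - fl).astype(np.int8)
    alleles[flip_arr] = swapped
    ref = out.ref.copy()
    alt = out.alt.copy()
    ref[flip_arr], alt[flip_arr] = out.alt[flip_arr], out.ref[flip_arr]
    return replace(out, alleles=alleles, ref=ref, alt=alt, polarized=True)


def read_ancestral_table(path: str) -> dict[str, str]:
    """Read a two-column TSV ``site_id<TAB>ancestral_base``."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            site_id, base = line.split("\t")[:2]
            table[site_id] = base
    return table


# ---------------------------------------------------------------------------
# Missingness QC
# ---------------------------------------------------------------------------

@dataclass
class MissingnessReport:
    removed_samples: list[str]
    removed_sites: list[str]


def missingness_filter(
    matrix: HaplotypeMatrix,
    site_max: float = 0.10,
    sample_max: float = 0.10,
) -> tuple[HaplotypeMatrix, MissingnessReport]:
    """Drop samples, then sites, whose missing-allele fraction exceeds a threshold.

    Samples are removed first so that a few very incomplete individuals do not
    inflate per-site missingness and drag otherwise good sites down with them.
    Defaults match the common 10% QC cutoff.
    """
    for t, name in ((site_max, "site_max"), (sample_max, "sample_max")):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    miss = matrix.alleles == MISSING
    # per-sample fraction over both haplotypes
    per_sample = miss.reshape(matrix.n_sites, matrix.n_samples, 2).sum(axis=(0, 2)) / (
        2 * matrix.n_sites
    )
    keep_samples = np.flatnonzero(per_sample <= sample_max)
    removed_samples = [str(s) for s in matrix.sample_ids[per_sample > sample_max]]
    if keep_samples.size == 0:
        raise ValueError("missingness filter removed every sample")
    out = matrix.take_samples(keep_samples)
    per_site = (out.alleles == MISSING).mean(axis=1)
    keep_sites = np.flatnonzero(per_site <= site_max)
    removed_sites = [str(s) for s in out.site_ids[per_site > site_max]]
    out = out.take_sites(keep_sites)
    if removed_samples or removed_sites:
        logger.info(
            "missingness filter removed %d samples, %d sites",
            len(removed_samples),
            len(removed_sites),
        )
    return out, MissingnessReport(removed_samples, removed_sites)


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_population_map(
    path: str,
    sample_ids: Sequence[str],
    roles: Mapping[str, str],
) -> PopulationPartition:
    """Read ``sample_id<TAB>population`` and partition the matrix's samples.

    Every matrix sample must appear exactly once; ``roles`` names which label
    is the focal, sister and outgroup population.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, pop = line.split("\t")[:2]
            if sid in mapping:
                raise ValueError(f"duplicate sample {sid!r} in population map")
            mapping[sid] = pop
    unmapped = [str(s) for s in sample_ids if str(s) not in mapping]
    if unmapped:
        raise ValueError(f"samples missing from population map: {unmapped}")
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(sample_ids):
        groups.setdefault(mapping[str(sid)], []).append(i)
    return PopulationPartition(
        groups={k: np.array(v, dtype=np.int64) for k, v in groups.items()},
        roles=dict(roles),
    )


def read_exclusion_list(path: str) -> list[str]:
    """One sample id per line (e.g. relatedness exclusions)."""
    with open(path) as fh:
        return [ln.strip().split("\t")[0] for ln in fh if ln.strip() and not ln.startswith("#")]
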