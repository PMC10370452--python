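"""Synthetic data with the statistical structure the scans assume.

Three generators:

* :func:`balding_nichols_counts` — per-population allele frequencies drawn from
  the Balding-Nichols Beta model around a shared ancestral frequency, with
  Hardy-Weinberg diploid genotype counts.  The model's expected FST equals the
  divergence parameter F, giving a closed-form calibration target for the
  Weir-Cockerham estimator.
* :func:`wright_fisher_sim` — a discrete-generation forward Wright-Fisher
  simulation of three demes (focal A, sister B, outgroup C) on a fixed grid of
  L sites, with recombination, finite-sites mutation (re-mutation allowed) and
  optional positive selection at a focal site in deme A starting at the A/B
  split.  Output is phased, polarized haplotype matrices (ancestral = initial
  state), the substrate for nSL/XP-nSL/PBS power and calibration checks.
* :func:`simulate_phenotypes` — phenotypes with an additive genotype effect
  plus sex and optional structure covariates, emitted on the raw (exponential)
  scale so the pipeline's log transform is exercised.

Determinism: every draw funnels through the ``seed`` field; identical
:class:`SimParams` give bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .io import HaplotypeMatrix, write_vcf
from .popgen import SiteFrequencyTable

logger = logging.getLogger(__name__)

_MOD = 2**31


@dataclass
class SimParams:
    """All generator knobs in one reproducible record.

    Wright-Fisher defaults emulate three recently diverged human populations
    at forward-simulation scale: N = 500 diploids per deme, 500 sites spaced
    1 kb apart, with mutation/recombination rates and split times scaled so
    pairwise differentiation lands in the FST ~ 0.05-0.15 range typical of
    continental human population pairs.  Sample sizes default to the
    46/112/48 diploid design of a focal cohort versus two reference panels.
    """

    seed: int = 0
    # Balding-Nichols
    bn_f: tuple[float, ...] = (0.1, 0.1)
    bn_n_diploid: tuple[int, ...] = (100, 100)
    bn_n_sites: int = 5000
    bn_p0_range: tuple[float, float] = (0.05, 0.95)
    # Wright-Fisher
    wf_n: int = 500          # diploids per deme
    wf_l: int = 400          # sites, 1 kb spacing
    wf_mu: float = 5e-5      # per-site per-generation mutation probability
    wf_rho: float = 2e-4     # per-adjacent-boundary crossover rate
    wf_t_burn: int = 150     # ancestral LD build-up generations
    wf_t_split_out: int = 200  # generations ago: (AB) / C split
    wf_t_split_ab: int = 100   # generations ago: A / B split (= sweep onset)
    wf_s: float = 0.0        # selection coefficient at the focal site, deme A
    wf_h: float = 1.0        # dominance: fitnesses 1, 1+hs, 1+2s (h=1 = additive)
    wf_sample_sizes: tuple[int, int, int] = (46, 112, 48)
    wf_onset_freq_range: tuple[float, float] = (0.01, 0.05)
    wf_origin_copies: int = 10
    wf_init_uniform_frac: float = 0.5  # intermediate-frequency share of founder spectrum
    wf_condition_daf: tuple[float, float] | None = None
    wf_max_attempts: int = 100
    # phenotype
    beta_g: float = 0.20
    beta_sex: float = 0.37
    pc_effects: tuple[float, ...] = ()
    sigma: float = 0.7
    intercept: float = 2.0

    def __post_init__(self) -> None:
        for rate, name in ((self.wf_mu, "wf_mu"), (self.wf_rho, "wf_rho")):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.wf_n < 2:
            raise ValueError("wf_n must be at least 2 diploids")
        if self.wf_t_split_ab > self.wf_t_split_out:
            raise ValueError("A/B split must be more recent than the outgroup split")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Balding-Nichols
# ---------------------------------------------------------------------------

@dataclass
class BaldingNicholsCounts:
    """Per-site ancestral frequency, per-population frequencies and HWE
    diploid genotype counts (columns: hom-ancestral, het, hom-derived)."""

    p0: np.ndarray
    freqs: np.ndarray            # (n_pops, n_sites)
    genotype_counts: np.ndarray  # (n_pops, n_sites, 3)
    n_diploid: tuple[int, ...]


def balding_nichols_counts(
    params: SimParams, rng: np.random.Generator | None = None
) -> BaldingNicholsCounts:
    """Draw Balding-Nichols population frequencies and diploid genotype counts.

    ``p_k ~ Beta(p0*(1-F_k)/F_k, (1-p0)*(1-F_k)/F_k)`` around an ancestral
    frequency ``p0`` uniform on the configured range; genotypes are binomial
    under Hardy-Weinberg.  ``F = 0`` degenerates to ``p_k = p0``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    lo, hi = params.bn_p0_range
    p0 = rng.uniform(lo, hi, params.bn_n_sites)
    freqs = np.empty((len(params.bn_f), params.bn_n_sites))
    counts = np.empty((len(params.bn_f), params.bn_n_sites, 3), dtype=np.int64)
    for k, f_k in enumerate(params.bn_f):
        if not 0 <= f_k < 1:
            raise ValueError(f"divergence F must be in [0, 1), got {f_k}")
        if f_k == 0:
            p = p0.copy()
        else:
            ratio = (1 - f_k) / f_k
            p = rng.beta(p0 * ratio, (1 - p0) * ratio)
        freqs[k] = p
        hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
        counts[k] = rng.multinomial(params.bn_n_diploid[k], hwe)
    return BaldingNicholsCounts(
        p0=p0, freqs=freqs, genotype_counts=counts, n_diploid=tuple(params.bn_n_diploid)
    )


def frequency_table_from_counts(bn: BaldingNicholsCounts) -> SiteFrequencyTable:
    """Adapt Balding-Nichols genotype counts to the frequency-table interface
    consumed by :func:`sweepscan.popgen.wc_fst` (no missing data)."""
    labels = [f"pop{k}" for k in range(bn.freqs.shape[0])]
    table = SiteFrequencyTable(
        populations=labels,
        der_count={}, called={}, daf={}, maf={},
        n_dip={}, p_dip={}, het_count={},
        n_sites=bn.p0.size,
    )
    for k, label in enumerate(labels):
        gc = bn.genotype_counts[k]
        n = bn.n_diploid[k]
        der = gc[:, 1] + 2 * gc[:, 2]
        table.der_count[label] = der
        table.called[label] = np.full(bn.p0.size, 2 * n, dtype=np.int64)
        daf = der / (2 * n)
        table.daf[label] = daf
        table.maf[label] = np.minimum(daf, 1 - daf)
        table.n_dip[label] = np.full(bn.p0.size, n, dtype=np.int64)
        table.p_dip[label] = daf
        table.het_count[label] = gc[:, 1]
    return table


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed_numba(seed):  # pragma: no cover
    np.random.seed(seed)


@njit(cache=True)
def _make_gamete(pop, parent, out, rho):  # pragma: no cover
    L = pop.shape[1]
    cur = np.random.randint(0, 2)
    n_x = 0
    if rho > 0.0:
        n_x = np.random.poisson(rho * (L - 1))
    if n_x == 0:
        for l in range(L):
            out[l] = pop[2 * parent + cur, l]
        return
    xpos = np.empty(n_x, dtype=np.int64)
    for i in range(n_x):
        xpos[i] = np.random.randint(1, L)  # boundary b: switch before site b
    xpos.sort()
    ptr = 0
    for l in range(L):
        while ptr < n_x and xpos[ptr] == l:
            cur = 1 - cur
            ptr += 1
        out[l] = pop[2 * parent + cur, l]


@njit(cache=True)
def _evolve(pop, n_gen, focal, s, h, mu, rho):  # pragma: no cover
    """Evolve one deme in place for ``n_gen`` generations; returns the deme.

    Parents are drawn with replacement proportional to fitness (1, 1+hs, 1+2s
    by focal-site genotype; uniform when s = 0); each gamete is a crossover
    mosaic of the parent's two haplotypes; mutation flips alleles site-wise
    with probability ``mu`` (geometric skip sampling).
    """
    two_n, L = pop.shape
    n_dip = two_n // 2
    new = np.empty_like(pop)
    fit = np.empty(n_dip)
    cum = np.empty(n_dip)
    for _ in range(n_gen):
        use_fitness = s != 0.0
        if use_fitness:
            for d in range(n_dip):
                g = pop[2 * d, focal] + pop[2 * d + 1, focal]
                if g == 0:
                    fit[d] = 1.0
                elif g == 1:
                    fit[d] = 1.0 + h * s
                else:
                    fit[d] = 1.0 + 2.0 * s
            total = 0.0
            for d in range(n_dip):
                total += fit[d]
            acc = 0.0
            for d in range(n_dip):
                acc += fit[d] / total
                cum[d] = acc
            cum[n_dip - 1] = 1.0
        for child in range(n_dip):
            for g in range(2):
                if use_fitness:
                    parent = np.searchsorted(cum, np.random.random())
                else:
                    parent = np.random.randint(0, n_dip)
                _make_gamete(pop, parent, new[2 * child + g], rho)
        if mu > 0.0:
            total_cells = two_n * L
            idx = np.random.geometric(mu) - 1
            while idx < total_cells:
                r = idx // L
                c = idx % L
                new[r, c] = 1 - new[r, c]
                idx += np.random.geometric(mu)
        pop[:, :] = new[:, :]
    return pop


@dataclass
class WrightFisherResult:
    matrices: dict[str, HaplotypeMatrix]
    focal_site: int
    focal_daf: dict[str, float]
    attempts: int
    params: SimParams = field(repr=False)


def _deme_matrix(
    hap: np.ndarray,
    sample_idx: np.ndarray,
    label: str,
) -> HaplotypeMatrix:
    rows = np.ravel(np.column_stack((2 * sample_idx, 2 * sample_idx + 1)))
    alleles = hap[rows].T.astype(np.int8)  # sites x haplotypes
    L = alleles.shape[0]
    positions = 1000 * (np.arange(L) + 1)
    return HaplotypeMatrix(
        alleles=alleles,
        positions=positions,
        site_ids=np.array([f"1:{p}" for p in positions], dtype=object),
        chrom=np.full(L, "1", dtype=object),
        ref=np.full(L, "A", dtype=object),
        alt=np.full(L, "G", dtype=object),
        sample_ids=np.array([f"{label}{i:03d}" for i in range(sample_idx.size)], dtype=object),
        populations=np.full(sample_idx.size, label, dtype=object),
        polarized=True,
    )


def wright_fisher_sim(params: SimParams) -> WrightFisherResult:
    """Three-deme forward simulation; see the module docstring for the model.

    Timeline (generations before present): burn-in ends at ``wf_t_split_out``,
    when the outgroup C splits off; A and B separate at ``wf_t_split_ab``,
    which is also the sweep onset in deme A.

    Focal-site choice depends on the selection regime.  Under neutrality
    (``wf_s == 0``) the focal site is the segregating site nearest the center
    of the region whose deme-A frequency at onset lies in
    ``wf_onset_freq_range``.  Under selection the beneficial allele is
    injected at onset as a young mutation private to deme A: at the
    monomorphic-ancestral site nearest the center, ``wf_origin_copies``
    haplotypes — all copies of a single randomly chosen founder background —
    receive the derived allele (a hard sweep from a single origin, the regime
    that produces the private-allele, long-shared-haplotype signature these
    scans target).  Replicates without a usable focal site, where the swept
    allele is lost, or (when ``wf_condition_daf`` is set) whose final sampled
    focal DAF falls outside that window, are re-drawn with a logged attempt
    count.
    """
    p = params
    for attempt in range(1, p.wf_max_attempts + 1):
        base = (p.seed + 1_000_003 * (attempt - 1)) % _MOD
        rng = np.random.default_rng(base)
        _seed_numba(int(rng.integers(_MOD)))

        # ancestral standing variation: rare-heavy log-uniform spectrum mixed
        # with an intermediate-frequency component (segregating-site panels
        # are enriched for common variants relative to the neutral SFS)
        q_min = 1.0 / (2 * p.wf_n)
        q = q_min ** (1 - rng.random(p.wf_l))
        uni = rng.random(p.wf_l) < p.wf_init_uniform_frac
        q[uni] = rng.uniform(0.05, 0.95, int(uni.sum()))
        anc = (rng.random((2 * p.wf_n, p.wf_l)) < q).astype(np.int8)
        _evolve(anc, p.wf_t_burn, 0, 0.0, p.wf_h, p.wf_mu, p.wf_rho)

        c_pop = anc.copy()
        ab = anc
        inter = p.wf_t_split_out - p.wf_t_split_ab
        _evolve(ab, inter, 0, 0.0, p.wf_h, p.wf_mu, p.wf_rho)
        _evolve(c_pop, inter, 0, 0.0, p.wf_h, p.wf_mu, p.wf_rho)

        onset_freq = ab.mean(axis=0)
        if p.wf_s != 0.0:
            candidates = np.flatnonzero(onset_freq == 0.0)
        else:
            lo, hi = p.wf_onset_freq_range
            candidates = np.flatnonzero((onset_freq >= lo) & (onset_freq <= hi))
        if candidates.size == 0:
            continue
        focal = int(candidates[np.argmin(np.abs(candidates - p.wf_l // 2))])

        a_pop = ab.copy()
        b_pop = ab
        if p.wf_s != 0.0:
            # de novo single-origin beneficial mutation in A only
            k = min(p.wf_origin_copies, 2 * p.wf_n)
            carriers = rng.choice(2 * p.wf_n, size=k, replace=False)
            founder = a_pop[carriers[0]].copy()
            a_pop[carriers] = founder
            a_pop[carriers, focal] = 1
        _evolve(a_pop, p.wf_t_split_ab, focal, p.wf_s, p.wf_h, p.wf_mu, p.wf_rho)
        _evolve(b_pop, p.wf_t_split_ab, 0, 0.0, p.wf_h, p.wf_mu, p.wf_rho)
        _evolve(c_pop, p.wf_t_split_ab, 0, 0.0, p.wf_h, p.wf_mu, p.wf_rho)

        matrices = {}
        focal_daf = {}
        for label, deme, n_sample in zip(
            ("A", "B", "C"), (a_pop, b_pop, c_pop), p.wf_sample_sizes
        ):
            sample_idx = rng.choice(p.wf_n, size=n_sample, replace=False)
            matrices[label] = _deme_matrix(deme, np.sort(sample_idx), label)
            focal_daf[label] = float(matrices[label].alleles[focal].mean())
        if p.wf_condition_daf is not None:
            dlo, dhi = p.wf_condition_daf
            if not dlo <= focal_daf["A"] <= dhi:
                continue
        if attempt > 1:
            logger.info("wright_fisher_sim: accepted on attempt %d", attempt)
        return WrightFisherResult(
            matrices=matrices,
            focal_site=focal,
            focal_daf=focal_daf,
            attempts=attempt,
            params=p,
        )
    raise RuntimeError(
        f"focal-site conditioning failed in {p.wf_max_attempts} attempts; "
        "raise wf_s, wf_n or wf_max_attempts"
    )


def merge_matrices(matrices: dict[str, HaplotypeMatrix]) -> HaplotypeMatrix:
    """Concatenate per-population matrices (common site grid) sample-wise."""
    labels = list(matrices)
    first = matrices[labels[0]]
    for label in labels[1:]:
        m = matrices[label]
        if not np.array_equal(m.positions, first.positions):
            raise ValueError("matrices do not share a common site list")
    return HaplotypeMatrix(
        alleles=np.hstack([matrices[k].alleles for k in labels]),
        positions=first.positions,
        site_ids=first.site_ids,
        chrom=first.chrom,
        ref=first.ref,
        alt=first.alt,
        sample_ids=np.concatenate([matrices[k].sample_ids for k in labels]),
        populations=np.concatenate(
            [np.full(matrices[k].n_samples, k, dtype=object) for k in labels]
        ),
        polarized=first.polarized,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    dosage: np.ndarray,
    params: SimParams,
    rng: np.random.Generator | None = None,
    sample_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Phenotypes from a linear model on the log scale, emitted raw.

    ``log(y) = intercept + beta_g*dosage + beta_sex*sex + sum gamma_k*PC_k + e``
    with ``e ~ N(0, sigma^2)``, sex ~ Bernoulli(0.5) and standard-normal PC
    covariates (one per entry of ``pc_effects``).  The returned ``phenotype``
    column is ``exp(log y)`` so the analysis pipeline's log transform is
    exercised end to end.
    """
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dosage = np.asarray(dosage, dtype=float)
    n = dosage.size
    sex = rng.integers(0, 2, n).astype(float)
    y = params.intercept + params.beta_g * dosage + params.beta_sex * sex
    k = len(params.pc_effects)
    pcs = rng.standard_normal((n, k)) if k else np.zeros((n, 0))
    if k:
        y = y + pcs @ np.asarray(params.pc_effects)
    y = y + rng.normal(0.0, params.sigma, n)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else [f"S{i:04d}" for i in range(n)],
            "sex": sex.astype(int),
            "phenotype": np.exp(y),
        }
    )
    for j in range(k):
        df[f"PC{j + 1}"] = pcs[:, j]
    return df


def write_dataset(
    result: WrightFisherResult,
    outdir: str | Path,
    phenotypes: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write VCF + population map (+ phenotype TSV) + the SimParams record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    merged = merge_matrices(result.matrices)
    paths = {
        "vcf": outdir / "simulated.vcf",
        "popmap": outdir / "populations.tsv",
        "params": outdir / "sim_params.json",
    }
    write_vcf(merged, str(paths["vcf"]))
    with open(paths["popmap"], "w") as fh:
        for sid, pop in zip(merged.sample_ids, merged.populations):
            fh.write(f"{sid}\t{pop}\n")
    result.params.to_json(paths["params"])
    if phenotypes is not None:
        paths["phenotypes"] = outdir / "phenotypes.tsv"
        phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    return paths
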