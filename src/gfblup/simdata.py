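"""Synthetic two-cohort genotype/phenotype simulator with known QTL truth.

Emulates the study design the pipeline targets: a discovery cohort used
for a GWAS scan and a separate reference/validation cohort on which
prediction accuracy is cross-validated. Both cohorts are drawn from one
base population: each SNP gets an allele frequency sampled uniformly from
``maf_range``, shared by the two cohorts, so cross-cohort panel
intersection and allele-frequency correlation are nontrivial.

Haplotypes use a first-order Gaussian copula: per chromosome, a latent
AR(1) series with lag-one correlation ``ld_rho`` is thresholded at the
normal quantile of each allele frequency, giving local LD that decays
geometrically with marker distance. An individual's dosage is the sum of
two independent haplotypes, so genotypes are in {0, 1, 2} and sites are
in Hardy-Weinberg proportions by construction.

Traits are additive: a set of QTL SNPs gets i.i.d. normal effects; the
genetic values are rescaled so the genetic share of the (fixed-effect
free) phenotypic variance equals the requested heritability; sex and age
enter as fixed effects. The :class:`TruthRecord` keeps the QTL keys,
effects, true breeding values and the realized heritability so parameter
recovery is checkable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .genio import GenotypeData, PhenotypeTable

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults mirror the emulated study design: a ~685-individual discovery
    cohort, a ~651-individual reference/validation cohort, heritability
    0.45 (typical of moderately heritable pig growth traits), and a trait
    scale resembling loin muscle area (mean ~40 cm^2, SD ~5 cm^2).
    """

    n_discovery: int = 685
    n_target: int = 651
    n_snps: int = 5000
    n_chromosomes: int = 18
    n_qtls: int = 500
    h2_trait: float = 0.45
    maf_range: tuple[float, float] = (0.05, 0.5)
    # latent adjacent-marker correlation 0.98 gives a correlation length of
    # ~50 markers, i.e. a few hundred effective independent segments over
    # 18 chromosomes — the strong-LD regime of commercial livestock panels
    ld_rho: float = 0.98
    prop_shared_qtl: float = 1.0
    seed: int = 0
    # trait scale and fixed effects
    trait_mean: float = 40.0
    trait_sd: float = 5.0
    sex_effect: float = 1.5
    age_slope: float = 0.05
    age_range: tuple[float, float] = (160.0, 220.0)
    missing_rate: float = 0.0
    qtls_in_panel: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.h2_trait < 1:
            raise ConfigError(f"h2_trait must be in (0,1), got {self.h2_trait}")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError(f"ld_rho must be in [0,1), got {self.ld_rho}")
        if self.n_qtls > self.n_snps:
            raise ConfigError(
                f"n_qtls ({self.n_qtls}) exceeds n_snps ({self.n_snps})"
            )
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not 0 <= self.prop_shared_qtl <= 1:
            raise ConfigError(f"prop_shared_qtl must be in [0,1], got {self.prop_shared_qtl}")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        for name in ("n_discovery", "n_target", "n_snps", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated trait."""

    qtl_keys: list[str]
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    realized_h2: float

    def __post_init__(self) -> None:
        if len(self.qtl_keys) != len(self.qtl_effects):
            raise ValueError("qtl_keys and qtl_effects length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"qtl_key": self.qtl_keys, "effect": self.qtl_effects})


def loin_muscle_area(height: float, width: float) -> float:
    """Loin muscle area (cm^2) from caliper height and width (cm).

    The standard carcass-measurement approximation: area = height x width x 0.7.
    """
    if height <= 0 or width <= 0:
        raise ValueError("height and width must be positive")
    return height * width * 0.7


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _snp_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Marker map: chromosomes, strictly increasing positions, allele pairs."""
    m = config.n_snps
    chrom_of = np.sort(rng.integers(1, config.n_chromosomes + 1, size=m))
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom_of):
        idx = np.flatnonzero(chrom_of == c)
        # strictly increasing positions via cumulative gaps of >= 1 kb
        pos[idx] = np.cumsum(rng.integers(1_000, 50_000, size=idx.size))
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    return pd.DataFrame(
        {
            "chrom": chrom_of.astype(str),
            "pos": pos,
            "snp_id": [f"snp{c}_{p}" for c, p in zip(chrom_of, pos)],
            "a1": [p[0] for p in pairs],
            "a2": [p[1] for p in pairs],
        }
    )


def _haplotypes(
    n_hap: int,
    freqs: np.ndarray,
    chrom: np.ndarray,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent AR(1) Gaussian copula haplotypes: (n_hap, m) in {0, 1}."""
    m = freqs.size
    z = rng.standard_normal((n_hap, m))
    if rho > 0:
        w = np.sqrt(1.0 - rho * rho)
        # chromosome starts restart the chain
        starts = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1]])
        start_set = set(starts.tolist())
        for j in range(1, m):
            if j in start_set:
                continue
            z[:, j] = rho * z[:, j - 1] + w * z[:, j]
    thresh = stats.norm.ppf(freqs)
    return (z < thresh).astype(np.int8)


def _cohort(
    n: int,
    freqs: np.ndarray,
    snp_meta: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    iid_prefix: str,
) -> GenotypeData:
    chrom = snp_meta["chrom"].to_numpy()
    h1 = _haplotypes(n, freqs, chrom, config.ld_rho, rng)
    h2 = _haplotypes(n, freqs, chrom, config.ld_rho, rng)
    dosage = (h1 + h2).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    sex = rng.permutation(np.arange(n) % 2)  # balanced 0/1
    sample_meta = pd.DataFrame({"iid": [f"{iid_prefix}{i:05d}" for i in range(n)], "sex": sex})
    return GenotypeData(dosage, snp_meta.copy(), sample_meta)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeData, GenotypeData]:
    """Simulate the discovery and reference/validation cohorts.

    Returns ``(discovery, target)``; both cohorts share one marker map and
    one base-population allele-frequency spectrum drawn uniformly from
    ``config.maf_range``.
    """
    rng = np.random.default_rng(config.seed)
    snp_meta = _snp_map(config, rng)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    discovery = _cohort(config.n_discovery, freqs, snp_meta, config, rng, "D")
    target = _cohort(config.n_target, freqs, snp_meta, config, rng, "T")
    return discovery, target


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class QtlArchitecture:
    """A trait's causal SNPs and their additive effects (pre-rescaling)."""

    keys: list[str]
    effects: np.ndarray


def draw_architecture(
    keys: list[str], config: SimConfig, rng: np.random.Generator
) -> QtlArchitecture:
    """Place ``n_qtls`` QTLs uniformly at random among the panel SNPs."""
    if config.n_qtls == 0 and config.h2_trait > 0:
        raise ConfigError("n_qtls = 0 is inconsistent with h2_trait > 0")
    idx = rng.choice(len(keys), size=config.n_qtls, replace=False)
    effects = rng.standard_normal(config.n_qtls)
    return QtlArchitecture([keys[i] for i in idx], effects)


def shared_architecture(
    base: QtlArchitecture, keys: list[str], config: SimConfig, rng: np.random.Generator
) -> QtlArchitecture:
    """Derive a second cohort's architecture sharing ``prop_shared_qtl`` of QTLs."""
    n_shared = int(round(config.prop_shared_qtl * len(base.keys)))
    keep = rng.choice(len(base.keys), size=n_shared, replace=False)
    kept_keys = [base.keys[i] for i in keep]
    kept_eff = base.effects[keep]
    n_new = len(base.keys) - n_shared
    pool = [k for k in keys if k not in set(base.keys)]
    new_keys = [pool[i] for i in rng.choice(len(pool), size=n_new, replace=False)] if n_new else []
    new_eff = rng.standard_normal(n_new)
    return QtlArchitecture(kept_keys + list(new_keys), np.r_[kept_eff, new_eff])


def simulate_phenotypes(
    genotypes: GenotypeData,
    config: SimConfig,
    architecture: QtlArchitecture | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, TruthRecord]:
    """Simulate one quantitative trait on a genotyped cohort.

    The genetic value of individual *i* is ``sum_q a_q x_iq`` over the QTL
    set, rescaled so its sample variance equals ``h2_trait * trait_sd^2``;
    residuals are drawn with variance ``(1 - h2_trait) * trait_sd^2``, so
    the realized heritability matches ``h2_trait`` in expectation. Sex
    (balanced 0/1) and age (uniform over ``age_range``) add fixed effects.

    Pass a shared ``architecture`` to give two cohorts the same causal
    model; pass an explicit ``rng`` to continue a reproducible stream.
    """
    if genotypes.n_individuals == 0 or genotypes.n_snps == 0:
        raise ValueError("genotypes are empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 104729)
    keys = genotypes.keys()
    if architecture is None:
        architecture = draw_architecture(keys, config, rng)

    key_to_col = {k: j for j, k in enumerate(keys)}
    cols = [key_to_col[k] for k in architecture.keys if k in key_to_col]
    effects = np.array(
        [a for k, a in zip(architecture.keys, architecture.effects) if k in key_to_col]
    )
    x = np.nan_to_num(genotypes.dosage[:, cols], nan=0.0)
    g_raw = x @ effects
    var_g = g_raw.var()
    if var_g == 0:
        raise ValueError("QTL genotypes carry no variance in this cohort")
    target_var_g = config.h2_trait * config.trait_sd**2
    scale = np.sqrt(target_var_g / var_g)
    g = (g_raw - g_raw.mean()) * scale
    e = rng.normal(0.0, np.sqrt((1.0 - config.h2_trait) * config.trait_sd**2), size=len(g))

    sex = genotypes.sample_meta["sex"].to_numpy()
    age = rng.uniform(*config.age_range, size=len(g))
    y = (
        config.trait_mean
        + config.sex_effect * (sex - 0.5)
        + config.age_slope * (age - age.mean())
        + g
        + e
    )
    realized = float(g.var() / (g + e).var())
    table = PhenotypeTable(iid=genotypes.iids, value=y, sex=sex, age=age)
    truth = TruthRecord(
        qtl_keys=list(architecture.keys),
        qtl_effects=architecture.effects * scale,
        true_breeding_values=g,
        realized_h2=realized,
    )
    return table, truth


def simulate_study(
    config: SimConfig,
) -> dict:
    """Full two-cohort study: genotypes and one trait per cohort.

    Returns a dict with keys ``discovery``, ``target`` (GenotypeData),
    ``discovery_pheno``, ``target_pheno`` (PhenotypeTable),
    ``discovery_truth``, ``target_truth`` (TruthRecord). The two cohorts'
    trait architectures share ``prop_shared_qtl`` of their QTLs.
    """
    discovery, target = simulate_genotypes(config)
    rng = np.random.default_rng(config.seed + 104729)
    arch_d = draw_architecture(discovery.keys(), config, rng)
    arch_t = (
        arch_d
        if config.prop_shared_qtl == 1.0
        else shared_architecture(arch_d, target.keys(), config, rng)
    )
    pheno_d, truth_d = simulate_phenotypes(discovery, config, arch_d, rng)
    pheno_t, truth_t = simulate_phenotypes(target, config, arch_t, rng)
    return {
        "discovery": discovery,
        "target": target,
        "discovery_pheno": pheno_d,
        "target_pheno": pheno_t,
        "discovery_truth": truth_d,
        "target_truth": truth_t,
    }
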