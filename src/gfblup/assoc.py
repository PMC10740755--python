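"""Mixed-linear-model association scan (MLMA) and genomic inflation.

Per-SNP model: y = 1 mu + g + b x + e, with the polygenic effect
g ~ N(0, G s2_g) absorbing relatedness/population structure. The
polygenic and residual variances are estimated once under the null model
(no SNP term) and then held fixed while every SNP is tested, so the
phenotypic covariance V = G s2_g + I s2_e is factorized a single time and
reused across the scan. Each SNP's effect is the GLS estimate with the
intercept projected out, tested by a Wald chi-square on one degree of
freedom. The candidate SNP stays in the GRM (no leave-one-chromosome-out),
so proximal contamination is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import AlignmentError
from .genio import GenotypeData
from .kinship import Kinship
from .varcomp import MixedModelSpec, VarianceComponents, estimate_reml

_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


@dataclass
class AssocTable:
    """Per-SNP association results plus the null-model variances used."""

    table: pd.DataFrame  # key, chrom, pos, a1, a2, freq, b, se, p, tested
    sigma2_g: float
    sigma2_e: float
    n_individuals: int

    def __post_init__(self) -> None:
        tested = self.table["tested"]
        p = self.table.loc[tested, "p"]
        if len(p) and not ((p > 0) & (p <= 1)).all():
            raise ValueError("tested p-values must lie in (0, 1]")

    def to_mlma_frame(self) -> pd.DataFrame:
        """Standard association layout: Chr, SNP, bp, A1, A2, Freq, b, se, p."""
        t = self.table
        return pd.DataFrame(
            {
                "Chr": t["chrom"],
                "SNP": t["key"],
                "bp": t["pos"],
                "A1": t["a1"],
                "A2": t["a2"],
                "Freq": t["freq"],
                "b": t["b"],
                "se": t["se"],
                "p": t["p"],
            }
        )


def mlma_scan(
    g: GenotypeData,
    pheno: np.ndarray,
    k: Kinship,
    vc: VarianceComponents | None = None,
) -> AssocTable:
    """Scan every SNP for association under the fixed-variance mixed model.

    Parameters
    ----------
    g
        Genotypes of the scan cohort (missing dosages mean-imputed per SNP).
    pheno
        Corrected phenotype vector aligned to ``g``'s individuals.
    k
        Genomic relationship matrix built from the scan panel, same
        individual order as ``g``.
    vc
        Null-model variance components; estimated by REML (intercept-only
        fixed design) when not supplied.

    Zero-variance (monomorphic) SNPs are flagged untestable with missing
    effect, SE and p-value rather than dropped.
    """
    y = np.asarray(pheno, dtype=float).ravel()
    if list(k.ids) != list(g.iids):
        raise AlignmentError("kinship ids do not match genotype individuals")
    if y.size != g.n_individuals:
        raise AlignmentError("phenotype length does not match genotype rows")

    if vc is None:
        spec = MixedModelSpec(y, np.ones((y.size, 1)), [k], ids=list(g.iids))
        vc = estimate_reml(spec)
    s2g = vc.components.get("sigma2_g", vc.genetic)
    s2e = vc.components["sigma2_e"]

    n = y.size
    V = s2g * k.matrix + s2e * np.eye(n)
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    ones = np.ones(n)
    Vi1 = linalg.cho_solve(cho, ones, check_finite=False)
    denom1 = ones @ Vi1
    Viy = linalg.cho_solve(cho, y, check_finite=False)
    Py = Viy - Vi1 * (ones @ Viy) / denom1  # V^-1 residual after projecting out mu

    freqs = g.allele_freqs()
    X = g.dosage.copy()
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(2.0 * freqs, np.where(nan_mask)[1])
    variances = X.var(axis=0)
    testable = variances > 0

    b = np.full(g.n_snps, np.nan)
    se = np.full(g.n_snps, np.nan)
    pvals = np.full(g.n_snps, np.nan)
    if testable.any():
        Xt = X[:, testable]
        # V^{-1} X in one shot, then project out the intercept
        ViX = linalg.cho_solve(cho, Xt, check_finite=False)
        PX = ViX - np.outer(Vi1, (ones @ ViX) / denom1)
        xPx = np.einsum("ij,ij->j", Xt, PX)
        xPy = Xt.T @ Py
        b_t = xPy / xPx
        se_t = 1.0 / np.sqrt(xPx)
        chi2 = (b_t / se_t) ** 2
        p_t = stats.chi2.sf(chi2, df=1)
        b[testable] = b_t
        se[testable] = se_t
        pvals[testable] = np.clip(p_t, np.finfo(float).tiny, 1.0)

    sm = g.snp_meta
    table = pd.DataFrame(
        {
            "key": g.keys(),
            "chrom": sm["chrom"].to_numpy(),
            "pos": sm["pos"].to_numpy(),
            "a1": sm["a1"].to_numpy(),
            "a2": sm["a2"].to_numpy(),
            "freq": freqs,
            "b": b,
            "se": se,
            "p": pvals,
            "tested": testable,
        }
    )
    return AssocTable(table, float(s2g), float(s2e), n)


def genomic_inflation(tab: AssocTable) -> float:
    """Genomic inflation factor: median association chi-square / 0.4549."""
    p = tab.table.loc[tab.table["tested"], "p"].to_numpy()
    if p.size < 100:
        raise ValueError(f"need >= 100 tested SNPs for lambda_gc, got {p.size}")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)
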