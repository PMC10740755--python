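"""Genomic relationship matrices (GRM) and the feature/remainder combination.

The GRM is the standard per-SNP-standardized estimator:

    G_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with p_i the sample frequency of the counted allele and m the number of
polymorphic SNPs used. Missing dosages are mean-imputed (2 p_i) before
centering, matching how they are handled in association testing.

For two-kernel (feature + remainder) prediction, the kernels are collapsed
into a single relationship matrix

    G_new = lambda * G_f + (1 - lambda) * G_r,   lambda = s2_f / (s2_f + s2_r)

which together with the total genetic variance s2_f + s2_r reproduces the
two-kernel covariance exactly: lambda*(s2_f+s2_r) = s2_f.

An exact algebraic identity anchors the scaling convention: for any
disjoint split into m_f feature and m_r remainder SNPs computed with
*shared* allele frequencies, (m_f*Gf + m_r*Gr)/(m_f+m_r) equals the
full-panel G elementwise.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegenerateInputError, EmptyPanelError
from .genio import GenotypeData


@dataclass
class Kinship:
    """Symmetric individual-by-individual relationship matrix."""

    matrix: np.ndarray
    ids: list[str]
    n_snps_used: int
    role: str = "full"  # one of {full, feature, remainder, combined}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if len(self.ids) != n:
            raise ValueError("ids length does not match matrix dimension")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids in kinship")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric within 1e-10")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, ids: list[str]) -> "Kinship":
        """Principal submatrix for the given ids (in the given order)."""
        pos = {iid: i for i, iid in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in ids])
        except KeyError as err:
            raise AlignmentError(f"id {err} not present in kinship") from err
        return Kinship(self.matrix[np.ix_(idx, idx)], list(ids), self.n_snps_used, self.role)


def build_grm(
    g: GenotypeData,
    snp_subset: set[str] | None = None,
    allele_freqs: np.ndarray | None = None,
    role: str = "full",
    vanraden: bool = False,
) -> Kinship:
    """Build a GRM from dosage data.

    Parameters
    ----------
    g
        Genotypes; dosages count the second listed allele.
    snp_subset
        Optional set of canonical SNP keys; only matching columns are used.
    allele_freqs
        Optional per-SNP frequencies for the *full* panel (aligned to
        ``g``'s columns before subsetting). Defaults to the sample
        frequencies of the cohort, recomputed per subset. Supplying shared
        frequencies makes feature/remainder GRMs partition the full G
        exactly.
    vanraden
        Use the ratio form G = WW' / (2 * sum p(1-p)) with centered but
        unstandardized dosages instead of the per-SNP-standardized default.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals to build a GRM")
    dosage = g.dosage
    if allele_freqs is not None:
        allele_freqs = np.asarray(allele_freqs, dtype=float)
        if allele_freqs.size != g.n_snps:
            raise ValueError("allele_freqs length does not match SNP count")
    if snp_subset is not None:
        keyset = set(snp_subset)
        mask = np.array([k in keyset for k in g.keys()])
        if not mask.any():
            raise EmptyPanelError("snp_subset matches no SNPs in the panel")
        dosage = dosage[:, mask]
        if allele_freqs is not None:
            allele_freqs = allele_freqs[mask]

    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(dosage, axis=0) / 2.0
    else:
        p = allele_freqs
    poly = (p > 0) & (p < 1)
    m = int(poly.sum())
    if m == 0:
        raise DegenerateInputError("no polymorphic SNPs: degenerate panel")
    x = dosage[:, poly]
    p = p[poly]
    x = np.where(np.isnan(x), 2.0 * p, x)  # mean-impute missing
    centered = x - 2.0 * p
    if vanraden:
        grm = (centered @ centered.T) / (2.0 * np.sum(p * (1.0 - p)))
    else:
        w = centered / np.sqrt(2.0 * p * (1.0 - p))
        grm = (w @ w.T) / m
    grm = (grm + grm.T) / 2.0
    return Kinship(grm, list(g.iids), m, role=role)


def combine_grms(
    gf: Kinship, gr: Kinship, sigma2_f: float, sigma2_r: float
) -> tuple[Kinship, float]:
    """Collapse feature and remainder GRMs into one weighted kernel.

    Returns ``(G_new, lambda)`` with ``lambda = s2_f / (s2_f + s2_r)`` and
    ``G_new = lambda * Gf + (1 - lambda) * Gr``.
    """
    if gf.ids != gr.ids:
        raise AlignmentError("feature and remainder GRMs have different id order")
    if sigma2_f < 0 or sigma2_r < 0:
        raise ValueError("variances must be non-negative")
    total = sigma2_f + sigma2_r
    if total == 0:
        raise DegenerateInputError("both variance components are zero")
    lam = sigma2_f / total
    gnew = lam * gf.matrix + (1.0 - lam) * gr.matrix
    return (
        Kinship(gnew, list(gf.ids), gf.n_snps_used + gr.n_snps_used, role="combined"),
        float(lam),
    )


# ---------------------------------------------------------------------------
# Text I/O (GCTA-style gzip triplet + id file)
# ---------------------------------------------------------------------------

def write_grm(k: Kinship, prefix: str | Path) -> None:
    """Write ``prefix``.grm.gz (i, j, n_snps, value; lower triangle) + .grm.id."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for i in range(k.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{k.n_snps_used}\t{k.matrix[i, j]:.10g}\n")
    pd.DataFrame({"fid": k.ids, "iid": k.ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix: str | Path, role: str = "full") -> Kinship:
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None, dtype=str)[1].tolist()
    n = len(ids)
    tri = pd.read_csv(
        f"{prefix}.grm.gz", sep="\t", header=None, names=["i", "j", "m", "v"]
    )
    mat = np.zeros((n, n))
    ii = tri["i"].to_numpy() - 1
    jj = tri["j"].to_numpy() - 1
    mat[ii, jj] = tri["v"]
    mat[jj, ii] = tri["v"]
    return Kinship(mat, ids, int(tri["m"].iloc[0]), role=role)
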