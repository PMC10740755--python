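"""PLINK-format genotype I/O, phenotype tables and panel quality control.

Genotypes live in a :class:`GenotypeData`: an individuals x SNPs dosage
matrix holding counts of the *second* listed allele (the .bim A2 column),
coded 0/1/2 with NaN for missing calls, plus per-SNP and per-individual
metadata. SNP identity throughout the pipeline is the canonical key
``chrom:pos:alleleA/alleleB`` with the two alleles in alphabetical order,
so that cross-panel intersection is allele-aware but allele-order
insensitive.

QC applies the standard chip filters in a fixed order: individual call
rate, SNP call rate, minor allele frequency, Hardy-Weinberg exact test,
then sex-chromosome / monomorphic removal. Allele frequencies are
recomputed after individual removal so SNP statistics reflect the
retained cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyPanelError,
    PlinkCorruptionError,
    PlinkFormatError,
)

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

#: chromosome labels excluded by the sex-chromosome filter
SEX_CHROMOSOMES = frozenset({"X", "Y", "XY", "MT", "23", "24", "25", "26"})


def canonical_key(chrom, pos, a1: str, a2: str) -> str:
    """Canonical SNP key ``chrom:pos:minAllele/maxAllele`` (alphabetical)."""
    lo, hi = sorted((str(a1), str(a2)))
    return f"{chrom}:{pos}:{lo}/{hi}"


@dataclass
class GenotypeData:
    """Dosage matrix plus SNP and sample metadata.

    Parameters
    ----------
    dosage
        ``(n_individuals, n_snps)`` float array; entries in {0, 1, 2}
        count copies of allele2, NaN marks a missing call.
    snp_meta
        DataFrame with columns ``chrom, pos, snp_id, a1, a2``.
    sample_meta
        DataFrame with columns ``iid, sex`` (sex coded 0/1).
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x SNPs)")
        n, m = self.dosage.shape
        if len(self.sample_meta) != n:
            raise ValueError(
                f"sample_meta has {len(self.sample_meta)} rows for {n} dosage rows"
            )
        if len(self.snp_meta) != m:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for {m} dosage columns"
            )
        if self.sample_meta["iid"].duplicated().any():
            raise ValueError("duplicate individual ids")
        keys = self.keys()
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate SNP keys (chrom:pos:alleles)")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    # -- basic views -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def iids(self) -> np.ndarray:
        return self.sample_meta["iid"].to_numpy()

    def keys(self) -> list[str]:
        """Canonical SNP keys in column order."""
        sm = self.snp_meta
        return [
            canonical_key(c, p, a, b)
            for c, p, a, b in zip(sm["chrom"], sm["pos"], sm["a1"], sm["a2"])
        ]

    def allele_freqs(self) -> np.ndarray:
        """Frequency of allele2 from non-missing calls, per SNP."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def call_rate_individuals(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    # -- subsetting --------------------------------------------------

    def subset_snps(self, index: np.ndarray) -> "GenotypeData":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeData(
            self.dosage[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            self.sample_meta.copy(),
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeData":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeData(
            self.dosage[index, :],
            self.snp_meta.copy(),
            self.sample_meta.iloc[index].reset_index(drop=True),
        )

    def select_keys(self, keys) -> "GenotypeData":
        """Columns whose canonical key is in ``keys`` (order preserved)."""
        keyset = set(keys)
        mask = np.array([k in keyset for k in self.keys()])
        if not mask.any():
            raise EmptyPanelError("no SNP keys matched the panel")
        return self.subset_snps(mask)


# ---------------------------------------------------------------------------
# PLINK binary I/O (v1 .bed/.bim/.fam, SNP-major)
# ---------------------------------------------------------------------------

# 2-bit codes per PLINK v1: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# Dosage counts copies of A2, so code -> dosage is 00->0, 10->1, 11->2.
_CODE_TO_DOSAGE = np.array([0.0, np.nan, 1.0, 2.0])
_DOSAGE_TO_CODE = {0.0: 0b00, 1.0: 0b10, 2.0: 0b11}


def write_plink(g: GenotypeData, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam (PLINK v1 binary, SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.dosage.shape
    n_bytes = (n + 3) // 4

    codes = np.full(g.dosage.shape, 0b01, dtype=np.uint8)  # missing
    for dose, code in _DOSAGE_TO_CODE.items():
        codes[g.dosage == dose] = code
    # pack 4 individuals per byte, low bits first, per SNP column
    padded = np.zeros((n_bytes * 4, m), dtype=np.uint8)
    padded[:n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (
        (padded.reshape(n_bytes, 4, m) << shifts[None, :, None]).sum(axis=1)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.T.tobytes())  # SNP-major: all bytes of SNP 0, then SNP 1, ...

    sm = g.snp_meta
    bim = pd.DataFrame(
        {
            "chrom": sm["chrom"],
            "snp_id": sm["snp_id"],
            "cm": 0,
            "pos": sm["pos"],
            "a1": sm["a1"],
            "a2": sm["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": g.sample_meta["iid"],
            "iid": g.sample_meta["iid"],
            "pat": 0,
            "mat": 0,
            "sex": g.sample_meta["sex"].astype(int) + 1,  # PLINK: 1 male, 2 female
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeData:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeData`.

    Raises
    ------
    PlinkFormatError
        Bad magic bytes or a mode byte other than SNP-major.
    PlinkCorruptionError
        .bed payload size inconsistent with the .bim/.fam line counts.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed: not SNP-major (mode byte {raw[2]:#x})")
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != n_bytes * m:
        raise PlinkCorruptionError(
            f"{prefix}.bed: payload {payload.size} bytes, expected {n_bytes * m} "
            f"for {n} individuals x {m} SNPs"
        )
    blocks = payload.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for j, shift in enumerate((0, 2, 4, 6)):
        codes[:, j::4] = (blocks >> shift) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T  # individuals x SNPs

    snp_meta = bim[["chrom", "pos", "snp_id", "a1", "a2"]].copy()
    sample_meta = pd.DataFrame(
        {"iid": fam["iid"].astype(str), "sex": (fam["sex"] - 1).clip(0, 1)}
    )
    return GenotypeData(dosage, snp_meta, sample_meta)


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-individual trait record: raw value, covariates, corrected slot."""

    iid: np.ndarray
    value: np.ndarray
    sex: np.ndarray
    age: np.ndarray
    corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.iid = np.asarray(self.iid)
        self.value = np.asarray(self.value, dtype=float)
        self.sex = np.asarray(self.sex)
        self.age = np.asarray(self.age, dtype=float)
        lens = {len(self.iid), len(self.value), len(self.sex), len(self.age)}
        if len(lens) != 1:
            raise ValueError("phenotype columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.iid)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"iid": self.iid, "trait": self.value, "sex": self.sex, "age": self.age}
        )
        if self.corrected is not None:
            df["corrected"] = self.corrected
        return df


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"iid": str})
    return PhenotypeTable(
        iid=df["iid"].to_numpy(),
        value=df["trait"].to_numpy(float),
        sex=df["sex"].to_numpy(),
        age=df["age"].to_numpy(float),
        corrected=df["corrected"].to_numpy(float) if "corrected" in df else None,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed count (two-sided exact test on genotype counts).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("total genotype count must be positive")
    rare = 2 * min(n_hom1, n_hom2) + n_het  # minor allele copies
    if rare == 0:
        return 1.0  # monomorphic: single possible configuration

    # Unnormalized probabilities over het counts of the same parity as
    # `rare`, built by recurrence from the conditional mode (Wigginton).
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = np.zeros(rare + 1)
    probs[mid] = 1.0
    het = mid
    hom_r = (rare - mid) // 2
    hom_c = n - het - hom_r
    while het >= 2:
        # P(het-2) / P(het) = het(het-1) / (4 (hom_r+1)(hom_c+1))
        probs[het - 2] = probs[het] * het * (het - 1) / (
            4.0 * (hom_r + 1) * (hom_c + 1)
        )
        het -= 2
        hom_r += 1
        hom_c += 1
    het, hom_r, hom_c = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het <= rare - 2:
        # P(het+2) / P(het) = 4 hom_r hom_c / ((het+1)(het+2))
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / (
            (het + 1.0) * (het + 2.0)
        )
        het += 2
        hom_r -= 1
        hom_c -= 1
    probs /= probs.sum()
    p_obs = probs[n_het]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Per-stage removal tallies; counts over SNPs reconcile exactly."""

    n_individuals_input: int
    n_snps_input: int
    n_individuals_removed: int = 0
    n_snps_removed_callrate: int = 0
    n_snps_removed_maf: int = 0
    n_snps_removed_hwe: int = 0
    n_snps_removed_sexchrom_or_uninformative: int = 0
    n_snps_retained: int = 0

    def check(self) -> None:
        removed = (
            self.n_snps_removed_callrate
            + self.n_snps_removed_maf
            + self.n_snps_removed_hwe
            + self.n_snps_removed_sexchrom_or_uninformative
        )
        assert removed + self.n_snps_retained == self.n_snps_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(vars(self)), "count": list(vars(self).values())}
        )


def apply_qc(
    g: GenotypeData,
    ind_call_min: float = 0.90,
    snp_call_min: float = 0.90,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    drop_sex_chromosomes: bool = True,
) -> tuple[GenotypeData, QcReport]:
    """Apply chip QC filters in fixed order; return filtered data + report.

    Order: individuals by call rate, then SNPs by call rate, MAF,
    Hardy-Weinberg exact test, and finally sex-chromosome/monomorphic
    removal. Frequencies are recomputed after individual removal. MAF uses
    non-missing calls only; "uninformative" means MAF exactly 0.
    """
    if g.n_snps == 0 or g.n_individuals == 0:
        raise EmptyPanelError("empty genotype data")
    report = QcReport(n_individuals_input=g.n_individuals, n_snps_input=g.n_snps)

    keep_ind = g.call_rate_individuals() > ind_call_min
    report.n_individuals_removed = int((~keep_ind).sum())
    if not keep_ind.all():
        g = g.subset_individuals(keep_ind)

    keep = g.call_rate_snps() > snp_call_min
    report.n_snps_removed_callrate = int((~keep).sum())
    g = _drop(g, keep)

    freqs = g.allele_freqs()
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = maf > maf_min
    report.n_snps_removed_maf = int((~keep).sum())
    g = _drop(g, keep)

    hwe_p = np.array(
        [
            hwe_exact_test(
                int(np.nansum(col == 0)),
                int(np.nansum(col == 1)),
                int(np.nansum(col == 2)),
            )
            for col in g.dosage.T
        ]
    )
    keep = hwe_p > hwe_p_min
    report.n_snps_removed_hwe = int((~keep).sum())
    g = _drop(g, keep)

    freqs = g.allele_freqs()
    mono = np.minimum(freqs, 1.0 - freqs) == 0.0
    sexchrom = np.zeros(g.n_snps, dtype=bool)
    if drop_sex_chromosomes:
        sexchrom = g.snp_meta["chrom"].astype(str).isin(SEX_CHROMOSOMES).to_numpy()
    keep = ~(mono | sexchrom)
    report.n_snps_removed_sexchrom_or_uninformative = int((~keep).sum())
    g = _drop(g, keep)

    report.n_snps_retained = g.n_snps
    report.check()
    return g, report


def _drop(g: GenotypeData, keep: np.ndarray) -> GenotypeData:
    if not keep.any():
        raise EmptyPanelError("all SNPs removed during QC: empty panel")
    if keep.all():
        return g
    return g.subset_snps(keep)
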