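"""SNP preselection from discovery GWAS results.

SNPs from the discovery scan are binned by p-value at a declared, ordered
list of cutoffs (strict ``p < cutoff``, so the per-cutoff sets are
nested), then each set is intersected with the target cohort's panel to
define the genomic features that feed the feature kernel. Matching is by
canonical key — chromosome, position and the *unordered* allele pair —
so a site with different alleles in the two panels never matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import AssocTable
from .genio import GenotypeData

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.05, 0.005, 0.0005, 0.00005)


@dataclass
class FeatureSet:
    """SNPs selected at one p-value cutoff and their target-panel overlap."""

    threshold: float
    discovery_keys: set[str]
    feature_keys: set[str]

    def __post_init__(self) -> None:
        if not self.feature_keys <= self.discovery_keys:
            raise ValueError("feature_keys must be a subset of discovery_keys")

    @property
    def n_discovery(self) -> int:
        return len(self.discovery_keys)

    @property
    def n_feature(self) -> int:
        return len(self.feature_keys)


def preselect(
    tab: AssocTable, thresholds: list[float] = list(DEFAULT_THRESHOLDS)
) -> dict[float, set[str]]:
    """Per-cutoff sets of discovery SNP keys with ``p < cutoff`` (strict)."""
    t = tab.table
    if len(t) == 0:
        raise ValueError("association table is empty")
    tested = t[t["tested"]]
    out: dict[float, set[str]] = {}
    for cut in thresholds:
        keys = set(tested.loc[tested["p"] < cut, "key"])
        if not keys:
            warnings.warn(f"no SNPs pass p < {cut}", stacklevel=2)
        out[cut] = keys
    return out


def intersect_with_panel(keys: set[str], target: GenotypeData) -> FeatureSet:
    """Intersect discovery keys with the target panel (allele-aware)."""
    panel = set(target.keys())
    feature = set(keys) & panel
    if keys and not feature:
        warnings.warn("no discovery SNPs present in the target panel", stacklevel=2)
    return FeatureSet(threshold=float("nan"), discovery_keys=set(keys), feature_keys=feature)


def build_feature_sets(
    tab: AssocTable,
    target: GenotypeData,
    thresholds: list[float] = list(DEFAULT_THRESHOLDS),
) -> dict[float, FeatureSet]:
    """Preselect at every cutoff and intersect each set with the target panel."""
    sets = preselect(tab, thresholds)
    out = {}
    for cut, keys in sets.items():
        fs = intersect_with_panel(keys, target)
        out[cut] = FeatureSet(cut, fs.discovery_keys, fs.feature_keys)
    return out


def feature_count_report(feature_sets: dict[float, FeatureSet]) -> pd.DataFrame:
    """Per-threshold discovery / feature SNP counts (two-column report)."""
    rows = [
        {
            "p_value": cut,
            "n_snps_gwas": fs.n_discovery,
            "n_snps_gf": fs.n_feature,
        }
        for cut, fs in sorted(feature_sets.items(), reverse=True)
    ]
    return pd.DataFrame(rows)


def write_features(fs: FeatureSet, path) -> None:
    """One canonical SNP key per line (consumable by the GRM builder)."""
    with open(path, "w") as fh:
        for key in sorted(fs.feature_keys):
            fh.write(key + "\n")


def read_features(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
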