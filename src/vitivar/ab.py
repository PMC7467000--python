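"""Allele-balance genotype filtering and correction.

Allele balance (AB) is defined here as the percentage of reads at a
genotype supporting the *less-supported* allele:

    AB = 100 * min(ad_ref, ad_alt) / (ad_ref + ad_alt)

A clean homozygote has AB near 0; a clean heterozygote near 50. Two
error signatures fall out of this single quantity at one threshold
(default 30):

* a called heterozygote with AB below the threshold is implausible
  (too few reads on one allele) and is filtered to missing;
* a called homozygote with AB above the threshold still carries
  substantial minor-allele reads — in samples genomically divergent
  from the reference (interspecific hybrids, wild relatives) this is
  the footprint of allele dropout, and the genotype is converted to a
  heterozygote.

Conversion is restricted to the eligible taxon groups (default hybrid
and wild); reference-like samples are never modified, where the same
signature is treated as basal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .callset import HET, HOM_ALT, HOM_REF, MISSING, CohortCallset
from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class ABConfig:
    """Thresholds for allele-balance filtering and conversion.

    ``min_dp_for_ab`` guards both rules at low depth, where AB is too
    noisy to act on; it matches the genotype-level depth filter.
    """

    ab_het_min_percent: float = 30.0
    ab_hom_max_percent: float = 30.0
    eligible_groups: frozenset[str] = frozenset({"hybrid", "wild"})
    min_dp_for_ab: int = 15

    def __post_init__(self) -> None:
        for v in (self.ab_het_min_percent, self.ab_hom_max_percent):
            if not (0.0 <= v <= 100.0):
                raise ConfigurationError("AB thresholds are percentages in [0, 100]")
        if not self.eligible_groups <= {"vinifera", "hybrid", "wild"}:
            raise ConfigurationError(f"unknown taxon groups: {self.eligible_groups}")


def compute_ab(ad_ref: int, ad_alt: int) -> float:
    """Allele balance of one genotype, in percent.

    Returns NaN (undefined) when no reads are present.
    """
    if ad_ref < 0 or ad_alt < 0:
        raise DataError("negative allele depths")
    total = ad_ref + ad_alt
    if total == 0:
        return float("nan")
    return 100.0 * min(ad_ref, ad_alt) / total


def ab_matrix(callset: CohortCallset) -> np.ndarray:
    """Vectorised allele balance for every genotype (NaN where the
    allele depths sum to zero)."""
    total = callset.ad_ref.astype(float) + callset.ad_alt.astype(float)
    minor = np.minimum(callset.ad_ref, callset.ad_alt).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, 100.0 * minor / total, np.nan)


def filter_low_ab_hets(
    callset: CohortCallset, config: ABConfig | None = None
) -> tuple[CohortCallset, pd.Series]:
    """Set implausible heterozygotes (AB below threshold at adequate
    depth) to missing. Returns the new call set and per-sample counts
    of filtered genotypes."""
    cfg = config if config is not None else ABConfig()
    ab = ab_matrix(callset)
    depth_ok = (callset.ad_ref + callset.ad_alt) >= cfg.min_dp_for_ab
    with np.errstate(invalid="ignore"):
        bad = (callset.gt == HET) & depth_ok & (ab < cfg.ab_het_min_percent)
    out = callset.copy()
    out.gt[bad] = MISSING
    counts = pd.Series(bad.sum(axis=0), index=callset.samples, name="n_het_filtered")
    return out, counts


def convert_hom_to_het(
    callset: CohortCallset,
    sample_groups: Mapping[str, str],
    config: ABConfig | None = None,
) -> tuple[CohortCallset, pd.Series]:
    """Convert dropout-signature homozygotes to heterozygotes.

    A called homozygote becomes a het iff its sample belongs to an
    eligible taxon group AND its AB strictly exceeds the threshold AND
    its allele depths reach ``min_dp_for_ab``. AD/DP are left untouched.
    Returns the new call set and per-sample conversion counts.
    """
    cfg = config if config is not None else ABConfig()
    eligible = np.empty(callset.n_samples, dtype=bool)
    for j, s in enumerate(callset.samples):
        if s not in sample_groups:
            raise ConfigurationError(f"sample {s} missing from group map")
        eligible[j] = sample_groups[s] in cfg.eligible_groups
    ab = ab_matrix(callset)
    depth_ok = (callset.ad_ref + callset.ad_alt) >= cfg.min_dp_for_ab
    is_hom = (callset.gt == HOM_REF) | (callset.gt == HOM_ALT)
    with np.errstate(invalid="ignore"):
        convert = is_hom & depth_ok & (ab > cfg.ab_hom_max_percent) & eligible[None, :]
    out = callset.copy()
    out.gt[convert] = HET
    counts = pd.Series(convert.sum(axis=0), index=callset.samples, name="n_hom_converted")
    return out, counts


def ab_correct(
    callset: CohortCallset,
    sample_groups: Mapping[str, str],
    config: ABConfig | None = None,
) -> tuple[CohortCallset, pd.DataFrame]:
    """Full allele-balance pass: het filtering then hom-to-het
    conversion. Returns the corrected call set and a per-sample table
    of both counts."""
    cfg = config if config is not None else ABConfig()
    filtered, n_filtered = filter_low_ab_hets(callset, cfg)
    converted, n_converted = convert_hom_to_het(filtered, sample_groups, cfg)
    counts = pd.DataFrame({"n_het_filtered": n_filtered, "n_hom_converted": n_converted})
    counts.index.name = "sample"
    return converted, counts
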