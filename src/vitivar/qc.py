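"""Hard filtering, biallelic selection, depth masking and
population-level site filters.

The filter chain mirrors GATK-style hard filtering of raw calls from a
highly diverse cohort:

1. per-site hard thresholds on the standard annotations, separately
   parameterised for SNPs and indels, plus a genotype-level minimum
   depth that masks (rather than removes) individual calls;
2. biallelic selection;
3. a per-sample high-depth mask — a genotype whose depth exceeds a
   multiple (default 4x) of its sample's mean mapped depth is treated
   as a repeat-region artifact and set to missing;
4. cohort-level missing-rate / minor-allele-frequency / non-reference
   allele-count filters.

All inequalities are strict, so boundary values pass. An unset (absent)
annotation never triggers its filter; such sites are tallied in the
result's ``n_unset_annotations``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .callset import MISSING, CohortCallset
from .errors import ClassificationError, ConfigurationError

SNP = "snp"
INDEL = "indel"


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds; defaults are the standard values for a
    33-sample high-depth cohort.

    ``site_dp_min`` is a cohort-total depth minimum; for cohorts of a
    different size use :meth:`scaled_for`, which rescales it
    proportionally to the sample count.
    """

    snp_mq_rank_sum_min: float = -12.5
    snp_qual_min: float = 30.0
    snp_qd_min: float = 3.0
    snp_fs_max: float = 30.0
    snp_mq_min: float = 30.0
    site_dp_min: float = 200.0
    gt_dp_min: int = 15
    indel_read_pos_rank_sum_min: float = -20.0
    indel_qual_min: float = 30.0
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    per_sample_depth_multiplier: float = 4.0
    missing_rate_max_stage1: float = 0.30
    missing_rate_max_stage2: float = 0.10
    maf_min: float = 0.05
    nonref_ac_min: int = 1
    site_dp_ref_n_samples: int = 33

    def scaled_for(self, n_samples: int) -> "FilterThresholds":
        """Rescale the cohort-total depth minimum to ``n_samples``."""
        return replace(
            self, site_dp_min=self.site_dp_min * n_samples / self.site_dp_ref_n_samples
        )


@dataclass
class HardFilterResult:
    """Outcome of :func:`hard_filter`.

    ``passed`` flags surviving sites; ``reasons`` lists, per site, every
    violated rule (empty tuple for passing sites);
    ``n_low_dp_genotypes`` counts genotype calls masked by the
    genotype-level depth filter."""

    callset: CohortCallset
    passed: np.ndarray
    reasons: list[tuple[str, ...]]
    n_low_dp_genotypes: int
    n_unset_annotations: int

    def filtered(self) -> CohortCallset:
        """Surviving sites only (genotype-level mask already applied)."""
        return self.callset.take_sites(self.passed)

    def report(self) -> pd.DataFrame:
        """One row per removed site with its failure reasons."""
        failed = np.flatnonzero(~self.passed)
        return pd.DataFrame(
            {
                "chrom": self.callset.chrom[failed],
                "pos": self.callset.pos[failed],
                "reasons": [",".join(self.reasons[i]) for i in failed],
            }
        )


def hard_filter(
    callset: CohortCallset,
    thresholds: FilterThresholds | None = None,
    variant_class: str = SNP,
) -> HardFilterResult:
    """Apply the per-site hard filters and the genotype-level depth mask.

    Every site must belong to ``variant_class`` (``snp`` or ``indel``);
    a mismatch raises :class:`ClassificationError`. A SNP fails iff any
    of MQRankSum, QUAL, QD, FS, MQ, or total DP violates its threshold;
    an indel iff any of ReadPosRankSum, QUAL, QD, FS, or total DP does.
    Genotypes with depth below ``gt_dp_min`` are set to missing without
    affecting site pass/fail.
    """
    th = thresholds if thresholds is not None else FilterThresholds()
    if variant_class not in (SNP, INDEL):
        raise ConfigurationError(f"unknown variant class {variant_class!r}")
    is_snp = callset.is_snp()
    if variant_class == SNP and not is_snp.all():
        bad = np.flatnonzero(~is_snp)[0]
        raise ClassificationError(
            f"site {callset.chrom[bad]}:{callset.pos[bad]} is not a SNP"
        )
    if variant_class == INDEL and is_snp.any():
        bad = np.flatnonzero(is_snp)[0]
        raise ClassificationError(
            f"site {callset.chrom[bad]}:{callset.pos[bad]} is not an indel"
        )

    info = callset.info
    qual = callset.qual
    n = callset.n_sites

    def violates(values: np.ndarray, bound: float, kind: str) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            out = values < bound if kind == "lt" else values > bound
        out[~np.isfinite(values)] = False  # unset annotations never trigger
        return out

    if variant_class == SNP:
        rules = [
            ("MQRankSum", violates(info["MQRankSum"], th.snp_mq_rank_sum_min, "lt")),
            ("QUAL", violates(qual, th.snp_qual_min, "lt")),
            ("QD", violates(info["QD"], th.snp_qd_min, "lt")),
            ("FS", violates(info["FS"], th.snp_fs_max, "gt")),
            ("MQ", violates(info["MQ"], th.snp_mq_min, "lt")),
            ("DP", violates(info["DP"], th.site_dp_min, "lt")),
        ]
        unset_keys = ["MQRankSum", "QD", "FS", "MQ", "DP"]
    else:
        rules = [
            ("ReadPosRankSum", violates(info["ReadPosRankSum"], th.indel_read_pos_rank_sum_min, "lt")),
            ("QUAL", violates(qual, th.indel_qual_min, "lt")),
            ("QD", violates(info["QD"], th.indel_qd_min, "lt")),
            ("FS", violates(info["FS"], th.indel_fs_max, "gt")),
            ("DP", violates(info["DP"], th.site_dp_min, "lt")),
        ]
        unset_keys = ["ReadPosRankSum", "QD", "FS", "DP"]

    reasons: list[tuple[str, ...]] = []
    fail_any = np.zeros(n, dtype=bool)
    for name, mask in rules:
        fail_any |= mask
    for i in range(n):
        reasons.append(tuple(name for name, mask in rules if mask[i]))

    n_unset = int(sum(int(np.isnan(info[k]).sum()) for k in unset_keys))

    out = callset.copy()
    low_dp = (out.dp < th.gt_dp_min) & (out.gt != MISSING)
    out.gt[low_dp] = MISSING
    return HardFilterResult(
        callset=out,
        passed=~fail_any,
        reasons=reasons,
        n_low_dp_genotypes=int(low_dp.sum()),
        n_unset_annotations=n_unset,
    )


def select_biallelic(callset: CohortCallset) -> CohortCallset:
    """Retain sites with exactly one REF and one ALT allele."""
    return callset.take_sites(callset.is_biallelic())


def depth_mask(
    callset: CohortCallset,
    sample_mean_depths: Mapping[str, float],
    multiplier: float = 4.0,
) -> CohortCallset:
    """Mask genotypes whose depth exceeds ``multiplier`` x the sample's
    mean mapped depth (strict inequality).

    The affected genotype is set to missing; no site is removed here —
    the downstream missing-rate filter drops sites masked in many
    samples. Raises :class:`ConfigurationError` for any sample with
    called genotypes but no supplied mean depth.
    """
    means = np.empty(callset.n_samples)
    for j, s in enumerate(callset.samples):
        if s not in sample_mean_depths:
            if (callset.gt[:, j] != MISSING).any():
                raise ConfigurationError(f"no mean depth supplied for sample {s}")
            means[j] = np.inf
        else:
            means[j] = float(sample_mean_depths[s])
            if means[j] <= 0:
                raise ConfigurationError(f"non-positive mean depth for sample {s}")
    out = callset.copy()
    high = (out.dp > multiplier * means[None, :]) & (out.gt != MISSING)
    out.gt[high] = MISSING
    return out


def population_filter(
    callset: CohortCallset,
    missing_rate_max: float,
    maf_min: float = 0.0,
    nonref_ac_min: int = 0,
) -> CohortCallset:
    """Cohort-level site filter.

    A site is removed iff its missing fraction exceeds
    ``missing_rate_max``, or its minor-allele frequency among called
    alleles is below ``maf_min``, or its non-reference allele count is
    below ``nonref_ac_min``. All comparisons strict.
    """
    if not (0.0 <= missing_rate_max <= 1.0):
        raise ConfigurationError("missing_rate_max must lie in [0, 1]")
    missing = callset.missing_rate()
    maf = callset.minor_allele_freq()
    ac = callset.nonref_allele_count()
    with np.errstate(invalid="ignore"):
        keep = (missing <= missing_rate_max) & (ac >= nonref_ac_min)
        if maf_min > 0:
            keep &= ~(np.nan_to_num(maf, nan=-1.0) < maf_min)
    return callset.take_sites(keep)
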