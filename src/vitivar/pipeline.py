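"""End-to-end convenience drivers.

``run_qc_pipeline`` chains the call-set post-processing stages in their
default order:

    hard filters -> biallelic selection -> per-sample depth mask ->
    stage-1 missing-rate filter (30%) -> allele-balance correction ->
    stage-2 missing-rate (10%) + MAF (5%) + non-ref-count filter

``analyze_seedlessness`` then runs the trait machinery on the cleaned
call set: per-SNP association, a windowed F_ST scan between the seeded
and seedless populations, sweep-peak selection, Group classification of
deleterious SNPs and the candidate report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .ab import ABConfig, ab_correct
from .assoc import FISHER, associate
from .callset import CohortCallset, depth_map, group_map, phenotype_map
from .popgen import windowed_fst
from .qc import (
    FilterThresholds,
    depth_mask,
    hard_filter,
    population_filter,
    select_biallelic,
)
from .seedless import candidate_report, classify_sites, peak_windows


@dataclass
class QCResult:
    callset: CohortCallset
    n_input: int
    n_hard_fail: int
    n_multiallelic: int
    n_stage1_removed: int
    n_stage2_removed: int
    ab_counts: pd.DataFrame


def run_qc_pipeline(
    callset: CohortCallset,
    metadata: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    ab_config: ABConfig | None = None,
    scale_site_dp: bool = True,
) -> QCResult:
    """Default post-processing chain for a SNP call set.

    ``scale_site_dp`` rescales the cohort-total depth minimum to the
    actual sample count (it is calibrated for a 33-sample panel).
    """
    th = thresholds if thresholds is not None else FilterThresholds()
    if scale_site_dp:
        th = th.scaled_for(callset.n_samples)
    n_input = callset.n_sites

    hf = hard_filter(callset, th, variant_class="snp")
    cs = hf.filtered()
    n_hard_fail = n_input - cs.n_sites

    n_before = cs.n_sites
    cs = select_biallelic(cs)
    n_multiallelic = n_before - cs.n_sites

    cs = depth_mask(cs, depth_map(metadata), multiplier=th.per_sample_depth_multiplier)

    n_before = cs.n_sites
    cs = population_filter(cs, missing_rate_max=th.missing_rate_max_stage1)
    n_stage1 = n_before - cs.n_sites

    cs, ab_counts = ab_correct(cs, group_map(metadata), ab_config)

    n_before = cs.n_sites
    cs = population_filter(
        cs,
        missing_rate_max=th.missing_rate_max_stage2,
        maf_min=th.maf_min,
        nonref_ac_min=th.nonref_ac_min,
    )
    n_stage2 = n_before - cs.n_sites

    return QCResult(
        callset=cs,
        n_input=n_input,
        n_hard_fail=n_hard_fail,
        n_multiallelic=n_multiallelic,
        n_stage1_removed=n_stage1,
        n_stage2_removed=n_stage2,
        ab_counts=ab_counts,
    )


@dataclass
class SeedlessAnalysis:
    assoc: pd.DataFrame
    scan: pd.DataFrame
    peaks: list
    assignments: pd.DataFrame
    report: pd.DataFrame


def analyze_seedlessness(
    callset: CohortCallset,
    metadata: pd.DataFrame,
    chrom_lengths: Mapping[str, int] | None = None,
    method: str = FISHER,
    window: int = 100_000,
    step: int = 10_000,
    top_fraction: float = 0.005,
    flank: int = 50_000,
    logp_min: float = 2.5,
    genes: pd.DataFrame | None = None,
) -> SeedlessAnalysis:
    """Association + differentiation scan + Group classification on the
    phenotyped (seeded/seedless) subset of a cleaned call set."""
    phen = phenotype_map(metadata)
    keep = [s for s in callset.samples if phen.get(s) in ("seeded", "seedless")]
    cs = callset.take_samples(keep)
    phen = {s: phen[s] for s in keep}

    assoc = associate(cs, phen, method=method)
    seeded = [s for s in keep if phen[s] == "seeded"]
    seedless = [s for s in keep if phen[s] == "seedless"]
    scan = windowed_fst(cs, seeded, seedless, window=window, step=step, chrom_lengths=chrom_lengths)
    peaks = peak_windows(scan, top_fraction=top_fraction, flank=flank)
    assignments = classify_sites(cs, phen, assoc, logp_min=logp_min)
    report = candidate_report(cs, peaks, assignments, genes=genes)
    return SeedlessAnalysis(
        assoc=assoc, scan=scan, peaks=peaks, assignments=assignments, report=report
    )
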