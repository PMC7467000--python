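"""Inheritance-model engine for stenospermocarpic seedlessness.

The genetic model is the classical one for Sultanina-type seedlessness:
three independently inherited complementary recessive loci sit under
the control of a completely dominant regulator (the *SDI* locus). A
plant is seedless iff it carries at least one dominant (non-reference)
allele at the regulator AND is homozygous non-reference at a minimum
number (default two) of the recessive loci.

This module turns that rule into testable machinery:

* :func:`phenotype_from_genotype` — the penetrance rule itself;
* :func:`dominant_consistency` — does an observed genotype vector match
  the expected pattern of a dominant causal site (carrier in every
  seedless sample, reference homozygous in every seeded sample)?
* :func:`assign_group` / :func:`classify_sites` — the Group I/II/III
  triage of deleterious SNPs by association strength and by how many
  seedless samples are recessive homozygotes;
* :func:`peak_windows` — top-fraction selection and merging of sweep
  windows from a differentiation scan;
* :func:`candidate_report` — deleterious SNPs inside sweep peaks, with
  their group labels and overlapping gene models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .callset import HET, HOM_ALT, HOM_REF, MISSING, CohortCallset
from .errors import ClassificationError, ConfigurationError, PhenotypeError

SEEDED = "seeded"
SEEDLESS = "seedless"

GROUP_DOMINANT = "dominant_consistent"
GROUP_I = "I"
GROUP_II = "II"
GROUP_III = "III"


@dataclass(frozen=True)
class TraitModel:
    """One dominant regulator plus complementary recessive loci.

    Locus identifiers are ``chrom:pos`` strings (or None before a
    simulation has placed them).
    """

    dominant_locus: str | None = None
    recessive_loci: tuple[str, ...] = (None, None, None)  # type: ignore[assignment]
    min_recessive_hom: int = 2

    def __post_init__(self) -> None:
        loci = [l for l in (self.dominant_locus, *self.recessive_loci) if l is not None]
        if len(set(loci)) != len(loci):
            raise ConfigurationError("trait-model loci must be distinct")
        if not (1 <= self.min_recessive_hom <= len(self.recessive_loci)):
            raise ConfigurationError(
                "min_recessive_hom must be between 1 and the number of recessive loci"
            )

    @property
    def loci(self) -> tuple[str, ...]:
        return (self.dominant_locus, *self.recessive_loci)


def phenotype_from_genotype(model: TraitModel, genotypes: Mapping[str, int] | Sequence[int]) -> str:
    """Apply the penetrance rule to genotypes at the model loci.

    ``genotypes`` maps locus id -> genotype code, or is a sequence
    ordered (dominant, recessive...). A missing genotype at any model
    locus makes the phenotype undetermined.
    """
    if isinstance(genotypes, Mapping):
        try:
            codes = [int(genotypes[l]) for l in model.loci]
        except KeyError as exc:
            raise PhenotypeError(f"no genotype supplied for model locus {exc}") from exc
    else:
        codes = [int(g) for g in genotypes]
        if len(codes) != len(model.loci):
            raise PhenotypeError(
                f"expected {len(model.loci)} genotypes, got {len(codes)}"
            )
    if any(c == MISSING for c in codes):
        raise PhenotypeError("phenotype undetermined: missing genotype at a model locus")
    dominant_carrier = codes[0] in (HET, HOM_ALT)
    n_recessive_hom = sum(1 for c in codes[1:] if c == HOM_ALT)
    if dominant_carrier and n_recessive_hom >= model.min_recessive_hom:
        return SEEDLESS
    return SEEDED


@dataclass(frozen=True)
class DominantConsistency:
    consistent: bool
    n_seedless_carrier: int
    n_seedless_called: int
    n_seeded_ref: int
    n_seeded_called: int


def dominant_consistency(
    genotypes: np.ndarray, phenotypes: Sequence[str]
) -> DominantConsistency:
    """Test a genotype vector against the dominant causal-site pattern.

    TRUE iff every *called* seedless genotype carries the alternate
    allele (het or hom-alt) and every *called* seeded genotype is
    reference homozygous. Missing genotypes are ignored; they can never
    break consistency.
    """
    gt = np.asarray(genotypes)
    ph = np.asarray(phenotypes, dtype=object)
    if gt.shape != ph.shape:
        raise ConfigurationError("genotype and phenotype vectors differ in length")
    seedless = ph == SEEDLESS
    seeded = ph == SEEDED
    if not seedless.any() or not seeded.any():
        raise ConfigurationError("need at least one seedless and one seeded sample")
    sl_called = seedless & (gt != MISSING)
    sd_called = seeded & (gt != MISSING)
    n_carrier = int(np.isin(gt[sl_called], (HET, HOM_ALT)).sum())
    n_ref = int((gt[sd_called] == HOM_REF).sum())
    consistent = n_carrier == int(sl_called.sum()) and n_ref == int(sd_called.sum())
    return DominantConsistency(
        consistent=bool(consistent),
        n_seedless_carrier=n_carrier,
        n_seedless_called=int(sl_called.sum()),
        n_seeded_ref=n_ref,
        n_seeded_called=int(sd_called.sum()),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def scaled_hom_count_high(hom_count_high: int, n_seedless: int, n_seedless_ref: int) -> int:
    """Proportionally rescale the Group I count threshold for cohorts
    whose seedless sample size differs from the reference panel size."""
    if n_seedless == n_seedless_ref:
        return int(hom_count_high)
    return _round_half_up(hom_count_high * n_seedless / n_seedless_ref)


def assign_group(
    neg_log10_p: float,
    n_seedless_hom_alt: int,
    n_seedless: int,
    *,
    logp_min: float = 2.5,
    hom_count_high: int = 10,
    n_seedless_ref: int = 15,
) -> str:
    """Group a single deleterious SNP.

    Group III: association signal at or below the -log10 P threshold.
    Otherwise the count of seedless recessive homozygotes (missing
    genotypes count as non-homozygous) splits Group I (strictly above
    the count threshold) from Group II (at or below it; the exact-tie
    case is deliberately conservative).
    """
    if neg_log10_p is None or (isinstance(neg_log10_p, float) and math.isnan(neg_log10_p)):
        raise ClassificationError("missing association result")
    if neg_log10_p <= logp_min:
        return GROUP_III
    threshold = scaled_hom_count_high(hom_count_high, n_seedless, n_seedless_ref)
    return GROUP_I if n_seedless_hom_alt > threshold else GROUP_II


def classify_sites(
    callset: CohortCallset,
    phenotypes: Mapping[str, str],
    assoc: pd.DataFrame,
    *,
    logp_min: float = 2.5,
    hom_count_high: int = 10,
    n_seedless_ref: int = 15,
    deleterious_only: bool = True,
) -> pd.DataFrame:
    """Vectorised Group assignment for a call set.

    Precedence: the association gate first (at or below ``logp_min`` is
    Group III); then the recessive-homozygote count (above the scaled
    threshold is Group I); a remaining site whose genotype vector
    satisfies :func:`dominant_consistency` is labelled
    ``dominant_consistent`` (carrier in every seedless sample without
    the recessive-homozygote excess — the dominant-regulator pattern);
    everything else is Group II. Returns one row per classified site
    with the supporting counts.
    """
    ph = np.array([phenotypes[s] for s in callset.samples], dtype=object)
    seedless_mask = ph == SEEDLESS
    n_seedless = int(seedless_mask.sum())
    if n_seedless == 0 or not (ph == SEEDED).any():
        raise ConfigurationError("phenotype map must contain both classes")

    key = pd.DataFrame({"chrom": callset.chrom, "pos": callset.pos})
    assoc_idx = assoc.set_index(["chrom", "pos"])["neg_log10_p"]
    logp = np.full(callset.n_sites, np.nan)
    for i, (c, p) in enumerate(zip(key["chrom"], key["pos"])):
        if (c, p) in assoc_idx.index:
            logp[i] = float(assoc_idx.loc[(c, p)])

    sites = np.arange(callset.n_sites)
    if deleterious_only:
        sites = sites[callset.deleterious]
    rows = []
    for i in sites:
        if np.isnan(logp[i]):
            raise ClassificationError(
                f"no association result for site {callset.chrom[i]}:{callset.pos[i]}"
            )
        gt_row = callset.gt[i]
        n_hom = int((gt_row[seedless_mask] == HOM_ALT).sum())
        n_called = int((gt_row[seedless_mask] != MISSING).sum())
        if logp[i] <= logp_min:
            group = GROUP_III
        else:
            group = assign_group(
                logp[i],
                n_hom,
                n_seedless,
                logp_min=logp_min,
                hom_count_high=hom_count_high,
                n_seedless_ref=n_seedless_ref,
            )
            if group == GROUP_II and dominant_consistency(gt_row, ph).consistent:
                group = GROUP_DOMINANT
        rows.append(
            (
                callset.chrom[i],
                int(callset.pos[i]),
                f"{callset.chrom[i]}:{callset.pos[i]}",
                group,
                n_hom,
                n_called,
                float(logp[i]),
                bool(callset.deleterious[i]),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "site",
            "group",
            "n_seedless_hom_alt",
            "n_seedless_called",
            "neg_log10_p",
            "deleterious",
        ],
    )


@dataclass(frozen=True)
class SweepPeak:
    chrom: str
    peak_pos: int
    flank: int
    score: float

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ConfigurationError("flank must be positive")


def peak_windows(
    scan: pd.DataFrame, top_fraction: float = 0.005, flank: int = 50_000
) -> list[SweepPeak]:
    """Pick sweep peaks from a windowed differentiation scan.

    Windows in the top ``top_fraction`` by score are selected (ties
    broken by genome order), overlapping or adjacent selected windows
    are merged, and each merged run reports the centre of its
    maximum-scoring window as the peak position.
    """
    if not (0 < top_fraction <= 1):
        raise ConfigurationError("top_fraction must be in (0, 1]")
    frame = scan.dropna(subset=["score"]).reset_index(drop=True) if "score" in scan else scan
    if "score" not in scan.columns:
        raise ConfigurationError("scan table needs a 'score' column")
    if len(frame) == 0:
        raise ConfigurationError("empty scan")
    k = math.ceil(top_fraction * len(frame))
    order = frame.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    top = order.head(k).sort_values(["chrom", "start"], kind="mergesort")
    peaks: list[SweepPeak] = []
    run: list[pd.Series] = []

    def flush(run: list[pd.Series]) -> None:
        if not run:
            return
        best = max(run, key=lambda w: (w["score"], -w["start"]))
        centre = int((int(best["start"]) + int(best["end"])) // 2)
        peaks.append(SweepPeak(str(best["chrom"]), centre, int(flank), float(best["score"])))

    prev_chrom, prev_end = None, None
    for _, w in top.iterrows():
        if prev_chrom == w["chrom"] and int(w["start"]) <= int(prev_end):
            run.append(w)
            prev_end = max(prev_end, int(w["end"]))
        else:
            flush(run)
            run = [w]
            prev_chrom, prev_end = w["chrom"], int(w["end"])
    flush(run)
    return peaks


def candidate_report(
    callset: CohortCallset,
    peaks: Sequence[SweepPeak],
    assignments: pd.DataFrame,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Deleterious SNPs within ``peak_pos +/- flank`` of any sweep peak.

    ``genes``, if given, is a table of 1-based inclusive gene intervals
    (chrom, start, end, gene_id); each report row carries the first
    overlapping gene. Rows are sorted by (chrom, pos).
    """
    if len(assignments) == 0:
        return pd.DataFrame(
            columns=[
                "chrom",
                "pos",
                "site",
                "peak",
                "group",
                "n_seedless_hom_alt",
                "n_seedless_called",
                "neg_log10_p",
                "gene_id",
            ]
        )
    rows = []
    for _, snp in assignments.iterrows():
        if not snp["deleterious"]:
            continue
        hit = None
        for pk in peaks:
            if snp["chrom"] == pk.chrom and abs(int(snp["pos"]) - pk.peak_pos) <= pk.flank:
                hit = pk
                break
        if hit is None:
            continue
        gene_id = ""
        if genes is not None and len(genes):
            m = genes[
                (genes["chrom"] == snp["chrom"])
                & (genes["start"] <= int(snp["pos"]))
                & (genes["end"] >= int(snp["pos"]))
            ]
            if len(m):
                gene_id = str(m.iloc[0]["gene_id"])
        rows.append(
            (
                snp["chrom"],
                int(snp["pos"]),
                snp["site"],
                f"{hit.chrom}:{hit.peak_pos}",
                snp["group"],
                int(snp["n_seedless_hom_alt"]),
                int(snp["n_seedless_called"]),
                float(snp["neg_log10_p"]),
                gene_id,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "site",
            "peak",
            "group",
            "n_seedless_hom_alt",
            "n_seedless_called",
            "neg_log10_p",
            "gene_id",
        ],
    )
    return report.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Extract gene intervals (1-based inclusive) from a GFF3 file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                (parts[0], int(parts[3]), int(parts[4]), attrs.get("ID", attrs.get("Name", "")))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
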