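"""Synthetic diploid cohort generator.

Emulates the statistical structure of a high-depth resequencing panel
of a highly heterozygous woody perennial genotyped against a single
reference genome: a low-divergence stratum (``vinifera``-like cultivars
close to the reference), plus high-divergence strata (interspecific
``hybrid`` cultivars and ``wild`` relatives) with

* higher alternate-allele frequencies and excess heterozygosity,
* allele-dropout genotyping errors — a true heterozygote whose two
  haplotypes are unevenly captured is emitted as a homozygous call
  while its allele depths (AD) still carry the minor-allele reads,

which is exactly the error signature the allele-balance correction in
:mod:`vitivar.ab` targets. Per-genotype depths are overdispersed counts
around each sample's mean mapped depth (>37x by default), repeat tracts
carry multiplicatively inflated depth (the target of the per-sample
high-depth mask), and a seeded/seedless phenotype is planted through
one dominant regulator locus plus three complementary recessive loci.

The generator is the ground-truth side of every end-to-end test: it
returns the emitted (error-containing) call set, the clean
:class:`TruthSet`, and the sample metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .callset import (
    HET,
    HOM_ALT,
    HOM_REF,
    INFO_FIELDS,
    MISSING,
    CohortCallset,
)
from .errors import ConfigurationError, DataError
from .io import write_bed, write_metadata, write_truth, write_vcf
from .seedless import SEEDED, SEEDLESS, TraitModel, phenotype_from_genotype

_BASES = np.array(["A", "C", "G", "T"], dtype=object)


@dataclass(frozen=True)
class SimulationParams:
    """Everything that defines a synthetic cohort.

    Defaults describe a 30-sample panel: 20 reference-like cultivars,
    8 interspecific hybrids, 2 wild relatives; 15 samples carry
    seedless-compatible trait genotypes. Allele frequencies are
    Beta-distributed per stratum; dropout rates are strongly elevated
    in the divergent strata, reproducing the observed ordering
    wild >= hybrid >> vinifera of erroneous homozygote counts.
    """

    n_vinifera: int = 20
    n_hybrid: int = 8
    n_wild: int = 2
    n_seedless: int = 15
    n_sites: int = 5000
    chrom_lengths: tuple[int, ...] = (1_000_000,) * 5
    alt_freq_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "vinifera": (0.4, 2.6),
            "hybrid": (0.8, 1.2),
            "wild": (1.0, 1.0),
        }
    )
    het_excess_hybrid: float = 1.3
    mean_depth_range: tuple[float, float] = (37.0, 65.0)
    mean_depths: tuple[float, ...] | None = None
    depth_dispersion: float = 0.01
    seq_error_rate: float = 0.005
    dropout_prob: Mapping[str, float] = field(
        default_factory=lambda: {"vinifera": 0.002, "hybrid": 0.15, "wild": 0.25}
    )
    repeat_fraction: float = 0.08
    repeat_tract_length: int = 5000
    repeat_depth_multiplier: float = 6.0
    deleterious_flag_rate: float = 0.02
    filter_fail_fraction: float = 0.01
    trait_model: TraitModel | None = field(default_factory=TraitModel)
    trait_flank: int = 50_000
    trait_linkage: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_vinifera, self.n_hybrid, self.n_wild, self.n_seedless, self.n_sites)
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be non-negative")
        probs = [
            self.seq_error_rate,
            self.trait_linkage,
            self.repeat_fraction,
            self.deleterious_flag_rate,
            self.filter_fail_fraction,
            *self.dropout_prob.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.repeat_depth_multiplier <= 1:
            raise ConfigurationError("repeat_depth_multiplier must exceed 1")
        if self.het_excess_hybrid < 1:
            raise ConfigurationError("het_excess_hybrid must be >= 1")
        if self.n_seedless > self.n_samples:
            raise ConfigurationError("n_seedless exceeds the cohort size")
        if self.n_seedless > self.n_vinifera + self.n_hybrid:
            raise ConfigurationError(
                "n_seedless exceeds the number of phenotyped (non-wild) samples"
            )

    @property
    def n_samples(self) -> int:
        return self.n_vinifera + self.n_hybrid + self.n_wild


@dataclass
class TruthSet:
    """Ground truth behind a simulated call set."""

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    true_genotypes: np.ndarray  # (n_sites, n_samples) int8
    samples: list[str]
    trait_model: TraitModel
    repeat_intervals: pd.DataFrame  # chrom, start, end (0-based half-open)
    true_phenotypes: dict[str, str]

    def site_ids(self) -> np.ndarray:
        return np.array([f"{c}:{p}" for c, p in zip(self.chrom, self.pos)], dtype=object)

    def locus_index(self, locus: str) -> int:
        ids = self.site_ids()
        hits = np.flatnonzero(ids == locus)
        if len(hits) != 1:
            raise DataError(f"trait locus {locus} not found in truth set")
        return int(hits[0])

    def in_repeat(self) -> np.ndarray:
        """Per-site flag: does the site fall inside a repeat tract?"""
        mask = np.zeros(len(self.pos), dtype=bool)
        for _, iv in self.repeat_intervals.iterrows():
            mask |= (
                (self.chrom == iv["chrom"])
                & (self.pos - 1 >= iv["start"])
                & (self.pos - 1 < iv["end"])
            )
        return mask


def _sample_table(params: SimulationParams, rng: np.random.Generator):
    names, groups = [], []
    for prefix, group, n in (
        ("VIN", "vinifera", params.n_vinifera),
        ("HYB", "hybrid", params.n_hybrid),
        ("WLD", "wild", params.n_wild),
    ):
        for i in range(n):
            names.append(f"{prefix}{i + 1:02d}")
            groups.append(group)
    groups_arr = np.array(groups, dtype=object)
    phenotyped = np.flatnonzero(groups_arr != "wild")
    seedless_idx = rng.choice(phenotyped, size=params.n_seedless, replace=False)
    phenotypes = np.array(
        ["unknown" if g == "wild" else SEEDED for g in groups], dtype=object
    )
    phenotypes[seedless_idx] = SEEDLESS
    return names, groups_arr, phenotypes


def _site_positions(params: SimulationParams, rng: np.random.Generator):
    lengths = np.asarray(params.chrom_lengths, dtype=np.int64)
    share = lengths / lengths.sum()
    counts = np.floor(share * params.n_sites).astype(int)
    for i in range(params.n_sites - counts.sum()):
        counts[i % len(counts)] += 1
    chroms, positions = [], []
    for ci, (L, k) in enumerate(zip(lengths, counts)):
        k = min(k, int(L))
        pos = np.sort(rng.choice(int(L), size=k, replace=False)) + 1
        chroms.append(np.full(k, f"chr{ci + 1}", dtype=object))
        positions.append(pos.astype(np.int64))
    return np.concatenate(chroms), np.concatenate(positions)


def _insert_trait_sites(chrom, pos, params: SimulationParams):
    """Place 1 dominant + K recessive loci at distinct chromosome
    centres (independent inheritance), inserting sites if needed."""
    model = params.trait_model
    k = 1 + len(model.recessive_loci)
    if len(params.chrom_lengths) < k:
        raise ConfigurationError(
            f"trait model needs >= {k} chromosomes for independently inherited loci"
        )
    chrom_index = np.array([int(str(c)[3:]) for c in chrom])
    loci = []
    for ci in range(k):
        name = f"chr{ci + 1}"
        centre = params.chrom_lengths[ci] // 2
        if not ((chrom == name) & (pos == centre)).any():
            before = int((chrom_index < ci + 1).sum())
            local = int(np.searchsorted(pos[chrom == name], centre))
            at = before + local
            chrom = np.insert(chrom, at, name)
            pos = np.insert(pos, at, centre)
            chrom_index = np.insert(chrom_index, at, ci + 1)
        loci.append(f"{name}:{centre}")
    concrete = TraitModel(
        dominant_locus=loci[0],
        recessive_loci=tuple(loci[1:]),
        min_recessive_hom=model.min_recessive_hom,
    )
    return chrom, pos, concrete


def _repeat_intervals(params: SimulationParams, trait_centres, rng: np.random.Generator):
    """Non-overlapping repeat tracts on a tract-length grid, kept clear
    of the trait windows so planted loci never sit in inflated-depth
    regions."""
    rows = []
    tl = params.repeat_tract_length
    for ci, L in enumerate(params.chrom_lengths):
        name = f"chr{ci + 1}"
        n_blocks = int(L) // tl
        n_tracts = int(round(params.repeat_fraction * L / tl))
        if n_blocks == 0 or n_tracts == 0:
            continue
        blocked = set()
        for c_chrom, c_pos in trait_centres:
            if c_chrom != name:
                continue
            lo = max(0, (c_pos - params.trait_flank - tl) // tl)
            hi = min(n_blocks, (c_pos + params.trait_flank) // tl + 1)
            blocked.update(range(int(lo), int(hi)))
        avail = np.array([b for b in range(n_blocks) if b not in blocked])
        n_tracts = min(n_tracts, len(avail))
        chosen = rng.choice(avail, size=n_tracts, replace=False) if n_tracts else []
        for b in sorted(int(x) for x in chosen):
            rows.append((name, b * tl, (b + 1) * tl))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _genotype_probs(p: np.ndarray, het_excess: float):
    """HWE genotype probabilities with optional heterozygote excess,
    constrained to keep the allele frequency unbiased."""
    p_het = np.minimum(het_excess * 2 * p * (1 - p), np.minimum(2 * p, 2 * (1 - p)))
    p_hom_alt = p - p_het / 2
    p_hom_ref = 1.0 - p_het - p_hom_alt
    return p_hom_ref, p_het, p_hom_alt


def simulate_cohort(params: SimulationParams):
    """Generate ``(callset, truth, metadata)`` for one synthetic cohort.

    The call set contains the *emitted* genotypes (with dropout errors,
    depth artifacts and planted hard-filter failures); the truth set
    contains the clean genotypes, the concrete trait model, the repeat
    tracts and the genetically determined phenotypes. Identical
    parameters (including the seed) give byte-identical outputs.
    """
    if params.n_sites == 0:
        raise ConfigurationError("empty cohort: n_sites must be positive")
    if params.n_samples == 0:
        raise ConfigurationError("empty cohort: no samples")
    rng = np.random.default_rng(params.seed)

    names, groups, phenotypes = _sample_table(params, rng)
    n_samples = len(names)
    if params.mean_depths is not None:
        if len(params.mean_depths) != n_samples:
            raise ConfigurationError("mean_depths length mismatch")
        mean_depths = np.asarray(params.mean_depths, dtype=float)
    else:
        lo, hi = params.mean_depth_range
        mean_depths = np.round(rng.uniform(lo, hi, size=n_samples), 2)

    chrom, pos = _site_positions(params, rng)
    model = None
    trait_centres: list[tuple[str, int]] = []
    if params.trait_model is not None:
        chrom, pos, model = _insert_trait_sites(chrom, pos, params)
        trait_centres = [
            (l.split(":")[0], int(l.split(":")[1])) for l in model.loci
        ]
    n_sites = len(pos)

    ref = rng.choice(_BASES, size=n_sites)
    shift = rng.integers(1, 4, size=n_sites)
    base_idx = np.searchsorted(_BASES, ref.astype(str))
    alt = _BASES[(base_idx + shift) % 4]

    repeats = _repeat_intervals(params, trait_centres, rng)

    # --- true genotypes -------------------------------------------------
    strata_freq = {
        s: rng.beta(a, b, size=n_sites) for s, (a, b) in sorted(params.alt_freq_dist.items())
    }
    gt_true = np.empty((n_sites, n_samples), dtype=np.int8)
    u = rng.random((n_sites, n_samples))
    for j, g in enumerate(groups):
        p = strata_freq[g]
        excess = 1.0 if g == "vinifera" else params.het_excess_hybrid
        p0, p1, _ = _genotype_probs(p, excess)
        col = np.full(n_sites, HOM_ALT, dtype=np.int8)
        col[u[:, j] < p0 + p1] = HET
        col[u[:, j] < p0] = HOM_REF
        gt_true[:, j] = col

    site_ids = np.array([f"{c}:{q}" for c, q in zip(chrom, pos)], dtype=object)
    seedless_mask = phenotypes == SEEDLESS
    protected = np.zeros(n_sites, dtype=bool)
    if model is not None:
        # trait loci: seedless samples satisfy the model, others cannot
        dom_i = int(np.flatnonzero(site_ids == model.dominant_locus)[0])
        rec_is = [int(np.flatnonzero(site_ids == l)[0]) for l in model.recessive_loci]
        gt_true[dom_i] = HOM_REF
        gt_true[dom_i, seedless_mask] = HET
        for ri in rec_is:
            bg = rng.random(n_samples)
            gt_true[ri] = np.where(bg < 0.75, HOM_REF, HET).astype(np.int8)
            gt_true[ri, seedless_mask] = HOM_ALT
        # linked flanks: seedless samples share the founder haplotype
        for locus_i, locus_gt in [(dom_i, HET)] + [(ri, HOM_ALT) for ri in rec_is]:
            c, q = chrom[locus_i], pos[locus_i]
            win = (chrom == c) & (np.abs(pos - q) <= params.trait_flank)
            protected |= win
            win_idx = np.flatnonzero(win & (np.arange(n_sites) != locus_i))
            if len(win_idx):
                link = rng.random((len(win_idx), n_samples)) < params.trait_linkage
                block = gt_true[win_idx]
                block[link & seedless_mask[None, :]] = locus_gt
                gt_true[win_idx] = block

    true_phen = {
        s: phenotype_from_genotype(
            model, {l: int(gt_true[int(np.flatnonzero(site_ids == l)[0]), j]) for l in model.loci}
        )
        if model is not None
        else str(phenotypes[j])
        for j, s in enumerate(names)
    }

    # --- depths and reads ----------------------------------------------
    in_repeat = np.zeros(n_sites, dtype=bool)
    for _, iv in repeats.iterrows():
        in_repeat |= (chrom == iv["chrom"]) & (pos - 1 >= iv["start"]) & (pos - 1 < iv["end"])
    depth_mean = np.broadcast_to(mean_depths, (n_sites, n_samples)).copy()
    depth_mean[in_repeat] *= params.repeat_depth_multiplier
    if params.depth_dispersion > 0:
        r = 1.0 / params.depth_dispersion
        dp = rng.negative_binomial(r, r / (r + depth_mean)).astype(np.int32)
    else:
        dp = rng.poisson(depth_mean).astype(np.int32)

    p_read = np.full(gt_true.shape, params.seq_error_rate)
    p_read[gt_true == HET] = 0.5
    p_read[gt_true == HOM_ALT] = 1.0 - params.seq_error_rate
    ad_alt = rng.binomial(dp, p_read).astype(np.int32)
    ad_ref = (dp - ad_alt).astype(np.int32)

    # --- emitted genotypes: allele dropout, uncallable sites ------------
    gt_emit = gt_true.copy()
    dropout_rate = np.array([params.dropout_prob.get(g, 0.0) for g in groups])
    drop = (gt_true == HET) & (rng.random(gt_true.shape) < dropout_rate[None, :])
    gt_emit[drop] = np.where(ad_alt[drop] >= ad_ref[drop], HOM_ALT, HOM_REF)
    gt_emit[dp == 0] = MISSING

    # --- site annotations ------------------------------------------------
    info = pd.DataFrame(index=range(n_sites), columns=list(INFO_FIELDS), dtype=float)
    qual = rng.uniform(60.0, 2000.0, size=n_sites)
    info["QD"] = rng.uniform(8.0, 34.0, size=n_sites)
    info["FS"] = rng.exponential(3.0, size=n_sites)
    info["MQ"] = rng.normal(60.0, 0.8, size=n_sites)
    info["MQRankSum"] = rng.normal(0.0, 1.2, size=n_sites)
    info["ReadPosRankSum"] = rng.normal(0.0, 1.5, size=n_sites)
    info["DP"] = dp.sum(axis=1).astype(float)

    frac = params.filter_fail_fraction
    if frac > 0:
        plantable = ~protected
        fails = {
            "QUAL": (lambda n: rng.uniform(5.0, 29.0, n)),
            "QD": (lambda n: rng.uniform(0.2, 2.9, n)),
            "FS": (lambda n: rng.uniform(31.0, 120.0, n)),
            "MQ": (lambda n: rng.uniform(10.0, 29.0, n)),
            "MQRankSum": (lambda n: rng.uniform(-20.0, -12.6, n)),
        }
        for key, draw in fails.items():
            mask = (rng.random(n_sites) < frac) & plantable
            k = int(mask.sum())
            if k == 0:
                continue
            if key == "QUAL":
                qual[mask] = draw(k)
            else:
                info.loc[mask, key] = draw(k)

    deleterious = rng.random(n_sites) < params.deleterious_flag_rate
    if model is not None:
        for l in model.loci:
            deleterious[int(np.flatnonzero(site_ids == l)[0])] = True

    callset = CohortCallset(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        info=info,
        gt=gt_emit,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=dp,
        samples=names,
        deleterious=deleterious,
    )
    truth = TruthSet(
        chrom=chrom.copy(),
        pos=pos.copy(),
        ref=ref.copy(),
        alt=alt.copy(),
        true_genotypes=gt_true,
        samples=list(names),
        trait_model=model if model is not None else TraitModel(),
        repeat_intervals=repeats,
        true_phenotypes=true_phen,
    )
    metadata = pd.DataFrame(
        {
            "sample": names,
            "group": groups,
            "phenotype": phenotypes,
            "mean_depth": mean_depths,
        }
    )
    return callset, truth, metadata


def callset_from_truth(truth: TruthSet, depth: int = 30) -> CohortCallset:
    """Build an error-free call set from true genotypes (for
    concordance and validation baselines)."""
    n, s = truth.true_genotypes.shape
    gt = truth.true_genotypes
    ad_alt = np.where(gt == HET, depth // 2, np.where(gt == HOM_ALT, depth, 0)).astype(np.int32)
    ad_alt[gt == MISSING] = 0
    dp = np.full((n, s), depth, dtype=np.int32)
    info = pd.DataFrame({k: np.full(n, np.nan) for k in INFO_FIELDS})
    info["DP"] = float(depth * s)
    return CohortCallset(
        chrom=truth.chrom,
        pos=truth.pos,
        ref=truth.ref,
        alt=truth.alt,
        qual=np.full(n, 1000.0),
        info=info,
        gt=gt.copy(),
        ad_ref=(dp - ad_alt).astype(np.int32),
        ad_alt=ad_alt,
        dp=dp,
        samples=list(truth.samples),
    )


def write_cohort(
    callset: CohortCallset,
    metadata: pd.DataFrame,
    out_prefix: str,
    truth: TruthSet | None = None,
) -> dict[str, str]:
    """Write ``<prefix>.vcf``, ``<prefix>.samples.tsv`` and, when truth
    is supplied, ``<prefix>.truth.tsv`` and ``<prefix>.repeats.bed``.
    Returns the mapping of artifact name to path."""
    paths = {"vcf": f"{out_prefix}.vcf", "samples": f"{out_prefix}.samples.tsv"}
    write_vcf(callset, paths["vcf"])
    write_metadata(metadata, paths["samples"])
    if truth is not None:
        paths["truth"] = f"{out_prefix}.truth.tsv"
        paths["repeats"] = f"{out_prefix}.repeats.bed"
        write_truth(truth, paths["truth"])
        write_bed(truth.repeat_intervals, paths["repeats"])
    return paths


def parse_config(path: str) -> SimulationParams:
    """Parse a flat ``key=value`` simulation config.

    Nested parameters use dotted keys (``dropout_prob.hybrid=0.2``,
    ``alt_freq_dist.wild=1.0,1.0``); ``chrom_lengths`` is a comma list.
    """
    base = SimulationParams()
    kwargs: dict = {}
    nested: dict[str, dict] = {"dropout_prob": dict(base.dropout_prob), "alt_freq_dist": dict(base.alt_freq_dist)}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if "." in key:
                outer, inner = key.split(".", 1)
                if outer not in nested:
                    raise ConfigurationError(f"unknown nested parameter {outer}")
                parts = [float(x) for x in value.split(",")]
                nested[outer][inner] = parts[0] if len(parts) == 1 else tuple(parts)
            elif key == "chrom_lengths":
                kwargs[key] = tuple(int(float(x)) for x in value.split(","))
            elif key in ("mean_depth_range",):
                kwargs[key] = tuple(float(x) for x in value.split(","))
            elif key in SimulationParams.__dataclass_fields__:
                fld = SimulationParams.__dataclass_fields__[key].type
                kwargs[key] = int(float(value)) if "int" in str(fld) else float(value)
            else:
                raise ConfigurationError(f"unknown parameter {key}")
    kwargs["dropout_prob"] = nested["dropout_prob"]
    kwargs["alt_freq_dist"] = nested["alt_freq_dist"]
    return replace(base, **kwargs)
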