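"""Bundled worked-example data.

``sweep_snp_panel`` builds a *synthetic reconstruction* of the
deleterious-SNP table from the grape seedlessness panel (15 seedless
and 13 seeded accessions): 41 deleterious SNPs with association
-log10 P above 2.5, lying in candidate selective sweeps. The published
facts are encoded exactly —

* the dominant-locus sweep on chromosome 18 (29.46–30.46 Mb) holds 7
  such SNPs; the SNP at position 30,306,458 is heterozygous in all 15
  seedless accessions, reference homozygous in 11 of 13 seeded
  accessions and uncalled in the other 2, and it is the only one of
  the 7 whose genotype distribution matches a dominant causal site
  (the remaining six are heterozygous in the Rizamat accession, one
  also in Italia and Nebbiolo, and two are reference homozygous in one
  and two seedless accessions respectively);
* 13 SNPs in four sweeps (six on chromosome 1 at 4.3–5.3 Mb — where
  Rizamat is non-reference homozygous at all six — one on chromosome 8
  at 17.47–18.47 Mb, three on chromosome 8 at 20.20–21.20 Mb, three on
  chromosome 18 at 12.83–13.83 Mb) are non-reference homozygous in
  more than 10 of 15 seedless accessions;
* 21 SNPs in eight further sweeps are non-reference homozygous in
  fewer than 10 of 15 seedless accessions, most in fewer than five and
  five of them in seven or eight.

Positions and genotype details not individually printed (exact
coordinates of the unnamed SNPs, which seeded accessions carry
heterozygous genotypes) are invented deterministically; the panel is a
stand-in fixture, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .callset import HET, HOM_ALT, HOM_REF, INFO_FIELDS, MISSING, CohortCallset
from .seedless import SEEDED, SEEDLESS

#: Seedless accessions of the panel (analysis subset).
SEEDLESS_ACCESSIONS: tuple[str, ...] = (
    "Autumn_Royal",
    "Autumn_Seedless",
    "Cheongsoo",
    "Crimson_SDS",
    "Dawn_SDS",
    "Fantasy_SDS",
    "Himrod",
    "Hongju",
    "Kishm_Chernyi",
    "Perlon",
    "Princess",
    "RSDS",
    "Shiny_Star",
    "Suffolk_Red",
    "Thompson_SDS",
)

#: Seeded accessions of the panel (analysis subset; RZ is Rizamat).
SEEDED_ACCESSIONS: tuple[str, ...] = (
    "Baily_Alic",
    "Campbell_Early",
    "Chardonnay",
    "Cannonau",
    "Italia",
    "Muscat_Alex",
    "Nebbiolo_CVT71",
    "RG",
    "RZ",
    "Tamnara",
    "Tannat",
    "TR_1",
    "Zinfandel",
)

#: Dominant-locus sweep interval on chromosome 18 (1-based inclusive).
SDI_SWEEP: tuple[str, int, int] = ("chr18", 29_460_000, 30_460_000)

#: The dominant causal SNP position within that sweep.
SDI_SNP_POS: int = 30_306_458


def _seedless_vector(n_hom_alt: int, n_het: int | None = None) -> list[int]:
    """First ``n_hom_alt`` seedless accessions hom-alt, then hets, then
    reference homozygotes."""
    n = len(SEEDLESS_ACCESSIONS)
    if n_het is None:
        n_het = n - n_hom_alt
    out = [HOM_ALT] * n_hom_alt + [HET] * n_het
    out += [HOM_REF] * (n - len(out))
    return out[:n]


def _seeded_vector(overrides: dict[str, int] | None = None) -> list[int]:
    out = [HOM_REF] * len(SEEDED_ACCESSIONS)
    for name, code in (overrides or {}).items():
        out[SEEDED_ACCESSIONS.index(name)] = code
    return out


@dataclass
class SweepPanel:
    """Synthetic reconstruction of the deleterious-SNP sweep table."""

    callset: CohortCallset
    phenotypes: dict[str, str]
    regions: pd.DataFrame  # chrom, start, end, label per sweep
    assoc: pd.DataFrame  # chrom, pos, neg_log10_p (logistic association)

    def sdi_mask(self) -> np.ndarray:
        chrom, lo, hi = SDI_SWEEP
        return (
            (self.callset.chrom == chrom)
            & (self.callset.pos >= lo)
            & (self.callset.pos <= hi)
        )


def sweep_snp_panel() -> SweepPanel:
    """Build the 41-SNP synthetic panel (see module docstring)."""
    rows: list[tuple[str, int, float, list[int], list[int]]] = []

    # --- dominant-locus (SDI) sweep: 7 SNPs on chr18, 29.46-30.46 Mb ---
    all_het = [HET] * 15
    rows += [
        (
            "chr18",
            SDI_SNP_POS,
            5.051,
            all_het,
            _seeded_vector({"Cannonau": MISSING, "TR_1": MISSING}),
        ),
        ("chr18", 29_650_000, 2.92, [HOM_REF] + [HET] * 14, _seeded_vector({"RZ": HET})),
        ("chr18", 29_810_000, 2.71, [HOM_REF] * 2 + [HET] * 13, _seeded_vector({"RZ": HET})),
        (
            "chr18",
            30_050_000,
            3.18,
            all_het,
            _seeded_vector({"Italia": HET, "Nebbiolo_CVT71": HET, "RZ": HET}),
        ),
        ("chr18", 30_120_000, 2.86, all_het, _seeded_vector({"RZ": HET})),
        ("chr18", 30_390_000, 3.05, all_het, _seeded_vector({"RZ": HET})),
        ("chr18", 30_441_000, 2.64, all_het, _seeded_vector({"RZ": HET})),
    ]

    # --- Group I: 13 SNPs, hom-alt in >10/15 seedless, four sweeps ----
    chr1_counts = [(4_410_000, 3.9, 15), (4_560_000, 3.4, 14), (4_720_000, 3.1, 13),
                   (4_800_000, 4.2, 15), (4_950_000, 2.9, 12), (5_180_000, 3.6, 14)]
    for pos, logp, k in chr1_counts:
        rows.append(
            (
                "chr1",
                pos,
                logp,
                _seedless_vector(k),
                _seeded_vector({"RZ": HOM_ALT, "Campbell_Early": HET}),
            )
        )
    rows.append(
        ("chr8", 17_890_000, 3.8, _seedless_vector(13), _seeded_vector({"Baily_Alic": HET}))
    )
    for pos, logp, k in [(20_350_000, 3.0, 12), (20_710_000, 2.8, 11), (21_050_000, 3.3, 14)]:
        rows.append(("chr8", pos, logp, _seedless_vector(k), _seeded_vector({"Tamnara": HET})))
    for pos, logp, k in [(12_980_000, 3.2, 13), (13_400_000, 2.7, 12), (13_710_000, 3.1, 11)]:
        rows.append(("chr18", pos, logp, _seedless_vector(k), _seeded_vector({"Italia": HET})))

    # --- Group II: 21 SNPs, hom-alt in <10/15 seedless, eight sweeps --
    group2_regions = [
        ("chr2", 6_000_000, 3),
        ("chr3", 1_200_000, 3),
        ("chr4", 14_500_000, 3),
        ("chr5", 8_300_000, 2),
        ("chr7", 3_900_000, 3),
        ("chr10", 10_100_000, 2),
        ("chr11", 18_200_000, 3),
        ("chr14", 2_400_000, 2),
    ]
    low_counts = [0, 1, 2, 3, 4, 0, 1, 2, 3, 4, 0, 1, 2, 3, 4, 2]
    mid_counts = [7, 8, 7, 8, 7]
    counts = mid_counts + low_counts
    logps = [2.55 + 0.04 * i for i in range(21)]
    carriers = list(SEEDED_ACCESSIONS)
    idx = 0
    for chrom, start, n_snps in group2_regions:
        for j in range(n_snps):
            k = counts[idx]
            rows.append(
                (
                    chrom,
                    start + 120_000 * (j + 1),
                    logps[idx],
                    _seedless_vector(k, n_het=min(6, 15 - k)),
                    _seeded_vector({carriers[idx % len(carriers)]: HET}),
                )
            )
            idx += 1

    samples = list(SEEDLESS_ACCESSIONS) + list(SEEDED_ACCESSIONS)
    n_sites = len(rows)
    gt = np.array([r[3] + r[4] for r in rows], dtype=np.int8)
    dp = np.where(gt == MISSING, 0, 50).astype(np.int32)
    ad_alt = np.select(
        [gt == HOM_REF, gt == HET, gt == HOM_ALT], [0, 25, 50], default=0
    ).astype(np.int32)
    info = pd.DataFrame({k: np.full(n_sites, np.nan) for k in INFO_FIELDS})
    info["QD"] = 20.0
    info["FS"] = 1.0
    info["MQ"] = 60.0
    info["MQRankSum"] = 0.0
    info["ReadPosRankSum"] = 0.0
    info["DP"] = float(50 * len(samples))
    callset = CohortCallset(
        chrom=np.array([r[0] for r in rows], dtype=object),
        pos=np.array([r[1] for r in rows], dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        qual=np.full(n_sites, 1000.0),
        info=info,
        gt=gt,
        ad_ref=(dp - ad_alt).astype(np.int32),
        ad_alt=ad_alt,
        dp=dp,
        samples=samples,
        deleterious=np.ones(n_sites, dtype=bool),
    )
    phenotypes = {s: SEEDLESS for s in SEEDLESS_ACCESSIONS}
    phenotypes.update({s: SEEDED for s in SEEDED_ACCESSIONS})
    regions = pd.DataFrame(
        [
            (SDI_SWEEP[0], SDI_SWEEP[1], SDI_SWEEP[2], "sdi"),
            ("chr1", 4_300_000, 5_300_000, "recessive"),
            ("chr8", 17_470_000, 18_470_000, "recessive"),
            ("chr8", 20_200_000, 21_200_000, "recessive"),
            ("chr18", 12_830_000, 13_830_000, "recessive"),
        ]
        + [(c, s, s + 1_000_000, "other") for c, s, _ in group2_regions],
        columns=["chrom", "start", "end", "label"],
    )
    assoc = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "pos": [r[1] for r in rows],
            "neg_log10_p": [r[2] for r in rows],
        }
    )
    assoc["p_value"] = 10.0 ** (-assoc["neg_log10_p"])
    return SweepPanel(callset=callset, phenotypes=phenotypes, regions=regions, assoc=assoc)
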