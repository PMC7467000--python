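"""In-memory cohort call set.

The central container is :class:`CohortCallset`: a sites x samples
matrix of diploid genotype codes together with per-genotype allele
depths (AD), per-genotype total depth (DP), and the per-site
annotations consumed by hard filtering (QUAL, QD, FS, MQ, MQRankSum,
ReadPosRankSum, DP).

Genotype codes follow the usual dosage-friendly convention:

====================  ====
``HOM_REF``              0
``HET``                  1
``HOM_ALT``              2
``MISSING``             -1
====================  ====

so ``gt`` doubles as an alternate-allele dosage matrix wherever
genotypes are called. All coordinates are 1-based (VCF convention);
interval files (BED) are 0-based half-open and converted at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

#: INFO keys carried by the container, in canonical VCF order.
INFO_FIELDS: tuple[str, ...] = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP")

#: Taxon groups recognised by group-aware operations.
TAXON_GROUPS: tuple[str, ...] = ("vinifera", "hybrid", "wild")

#: Phenotype labels.
PHENOTYPES: tuple[str, ...] = ("seeded", "seedless", "unknown")


@dataclass(frozen=True)
class SampleRecord:
    """Identity and per-sample context used throughout the pipeline.

    Parameters
    ----------
    sample:
        Sample name, matching the VCF header column.
    group:
        Taxon group, one of ``vinifera``, ``hybrid``, ``wild``. Drives
        eligibility for allele-balance genotype conversion.
    phenotype:
        ``seeded``, ``seedless`` or ``unknown``.
    mean_depth:
        Mean mapped read depth of the sample; the reference point for
        the per-sample high-depth (repeat) mask.
    """

    sample: str
    group: str
    phenotype: str
    mean_depth: float


def metadata_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Assemble sample records into the canonical metadata table."""
    return pd.DataFrame(
        [(r.sample, r.group, r.phenotype, r.mean_depth) for r in records],
        columns=["sample", "group", "phenotype", "mean_depth"],
    )


def metadata_records(frame: pd.DataFrame) -> list[SampleRecord]:
    """Inverse of :func:`metadata_frame`."""
    return [
        SampleRecord(str(r["sample"]), str(r["group"]), str(r["phenotype"]), float(r["mean_depth"]))
        for _, r in frame.iterrows()
    ]


@dataclass
class CohortCallset:
    """Genotypes, allele depths and site annotations for one cohort.

    Arrays are sites-major: every per-genotype array has shape
    ``(n_sites, n_samples)``; per-site arrays have shape ``(n_sites,)``.
    ``alt`` stores the ALT column verbatim, so a multi-allelic site
    carries a comma-joined allele list and is detected by
    :meth:`is_biallelic`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    info: pd.DataFrame
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray
    samples: list[str]
    deleterious: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.qual = np.asarray(self.qual, dtype=float)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.ad_ref = np.asarray(self.ad_ref, dtype=np.int32)
        self.ad_alt = np.asarray(self.ad_alt, dtype=np.int32)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        self.samples = list(self.samples)
        if self.deleterious is None:
            self.deleterious = np.zeros(self.n_sites, dtype=bool)
        else:
            self.deleterious = np.asarray(self.deleterious, dtype=bool)
        n, s = self.n_sites, self.n_samples
        for name in ("gt", "ad_ref", "ad_alt", "dp"):
            arr = getattr(self, name)
            if arr.shape != (n, s):
                raise DataError(f"{name} has shape {arr.shape}, expected {(n, s)}")
        if not isinstance(self.info, pd.DataFrame):
            self.info = pd.DataFrame(self.info)
        missing_cols = [c for c in INFO_FIELDS if c not in self.info.columns]
        for c in missing_cols:
            self.info[c] = np.nan
        self.info = self.info[list(INFO_FIELDS)].reset_index(drop=True).astype(float)
        if len(self.info) != n:
            raise DataError(f"info table has {len(self.info)} rows, expected {n}")
        if np.any((self.ad_ref < 0) | (self.ad_alt < 0) | (self.dp < 0)):
            raise DataError("negative read depths")

    # ------------------------------------------------------------------
    # basic views
    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_ids(self) -> np.ndarray:
        """``chrom:pos`` identifiers, the package-wide site key."""
        return np.array([f"{c}:{p}" for c, p in zip(self.chrom, self.pos)], dtype=object)

    def is_biallelic(self) -> np.ndarray:
        return np.array([("," not in a) and a != "." for a in self.alt], dtype=bool)

    def is_snp(self) -> np.ndarray:
        """True where REF and every ALT allele are single bases."""
        out = np.empty(self.n_sites, dtype=bool)
        for i, (r, a) in enumerate(zip(self.ref, self.alt)):
            alts = str(a).split(",")
            out[i] = len(str(r)) == 1 and all(len(x) == 1 and x != "." and x != "*" for x in alts)
        return out

    def called(self) -> np.ndarray:
        return self.gt != MISSING

    def missing_rate(self) -> np.ndarray:
        """Per-site fraction of samples with no called genotype."""
        return 1.0 - self.called().mean(axis=1)

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage in {0,1,2}, NaN where missing."""
        d = self.gt.astype(float)
        d[self.gt == MISSING] = np.nan
        return d

    def alt_allele_freq(self) -> np.ndarray:
        """Per-site alternate-allele frequency among called alleles
        (NaN where no genotype is called)."""
        called = self.called()
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, self.gt, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    def nonref_allele_count(self) -> np.ndarray:
        called = self.called()
        return np.where(called, self.gt, 0).sum(axis=1)

    # ------------------------------------------------------------------
    # subsetting / copying
    # ------------------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "CohortCallset":
        """New call set restricted to the given site indices or mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortCallset(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            qual=self.qual[index],
            info=self.info.iloc[index].reset_index(drop=True),
            gt=self.gt[index],
            ad_ref=self.ad_ref[index],
            ad_alt=self.ad_alt[index],
            dp=self.dp[index],
            samples=list(self.samples),
            deleterious=self.deleterious[index],
        )

    def take_samples(self, names: Sequence[str]) -> "CohortCallset":
        idx = [self.samples.index(n) for n in names]
        return CohortCallset(
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            qual=self.qual.copy(),
            info=self.info.copy(),
            gt=self.gt[:, idx],
            ad_ref=self.ad_ref[:, idx],
            ad_alt=self.ad_alt[:, idx],
            dp=self.dp[:, idx],
            samples=list(names),
            deleterious=self.deleterious.copy(),
        )

    def copy(self) -> "CohortCallset":
        return self.take_sites(np.arange(self.n_sites))

    # ------------------------------------------------------------------
    # comparison
    # ------------------------------------------------------------------
    def equals(self, other: "CohortCallset", rtol: float = 1e-4, atol: float = 1e-3) -> bool:
        """Field-by-field equality with float tolerance on annotations
        (the VCF writer prints floats to 4 decimal places)."""
        if self.samples != other.samples or self.n_sites != other.n_sites:
            return False
        if not (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.ad_ref, other.ad_ref)
            and np.array_equal(self.ad_alt, other.ad_alt)
            and np.array_equal(self.dp, other.dp)
            and np.array_equal(self.deleterious, other.deleterious)
        ):
            return False
        if not np.allclose(self.qual, other.qual, rtol=rtol, atol=atol, equal_nan=True):
            return False
        return np.allclose(
            self.info.to_numpy(), other.info.to_numpy(), rtol=rtol, atol=atol, equal_nan=True
        )


def group_map(metadata: pd.DataFrame) -> Mapping[str, str]:
    """sample -> taxon group from a metadata table."""
    return dict(zip(metadata["sample"].astype(str), metadata["group"].astype(str)))


def phenotype_map(metadata: pd.DataFrame) -> Mapping[str, str]:
    """sample -> phenotype from a metadata table."""
    return dict(zip(metadata["sample"].astype(str), metadata["phenotype"].astype(str)))


def depth_map(metadata: pd.DataFrame) -> Mapping[str, float]:
    """sample -> mean mapped depth from a metadata table."""
    return dict(zip(metadata["sample"].astype(str), metadata["mean_depth"].astype(float)))
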