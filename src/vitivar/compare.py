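"""Call-set agreement and truth-set validation.

Two complementary quality measures for a variant-calling pipeline:

* :func:`genotype_concordance` — per-sample percentage of identical
  genotypes between two call sets at sites sharing reference
  coordinates and alleles (the classic between-caller comparison);
* :func:`validation_rate` — per-sample agreement against a ground-truth
  genotype set over declared intervals, where truth sites the caller
  never emitted count *against* the rate (a caller that drops hard
  sites must not look better for it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .callset import MISSING, CohortCallset
from .errors import ComparisonError, ValidationError
from .simulate import TruthSet


def _site_key(callset: CohortCallset) -> pd.Index:
    return pd.MultiIndex.from_arrays(
        [callset.chrom, callset.pos, callset.ref, callset.alt],
        names=["chrom", "pos", "ref", "alt"],
    )


def genotype_concordance(a: CohortCallset, b: CohortCallset) -> pd.DataFrame:
    """Per-sample genotype agreement at shared sites.

    Sites are matched on (chrom, pos, ref, alt). For each shared
    sample, percent = 100 x (# sites with identical genotype, both
    called) / (# sites called in both); sites missing in either call
    set for that sample are excluded from its denominator. Genotypes
    are unphased, so 0/1 and 1/0 are identical by construction.

    Returns a table indexed by sample with columns ``percent``,
    ``n_compared`` and attribute-style access to ``n_shared_sites``
    via ``frame.attrs``.
    """
    shared_samples = [s for s in a.samples if s in set(b.samples)]
    if not shared_samples:
        raise ComparisonError("call sets share no samples")
    key_a, key_b = _site_key(a), _site_key(b)
    common, ia, ib = np.intersect1d(
        key_a.to_numpy(), key_b.to_numpy(), return_indices=True
    )
    ja = [a.samples.index(s) for s in shared_samples]
    jb = [b.samples.index(s) for s in shared_samples]
    # intersect1d sorts by key; apply the same order on both sides
    order_a = ia[np.argsort(key_a.to_numpy()[ia], kind="mergesort")]
    order_b = ib[np.argsort(key_b.to_numpy()[ib], kind="mergesort")]
    gta = a.gt[order_a][:, ja]
    gtb = b.gt[order_b][:, jb]
    both = (gta != MISSING) & (gtb != MISSING)
    agree = both & (gta == gtb)
    n_both = both.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_both > 0, 100.0 * agree.sum(axis=0) / n_both, np.nan)
    out = pd.DataFrame(
        {"percent": pct, "n_compared": n_both.astype(int)}, index=shared_samples
    )
    out.index.name = "sample"
    out.attrs["n_shared_sites"] = int(len(common))
    return out


def validation_rate(
    callset: CohortCallset,
    truth: TruthSet,
    intervals: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample validation against truth genotypes in intervals.

    ``intervals`` is a BED-like table (chrom, start, end; 0-based
    half-open). The per-sample denominator is the number of truth sites
    inside the intervals; each is *validated* (emitted call equals the
    truth genotype), *contradicted* (emitted call differs) or *missing*
    (no call emitted, either no genotype or the site absent from the
    call set). The three counts partition the denominator and
    rate = 100 x validated / denominator.
    """
    if intervals is None or len(intervals) == 0:
        raise ValidationError("no validation intervals supplied")
    in_iv = np.zeros(len(truth.pos), dtype=bool)
    for _, iv in intervals.iterrows():
        in_iv |= (
            (truth.chrom == iv["chrom"])
            & (truth.pos - 1 >= int(iv["start"]))
            & (truth.pos - 1 < int(iv["end"]))
        )
    t_idx = np.flatnonzero(in_iv)
    if len(t_idx) == 0:
        raise ValidationError("no truth variant sites inside the intervals")

    truth_key = pd.MultiIndex.from_arrays(
        [truth.chrom[t_idx], truth.pos[t_idx]], names=["chrom", "pos"]
    )
    call_key = pd.MultiIndex.from_arrays([callset.chrom, callset.pos])
    call_lookup = pd.Series(np.arange(callset.n_sites), index=call_key)

    samples = [s for s in truth.samples if s in set(callset.samples)]
    if not samples:
        raise ComparisonError("call set shares no samples with the truth set")
    jt = [truth.samples.index(s) for s in samples]
    jc = [callset.samples.index(s) for s in samples]

    rows = []
    for st, sc, name in zip(jt, jc, samples):
        validated = contradicted = missing = 0
        for k, ti in enumerate(t_idx):
            true_gt = int(truth.true_genotypes[ti, st])
            key = truth_key[k]
            if key in call_lookup.index:
                ci = int(call_lookup.loc[key])
                emitted = int(callset.gt[ci, sc])
            else:
                emitted = MISSING
            if emitted == MISSING:
                missing += 1
            elif emitted == true_gt:
                validated += 1
            else:
                contradicted += 1
        denom = len(t_idx)
        rows.append((name, 100.0 * validated / denom, validated, contradicted, missing, denom))
    out = pd.DataFrame(
        rows,
        columns=["sample", "percent", "validated", "contradicted", "missing", "denominator"],
    ).set_index("sample")
    return out
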