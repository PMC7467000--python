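import numpy as np
import pandas as pd
import pytest

from vitivar.callset import INFO_FIELDS, CohortCallset
from vitivar.simulate import SimulationParams, simulate_cohort


def make_callset(
    gt,
    pos=None,
    chrom=None,
    samples=None,
    ad_ref=None,
    ad_alt=None,
    dp=None,
    ref=None,
    alt=None,
    qual=None,
    info=None,
    deleterious=None,
):
    """Hand-built call set with passing annotations by default."""
    gt = np.asarray(gt, dtype=np.int8)
    n, s = gt.shape
    pos = np.asarray(pos) if pos is not None else np.arange(1, n + 1) * 1000
    chrom = np.asarray(chrom, dtype=object) if chrom is not None else np.full(n, "chr1", dtype=object)
    samples = list(samples) if samples is not None else [f"S{i + 1}" for i in range(s)]
    if dp is None:
        dp = np.full((n, s), 30, dtype=np.int32)
    dp = np.asarray(dp, dtype=np.int32)
    if ad_alt is None:
        ad_alt = np.select([gt == 0, gt == 1, gt == 2], [0, dp // 2, dp], default=0)
    ad_alt = np.asarray(ad_alt, dtype=np.int32)
    if ad_ref is None:
        ad_ref = np.clip(dp - ad_alt, 0, None)
    base_info = pd.DataFrame(
        {
            "QD": np.full(n, 20.0),
            "FS": np.full(n, 1.0),
            "MQ": np.full(n, 60.0),
            "MQRankSum": np.full(n, 0.0),
            "ReadPosRankSum": np.full(n, 0.0),
            "DP": dp.sum(axis=1).astype(float),
        }
    )
    if info is not None:
        for k, v in info.items():
            base_info[k] = v
    return CohortCallset(
        chrom=chrom,
        pos=pos,
        ref=np.asarray(ref, dtype=object) if ref is not None else np.full(n, "A", dtype=object),
        alt=np.asarray(alt, dtype=object) if alt is not None else np.full(n, "T", dtype=object),
        qual=np.asarray(qual, dtype=float) if qual is not None else np.full(n, 500.0),
        info=base_info,
        gt=gt,
        ad_ref=np.asarray(ad_ref, dtype=np.int32),
        ad_alt=ad_alt,
        dp=dp,
        samples=samples,
        deleterious=deleterious,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One medium synthetic cohort shared by read-only tests."""
    params = SimulationParams(seed=11, n_sites=4000)
    return params, *simulate_cohort(params)


@pytest.fixture(scope="session")
def dropout_cohort():
    """Cohort with the elevated hybrid dropout rate used by the
    allele-balance recovery checks."""
    params = SimulationParams(
        seed=11,
        n_sites=4000,
        dropout_prob={"vinifera": 0.002, "hybrid": 0.2, "wild": 0.25},
    )
    return params, *simulate_cohort(params)
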