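"""Per-SNP binary-trait association.

Produces a -log10 P value per SNP for a binary phenotype
(seeded = control, seedless = case). Two methods:

* ``fisher`` (default): two-sided Fisher exact test on the 2x2
  allele-count table (alternate/reference alleles x case/control),
  missing genotypes excluded. Exact and assumption-free, appropriate
  for cohorts of a few dozen samples.
* ``logistic_score``: score (Rao) test for adding the allele dosage to
  a logistic model of the phenotype, optionally with covariates (e.g.
  principal-component scores) for structure correction. The null model
  is fitted once per site on the samples called there; collinear
  covariates are handled by a pseudoinverse, so a constant covariate is
  a no-op.

Monomorphic sites are uninformative and report p = 1.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .callset import MISSING, CohortCallset
from .errors import ConfigurationError, DesignError
from .seedless import SEEDED, SEEDLESS

FISHER = "fisher"
LOGISTIC = "logistic_score"


def _logistic_null(y: np.ndarray, Z: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """IRLS fit of the null logistic model; returns fitted
    probabilities. Uses a pseudoinverse so rank-deficient designs
    (duplicated/constant covariates) behave like their reduced form."""
    beta = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        eta = np.clip(Z @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-10, None)
        # weighted least squares step via pseudoinverse
        zw = Z * w[:, None]
        h = Z.T @ zw
        g = Z.T @ (y - p)
        step = np.linalg.pinv(h) @ g
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(Z @ beta, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def _score_test(y: np.ndarray, x: np.ndarray, Z: np.ndarray) -> float:
    """Two-sided p-value of the logistic score test for dosage ``x``
    given null design ``Z``."""
    p0 = _logistic_null(y, Z)
    w = np.clip(p0 * (1.0 - p0), 1e-10, None)
    u = float(x @ (y - p0))
    zwz = Z.T @ (Z * w[:, None])
    zwx = Z.T @ (x * w)
    v = float(x @ (x * w) - zwx @ np.linalg.pinv(zwz) @ zwx)
    if v <= 0:
        return 1.0
    return float(stats.chi2.sf(u * u / v, df=1))


def associate(
    callset: CohortCallset,
    phenotypes: Mapping[str, str],
    method: str = FISHER,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP association of genotype with the seeded/seedless trait.

    Every sample in the call set must have a phenotype in
    {``seeded``, ``seedless``}; both classes need >= 2 samples.
    ``covariates`` (samples x k) applies to the logistic method only.
    Returns a table with chrom, pos, method, p_value, neg_log10_p and
    effect_direction (sign of alternate-allele enrichment in cases).
    """
    if method not in (FISHER, LOGISTIC):
        raise ConfigurationError(f"unknown association method {method!r}")
    try:
        ph = np.array([phenotypes[s] for s in callset.samples], dtype=object)
    except KeyError as exc:
        raise DesignError(f"phenotype unknown for sample {exc}") from exc
    bad = ~np.isin(ph, (SEEDED, SEEDLESS))
    if bad.any():
        raise DesignError(
            f"sample {callset.samples[int(np.flatnonzero(bad)[0])]} has no usable phenotype"
        )
    case = (ph == SEEDLESS).astype(float)
    if case.sum() < 2 or (1 - case).sum() < 2:
        raise DesignError("need at least 2 samples in each phenotype class")

    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != callset.n_samples:
            raise ConfigurationError("covariate rows must match samples")
    else:
        cov = np.zeros((callset.n_samples, 0))

    gt = callset.gt
    called = gt != MISSING
    rows = []
    for i in range(callset.n_sites):
        ok = called[i]
        g = gt[i, ok].astype(float)
        y = case[ok]
        n_case = y.sum()
        n_ctrl = len(y) - n_case
        alt_case = float(g[y == 1].sum())
        alt_ctrl = float(g[y == 0].sum())
        total_alt = alt_case + alt_ctrl
        total_ref = 2.0 * len(y) - total_alt
        if n_case == 0 or n_ctrl == 0 or total_alt == 0 or total_ref == 0:
            p = 1.0
            direction = 0
        else:
            f_case = alt_case / (2.0 * n_case)
            f_ctrl = alt_ctrl / (2.0 * n_ctrl)
            direction = int(np.sign(f_case - f_ctrl))
            if method == FISHER:
                table = [
                    [int(round(alt_case)), int(round(2 * n_case - alt_case))],
                    [int(round(alt_ctrl)), int(round(2 * n_ctrl - alt_ctrl))],
                ]
                p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            else:
                Z = np.column_stack([np.ones(len(y)), np.asarray(cov)[ok]])
                p = _score_test(y, g, Z)
        p = min(max(p, 1e-300), 1.0)
        rows.append(
            (callset.chrom[i], int(callset.pos[i]), method, p, -np.log10(p), direction)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "method", "p_value", "neg_log10_p", "effect_direction"],
    )
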