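"""Population summaries: distance-based phylogenetics, LD decay, and
sliding-window F_ST.

Phylogenetics uses a diploid *p*-distance with pairwise deletion: per
sample pair, sites where either genotype is missing are skipped; at the
remaining sites the similarity of two unphased diploid genotypes is the
fraction of shared alleles (0, 1/2 or 1), and distance is one minus the
mean similarity. Trees come from the canonical Saitou–Nei
neighbor-joining agglomeration; on additive distances the tree
reproduces the input matrix exactly. Branch support is the percentage
of site-bootstrap replicates whose NJ tree contains the same
bipartition.

LD is the squared Pearson correlation of alternate-allele dosages
between intra-chromosomal site pairs, averaged within 100-bp distance
bins; the half-decay distance is where the binned curve first falls to
the midpoint of its range.

Population differentiation is the Weir–Cockerham (1984) F_ST with the
ratio-of-sums ("weighted") window estimator: per-SNP variance
components a (among populations), b (among individuals within
populations) and c (within individuals) are summed over the SNPs in
each window and the window statistic is sum(a) / sum(a+b+c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .callset import HET, MISSING, CohortCallset
from .errors import ConfigurationError, DataError, RegionError

# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Pairwise diploid p-distances with per-pair site counts."""

    labels: list[str]
    d: np.ndarray
    n_sites_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DataError("distance matrix must have a zero diagonal")
        if np.any(self.d < 0):
            raise DataError("distances must be non-negative")


def _pair_arrays(gt: np.ndarray):
    """Per-pair absolute dosage difference and validity mask,
    shaped (n_pairs, n_sites); pairs enumerate i<j row-major."""
    n_sites, n_samples = gt.shape
    pairs = [(i, j) for i in range(n_samples) for j in range(i + 1, n_samples)]
    g = gt.astype(np.float64).T  # samples x sites
    called = gt.T != MISSING
    diff = np.empty((len(pairs), n_sites))
    valid = np.empty((len(pairs), n_sites))
    for k, (i, j) in enumerate(pairs):
        v = called[i] & called[j]
        valid[k] = v
        diff[k] = np.where(v, np.abs(g[i] - g[j]) / 2.0, 0.0)
    return pairs, diff, valid


def p_distance(callset: CohortCallset) -> DistanceMatrix:
    """Diploid p-distance matrix with pairwise deletion.

    Per site, two unphased diploid genotypes share 2, 1 or 0 alleles;
    with dosage codes this is ``1 - |g_i - g_j| / 2``. A pair with no
    jointly called site has an undefined distance and raises
    :class:`DataError`.
    """
    if callset.n_samples < 2 or callset.n_sites < 1:
        raise DataError("p-distance needs >= 2 samples and >= 1 site")
    pairs, diff, valid = _pair_arrays(callset.gt)
    n_used = valid.sum(axis=1)
    if np.any(n_used == 0):
        k = int(np.flatnonzero(n_used == 0)[0])
        i, j = pairs[k]
        raise DataError(
            f"samples {callset.samples[i]} and {callset.samples[j]} share no called sites"
        )
    dvals = diff.sum(axis=1) / n_used
    n = callset.n_samples
    d = np.zeros((n, n))
    counts = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        d[i, j] = d[j, i] = dvals[k]
        counts[i, j] = counts[j, i] = n_used[k]
    return DistanceMatrix(list(callset.samples), d, counts)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap supports.

    ``supports`` maps an internal-edge bipartition — the frozenset of
    tip names on the side not containing the first label — to the
    percentage of bootstrap replicates containing that bipartition.
    """

    root: TreeNode
    supports: dict[frozenset, float] | None = None

    @property
    def labels(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def tip_distances(self) -> DistanceMatrix:
        dm = self.root.tip_tip_distances()
        ids = list(dm.ids)
        return DistanceMatrix(ids, np.asarray(dm.data, dtype=float))

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.root)

    def newick(self) -> str:
        """Newick string; bootstrap supports, when present, become
        internal-node labels."""
        tree = self.root.copy()
        if self.supports is not None:
            all_tips = frozenset(t.name for t in tree.tips())
            ref = sorted(all_tips)[0]
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = all_tips - side
                if side in self.supports:
                    node.name = str(int(round(self.supports[side])))
        return str(tree).strip()


def tree_bipartitions(root: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each normalised to
    the side not containing the lexicographically first tip."""
    all_tips = frozenset(t.name for t in root.tips())
    ref = sorted(all_tips)[0]
    out: set[frozenset] = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(side)
    return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining on the Q-criterion.

    Negative branch-length estimates are clamped to zero with the
    deficit transferred to the sister edge, so the joined pair's total
    length is preserved. The returned tree is unrooted (trifurcating
    root node).
    """
    n = len(dm.labels)
    if n < 3:
        raise DataError("neighbor joining needs at least 3 labels")
    D = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        nodes.append(new)
        new_idx = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root)


def bootstrap_supports(
    callset: CohortCallset, n_reps: int = 1000, seed: int | None = None
) -> PhyloTree:
    """NJ tree with site-bootstrap branch supports.

    Sites are resampled with replacement ``n_reps`` times (equivalently
    multinomially reweighted); each internal edge's support is the
    percentage of replicate trees containing the same bipartition.
    Deterministic given the seed.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    if callset.n_samples < 4:
        raise DataError("bootstrap supports need >= 4 samples")
    rng = np.random.default_rng(seed)
    pairs, diff, valid = _pair_arrays(callset.gt)
    n_sites = callset.n_sites
    labels = list(callset.samples)

    def dm_from_weights(w: np.ndarray) -> DistanceMatrix:
        num = diff @ w
        den = valid @ w
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
        n = len(labels)
        d = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = vals[k]
        return DistanceMatrix(labels, d)

    reference = neighbor_joining(dm_from_weights(np.ones(n_sites)))
    ref_biparts = reference.bipartitions()
    hits = {bp: 0 for bp in ref_biparts}
    probs = np.full(n_sites, 1.0 / n_sites)
    for _ in range(n_reps):
        w = rng.multinomial(n_sites, probs).astype(float)
        rep = neighbor_joining(dm_from_weights(w))
        for bp in rep.bipartitions():
            if bp in hits:
                hits[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in hits.items()}
    return PhyloTree(root=reference.root, supports=supports)


def region_tree(
    callset: CohortCallset,
    chrom: str,
    center: int,
    flank: int = 50_000,
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[PhyloTree, int]:
    """NJ tree (with bootstrap) from the SNPs in
    ``[center - flank, center + flank]``. Returns the tree and the SNP
    count used."""
    window = (callset.chrom == chrom) & (np.abs(callset.pos - center) <= flank)
    if not window.any():
        raise RegionError(f"no SNPs in {chrom}:{center - flank}-{center + flank}")
    sub = callset.take_sites(window)
    if n_reps > 0 and sub.n_samples >= 4:
        tree = bootstrap_supports(sub, n_reps=n_reps, seed=seed)
    else:
        tree = neighbor_joining(p_distance(sub))
    return tree, sub.n_sites


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def _pairwise_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """r^2 between dosage vector ``x`` and each row of ``Y`` over
    pairwise-complete samples; NaN where undefined."""
    mask = ~np.isnan(x)[None, :] & ~np.isnan(Y)
    n = mask.sum(axis=1).astype(float)
    xm = np.where(mask, x[None, :], 0.0)
    ym = np.where(mask, Y, 0.0)
    sx = xm.sum(axis=1)
    sy = ym.sum(axis=1)
    sxx = (xm * xm).sum(axis=1)
    syy = (ym * ym).sum(axis=1)
    sxy = (xm * ym).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


def ld_decay(
    callset: CohortCallset,
    max_dist: int,
    bin_size: int = 100,
) -> tuple[pd.DataFrame, float]:
    """Binned r^2 decay curve and half-decay distance.

    r^2 is computed for every intra-chromosomal site pair at distance
    <= ``max_dist`` (monomorphic pairs are skipped as undefined) and
    averaged within ``bin_size``-bp distance blocks. The half-decay
    distance is the smallest bin midpoint whose mean r^2 falls to or
    below the midpoint of the binned curve's range.
    """
    if callset.n_sites < 2:
        raise DataError("LD decay needs at least two sites")
    dos = callset.dosage()
    n_bins = max_dist // bin_size + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in pd.unique(callset.chrom):
        idx = np.flatnonzero(callset.chrom == c)
        if len(idx) < 2:
            continue
        order = idx[np.argsort(callset.pos[idx], kind="mergesort")]
        pos = callset.pos[order]
        mat = dos[order]
        hi = 0
        for a in range(len(order) - 1):
            while hi < len(order) and pos[hi] - pos[a] <= max_dist:
                hi += 1
            if hi <= a + 1:
                continue
            r2 = _pairwise_r2(mat[a], mat[a + 1 : hi])
            dist = (pos[a + 1 : hi] - pos[a]).astype(np.int64)
            ok = ~np.isnan(r2)
            if ok.any():
                b = dist[ok] // bin_size
                np.add.at(sums, b, r2[ok])
                np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    bins = pd.DataFrame(
        {
            "dist_lo": np.arange(n_bins) * bin_size,
            "dist_hi": (np.arange(n_bins) + 1) * bin_size,
            "mean_r2": means,
            "n_pairs": counts,
        }
    )
    observed = bins.dropna(subset=["mean_r2"])
    if len(observed) == 0:
        raise DataError("no polymorphic site pairs within max_dist")
    level = (observed["mean_r2"].max() + observed["mean_r2"].min()) / 2.0
    below = observed[observed["mean_r2"] <= level]
    half = float((below["dist_lo"].iloc[0] + below["dist_hi"].iloc[0]) / 2.0)
    return bins, half


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def wc_components(
    callset: CohortCallset, pop_a: Sequence[str], pop_b: Sequence[str]
) -> pd.DataFrame:
    """Per-SNP Weir–Cockerham (1984) variance components for two
    populations: ``a`` among populations, ``b`` among individuals
    within populations, ``c`` within individuals. Sites monomorphic
    across both populations get a = b = c = 0."""
    set_a, set_b = set(pop_a), set(pop_b)
    if set_a & set_b:
        raise ConfigurationError("populations must be disjoint")
    if len(set_a) < 2 or len(set_b) < 2:
        raise ConfigurationError("each population needs at least 2 samples")
    ja = [callset.samples.index(s) for s in pop_a]
    jb = [callset.samples.index(s) for s in pop_b]

    comps = {}
    for tag, jj in (("a_pop", ja), ("b_pop", jb)):
        gt = callset.gt[:, jj]
        called = gt != MISSING
        n = called.sum(axis=1).astype(float)  # individuals sampled
        alt = np.where(called, gt, 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
            h = np.where(n > 0, (called & (gt == HET)).sum(axis=1) / n, np.nan)
        comps[tag] = (n, p, h)

    n1, p1, h1 = comps["a_pop"]
    n2, p2, h2 = comps["b_pop"]
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    usable = (n1 >= 1) & (n2 >= 1) & (n_bar > 1)
    mono = usable & np.isclose(s2, 0.0) & ((p_bar <= 0) | (p_bar >= 1)) & np.isclose(h_bar, 0.0)
    informative = usable & ~mono
    a = np.where(informative, a, 0.0)
    b = np.where(informative, b, 0.0)
    c = np.where(informative, c, 0.0)
    return pd.DataFrame(
        {
            "chrom": callset.chrom,
            "pos": callset.pos,
            "a": a,
            "b": b,
            "c": c,
            "informative": informative,
        }
    )


def site_fst(callset: CohortCallset, pop_a: Sequence[str], pop_b: Sequence[str]) -> np.ndarray:
    """Per-SNP Weir–Cockerham F_ST = a / (a+b+c), NaN where
    uninformative."""
    comp = wc_components(callset, pop_a, pop_b)
    denom = comp["a"] + comp["b"] + comp["c"]
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = comp["a"] / denom
    fst[~comp["informative"] | (denom == 0)] = np.nan
    return fst.to_numpy()


def windowed_fst(
    callset: CohortCallset,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    window: int = 100_000,
    step: int = 10_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window weighted Weir–Cockerham F_ST scan.

    Windows of ``window`` bp tile each chromosome at ``step`` bp;
    window F_ST is sum(a) / sum(a+b+c) over the SNPs inside (the
    ratio-of-sums estimator). Output coordinates are 0-based half-open;
    windows without informative SNPs have NaN scores.
    """
    if window <= 0 or step <= 0:
        raise ConfigurationError("window and step must be positive")
    comp = wc_components(callset, pop_a, pop_b)
    rows = []
    for c in pd.unique(callset.chrom):
        sel = comp["chrom"] == c
        pos = comp.loc[sel, "pos"].to_numpy()
        a = comp.loc[sel, "a"].to_numpy()
        abc = a + comp.loc[sel, "b"].to_numpy() + comp.loc[sel, "c"].to_numpy()
        informative = comp.loc[sel, "informative"].to_numpy()
        length = (
            int(chrom_lengths[c]) if chrom_lengths and c in chrom_lengths else int(pos.max())
        )
        start = 0
        while start < length:
            end = min(start + window, length)
            in_w = (pos - 1 >= start) & (pos - 1 < end)
            n_snps = int((in_w & informative).sum())
            num = a[in_w].sum()
            den = abc[in_w].sum()
            score = num / den if den != 0 else np.nan
            rows.append((c, start, end, n_snps, score))
            if start + window >= length:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "score"])
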