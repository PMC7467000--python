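"""Distance-based phylogenetics, LD decay and Weir-Cockerham F_ST."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from vitivar.callset import HET, HOM_ALT, HOM_REF, MISSING, phenotype_map
from vitivar.errors import ConfigurationError, DataError, RegionError
from vitivar.popgen import (
    DistanceMatrix,
    bootstrap_supports,
    ld_decay,
    neighbor_joining,
    p_distance,
    region_tree,
    site_fst,
    tree_bipartitions,
    wc_components,
    windowed_fst,
)
from vitivar.seedless import SEEDLESS

from conftest import make_callset

# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


def test_p_distance_allele_sharing_values():
    gt = np.array([[HOM_REF, HOM_REF, HOM_ALT, HET]])
    cs = make_callset(gt, samples=list("abcd"))
    dm = p_distance(cs)
    i = {l: k for k, l in enumerate(dm.labels)}
    assert dm.d[i["a"], i["b"]] == 0.0  # identical
    assert dm.d[i["a"], i["c"]] == 1.0  # hom-ref vs hom-alt
    assert dm.d[i["a"], i["d"]] == 0.5  # hom vs het shares one allele


def test_p_distance_pairwise_deletion():
    gt = np.array([[0, 2], [1, MISSING], [2, 2]])
    cs = make_callset(gt, samples=["a", "b"])
    dm = p_distance(cs)
    # only sites 1 and 3 comparable: distances 1 and 0 -> mean 0.5
    assert dm.d[0, 1] == pytest.approx(0.5)
    assert dm.n_sites_used[0, 1] == 2
    # with no missing data, deletion is a no-op
    full = make_callset(np.array([[0, 2], [2, 2]]), samples=["a", "b"])
    assert p_distance(full).d[0, 1] == pytest.approx(0.5)


def test_p_distance_undefined_pair_raises():
    gt = np.array([[0, MISSING], [MISSING, 1]])
    cs = make_callset(gt, samples=["a", "b"])
    with pytest.raises(DataError):
        p_distance(cs)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _tree_distance_matrix(tree, labels):
    dm = tree.tip_distances()
    idx = [dm.labels.index(l) for l in labels]
    return dm.d[np.ix_(idx, idx)]


def _brute_force_quartet(d):
    """Best-fit branch lengths for each of the 3 quartet topologies via
    least squares; returns the topology with zero residual."""
    # paths for topology ((0,1),(2,3)) with edges [l0,l1,l2,l3,internal]
    paths = {
        ((0, 1), (2, 3)): {
            (0, 1): [1, 1, 0, 0, 0],
            (0, 2): [1, 0, 1, 0, 1],
            (0, 3): [1, 0, 0, 1, 1],
            (1, 2): [0, 1, 1, 0, 1],
            (1, 3): [0, 1, 0, 1, 1],
            (2, 3): [0, 0, 1, 1, 0],
        }
    }
    results = []
    for split in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        perm = list(split[0]) + list(split[1])
        A, y = [], []
        for (i, j), row in paths[((0, 1), (2, 3))].items():
            A.append(row)
            y.append(d[perm[i], perm[j]])
        sol, res, *_ = np.linalg.lstsq(np.array(A, float), np.array(y), rcond=None)
        fitted = np.array(A) @ sol
        results.append((split, sol, float(np.abs(fitted - np.array(y)).max())))
    results.sort(key=lambda t: t[2])
    return results[0]


def test_four_taxon_quartet_matches_brute_force():
    d = np.array(
        [
            [0.0, 0.2, 0.6, 0.6],
            [0.2, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.2],
            [0.6, 0.6, 0.2, 0.0],
        ]
    )
    split, lengths, resid = _brute_force_quartet(d)
    assert split == ((0, 1), (2, 3)) and resid < 1e-12
    assert np.allclose(lengths[:4], 0.1) and lengths[4] == pytest.approx(0.4)

    tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
    assert tree_bipartitions(tree.root) == {frozenset({"C", "D"})}
    recovered = _tree_distance_matrix(tree, list("ABCD"))
    assert np.allclose(recovered, d, atol=1e-9)


def test_three_taxon_closed_form():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
    tree = neighbor_joining(DistanceMatrix(list("xyz"), d))
    lengths = {t.name: t.length for t in tree.root.tips()}
    assert lengths["x"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
    assert lengths["y"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
    assert lengths["z"] == pytest.approx((0.5 + 0.4 - 0.3) / 2)


def _random_additive_tree(rng, n_taxa):
    """Random binary tree; returns (labels, distance matrix,
    bipartitions) computed by path lengths, independently of NJ."""
    labels = [f"t{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    # assemble a random rooted topology, then measure leaf path lengths
    parent = {}
    lengths = {}
    next_id = n_taxa
    ids = list(range(n_taxa))
    while len(ids) > 1:
        i = ids.pop(rng.integers(len(ids)))
        j = ids.pop(rng.integers(len(ids)))
        for child in (i, j):
            parent[child] = next_id
            lengths[child] = float(rng.uniform(0.05, 1.0))
        ids.append(next_id)
        next_id += 1

    def path_to_root(v):
        out = []
        while v in parent:
            out.append((v, lengths[v]))
            v = parent[v]
        out.append((v, 0.0))
        return out

    for a in range(n_taxa):
        pa = path_to_root(a)
        anc_a = {v: sum(l for _, l in pa[:k]) for k, (v, _) in enumerate(pa)}
        for b in range(a + 1, n_taxa):
            pb = path_to_root(b)
            acc = 0.0
            for v, l in pb:
                if v in anc_a:
                    D[a, b] = D[b, a] = anc_a[v] + acc
                    break
                acc += l
    # bipartitions: leaf sets under each internal node
    children = {}
    for child, par in parent.items():
        children.setdefault(par, []).append(child)

    def leafset(v):
        if v < n_taxa:
            return {v}
        out = set()
        for c in children[v]:
            out |= leafset(c)
        return out

    all_leaves = frozenset(range(n_taxa))
    biparts = set()
    for v in children:
        side = frozenset(leafset(v))
        if 2 <= len(side) <= n_taxa - 2:
            norm = side if 0 not in side else all_leaves - side
            biparts.add(frozenset(labels[k] for k in norm))
    return labels, D, biparts


def test_random_additive_trees_recovered_exactly():
    rng = np.random.default_rng(42)
    for rep in range(50):
        n_taxa = int(rng.integers(6, 11))
        labels, D, biparts = _random_additive_tree(rng, n_taxa)
        tree = neighbor_joining(DistanceMatrix(labels, D))
        assert np.allclose(_tree_distance_matrix(tree, labels), D, atol=1e-9)
        assert tree_bipartitions(tree.root) == biparts


def test_nj_agrees_with_independent_implementation():
    rng = np.random.default_rng(7)
    labels, D, _ = _random_additive_tree(rng, 8)
    ours = neighbor_joining(DistanceMatrix(labels, D))
    theirs = skbio_nj(SkbioDM(D, ids=labels))
    their_dm = theirs.tip_tip_distances()
    idx = [list(their_dm.ids).index(l) for l in labels]
    assert np.allclose(
        _tree_distance_matrix(ours, labels), np.asarray(their_dm.data)[np.ix_(idx, idx)], atol=1e-9
    )


def test_nj_input_validation():
    with pytest.raises(DataError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    with pytest.raises(DataError):
        DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]]))
    with pytest.raises(DataError):
        DistanceMatrix(["a", "b"], np.array([[0, -0.1], [-0.1, 0]]))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _two_cluster_callset(n_sites=300, n_per=4, seed=0):
    rng = np.random.default_rng(seed)
    gt = rng.integers(0, 2, (n_sites, 2 * n_per)).astype(np.int8)
    gt[: n_sites // 2, n_per:] = 2  # strong divergence between halves
    return make_callset(gt, samples=[f"s{i}" for i in range(2 * n_per)])


def test_bootstrap_saturated_split_and_determinism():
    cs = _two_cluster_callset()
    t1 = bootstrap_supports(cs, n_reps=100, seed=5)
    t2 = bootstrap_supports(cs, n_reps=100, seed=5)
    assert t1.supports == t2.supports
    split = frozenset({"s4", "s5", "s6", "s7"})
    assert t1.supports[split] == 100.0
    newick = t1.newick()
    assert "100" in newick and newick.endswith(";")


def test_bootstrap_invariant_to_sample_order():
    cs = _two_cluster_callset()
    perm = [3, 0, 6, 1, 7, 2, 5, 4]
    shuffled = cs.take_samples([cs.samples[i] for i in perm])
    t1 = bootstrap_supports(cs, n_reps=50, seed=9)
    t2 = bootstrap_supports(shuffled, n_reps=50, seed=9)
    assert t1.supports == t2.supports


def test_star_data_has_no_strong_support():
    """All pairwise distances equal by construction (private alleles
    only) -> star-like tree, so no bipartition should reach high
    support."""
    n, copies = 6, 10
    gt = np.zeros((n * copies, n), dtype=np.int8)
    for i in range(n):
        gt[i * copies : (i + 1) * copies, i] = 2  # sample-private sites
    cs = make_callset(gt, samples=[f"s{i}" for i in range(n)])
    d = p_distance(cs).d
    off = d[~np.eye(n, dtype=bool)]
    assert np.allclose(off, off[0])
    t = bootstrap_supports(cs, n_reps=200, seed=3)
    assert all(v <= 80.0 for v in t.supports.values())


def test_bootstrap_validation():
    cs = _two_cluster_callset()
    with pytest.raises(ConfigurationError):
        bootstrap_supports(cs, n_reps=0)


# ---------------------------------------------------------------------------
# region trees
# ---------------------------------------------------------------------------


def test_region_tree_separates_seedless_clade(default_cohort):
    params, cs, truth, meta = default_cohort
    chrom, centre = truth.trait_model.dominant_locus.split(":")
    tree, n_snps = region_tree(
        cs, chrom, int(centre), flank=params.trait_flank, n_reps=0
    )
    assert n_snps > 10
    phen = phenotype_map(meta)
    seedless = frozenset(s for s in cs.samples if phen[s] == SEEDLESS)
    assert seedless in tree_bipartitions(tree.root) or (
        frozenset(cs.samples) - seedless
    ) in tree_bipartitions(tree.root)


def test_region_tree_errors_and_whole_genome_equivalence(default_cohort):
    params, cs, truth, meta = default_cohort
    with pytest.raises(RegionError):
        region_tree(cs, "chr1", 10, flank=1, n_reps=0)
    sub = cs.take_samples(cs.samples[:8])
    whole, n = region_tree(sub, "chr1", 500_000, flank=10**9, n_reps=0)
    assert n == (sub.chrom == "chr1").sum()
    direct = neighbor_joining(p_distance(sub.take_sites(sub.chrom == "chr1")))
    assert tree_bipartitions(whole.root) == tree_bipartitions(direct.root)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


def test_duplicated_columns_have_r2_one():
    rng = np.random.default_rng(2)
    col = rng.integers(0, 3, 28).astype(np.int8)
    gt = np.vstack([col, col])
    cs = make_callset(gt, pos=np.array([1000, 1500]))
    bins, _ = ld_decay(cs, max_dist=1000)
    filled = bins.dropna(subset=["mean_r2"])
    assert len(filled) == 1
    assert filled["mean_r2"].iloc[0] == pytest.approx(1.0)


def test_r2_invariant_under_allele_label_swap():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 3, 28).astype(np.int8)
    b = rng.integers(0, 3, 28).astype(np.int8)
    cs1 = make_callset(np.vstack([a, b]), pos=np.array([100, 300]))
    cs2 = make_callset(np.vstack([2 - a, b]), pos=np.array([100, 300]))
    r1 = ld_decay(cs1, max_dist=500)[0].dropna(subset=["mean_r2"])["mean_r2"].iloc[0]
    r2 = ld_decay(cs2, max_dist=500)[0].dropna(subset=["mean_r2"])["mean_r2"].iloc[0]
    assert r1 == pytest.approx(r2)


def test_independent_sites_mean_r2_near_one_over_n_minus_one():
    """For independent dosage columns over n samples, E[r^2] is exactly
    1/(n-1) (exchangeability); the empirical mean over ~10,000 pairs
    must fall within 3 standard errors."""
    rng = np.random.default_rng(8)
    n_samples, n_sites = 28, 2200
    gt = rng.binomial(2, 0.5, (n_sites, n_samples)).astype(np.int8)
    cs = make_callset(gt, pos=np.arange(n_sites) * 50 + 1)
    bins, _ = ld_decay(cs, max_dist=500)
    n_pairs = bins["n_pairs"].sum()
    assert n_pairs >= 10_000
    mean_r2 = (bins["mean_r2"] * bins["n_pairs"]).sum() / n_pairs
    expect = 1.0 / (n_samples - 1)
    se = np.sqrt(2) * expect / np.sqrt(n_pairs)  # var(r^2) ~ 2/(n-1)^2
    assert abs(mean_r2 - expect) < 3 * se


def test_decaying_ld_gives_monotone_curve():
    """Haplotype copying with distance-decaying fidelity produces a
    nonincreasing binned r^2 curve."""
    rng = np.random.default_rng(5)
    n_samples, n_blocks = 40, 120
    sites_per_block = 12
    gap = 400
    rows, positions = [], []
    for b in range(n_blocks):
        anchor = rng.binomial(2, 0.5, n_samples)
        for k in range(sites_per_block):
            fid = max(0.0, 1.0 - 0.22 * k)
            copy = rng.random(n_samples) < fid
            col = np.where(copy, anchor, rng.binomial(2, 0.5, n_samples))
            rows.append(col)
            positions.append(b * 100_000 + k * gap + 1)
    cs = make_callset(np.array(rows, dtype=np.int8), pos=np.array(positions))
    bins, half = ld_decay(cs, max_dist=sites_per_block * gap, bin_size=gap)
    curve = bins.dropna(subset=["mean_r2"])["mean_r2"].to_numpy()
    from scipy.stats import spearmanr

    rho, _ = spearmanr(np.arange(len(curve)), curve)
    assert rho < -0.8
    assert 0 < half < sites_per_block * gap


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def _wc_fst_scalar(n1, p1, h1, n2, p2, h2):
    """Independent transcription of the two-population Weir-Cockerham
    variance components, kept deliberately scalar and explicit."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def _gt_for_freq(n, p, rng):
    """Genotypes with observed heterozygosity exactly 2p(1-p) is not
    enforceable for all n; sample instead."""
    return (rng.random(n) < p).astype(int) + (rng.random(n) < p).astype(int)


def test_single_snp_matches_independent_formula():
    """n1=n2=10, p1=0.9, p2=0.1, HWE heterozygosity: the implementation
    must match an independent transcription to 1e-12."""
    # construct genotypes realising exactly p=0.9 (n=10: 8 hom + 2 het
    # -> 18 alt alleles) and h = 2p(1-p) = 0.18 is not integral; use
    # h = 0.2 (2 hets) and feed the same h to the oracle.
    pop1 = [HOM_ALT] * 8 + [HET] * 2  # p1 = 0.9, h1 = 0.2
    pop2 = [HOM_REF] * 8 + [HET] * 2  # p2 = 0.1, h2 = 0.2
    gt = np.array([pop1 + pop2], dtype=np.int8)
    cs = make_callset(gt, samples=[f"x{i}" for i in range(20)])
    pops = ([f"x{i}" for i in range(10)], [f"x{i}" for i in range(10, 20)])
    fst = site_fst(cs, *pops)[0]
    oracle = _wc_fst_scalar(10, 0.9, 0.2, 10, 0.1, 0.2)
    assert fst == pytest.approx(oracle, abs=1e-12)


def test_fixed_difference_gives_fst_one():
    gt = np.zeros((5, 8), dtype=np.int8)
    gt[:, 4:] = HOM_ALT
    cs = make_callset(gt)
    pops = ([f"S{i + 1}" for i in range(4)], [f"S{i + 1}" for i in range(4, 8)])
    assert np.allclose(site_fst(cs, *pops), 1.0)
    scan = windowed_fst(cs, *pops, window=100_000, step=10_000)
    assert scan["score"].dropna().iloc[0] == pytest.approx(1.0)


def test_null_populations_mean_window_fst_near_zero():
    """Populations drawn from identical allele frequencies: the mean of
    the (non-overlapping) window ratio-of-sums estimates sits within 3
    standard errors of zero, and negative values occur."""
    rng = np.random.default_rng(12)
    n_sites = 10_000
    p = rng.uniform(0.1, 0.9, n_sites)
    gt = (rng.random((n_sites, 20)) < p[:, None]).astype(np.int8) + (
        rng.random((n_sites, 20)) < p[:, None]
    ).astype(np.int8)
    cs = make_callset(gt, pos=np.arange(n_sites) * 100 + 1, samples=[f"n{i}" for i in range(20)])
    pops = ([f"n{i}" for i in range(10)], [f"n{i}" for i in range(10, 20)])
    scan = windowed_fst(cs, *pops, window=10_000, step=10_000)
    scores = scan["score"].dropna()
    se = scores.std(ddof=1) / np.sqrt(len(scores))
    assert abs(scores.mean()) < 3 * se
    assert (scores < 0).any()


def test_single_snp_window_equals_site_fst():
    rng = np.random.default_rng(4)
    gt = rng.integers(0, 3, (1, 12)).astype(np.int8)
    gt[0, :3] = 0
    gt[0, 6:9] = 2
    cs = make_callset(gt, pos=np.array([5000]))
    pops = ([f"S{i + 1}" for i in range(6)], [f"S{i + 1}" for i in range(6, 12)])
    scan = windowed_fst(cs, *pops, window=100_000, step=100_000)
    assert scan["score"].iloc[0] == pytest.approx(site_fst(cs, *pops)[0], abs=1e-12)


def test_monomorphic_sites_contribute_nothing():
    gt = np.zeros((3, 8), dtype=np.int8)
    gt[1, 4:] = HOM_ALT  # only site 2 is polymorphic
    cs = make_callset(gt)
    pops = ([f"S{i + 1}" for i in range(4)], [f"S{i + 1}" for i in range(4, 8)])
    comp = wc_components(cs, *pops)
    assert not comp.loc[0, "informative"] and not comp.loc[2, "informative"]
    scan = windowed_fst(cs, *pops, window=100_000, step=100_000)
    assert scan["n_snps"].iloc[0] == 1
    assert scan["score"].iloc[0] == pytest.approx(1.0)


def test_fst_population_validation():
    cs = make_callset(np.zeros((1, 4), dtype=np.int8))
    with pytest.raises(ConfigurationError):
        wc_components(cs, ["S1", "S2"], ["S2", "S3"])
    with pytest.raises(ConfigurationError):
        wc_components(cs, ["S1"], ["S2", "S3"])
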