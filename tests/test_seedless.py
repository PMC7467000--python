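"""Inheritance rule, dominant-consistency test, Group assignment,
sweep-peak selection and the candidate report."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vitivar.callset import HET, HOM_ALT, HOM_REF, MISSING
from vitivar.errors import ClassificationError, ConfigurationError, PhenotypeError
from vitivar.seedless import (
    GROUP_I,
    GROUP_II,
    GROUP_III,
    SweepPeak,
    TraitModel,
    assign_group,
    candidate_report,
    classify_sites,
    dominant_consistency,
    peak_windows,
    phenotype_from_genotype,
    scaled_hom_count_high,
)

from conftest import make_callset


def independent_rule(dom, recs, min_hom):
    """Deliberately separate evaluator of the penetrance rule."""
    carries_dominant = dom >= 1
    hom_count = len([g for g in recs if g == 2])
    return "seedless" if (carries_dominant and hom_count >= min_hom) else "seeded"


def test_phenotype_rule_examples():
    model = TraitModel("chr1:1", ("chr2:1", "chr3:1", "chr4:1"), 2)
    assert phenotype_from_genotype(model, [HET, HOM_ALT, HOM_ALT, HOM_REF]) == "seedless"
    assert phenotype_from_genotype(model, [HOM_REF, HOM_ALT, HOM_ALT, HOM_ALT]) == "seeded"
    assert phenotype_from_genotype(model, [HOM_ALT, HOM_ALT, HET, HOM_ALT]) == "seedless"
    with pytest.raises(PhenotypeError):
        phenotype_from_genotype(model, [MISSING, HOM_ALT, HOM_ALT, HOM_ALT])


def test_phenotype_rule_matches_exhaustive_enumeration():
    """All 3^4 = 81 genotype combinations at 1 dominant + 3 recessive
    loci agree with an independently coded evaluator."""
    model = TraitModel("chr1:1", ("chr2:1", "chr3:1", "chr4:1"), 2)
    for combo in itertools.product((0, 1, 2), repeat=4):
        expected = independent_rule(combo[0], combo[1:], 2)
        assert phenotype_from_genotype(model, list(combo)) == expected


def test_trait_model_validation():
    with pytest.raises(ConfigurationError):
        TraitModel("chr1:1", ("chr1:1", "chr2:1"), 1)
    with pytest.raises(ConfigurationError):
        TraitModel("chr1:1", ("chr2:1",), 2)


def test_dominant_consistency_printed_pattern():
    gt = np.array([HET] * 15 + [HOM_REF] * 11 + [MISSING] * 2)
    phen = ["seedless"] * 15 + ["seeded"] * 13
    res = dominant_consistency(gt, phen)
    assert res.consistent
    assert res.n_seedless_carrier == 15 and res.n_seeded_called == 11


def test_dominant_consistency_direct_violation():
    gt = np.array([HOM_REF] + [HET] * 14 + [HOM_REF] * 13)
    phen = ["seedless"] * 15 + ["seeded"] * 13
    assert not dominant_consistency(gt, phen).consistent


def test_dominant_consistency_brute_force_enumeration():
    """All 4^5 genotype vectors for 3 seedless + 2 seeded samples match
    an independently coded evaluator."""
    phen = ["seedless"] * 3 + ["seeded"] * 2

    def oracle(v):
        for g, ph in zip(v, phen):
            if g == MISSING:
                continue
            if ph == "seedless" and g not in (HET, HOM_ALT):
                return False
            if ph == "seeded" and g != HOM_REF:
                return False
        return True

    for v in itertools.product((-1, 0, 1, 2), repeat=5):
        assert dominant_consistency(np.array(v), phen).consistent == oracle(v), v


def test_dominant_consistency_monotone_in_missingness():
    """Setting any genotype to missing never flips TRUE -> FALSE."""
    rng = np.random.default_rng(0)
    phen = ["seedless"] * 4 + ["seeded"] * 3
    for _ in range(200):
        v = rng.integers(-1, 3, 7)
        base = dominant_consistency(v, phen).consistent
        if not base:
            continue
        for j in range(7):
            w = v.copy()
            w[j] = MISSING
            assert dominant_consistency(w, phen).consistent


def test_assign_group_examples_and_tie():
    assert assign_group(3.0, 12, 15) == GROUP_I
    assert assign_group(3.0, 7, 15) == GROUP_II
    assert assign_group(2.0, 14, 15) == GROUP_III
    assert assign_group(2.5, 14, 15) == GROUP_III  # boundary goes to III
    assert assign_group(3.0, 10, 15) == GROUP_II  # exact tie: conservative
    with pytest.raises(ClassificationError):
        assign_group(float("nan"), 5, 15)


def test_group_count_threshold_scales_with_cohort():
    assert scaled_hom_count_high(10, 15, 15) == 10
    assert scaled_hom_count_high(10, 30, 15) == 20
    assert scaled_hom_count_high(10, 8, 15) == 5  # 5.33 rounds half-up to 5
    assert scaled_hom_count_high(10, 9, 15) == 6
    assert assign_group(3.0, 6, 9) == GROUP_II
    assert assign_group(3.0, 7, 9) == GROUP_I


def test_classify_sites_partitions_and_counts():
    samples = [f"c{i}" for i in range(15)] + [f"k{i}" for i in range(13)]
    phen = {s: ("seedless" if s.startswith("c") else "seeded") for s in samples}
    rows = [
        [HOM_ALT] * 12 + [HET] * 3 + [HOM_REF] * 12 + [HET],  # I
        [HOM_ALT] * 7 + [HOM_REF] * 8 + [HOM_REF] * 13,  # II
        [HOM_ALT] * 14 + [MISSING] + [HOM_REF] * 13,  # I (missing not hom)
        [HET] * 15 + [HOM_REF] * 13,  # dominant-consistent pattern
        [HOM_ALT] * 15 + [HOM_REF] * 13,  # gate: low assoc -> III
    ]
    cs = make_callset(np.array(rows, dtype=np.int8), samples=samples,
                      deleterious=np.array([True] * 5))
    assoc = pd.DataFrame(
        {"chrom": cs.chrom, "pos": cs.pos, "neg_log10_p": [3.0, 3.0, 3.0, 3.0, 1.5]}
    )
    out = classify_sites(cs, phen, assoc)
    assert out["group"].tolist() == ["I", "II", "I", "dominant_consistent", "III"]
    assert out["n_seedless_hom_alt"].tolist() == [12, 7, 14, 0, 15]
    # groups partition the classified set
    assert out["group"].isin(["I", "II", "III", "dominant_consistent"]).all()


def test_classify_requires_association():
    samples = [f"c{i}" for i in range(2)] + [f"k{i}" for i in range(2)]
    phen = {s: ("seedless" if s.startswith("c") else "seeded") for s in samples}
    cs = make_callset(np.ones((1, 4), dtype=np.int8), samples=samples,
                      deleterious=np.array([True]))
    with pytest.raises(ClassificationError):
        classify_sites(cs, phen, pd.DataFrame(columns=["chrom", "pos", "neg_log10_p"]))


def _scan(scores, chrom="chr1", window=100_000, step=10_000):
    starts = np.arange(len(scores)) * step
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window,
            "n_snps": 10,
            "score": scores,
        }
    )


def test_peak_windows_single_planted_region():
    scores = np.full(400, 0.01)
    scores[200:210] = [0.5, 0.6, 0.9, 0.7, 0.6, 0.5, 0.45, 0.44, 0.43, 0.42]
    peaks = peak_windows(_scan(scores), top_fraction=0.005, flank=50_000)
    assert len(peaks) == 1
    best = 202
    assert peaks[0].peak_pos == best * 10_000 + 50_000


def test_peak_windows_two_distant_regions_not_merged():
    scores = np.full(1000, 0.01)
    scores[100] = 0.9
    scores[100 + 150] = 0.85  # 1.5 Mb away
    peaks = peak_windows(_scan(scores, window=10_000, step=10_000), top_fraction=0.002)
    assert len(peaks) == 2


def test_peak_windows_uniform_scores_deterministic():
    scores = np.full(200, 0.3)
    peaks = peak_windows(_scan(scores, window=10_000, step=10_000), top_fraction=0.005)
    # ceil(0.005 * 200) = 1 top window; ties broken by genome order
    assert len(peaks) == 1 and peaks[0].peak_pos == 5_000
    with pytest.raises(ConfigurationError):
        peak_windows(_scan(scores), top_fraction=0.0)


def test_candidate_report_flank_boundary():
    samples = [f"c{i}" for i in range(2)] + [f"k{i}" for i in range(2)]
    phen = {s: ("seedless" if s.startswith("c") else "seeded") for s in samples}
    pos = np.array([1_049_999, 1_050_001, 999_000])
    cs = make_callset(
        np.array([[2, 2, 0, 0]] * 3, dtype=np.int8),
        pos=pos,
        samples=samples,
        deleterious=np.array([True, True, True]),
    )
    assoc = pd.DataFrame({"chrom": cs.chrom, "pos": cs.pos, "neg_log10_p": [3.0] * 3})
    assignments = classify_sites(cs, phen, assoc)
    peaks = [SweepPeak("chr1", 1_000_000, 50_000, 0.9)]
    report = candidate_report(cs, peaks, assignments)
    assert set(report["pos"]) == {1_049_999, 999_000}
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [998_000], "end": [1_000_000], "gene_id": ["GeneX"]}
    )
    with_genes = candidate_report(cs, peaks, assignments, genes=genes)
    assert with_genes.set_index("pos").loc[999_000, "gene_id"] == "GeneX"
    # no deleterious SNPs -> empty report
    cs2 = cs.copy()
    cs2.deleterious[:] = False
    empty = candidate_report(cs2, peaks, classify_sites(cs2, phen, assoc, deleterious_only=False).assign(deleterious=False))
    assert len(empty) == 0


def test_sweep_peak_validation():
    with pytest.raises(ConfigurationError):
        SweepPeak("chr1", 100, 0, 1.0)
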