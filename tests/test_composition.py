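import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from habdiv.composition import (
    DissimilarityMatrix,
    bray_curtis,
    dispersion_check,
    nmds,
    permanova,
    shared_from_totals,
    venn_partition,
)


def _dm_from_points(X, habitats, labels=None):
    d = squareform(pdist(X))
    d = d / (d.max() * 1.01)
    labels = labels or [f"s{i:03d}" for i in range(len(X))]
    return DissimilarityMatrix(d=d, labels=labels, habitats=habitats)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_identical_samples_dissimilarity_zero():
    c = pd.DataFrame({"a": [3, 1], "b": [3, 1]})
    assert bray_curtis(c, ["x", "x"], "none").d[0, 1] == 0.0


def test_disjoint_samples_dissimilarity_one():
    c = pd.DataFrame({"a": [1, 0], "b": [0, 3]})
    assert bray_curtis(c, ["x", "y"], "sqrt").d[0, 1] == pytest.approx(1.0)


def test_sqrt_transform_hand_value():
    c = pd.DataFrame({"j": [4, 1], "k": [1, 1]})
    assert bray_curtis(c, ["x", "y"], "sqrt").d[0, 1] == pytest.approx(0.2)


def test_presence_transform_equals_sorensen_set_oracle(rng):
    counts = pd.DataFrame(rng.integers(0, 4, (12, 6)))
    counts.columns = [f"s{j}" for j in range(6)]
    dm = bray_curtis(counts, ["h"] * 6, "presence")
    for j in range(6):
        for k in range(j + 1, 6):
            a = set(np.nonzero(counts.iloc[:, j].to_numpy())[0])
            b = set(np.nonzero(counts.iloc[:, k].to_numpy())[0])
            sor = 1 - 2 * len(a & b) / (len(a) + len(b))
            assert dm.d[j, k] == pytest.approx(sor, abs=1e-12)


def test_two_empty_samples_rejected():
    c = pd.DataFrame({"a": [0, 0], "b": [0, 0], "c": [1, 2]})
    with pytest.raises(ValueError):
        bray_curtis(c, ["x", "y", "z"], "none")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def test_pseudo_f_matches_textbook_partition():
    """One-way pseudo-F on a 4-sample toy against an independently coded
    sum-of-squares partition."""
    d = np.array(
        [
            [0.0, 0.2, 0.8, 0.7],
            [0.2, 0.0, 0.9, 0.6],
            [0.8, 0.9, 0.0, 0.3],
            [0.7, 0.6, 0.3, 0.0],
        ]
    )
    dm = DissimilarityMatrix(d=d, labels=list("abcd"), habitats=["g1", "g1", "g2", "g2"])
    res = permanova(dm, n_perm=99, seed=0)
    d2 = d ** 2
    ss_total = d2[np.triu_indices(4, 1)].sum() / 4
    ss_within = (d2[0, 1] + d2[2, 3]) / 2
    f_hand = ((ss_total - ss_within) / 1) / (ss_within / 2)
    assert res.pseudo_F == pytest.approx(f_hand, abs=1e-12)
    assert res.exact  # tiny design enumerated exhaustively


def test_separated_clusters_reach_minimal_p():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.05, (8, 3))
    b = rng.normal(5, 0.05, (7, 3))
    dm = _dm_from_points(np.vstack([a, b]), ["a"] * 8 + ["b"] * 7)
    res = permanova(dm, n_perm=99, seed=1, pairwise=False)
    assert res.p_perm == pytest.approx(1 / 100)


def test_permanova_matches_scikit_bio():
    import skbio

    rng = np.random.default_rng(3)
    X = rng.normal(0, 1, (12, 4))
    hab = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    dm = _dm_from_points(X, hab)
    ours = permanova(dm, n_perm=99, seed=0, pairwise=False)
    theirs = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(dm.d, ids=dm.labels), grouping=hab, permutations=0
    )
    assert ours.pseudo_F == pytest.approx(theirs["test statistic"], abs=1e-9)


def test_p_invariant_to_sample_order_and_renaming(rng):
    X = rng.normal(0, 1, (12, 3))
    X[6:] += 1.0
    hab = ["aa"] * 6 + ["bb"] * 6
    labels = [f"s{i:02d}" for i in range(12)]
    dm = _dm_from_points(X, hab, labels)
    base = permanova(dm, n_perm=199, seed=5, pairwise=False)
    perm = rng.permutation(12)
    dm_shuffled = DissimilarityMatrix(
        d=dm.d[np.ix_(perm, perm)],
        labels=[labels[i] for i in perm],
        habitats=[hab[i] for i in perm],
    )
    dm_renamed = DissimilarityMatrix(
        d=dm.d, labels=labels, habitats=["zz" if h == "aa" else "bb" for h in hab]
    )
    assert permanova(dm_shuffled, n_perm=199, seed=5, pairwise=False).p_perm == base.p_perm
    assert permanova(dm_renamed, n_perm=199, seed=5, pairwise=False).p_perm == base.p_perm


def test_pairwise_table_covers_all_pairs(rng):
    X = rng.normal(0, 1, (12, 3))
    hab = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    res = permanova(_dm_from_points(X, hab), n_perm=49, seed=0)
    assert len(res.pairwise) == 3
    assert set(res.pairwise["group1"]) <= {"a", "b"}


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def test_translated_groups_show_no_dispersion_difference():
    """Groups that are translated copies share their dispersion: the check
    must not flag a location difference (median p over simulations > 0.3)."""
    ps = []
    for s in range(15):
        r = np.random.default_rng(100 + s)
        base = r.normal(0, 1, (15, 4))
        dm = _dm_from_points(np.vstack([base, base + 3.0]), ["a"] * 15 + ["b"] * 15)
        ps.append(dispersion_check(dm, n_perm=199, seed=r).p_perm)
    assert np.median(ps) > 0.3


def test_doubled_spread_is_detected():
    hits = 0
    for s in range(15):
        r = np.random.default_rng(200 + s)
        X = np.vstack([r.normal(0, 1, (20, 4)), r.normal(0, 2, (20, 4))])
        dm = _dm_from_points(X, ["a"] * 20 + ["b"] * 20)
        hits += dispersion_check(dm, n_perm=199, seed=r).p_perm <= 0.05
    assert hits / 15 > 0.5


def test_non_euclidean_distances_stay_real(rng):
    counts = pd.DataFrame(rng.integers(0, 5, (10, 8)))
    counts.columns = [f"s{j}" for j in range(8)]
    dm = bray_curtis(counts, ["a"] * 4 + ["b"] * 4, "sqrt")
    res = dispersion_check(dm, n_perm=99, seed=0)
    assert np.isfinite(res.distances).all()
    assert (res.distances >= 0).all()


def test_dispersion_statistic_matches_scikit_bio_centroid():
    import skbio

    rng = np.random.default_rng(8)
    X = rng.normal(0, 1, (14, 3))
    X[7:] *= 2.0
    hab = ["a"] * 7 + ["b"] * 7
    dm = _dm_from_points(X, hab)
    ours = dispersion_check(dm, n_perm=99, seed=0)
    theirs = skbio.stats.distance.permdisp(
        skbio.DistanceMatrix(dm.d, ids=dm.labels), grouping=hab,
        test="centroid", permutations=0,
    )
    assert ours.F == pytest.approx(theirs["test statistic"], rel=1e-6)


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------

def test_nmds_recovers_planar_configuration(rng):
    X = rng.normal(0, 1, (12, 2))
    dm = _dm_from_points(X, ["a"] * 6 + ["b"] * 6)
    coords, stress = nmds(dm, dims=2, restarts=10, seed=0)
    assert stress < 0.05
    assert list(coords.index) == dm.labels


def test_nmds_stress_not_worse_in_higher_dims(rng):
    # 8-dimensional cloud: a 2-D embedding carries real stress, so the
    # extra axis must reduce it (up to optimiser noise)
    X = rng.normal(0, 1, (14, 8))
    dm = _dm_from_points(X, ["a"] * 7 + ["b"] * 7)
    _, s2 = nmds(dm, dims=2, restarts=12, seed=0)
    _, s3 = nmds(dm, dims=3, restarts=12, seed=0)
    assert s2 > 0.02
    assert s3 < s2


def test_nmds_deterministic_given_seed(rng):
    X = rng.normal(0, 1, (8, 3))
    dm = _dm_from_points(X, ["a"] * 4 + ["b"] * 4)
    c1, s1 = nmds(dm, restarts=5, seed=3)
    c2, s2 = nmds(dm, restarts=5, seed=3)
    assert s1 == s2
    pd.testing.assert_frame_equal(c1, c2)


def test_nmds_needs_four_samples():
    d = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    dm = DissimilarityMatrix(d=d, labels=list("abc"), habitats=["x", "y", "z"])
    with pytest.raises(ValueError):
        nmds(dm)


# ---------------------------------------------------------------------------
# Venn
# ---------------------------------------------------------------------------

def test_disjoint_sets_share_nothing():
    v = venn_partition({"a": {1, 2}, "b": {3, 4, 5}})
    assert v.shared_all == 0
    assert v.unique == {"a": 2, "b": 3}
    assert v.union == 5


def test_three_set_inclusion_exclusion(rng):
    for _ in range(10):
        sets = {
            k: set(rng.integers(0, 30, rng.integers(1, 20)).tolist())
            for k in ("a", "b", "c")
        }
        v = venn_partition(sets)
        # inclusion-exclusion for the union
        ie = (
            sum(v.totals.values())
            - sum(v.pairwise_shared.values())
            + v.shared_all
        )
        assert v.union == ie
        assert v.union == len(sets["a"] | sets["b"] | sets["c"])


def test_shared_from_totals_inclusion_exclusion():
    shared, ua, ub = shared_from_totals(223, 179, 312)
    assert (shared, ua, ub) == (90, 133, 89)
    with pytest.raises(ValueError):
        shared_from_totals(3, 3, 10)
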