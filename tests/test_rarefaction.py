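import itertools

import numpy as np
import pytest

from habdiv.hill import IncidenceFrequencies, chao2_richness, empirical_hill, sample_coverage
from habdiv.rarefaction import (
    cmax,
    coverage_at_size,
    estimate_at_coverage,
    extrapolate_richness,
    incidence_bootstrap,
    rarefy_richness,
    re_curve,
    size_based_estimate,
    standardized_profile,
)

from conftest import freq_from_matrix, random_incidence_matrix


# ---------------------------------------------------------------------------
# rarefaction (q = 0)
# ---------------------------------------------------------------------------

def test_rarefy_identities(toy_freq):
    assert rarefy_richness(toy_freq, toy_freq.T) == pytest.approx(4.0, abs=1e-12)
    assert rarefy_richness(toy_freq, 1) == pytest.approx(toy_freq.U / toy_freq.T)


def test_rarefy_strictly_increasing_with_singletons(toy_freq):
    vals = [rarefy_richness(toy_freq, t) for t in range(1, 5)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_rarefy_out_of_range(toy_freq):
    with pytest.raises(ValueError):
        rarefy_richness(toy_freq, 5)


def test_rarefy_matches_subset_enumeration_oracle(rng):
    """For T <= 8 the rarefied richness equals the brute-force average over
    all C(T, t) subsets of sampling units."""
    for _ in range(5):
        m = random_incidence_matrix(rng, T=7, S=9, p_lo=0.1, p_hi=0.7)
        f = freq_from_matrix(m)
        T = m.shape[1]
        for t in range(1, T + 1):
            richness = [
                int((m[:, list(sub)].sum(axis=1) > 0).sum())
                for sub in itertools.combinations(range(T), t)
            ]
            assert rarefy_richness(f, t) == pytest.approx(np.mean(richness), abs=1e-9)


# ---------------------------------------------------------------------------
# extrapolation (q = 0)
# ---------------------------------------------------------------------------

def test_extrapolate_at_zero_is_observed(toy_freq):
    assert extrapolate_richness(toy_freq, 0) == 4.0


def test_extrapolate_limit_is_chao2(toy_freq):
    assert extrapolate_richness(toy_freq, 10 ** 6) == pytest.approx(
        chao2_richness(toy_freq).value, abs=1e-6
    )


def test_extrapolate_hand_value(toy_freq):
    # Q0 = 1.5; 4 + 1.5 * (1 - (1 - 2/8)^4)
    assert extrapolate_richness(toy_freq, 4) == pytest.approx(5.025390625)


def test_extrapolate_without_singletons_stays_observed():
    f = IncidenceFrequencies(T=4, Q=np.array([4, 2, 2]))
    assert extrapolate_richness(f, 100) == 3.0


# ---------------------------------------------------------------------------
# size-based curves
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("q", [0.0, 1.0, 2.0])
def test_curve_continuous_at_reference_size(toy_freq, q):
    curve = {p.t: p for p in re_curve(toy_freq, q, knots=10)}
    assert curve[4.0].estimate == pytest.approx(empirical_hill(toy_freq, q).value, rel=1e-9)
    assert not curve[4.0].extrapolated and curve[8.0].extrapolated


def test_simpson_curve_asymptotes_where_richness_does_not():
    """On a strongly undersampled heavy-tailed assemblage the Simpson curve
    flattens by 2T (relative slope < 1%) while the richness curve is still
    rising (> 1%)."""
    rng = np.random.default_rng(2)
    p = np.clip(np.exp(rng.normal(-4.5, 1.8, 800)), 0, 1)
    Q = rng.binomial(12, p)
    f = IncidenceFrequencies(T=12, Q=Q[Q > 0])
    slope = {}
    for q in (0.0, 2.0):
        d_end = size_based_estimate(f, q, 24)
        slope[q] = (d_end - size_based_estimate(f, q, 23)) / d_end
    assert slope[2.0] < 0.01 < slope[0.0]


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def test_coverage_at_reference_size(toy_freq):
    assert coverage_at_size(toy_freq, 4) == pytest.approx(0.8125)


def test_coverage_monotone_on_random_toys(rng):
    for _ in range(10):
        f = freq_from_matrix(random_incidence_matrix(rng, T=6, S=10, p_lo=0.05))
        cov = [coverage_at_size(f, t) for t in range(1, 2 * f.T + 1)]
        assert all(a <= b + 1e-12 for a, b in zip(cov, cov[1:]))


def test_coverage_complete_assemblage_is_one():
    f = IncidenceFrequencies(T=4, Q=np.array([4, 4, 4]))
    assert all(coverage_at_size(f, t) == pytest.approx(1.0) for t in range(1, 9))


def test_cmax_is_min_of_doubled_coverages(toy_freq):
    other = IncidenceFrequencies(T=6, Q=np.array([6, 6, 5, 2]))
    c_toy = coverage_at_size(toy_freq, 8)
    c_other = coverage_at_size(other, 12)
    assert cmax([toy_freq]) == pytest.approx(c_toy)
    assert cmax([toy_freq, other]) == pytest.approx(min(c_toy, c_other))


# ---------------------------------------------------------------------------
# coverage standardisation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("q", [0.0, 1.0, 2.0])
def test_standardised_anchor_at_observed_coverage(toy_freq, q):
    est = estimate_at_coverage(toy_freq, q, sample_coverage(toy_freq))
    assert est.estimate == pytest.approx(empirical_hill(toy_freq, q).value, rel=1e-9)


def test_standardised_monotone_in_target(toy_freq):
    targets = np.linspace(coverage_at_size(toy_freq, 1), coverage_at_size(toy_freq, 8), 12)
    vals = [estimate_at_coverage(toy_freq, 0.0, c).estimate for c in targets]
    assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))
    assert vals[0] <= empirical_hill(toy_freq, 0.0).value


def test_refuses_target_beyond_doubled_size(toy_freq):
    with pytest.raises(ValueError, match="refusing"):
        estimate_at_coverage(toy_freq, 0.0, 0.999)


def test_coverage_and_size_parameterisations_consistent(rng):
    """estimate_at_coverage at coverage(t) equals the size-based estimate at
    integer t, for every q."""
    f = freq_from_matrix(random_incidence_matrix(rng, T=8, S=14, p_lo=0.05))
    for t in range(2, 2 * f.T + 1, 3):
        c = coverage_at_size(f, t)
        for q in (0.0, 1.0, 2.0):
            assert estimate_at_coverage(f, q, c).estimate == pytest.approx(
                size_based_estimate(f, q, t), abs=1e-9
            )


def test_standardized_profile_matches_pointwise(toy_freq):
    qs = np.array([0.0, 0.5, 1.0, 2.0])
    c = coverage_at_size(toy_freq, 6)
    prof = standardized_profile(toy_freq, qs, c)
    for q, v in zip(qs, prof):
        assert v == pytest.approx(estimate_at_coverage(toy_freq, float(q), c).estimate, rel=1e-9)


def test_equal_process_different_effort_agree_after_standardisation():
    """Two habitats sampled from the same assemblage with different effort
    give standardized Shannon estimates closer than the bootstrap CI width."""
    rng = np.random.default_rng(11)
    p = np.clip(np.exp(rng.normal(-1.5, 0.9, 80)), 0, 1)
    qa = rng.binomial(20, p)
    qb = rng.binomial(40, p)
    fa = IncidenceFrequencies(T=20, Q=qa[qa > 0])
    fb = IncidenceFrequencies(T=40, Q=qb[qb > 0])
    c = min(coverage_at_size(fa, 40), coverage_at_size(fb, 80))
    ea = estimate_at_coverage(fa, 1.0, c, B=100, rng=np.random.default_rng(1))
    eb = estimate_at_coverage(fb, 1.0, c, B=100, rng=np.random.default_rng(2))
    width = (ea.ci_high - ea.ci_low) + (eb.ci_high - eb.ci_low)
    assert abs(ea.estimate - eb.estimate) < width


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_degenerate_assemblage_zero_width(rng):
    f = IncidenceFrequencies(T=6, Q=np.array([6]))
    ci = incidence_bootstrap(f, lambda fb: float(fb.S_obs), B=60, rng=rng)
    assert ci.se == 0.0
    assert ci.ci_low == ci.ci_high == 1.0


def test_bootstrap_ci_shrinks_with_effort():
    rng = np.random.default_rng(5)
    p = np.clip(np.exp(rng.normal(-2.2, 1.0, 80)), 0, 1)
    ses = []
    for T in (8, 32, 128):
        q = np.random.default_rng(9).binomial(T, p)
        f = IncidenceFrequencies(T=T, Q=q[q > 0])
        ci = incidence_bootstrap(
            f, lambda fb: chao2_richness(fb).value, B=100, rng=np.random.default_rng(T)
        )
        ses.append(ci.se)
    assert ses[0] > ses[1] > ses[2]


def test_bootstrap_reproducible_given_seed(toy_freq):
    a = incidence_bootstrap(toy_freq, lambda fb: chao2_richness(fb).value, B=60,
                            rng=np.random.default_rng(7))
    b = incidence_bootstrap(toy_freq, lambda fb: chao2_richness(fb).value, B=60,
                            rng=np.random.default_rng(7))
    assert a.ci_low == b.ci_low and a.ci_high == b.ci_high


def test_bootstrap_requires_enough_replicates(toy_freq):
    with pytest.raises(ValueError):
        incidence_bootstrap(toy_freq, lambda fb: 1.0, B=10)


def test_bootstrap_aborts_on_failure_storm(toy_freq, rng):
    def bad(fb):
        if fb is not toy_freq:  # fail only inside replicates
            raise RuntimeError("boom")
        return 1.0

    with pytest.raises(RuntimeError, match="replicates failed"):
        incidence_bootstrap(toy_freq, bad, B=60, rng=rng)
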