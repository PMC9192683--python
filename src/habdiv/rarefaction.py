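"""Size- and coverage-based rarefaction/extrapolation and the incidence bootstrap.

Size-based curves interpolate the expected diversity of ``t <= T`` sampling
units drawn without replacement from the observed ones, and extrapolate to
``t <= 2T`` using the asymptotic estimators; extrapolation past double the
observed sample size is deliberately unsupported (unreliable for richness).
Coverage-based curves reparameterise the same estimates by expected sample
coverage, enabling comparisons of habitats at equal completeness: the
standardisation level ``C_max`` is the lowest coverage reached by any habitat
when extrapolated to double its sample size.

Confidence bands come from the incidence bootstrap: the assemblage
reconstructed in :mod:`habdiv.hill` (detected phenotypes with shrunken
detection probabilities plus the estimated undetected phenotypes) is
resampled B times with T Bernoulli units per replicate, and bands are the
normal approximation ``estimate +/- 1.96 * bootstrap SD``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .hill import (
    IncidenceFrequencies,
    _coverage_A,
    _hill_from_relative,
    asymptotic_hill,
    asymptotic_profile,
    bootstrap_frequencies,
    chao2_richness,
    empirical_hill,
    empirical_profile,
    lchoose as _lchoose,
    sample_coverage,
)

logger = logging.getLogger("habdiv")


@dataclass
class RECurvePoint:
    """One knot of a rarefaction/extrapolation curve."""

    t: float
    q: float
    estimate: float
    coverage: float
    extrapolated: bool
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass
class StandardizedEstimate:
    """Diversity standardised to a target sample coverage."""

    q: float
    C_target: float
    estimate: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    habitat: Optional[str] = None


@dataclass
class BootstrapCI:
    """Normal-approximation bootstrap interval around an observed statistic."""

    observed: np.ndarray | float
    se: np.ndarray | float
    ci_low: np.ndarray | float
    ci_high: np.ndarray | float
    n_replicates: int


# ---------------------------------------------------------------------------
# Richness (q = 0)
# ---------------------------------------------------------------------------

def rarefy_richness(f: IncidenceFrequencies, t: int) -> float:
    """Expected richness of t <= T sampling units (hypergeometric mean).

    S(t) = S_obs - sum_i C(T - Q_i, t) / C(T, t).
    """
    if not 1 <= t <= f.T:
        raise ValueError(f"t must be in [1, T={f.T}], got {t}")
    ratio = np.exp(_lchoose(f.T - f.Q, t) - _lchoose(f.T, t))
    return float(f.S_obs - ratio.sum())


def extrapolate_richness(f: IncidenceFrequencies, t_star: int) -> float:
    """Expected richness t_star units beyond T (Chao2-anchored).

    S(T + t*) = S_obs + Q0 * [1 - (1 - Q1 / (T Q0 + Q1)) ** t*], with
    Q0 = S_chao2 - S_obs; the t* -> inf limit is the Chao2 estimate.
    """
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    q0 = chao2_richness(f).value - f.S_obs
    if q0 <= 0 or f.Q1 == 0:
        return float(f.S_obs)
    return float(f.S_obs + q0 * (1.0 - (1.0 - f.Q1 / (f.T * q0 + f.Q1)) ** t_star))


# ---------------------------------------------------------------------------
# Shannon / Simpson size-based estimators
# ---------------------------------------------------------------------------

def _expected_frequency_counts(f: IncidenceFrequencies, t: int) -> np.ndarray:
    """E[number of phenotypes with incidence k] in a t-unit subsample, k=1..t."""
    k = np.arange(1, t + 1)
    lc = (
        _lchoose(f.Q[:, None], k[None, :])
        + _lchoose(f.T - f.Q[:, None], t - k[None, :])
        - _lchoose(f.T, t)
    )
    return np.exp(lc).sum(axis=0)


def _rarefied_hill_from_counts(qk: np.ndarray, t: int, ut: float, q: float) -> float:
    """Plug-in qD from expected frequency counts Q_k(t), k = 1..t."""
    k = np.arange(1, t + 1)
    rel = k / ut
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(qk * rel * np.log(rel))))
    return float(np.sum(qk * rel ** q) ** (1.0 / (1.0 - q)))


def size_based_estimate(f: IncidenceFrequencies, q: float, t: int) -> float:
    """Expected order-q diversity at t sampling units, 1 <= t <= 2T.

    Rarefaction (t <= T) is exact for every q >= 0 via the expected
    incidence-frequency counts of a hypergeometric subsample (q = 0 uses
    the closed richness form).  Extrapolation (t > T) uses the
    Chao2-anchored formula for q = 0, a closed form for q = 2, and for all
    other orders interpolates log-diversity between the empirical value at
    T (weight T/t) and the asymptotic estimate (weight 1 - T/t), so the
    curve is continuous at t = T and approaches the asymptote as t grows.
    """
    if not 1 <= t <= 2 * f.T:
        raise ValueError(f"t must be in [1, 2T={2 * f.T}], got {t}")
    if q == 0:
        return rarefy_richness(f, t) if t <= f.T else extrapolate_richness(f, t - f.T)
    if q == 2:
        ut = t * f.U / f.T
        s2 = float(np.sum(f.Q * (f.Q - 1.0))) / (f.T * (f.T - 1.0))
        denom = ut + t * (t - 1.0) * s2
        return float(ut ** 2 / denom) if denom > 0 else float(f.S_obs)
    if t <= f.T:
        qk = _expected_frequency_counts(f, t)
        return _rarefied_hill_from_counts(qk, t, t * f.U / f.T, q)
    w = f.T / t
    log_d = w * np.log(empirical_hill(f, q).value) + (1.0 - w) * np.log(
        asymptotic_hill(f, q).value
    )
    return float(np.exp(log_d))


def size_based_profile(f: IncidenceFrequencies, q_grid: np.ndarray, t: int) -> np.ndarray:
    """Order-q diversity at size t over a whole q-grid (shared kernels)."""
    q_grid = np.asarray(q_grid, dtype=float)
    out = np.empty(q_grid.size)
    if t <= f.T:
        qk = _expected_frequency_counts(f, t)
        ut = t * f.U / f.T
        for i, q in enumerate(q_grid):
            out[i] = (
                rarefy_richness(f, t) if q == 0
                else _rarefied_hill_from_counts(qk, t, ut, float(q))
            )
        return out
    emp = empirical_profile(f, q_grid)
    asy = asymptotic_profile(f, q_grid)
    w = f.T / t
    for i, q in enumerate(q_grid):
        if q == 0:
            out[i] = extrapolate_richness(f, t - f.T)
        elif q == 2:
            out[i] = size_based_estimate(f, 2.0, t)
        else:
            out[i] = np.exp(w * np.log(emp[i]) + (1.0 - w) * np.log(asy[i]))
    return out


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def coverage_at_size(f: IncidenceFrequencies, t: float) -> float:
    """Expected sample coverage of a size-t sample, 1 <= t <= 2T.

    Rarefied (t < T) coverage is exact under hypergeometric subsampling;
    extrapolated coverage decays the singleton share geometrically.
    Non-integer t interpolates linearly between the bracketing integers.
    """
    if not 1 <= t <= 2 * f.T:
        raise ValueError(f"t must be in [1, 2T={2 * f.T}], got {t}")
    if float(t) != int(t):
        t0 = int(np.floor(t))
        frac = t - t0
        return float(
            (1 - frac) * coverage_at_size(f, t0) + frac * coverage_at_size(f, t0 + 1)
        )
    t = int(t)
    if t < f.T:
        # C(T-1, t) denominator keeps the estimator continuous and
        # monotone through t = T (Chat(T-1) = 1 - Q1/U <= Chat(T))
        ratio = np.exp(_lchoose(f.T - f.Q, t) - _lchoose(f.T - 1, t))
        return float(1.0 - np.sum((f.Q / f.U) * ratio))
    a = _coverage_A(f)
    return float(1.0 - (f.Q1 / f.U) * a ** (t - f.T + 1))


def cmax(habitats: Sequence[IncidenceFrequencies]) -> float:
    """Standardisation coverage: min over habitats of coverage at 2T."""
    if not habitats:
        raise ValueError("at least one habitat required")
    return float(min(coverage_at_size(f, 2 * f.T) for f in habitats))


# ---------------------------------------------------------------------------
# Curves and coverage standardisation
# ---------------------------------------------------------------------------

def re_curve(
    f: IncidenceFrequencies,
    q: float,
    knots: int = 40,
    B: int = 0,
    rng: np.random.Generator | None = None,
) -> list[RECurvePoint]:
    """Rarefaction/extrapolation curve over t in [1, 2T] at ~`knots` sizes.

    The grid always contains t = 1, T and 2T.  With B > 0, bootstrap bands
    are attached (the same replicate assemblages across all sizes).
    """
    if knots < 2:
        raise ValueError("knots must be >= 2")
    grid = np.unique(
        np.concatenate(
            [np.round(np.linspace(1, 2 * f.T, knots)), [1, f.T, 2 * f.T]]
        ).astype(int)
    )
    est = np.array([size_based_estimate(f, q, int(t)) for t in grid])
    cov = np.array([coverage_at_size(f, int(t)) for t in grid])
    lo = hi = [None] * len(grid)
    if B > 0:
        if rng is None:
            rng = np.random.default_rng()
        ci = incidence_bootstrap(
            f,
            lambda fb: np.array([size_based_estimate(fb, q, int(t)) for t in grid]),
            B=B,
            rng=rng,
        )
        lo, hi = ci.ci_low, ci.ci_high
    return [
        RECurvePoint(
            t=float(t), q=q, estimate=float(e), coverage=float(c),
            extrapolated=bool(t > f.T),
            ci_low=None if lo[i] is None else float(lo[i]),
            ci_high=None if hi[i] is None else float(hi[i]),
        )
        for i, (t, e, c) in enumerate(zip(grid, est, cov))
    ]


def _invert_coverage(f: IncidenceFrequencies, C_target: float) -> float:
    """Size t in [1, 2T] whose expected coverage is C_target (linear between knots)."""
    ts = np.arange(1, 2 * f.T + 1)
    cov = np.array([coverage_at_size(f, int(t)) for t in ts])
    if C_target > cov[-1] + 1e-12:
        raise ValueError(
            f"C_target={C_target:.4f} exceeds coverage at 2T ({cov[-1]:.4f}); "
            "refusing to extrapolate beyond double the sample size"
        )
    if C_target < cov[0] - 1e-12:
        raise ValueError(f"C_target={C_target:.4f} below coverage of a single unit")
    exact = np.nonzero(np.abs(cov - C_target) <= 1e-12)[0]
    if exact.size:
        return float(ts[exact[0]])
    j = int(np.searchsorted(cov, C_target))
    j = min(max(j, 1), len(ts) - 1)
    span = cov[j] - cov[j - 1]
    frac = 0.0 if span <= 0 else (C_target - cov[j - 1]) / span
    return float(ts[j - 1] + frac)


def estimate_at_coverage(
    f: IncidenceFrequencies,
    q: float,
    C_target: float,
    B: int = 0,
    rng: np.random.Generator | None = None,
    habitat: str | None = None,
) -> StandardizedEstimate:
    """Order-q diversity standardised to sample coverage ``C_target``.

    Inverts the coverage curve for the (possibly fractional) sample size and
    evaluates the size-based estimate there, interpolating linearly between
    the bracketing integer sizes.
    """

    def _standardised(fb: IncidenceFrequencies, clamp: bool = True) -> float:
        target = C_target
        if clamp:  # bootstrap replicates may not reach the observed coverage
            target = min(target, coverage_at_size(fb, 2 * fb.T))
        t = _invert_coverage(fb, target)
        t0 = int(np.floor(t))
        if t == t0:
            return size_based_estimate(fb, q, t0)
        frac = t - t0
        return float(
            (1 - frac) * size_based_estimate(fb, q, t0)
            + frac * size_based_estimate(fb, q, t0 + 1)
        )

    value = _standardised(f, clamp=False)  # raises if C_target out of range
    lo = hi = None
    if B > 0:
        if rng is None:
            rng = np.random.default_rng()
        ci = incidence_bootstrap(f, _standardised, B=B, rng=rng)
        lo, hi = float(ci.ci_low), float(ci.ci_high)
    return StandardizedEstimate(
        q=q, C_target=C_target, estimate=value, ci_low=lo, ci_high=hi, habitat=habitat
    )


def standardized_profile(
    f: IncidenceFrequencies, q_grid: np.ndarray, C_target: float
) -> np.ndarray:
    """Coverage-standardised qD over a q-grid (single coverage inversion).

    Clamps the target at the habitat's own 2T coverage, mirroring the rule
    that no habitat is extrapolated past double its sample size.
    """
    c = min(C_target, coverage_at_size(f, 2 * f.T))
    t = _invert_coverage(f, c)
    t0 = int(np.floor(t))
    prof = size_based_profile(f, q_grid, t0)
    if t > t0:
        prof = (1 - (t - t0)) * prof + (t - t0) * size_based_profile(f, q_grid, t0 + 1)
    return prof


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def incidence_bootstrap(
    f: IncidenceFrequencies,
    statistic: Callable[[IncidenceFrequencies], float | np.ndarray],
    B: int = 500,
    rng: np.random.Generator | None = None,
) -> BootstrapCI:
    """Bootstrap a statistic of incidence frequencies (B >= 50 replicates).

    Replicates that raise are dropped and logged; more than 10% failures
    aborts.  The interval is the normal approximation centred on the
    observed statistic: ``observed +/- 1.96 * SD(replicates)``.
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    if rng is None:
        rng = np.random.default_rng()
    observed = np.asarray(statistic(f), dtype=float)
    reps = []
    failures = 0
    for fb in bootstrap_frequencies(f, B, rng):
        try:
            reps.append(np.asarray(statistic(fb), dtype=float))
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            failures += 1
            logger.warning("bootstrap replicate failed: %s", exc)
    if failures > 0.1 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
    arr = np.stack(reps)
    se = arr.std(axis=0, ddof=1)
    out = BootstrapCI(
        observed=observed if observed.ndim else float(observed),
        se=se if se.ndim else float(se),
        ci_low=observed - 1.96 * se,
        ci_high=observed + 1.96 * se,
        n_replicates=len(reps),
    )
    return out
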