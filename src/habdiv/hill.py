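"""Incidence-frequency Hill numbers, Chao2 richness, coverage and completeness.

All estimators in this module consume the sufficient statistics of a binary
phenotype x sampling-unit matrix: the number of units ``T`` and the vector of
incidence frequencies ``Q_i`` (units in which phenotype i occurs), from which
follow the singleton/doubleton counts ``Q1``/``Q2``, the total number of
incidences ``U = sum Q_i`` and the observed richness ``S_obs``.

The model behind the estimators: each phenotype i has an unknown detection
probability ``pi_i`` per sampling unit, units are independent, and
``Q_i ~ Binomial(T, pi_i)``.  Hill numbers of order q are defined on the
normalised detection rates ``lambda_i = pi_i / sum_j pi_j``::

    qD = (sum_i lambda_i ** q) ** (1 / (1 - q)),   qD(1) = exp(-sum lambda_i ln lambda_i)

The *empirical* Hill number plugs in ``Q_i / U``; it is negatively biased for
q = 0 and 1 whenever rare phenotypes remain undetected (``Q1 > 0``).  The
*asymptotic* estimators correct that bias: Chao2 for q = 0, and the
incidence-data analogues of the asymptotic Shannon / Simpson estimators
(obtained from the abundance versions by substituting Q_i, T, U for
abundances and individuals) for q >= 1, with a general-q series estimator for
the profile in between.

Sample *completeness* at order q is the detected share of order-q diversity,
``C_q = sum_detected pi_i^q / sum_all pi_i^q``, estimated from the
reconstructed assemblage (detected phenotypes with shrunken detection
probabilities plus ``Q0_hat`` undetected phenotypes sharing the estimated
coverage deficit).  The two anchor identities hold exactly:
``C_0 = S_obs / S_chao2`` and ``C_1 = C_hat`` (the sample coverage).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import binom as _binom_real
from scipy.special import digamma, gammaln

from .data_model import IncidenceMatrix

logger = logging.getLogger("habdiv")

_Q1_EPS = 1e-9  # |q - 1| below this uses the Shannon limit


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Sufficient statistics of an incidence matrix.

    ``Q`` holds the positive incidence frequencies only (one entry per
    detected phenotype); all-zero rows of the source matrix carry no
    information and are dropped here.
    """

    T: int
    Q: np.ndarray

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        q = np.asarray(self.Q, dtype=np.int64)
        q = q[q > 0]
        if q.size == 0:
            raise ValueError("no detected phenotypes")
        if (q > self.T).any():
            raise ValueError("incidence frequency exceeds number of units")
        object.__setattr__(self, "Q", q)

    @property
    def Q1(self) -> int:
        return int((self.Q == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.Q == 2).sum())

    @property
    def U(self) -> int:
        return int(self.Q.sum())

    @property
    def S_obs(self) -> int:
        return int(self.Q.size)


@dataclass
class HillEstimate:
    """Order-q diversity estimate with optional bootstrap 95% bounds."""

    q: float
    value: float
    variant: str  # empirical | asymptotic | standardized
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass
class CompletenessProfile:
    """Sample-completeness profile over a grid of orders q in [0, 2]."""

    q_grid: np.ndarray
    completeness: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None


def incidence_frequencies(m: IncidenceMatrix) -> IncidenceFrequencies:
    """Row sums of the presence matrix as incidence frequencies."""
    if m.presence.size == 0:
        raise ValueError("empty incidence matrix")
    rowsums = m.presence.sum(axis=1).to_numpy()
    if (rowsums == 0).all():
        raise ValueError("incidence matrix has no occurrences")
    return IncidenceFrequencies(T=int(m.T), Q=rowsums)


# ---------------------------------------------------------------------------
# Empirical Hill numbers
# ---------------------------------------------------------------------------

def _hill_from_relative(p: np.ndarray, q: float) -> float:
    """qD of an explicit relative-frequency vector (p sums to 1)."""
    p = p[p > 0]
    if abs(q - 1.0) < _Q1_EPS:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def empirical_hill(f: IncidenceFrequencies, q: float) -> HillEstimate:
    """Plug-in Hill number of order q on relative incidences ``Q_i / U``."""
    if q < 0:
        raise ValueError("order q must be >= 0")
    if q == 0:
        value = float(f.S_obs)
    else:
        value = _hill_from_relative(f.Q / f.U, q)
    return HillEstimate(q=q, value=value, variant="empirical")


# ---------------------------------------------------------------------------
# Asymptotic estimators
# ---------------------------------------------------------------------------

def chao2_richness(f: IncidenceFrequencies) -> HillEstimate:
    """Chao2 lower-bound richness estimator for incidence data.

    Q2 > 0:  S = S_obs + ((T-1)/T) * Q1^2 / (2 Q2)
    Q2 = 0:  S = S_obs + ((T-1)/T) * Q1 (Q1 - 1) / 2
    Q1 = 0:  S = S_obs
    """
    if f.T < 2:
        raise ValueError("Chao2 requires at least two sampling units")
    k = (f.T - 1) / f.T
    if f.Q1 == 0:
        value = float(f.S_obs)
    elif f.Q2 > 0:
        value = f.S_obs + k * f.Q1 ** 2 / (2 * f.Q2)
    else:
        value = f.S_obs + k * f.Q1 * (f.Q1 - 1) / 2
    return HillEstimate(q=0.0, value=float(value), variant="asymptotic")


def _coverage_A(f: IncidenceFrequencies) -> float:
    """Singleton shrinkage constant A shared by coverage-type estimators."""
    if f.Q1 == 0:
        return 1.0
    if f.Q2 > 0:
        return (f.T - 1) * f.Q1 / ((f.T - 1) * f.Q1 + 2 * f.Q2)
    # Q2 = 0 modification keeps the estimator finite and defined at Q1 = 1
    return (f.T - 1) * (f.Q1 - 1) / ((f.T - 1) * (f.Q1 - 1) + 2)


def sample_coverage(f: IncidenceFrequencies) -> float:
    """Estimated sample coverage (sample completeness at q = 1).

    C = 1 - (Q1 / U) * A, where A = (T-1)Q1 / ((T-1)Q1 + 2 Q2); A uses the
    standard Q2 = 0 modification when there are no doubletons.
    """
    if f.U == 0:
        raise ValueError("U must be positive")
    return float(1.0 - (f.Q1 / f.U) * _coverage_A(f))


def _shannon_tail(T: int, A: float, max_terms: int = 200_000) -> float:
    """(1-A)^(1-T) * [-ln A - sum_{r<T} (1-A)^r / r], evaluated stably.

    Algebraically equals sum_{s>=1} (1-A)^s / (T - 1 + s); summing that
    series directly avoids the catastrophic cancellation of the closed form
    when A is near 1.
    """
    if A >= 1.0:
        return 0.0
    x = 1.0 - A
    total = 0.0
    s = np.arange(1, 4096)
    while s[0] < max_terms:
        terms = x ** s / (T - 1 + s)
        total += float(terms.sum())
        if terms[-1] < 1e-16 * max(total, 1e-300):
            break
        s = s + 4096
    return total


def _asymptotic_shannon(f: IncidenceFrequencies) -> float:
    """Asymptotic exponential Shannon entropy for incidence data."""
    T, U, Q = f.T, f.U, f.Q
    h = float(np.sum((Q / U) * (digamma(T) - digamma(Q))))
    if f.Q1 > 0:
        h += (f.Q1 / U) * _shannon_tail(T, _coverage_A(f))
    h += np.log(U / T)
    return float(np.exp(h))


def _asymptotic_simpson(f: IncidenceFrequencies) -> float:
    """Asymptotic inverse Simpson concentration for incidence data."""
    T, U, Q = f.T, f.U, f.Q
    denom = float(np.sum(Q * (Q - 1.0))) / (T * (T - 1.0))
    if denom <= 0:
        # every phenotype a singleton: the asymptote is not estimable;
        # fall back to the (conservative) empirical value
        logger.warning("asymptotic 2D undefined (all singletons); returning empirical value")
        return _hill_from_relative(Q / U, 2.0)
    return float((U / T) ** 2 / denom)


def lchoose(n, k):
    """log C(n, k), with C(n, k) = 0 (=> -inf) whenever n < k or k < 0."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    n, k = np.broadcast_arrays(n, k)
    out = np.full(n.shape, -np.inf)
    ok = (n >= k) & (k >= 0)
    out[ok] = gammaln(n[ok] + 1) - gammaln(k[ok] + 1) - gammaln(n[ok] - k[ok] + 1)
    return out


def _delta_vector(f: IncidenceFrequencies) -> np.ndarray:
    """delta_k = sum_i (Q_i/T) C(T-Q_i, k) / C(T-1, k), k = 0..T-1.

    The q-independent kernel of the general-order series estimator of
    sum(pi^q); computed once and shared across a q-grid.
    """
    k = np.arange(f.T)
    lc = lchoose(f.T - f.Q[:, None], k[None, :]) - lchoose(f.T - 1, k)[None, :]
    return np.sum((f.Q[:, None] / f.T) * np.exp(lc), axis=0)


def _general_tail(T: int, A: float, q: float, max_terms: int = 200_000) -> float:
    """(1-A)^(1-T) * [A^(q-1) - sum_{r<T} C(q-1,r) (A-1)^r], evaluated stably.

    Equals sum_{s>=1} C(q-1, T-1+s) (-1)^(T-1+s) (1-A)^s; the signed
    coefficient follows the recurrence c_r = c_{r-1} (r - q) / r.
    """
    if A >= 1.0:
        return 0.0
    x = 1.0 - A
    r = np.arange(1, T)
    c = float(np.prod((r - q) / r)) if T > 1 else 1.0  # C(q-1,T-1)(-1)^(T-1)
    total = 0.0
    xs = 1.0
    for s in range(1, max_terms):
        rr = T - 1 + s
        c *= (rr - q) / rr
        xs *= x
        term = c * xs
        total += term
        if abs(term) < 1e-16 * max(abs(total), 1e-300):
            break
    return total


def _general_from_deltas(f: IncidenceFrequencies, q: float, delta: np.ndarray) -> float:
    k = np.arange(f.T)
    coef = _binom_real(q - 1.0, k) * (-1.0) ** k
    s_hat = float(np.sum(coef * delta))
    if f.Q1 > 0:
        s_hat += (f.Q1 / f.T) * _general_tail(f.T, _coverage_A(f), q)
    if s_hat <= 0:
        return float(empirical_hill(f, q).value)
    return float((s_hat / (f.U / f.T) ** q) ** (1.0 / (1.0 - q)))


def _asymptotic_general(f: IncidenceFrequencies, q: float) -> float:
    """Series estimator of sum(pi^q) for non-integer q, normalised to qD."""
    return _general_from_deltas(f, q, _delta_vector(f))


def asymptotic_hill(f: IncidenceFrequencies, q: float) -> HillEstimate:
    """Asymptotic Hill number of order q >= 0 for incidence data."""
    if q < 0:
        raise ValueError("order q must be >= 0")
    if q == 0:
        value = chao2_richness(f).value
    elif abs(q - 1.0) < _Q1_EPS:
        value = _asymptotic_shannon(f)
    elif q == 2.0:
        value = _asymptotic_simpson(f)
    else:
        value = _asymptotic_general(f, q)
    return HillEstimate(q=q, value=value, variant="asymptotic")


def empirical_profile(f: IncidenceFrequencies, q_grid: np.ndarray) -> np.ndarray:
    """Empirical Hill numbers over a q-grid."""
    return np.array([empirical_hill(f, float(q)).value for q in np.asarray(q_grid)])


def asymptotic_profile(f: IncidenceFrequencies, q_grid: np.ndarray) -> np.ndarray:
    """Asymptotic Hill numbers over a q-grid (shared series kernel)."""
    q_grid = np.asarray(q_grid, dtype=float)
    delta = None
    out = np.empty(q_grid.size)
    for i, q in enumerate(q_grid):
        if q == 0:
            out[i] = chao2_richness(f).value
        elif abs(q - 1.0) < _Q1_EPS:
            out[i] = _asymptotic_shannon(f)
        elif q == 2.0:
            out[i] = _asymptotic_simpson(f)
        else:
            if delta is None:
                delta = _delta_vector(f)
            out[i] = _general_from_deltas(f, q, delta)
    return out


# ---------------------------------------------------------------------------
# Reconstructed assemblage and completeness profiles
# ---------------------------------------------------------------------------

def estimated_assemblage(f: IncidenceFrequencies) -> tuple[np.ndarray, float, float]:
    """Estimate the assemblage's per-unit detection probabilities.

    Returns ``(p_detected, Q0_hat, p_undetected)``: shrunken detection
    probabilities for the S_obs detected phenotypes, the (fractional)
    estimated number of undetected phenotypes, and the common detection
    probability assigned to each of them.  The construction conserves
    incidence mass: detected mass totals ``C_hat * U / T`` and undetected
    mass the coverage deficit ``(1 - C_hat) * U / T``.
    """
    T, U, Q = f.T, f.U, f.Q
    chat = sample_coverage(f)
    q0 = chao2_richness(f).value - f.S_obs
    qt = Q / T
    denom = float(np.sum(qt * (1.0 - qt) ** T))
    tau = 0.0 if denom <= 0 else (U / T) * (1.0 - chat) / denom
    p_det = qt * (1.0 - tau * (1.0 - qt) ** T)
    p0 = (U / T) * (1.0 - chat) / q0 if q0 > 0 else 0.0
    return p_det, float(q0), float(min(p0, 1.0))


def completeness_profile(
    f: IncidenceFrequencies,
    q_grid: np.ndarray | None = None,
    B: int = 0,
    rng: np.random.Generator | None = None,
) -> CompletenessProfile:
    """Sample-completeness profile over orders q (default grid 0..2 by 0.05).

    Anchors: completeness(0) = S_obs / S_chao2 and completeness(1) = C_hat
    hold exactly.  With ``B > 0`` a bootstrap confidence band (normal
    approximation, B replicate assemblages) is attached.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)

    def _profile(fr: IncidenceFrequencies) -> np.ndarray:
        p_det, q0, p0 = estimated_assemblage(fr)
        out = np.empty_like(q_grid)
        for i, q in enumerate(q_grid):
            det = float(np.sum(p_det ** q))
            undet = q0 * (p0 ** q) if q0 > 0 and p0 > 0 else (q0 if q == 0 else 0.0)
            out[i] = det / (det + undet) if det + undet > 0 else 1.0
        return np.clip(out, 0.0, 1.0)

    point = _profile(f)
    ci_low = ci_high = None
    if B > 0:
        if rng is None:
            rng = np.random.default_rng()
        reps = np.stack([_profile(fb) for fb in bootstrap_frequencies(f, B, rng)])
        sd = reps.std(axis=0, ddof=1)
        ci_low = np.clip(point - 1.96 * sd, 0.0, 1.0)
        ci_high = np.clip(point + 1.96 * sd, 0.0, 1.0)
    return CompletenessProfile(q_grid=q_grid, completeness=point, ci_low=ci_low, ci_high=ci_high)


def bootstrap_frequencies(
    f: IncidenceFrequencies, B: int, rng: np.random.Generator
) -> list[IncidenceFrequencies]:
    """B replicate incidence-frequency vectors from the estimated assemblage.

    The bootstrap assemblage has the S_obs detected phenotypes at their
    shrunken probabilities plus ceil(Q0_hat) undetected phenotypes sharing
    the coverage deficit; each replicate draws Q_i ~ Binomial(T, p_i)
    (equivalent to T independent Bernoulli sampling units).
    """
    p_det, q0, _ = estimated_assemblage(f)
    m = int(np.ceil(q0))
    if m > 0:
        mass = (f.U / f.T) * (1.0 - sample_coverage(f))
        p_ext = np.concatenate([p_det, np.full(m, min(mass / m, 1.0))])
    else:
        p_ext = p_det
    p_ext = np.clip(p_ext, 0.0, 1.0)
    draws = rng.binomial(f.T, p_ext, size=(B, p_ext.size))
    out = []
    for b in range(B):
        qb = draws[b]
        qb = qb[qb > 0]
        if qb.size == 0:  # pathological tiny assemblage; keep a placeholder
            qb = np.array([1])
        out.append(IncidenceFrequencies(T=f.T, Q=qb))
    return out


def default_q_grid(step: float = 0.05) -> np.ndarray:
    """Default diversity-order grid: 0 to 2 inclusive."""
    n = int(round(2.0 / step))
    return np.linspace(0.0, 2.0, n + 1)
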