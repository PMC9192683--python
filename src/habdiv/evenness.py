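"""Evenness profiles from Hill numbers and the classical diversity indices.

Two layers of evenness are computed.  The Hill-number layer works on
coverage-standardised diversities: the normalised-slope evenness
``E(q) = (qD - 1) / (0D - 1)`` for q > 0, and Pielou's
``J = ln(1D) / ln(0D)``.  The classical layer reproduces the index formulas
used for cross-study comparison tables, computed on the number of phenotypes
per higher taxon ``n_i`` with ``N = sum n_i``:

* Shannon index (base 2):  H' = -sum (n_i/N) log2(n_i/N)
* Simpson concentration:   D  = sum n_i (n_i - 1) / (N (N - 1))
* Evenness:                J  = [-sum (n_i/N) ln(n_i/N)] / ln(n_taxa)

Note the evenness denominator uses the number of *taxa present*, not N; this
is the unique reading under which published (H', evenness, taxa) triples are
internally consistent, and it makes J = H' * ln(2) / ln(n_taxa) an exact
identity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class EvennessProfile:
    """Normalised-slope evenness over orders q in (0, 2]."""

    q_grid: np.ndarray
    evenness: np.ndarray
    C_target: Optional[float] = None


@dataclass
class ClassicalIndices:
    taxon_counts: np.ndarray
    n_taxa: int
    N_total: int
    shannon_log2: float
    simpson: float
    evenness: float


def evenness_profile(
    hill_values: Sequence[float] | np.ndarray,
    richness: float,
    q_grid: Sequence[float] | np.ndarray,
    C_target: float | None = None,
) -> EvennessProfile:
    """E(q) = (qD - 1) / (0D - 1) for q > 0 at coverage-standardised qD.

    Equals 1 for perfectly even assemblages and tends to 0 in the maximally
    uneven single-dominant limit.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    hill_values = np.asarray(hill_values, dtype=float)
    if richness <= 1:
        raise ValueError("evenness undefined for richness <= 1")
    if (q_grid <= 0).any():
        raise ValueError("evenness profile is defined for q > 0 only")
    ev = (hill_values - 1.0) / (richness - 1.0)
    return EvennessProfile(q_grid=q_grid, evenness=ev, C_target=C_target)


def pielou_j(d0: float, d1: float) -> float:
    """Pielou's evenness from Hill numbers of order 0 and 1: ln(1D)/ln(0D)."""
    if d0 <= 1:
        raise ValueError("Pielou's J undefined for richness <= 1")
    if not 1 <= d1 <= d0 * (1 + 1e-9):
        raise ValueError("require 1 <= 1D <= 0D")
    return float(np.log(d1) / np.log(d0))


def classical_indices(taxon_counts: Sequence[int] | np.ndarray) -> ClassicalIndices:
    """Classical Shannon (log2), Simpson concentration and evenness.

    ``taxon_counts`` holds the number of phenotypes per higher taxon; zero
    entries are allowed and ignored.  Evenness requires at least two taxa
    present.
    """
    n = np.asarray(taxon_counts, dtype=float)
    if (n < 0).any():
        raise ValueError("taxon counts must be non-negative")
    n = n[n > 0]
    n_taxa = int(n.size)
    N = float(n.sum())
    if n_taxa == 0 or N <= 0:
        raise ValueError("no taxa present")
    p = n / N
    h2 = float(-np.sum(p * np.log2(p)))
    simpson = float(np.sum(n * (n - 1.0)) / (N * (N - 1.0))) if N > 1 else 1.0
    if n_taxa < 2:
        raise ValueError("evenness undefined with a single taxon")
    j = float(-np.sum(p * np.log(p)) / np.log(n_taxa))
    return ClassicalIndices(
        taxon_counts=n.astype(int),
        n_taxa=n_taxa,
        N_total=int(N),
        shannon_log2=h2,
        simpson=simpson,
        evenness=j,
    )


def evenness_from_shannon(h_log2: float, n_taxa: int) -> float:
    """Evenness implied by a printed base-2 Shannon index and taxon count.

    J = H' * ln(2) / ln(n_taxa): the deterministic consequence of the
    Shannon and evenness formulas sharing the same proportions.
    """
    if n_taxa < 2:
        raise ValueError("evenness undefined for fewer than two taxa")
    if h_log2 < 0:
        raise ValueError("Shannon index must be non-negative")
    return float(h_log2 * np.log(2.0) / np.log(n_taxa))
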