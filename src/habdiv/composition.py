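"""Community-composition statistics: Bray-Curtis, PERMANOVA, dispersion, nMDS, Venn.

The beta-diversity stage of the workflow: per-area abundance tables are
square-root transformed, pairwise Bray-Curtis dissimilarities computed, and
habitat differences tested with a one-way PERMANOVA (pseudo-F, permutation
p-value with unrestricted permutation of sample labels), backed by a
multivariate-dispersion homogeneity check (distances to group centroids in
principal-coordinate space) and a non-metric MDS ordination.  Phenotype
overlap between habitats is summarised by exact Venn set algebra.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import factorial
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("habdiv")


@dataclass
class DissimilarityMatrix:
    """Symmetric sample x sample dissimilarity matrix with habitat labels."""

    d: np.ndarray
    labels: list
    habitats: list

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ValueError("self-dissimilarity must be zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis dissimilarities must lie in [0, 1]")
        self.d = np.clip(d, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    p_perm: float
    n_perm: int
    exact: bool = False
    pairwise: Optional[pd.DataFrame] = None


@dataclass
class DispersionResult:
    F: float
    p_perm: float
    n_perm: int
    group_means: dict = field(default_factory=dict)
    distances: Optional[np.ndarray] = None


@dataclass
class VennPartition:
    totals: dict
    unique: dict
    pairwise_shared: dict
    shared_all: int
    union: int


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(
    counts: pd.DataFrame,
    habitats: Sequence[str] | Mapping[str, str],
    transform: str = "sqrt",
) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between samples (columns of ``counts``).

    ``transform`` is applied to the per-sample abundance vectors first:
    ``sqrt`` (the default used before PERMANOVA), ``none``, or ``presence``
    (binarise; Bray-Curtis on presences equals Sorensen dissimilarity, used
    for the incidence ordination).
    """
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("need at least two samples")
    if transform == "sqrt":
        y = np.sqrt(y)
    elif transform == "presence":
        y = (y > 0).astype(float)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    tot = y.sum(axis=0)
    if (tot == 0).sum() >= 2:
        raise ValueError("two all-zero samples make their dissimilarity undefined")
    diff = np.abs(y[:, :, None] - y[:, None, :]).sum(axis=0)
    summ = tot[:, None] + tot[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(summ > 0, diff / summ, 0.0)
    np.fill_diagonal(d, 0.0)
    if isinstance(habitats, Mapping):
        hab = [habitats[s] for s in counts.columns]
    else:
        hab = list(habitats)
    if len(hab) != y.shape[1]:
        raise ValueError("one habitat label per sample required")
    return DissimilarityMatrix(d=d, labels=list(counts.columns), habitats=hab)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f_batch(d2: np.ndarray, perms: np.ndarray, k: int, sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of ``perms`` (integer group labels per sample)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    onehot = (perms[:, :, None] == np.arange(k)[None, None, :]).astype(float)
    within = np.einsum("pik,ij,pjk->pk", onehot, d2, onehot) / 2.0
    ss_within = (within / sizes[None, :]).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        return ((ss_total - ss_within) / df_b) / (ss_within / df_w)


def _distinct_arrangements(labels: np.ndarray) -> int:
    n = len(labels)
    counts = np.unique(labels, return_counts=True)[1]
    total = factorial(n)
    for c in counts:
        total //= factorial(int(c))
    return total


def permanova(
    d: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    pairwise: bool = True,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix with habitat as factor.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under unrestricted
    permutation of sample labels.  When fewer distinct label arrangements
    than ``n_perm`` exist, all arrangements are enumerated exactly (with a
    warning) and p is the exact tail probability.  Pairwise tests repeat the
    procedure on each habitat pair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # canonical sample order: permutation stream pairs with samples by id,
    # making p invariant to input order and habitat renaming (same seed)
    order = np.argsort(np.asarray(d.labels, dtype=str))
    dmat = d.d[np.ix_(order, order)]
    hab = np.asarray(d.habitats)[order]
    groups, labels = np.unique(hab, return_inverse=True)
    k = len(groups)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(labels)
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = dmat ** 2
    n = d.n
    f_obs = float(_pseudo_f_batch(d2, labels[None, :], k, sizes)[0])

    n_arr = _distinct_arrangements(labels)
    exact = n_arr <= n_perm
    if exact:
        logger.warning(
            "only %d distinct label arrangements (< %d requested); "
            "enumerating exactly", n_arr, n_perm,
        )
        from sympy.utilities.iterables import multiset_permutations

        perms = np.array(list(multiset_permutations(labels.tolist())))
        f_all = _pseudo_f_batch(d2, perms, k, sizes)
        p = float(np.mean(f_all >= f_obs - 1e-12))
        n_used = n_arr
    else:
        perms = np.stack([rng.permutation(labels) for _ in range(n_perm)])
        f_perm = _pseudo_f_batch(d2, perms, k, sizes)
        p = float((1 + np.sum(f_perm >= f_obs - 1e-12)) / (1 + n_perm))
        n_used = n_perm

    pair_table = None
    if pairwise and k > 2:
        ids = np.asarray(d.labels, dtype=str)[order]
        rows = []
        for a, b in itertools.combinations(range(k), 2):
            sel = np.isin(labels, (a, b))
            sub = DissimilarityMatrix(
                d=dmat[np.ix_(sel, sel)],
                labels=list(ids[sel]),
                habitats=list(hab[sel]),
            )
            r = permanova(sub, n_perm=n_perm, seed=rng, pairwise=False)
            rows.append(
                {"group1": groups[a], "group2": groups[b],
                 "pseudo_F": r.pseudo_F, "p_perm": r.p_perm, "n_perm": r.n_perm}
            )
        pair_table = pd.DataFrame(rows)

    return PermanovaResult(
        pseudo_F=f_obs, df_between=k - 1, df_within=n - k,
        p_perm=p, n_perm=n_used, exact=exact, pairwise=pair_table,
    )


# ---------------------------------------------------------------------------
# Multivariate dispersion
# ---------------------------------------------------------------------------

def _centroid_distances(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Negative eigenvalues (non-Euclidean dissimilarities) contribute
    imaginary axes whose squared distances are subtracted; results are
    clamped at zero so distances stay real and non-negative.
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh((g + g.T) / 2.0)
    pos, neg = w > 1e-10, w < -1e-10
    xr = v[:, pos] * np.sqrt(w[pos])
    xi = v[:, neg] * np.sqrt(-w[neg])
    z2 = np.empty(n)
    for g_id in np.unique(labels):
        idx = labels == g_id
        cr, ci = xr[idx].mean(axis=0), xi[idx].mean(axis=0)
        z2[idx] = ((xr[idx] - cr) ** 2).sum(axis=1) - ((xi[idx] - ci) ** 2).sum(axis=1)
    return np.sqrt(np.clip(z2, 0.0, None))


def dispersion_check(
    d: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersion (PERMDISP-style).

    Computes each sample's distance to its group centroid in the
    principal-coordinate embedding and tests group differences in those
    distances with a one-way F statistic whose null distribution comes from
    permuting group membership of the distances.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = np.argsort(np.asarray(d.labels, dtype=str))
    hab = np.asarray(d.habitats)[order]
    groups, labels = np.unique(hab, return_inverse=True)
    k = len(groups)
    if k < 2:
        raise ValueError("dispersion check needs at least two groups")
    z = _centroid_distances(d.d[np.ix_(order, order)], labels)

    def _f(lbl: np.ndarray) -> float:
        gm = np.array([z[lbl == g].mean() for g in range(k)])
        sizes = np.bincount(lbl, minlength=k)
        ss_b = float(np.sum(sizes * (gm - z.mean()) ** 2))
        ss_w = float(np.sum((z - gm[lbl]) ** 2))
        df_b, df_w = k - 1, len(z) - k
        return (ss_b / df_b) / (ss_w / df_w) if ss_w > 0 else np.inf

    f_obs = _f(labels)
    f_perm = np.array([_f(rng.permutation(labels)) for _ in range(n_perm)])
    p = float((1 + np.sum(f_perm >= f_obs - 1e-12)) / (1 + n_perm))
    return DispersionResult(
        F=f_obs, p_perm=p, n_perm=n_perm,
        group_means={g: float(z[labels == i].mean()) for i, g in enumerate(groups)},
        distances=z,
    )


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------

def nmds(
    d: DissimilarityMatrix,
    dims: int = 2,
    restarts: int = 20,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS ordination minimising Kruskal stress-1.

    Runs ``restarts`` random initialisations plus one classical-scaling
    (PCoA) start and keeps the configuration with the lowest stress
    (ties broken by run order).  Returns (coordinates, stress).
    """
    if d.n < 4:
        raise ValueError("nMDS needs at least 4 samples")
    from sklearn.manifold import MDS

    best_coords, best_stress = None, np.inf
    inits = ["classical_mds"] + ["random"] * restarts
    for i, ini in enumerate(inits):
        mds = MDS(
            n_components=dims, metric_mds=False, metric="precomputed",
            n_init=1, max_iter=500, eps=1e-9, normalized_stress=True,
            init=ini, random_state=None if seed is None else seed + i,
        )
        coords = mds.fit_transform(d.d)
        if np.isfinite(mds.stress_) and mds.stress_ < best_stress - 1e-12:
            best_stress, best_coords = float(mds.stress_), coords
    if best_coords is None:
        raise RuntimeError("nMDS failed to converge in all restarts")
    frame = pd.DataFrame(
        best_coords, index=d.labels, columns=[f"axis{i + 1}" for i in range(dims)]
    )
    frame["habitat"] = d.habitats
    return frame, best_stress


# ---------------------------------------------------------------------------
# Venn partitioning
# ---------------------------------------------------------------------------

def venn_partition(habitat_sets: Mapping[str, set]) -> VennPartition:
    """Exact shared/unique phenotype counts for 2-3 habitat sets."""
    names = list(habitat_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_partition supports 2 or 3 sets")
    sets = {k: set(v) for k, v in habitat_sets.items()}
    union = set().union(*sets.values())
    inter_all = set.intersection(*sets.values())
    unique = {
        k: len(sets[k] - set().union(*(sets[o] for o in names if o != k)))
        for k in names
    }
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in itertools.combinations(names, 2)
    }
    return VennPartition(
        totals={k: len(v) for k, v in sets.items()},
        unique=unique,
        pairwise_shared=pairwise,
        shared_all=len(inter_all),
        union=len(union),
    )


def shared_from_totals(size_a: int, size_b: int, size_union: int) -> tuple[int, int, int]:
    """Inclusion-exclusion recovery of (shared, unique_a, unique_b) from totals."""
    shared = size_a + size_b - size_union
    if shared < 0:
        raise ValueError("inconsistent totals: |A| + |B| < |A u B|")
    return shared, size_a - shared, size_b - shared
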