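"""Community structure: commonness partition, Bray-Curtis distances, MRPP,
and PCoA-based multivariate dispersion (the betadisper-style evenness test).

Sampling units are transect sampling events (site x year x month x
treatment); distances between their species profiles are Bray-Curtis,
which is bounded in [0, 1] and non-Euclidean, so the PCoA embedding keeps
the imaginary axes that arise from negative eigenvalues and subtracts
their squared contributions from distances to centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy import stats

from .io import SurveyTable, TaxonRegistry, ValidationError, survey_matrix


# ---------------------------------------------------------------------------
# Commonness


@dataclass
class CommonnessPartition:
    """Common/uncommon split at a study-wide relative-abundance threshold.

    A species is common iff its share of all individuals collected over the
    entire study strictly exceeds ``threshold`` (default the ~1% boundary).
    ``mode`` controls the pooled taxon: ``exclude_pooled`` removes it from
    the candidate set (the "8 common" reading), ``include_pooled``
    classifies it like any other taxon (the "9 common" reading).
    """

    threshold: float
    mode: str
    common: tuple[str, ...]
    uncommon: tuple[str, ...]
    excluded: tuple[str, ...] = ()
    shares: pd.Series = field(default=None, repr=False)

    def group(self, name: str) -> tuple[str, ...]:
        if name == "common":
            return self.common
        if name == "uncommon":
            return self.uncommon
        raise KeyError(f"unknown commonness group {name!r}")


def classify_commonness(
    bees: SurveyTable,
    registry: TaxonRegistry,
    threshold: float = 0.01,
    mode: str = "include_pooled",
) -> CommonnessPartition:
    """Partition bee taxa by study-wide relative abundance (strict '>')."""
    if mode not in ("include_pooled", "exclude_pooled"):
        raise ValidationError(f"unknown mode {mode!r}")
    totals = bees.data.groupby("taxon")["value"].sum()
    grand = totals.sum()
    if grand <= 0:
        raise ValidationError("cannot classify an empty community")
    shares = totals / grand  # denominator: the entire community, pooled incl.
    pooled = registry.pooled_taxon
    excluded: tuple[str, ...] = ()
    candidates = shares
    if mode == "exclude_pooled" and pooled is not None and pooled in shares.index:
        excluded = (pooled,)
        candidates = shares.drop(pooled)
    common = tuple(sorted(candidates.index[candidates > threshold]))
    uncommon = tuple(sorted(candidates.index[candidates <= threshold]))
    return CommonnessPartition(
        threshold=threshold,
        mode=mode,
        common=common,
        uncommon=uncommon,
        excluded=excluded,
        shares=shares,
    )


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities among labelled sampling units."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValidationError("labels do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)


def bray_curtis_matrix(
    bees: SurveyTable,
    unit_keys: Sequence[str] = ("site", "treatment", "year", "month"),
    taxa=None,
) -> DistanceMatrix:
    """Bray-Curtis dissimilarities d = sum|x-y| / sum(x+y) between units."""
    wide = survey_matrix(bees, unit_keys=unit_keys, taxa=taxa)
    return bray_curtis_from_wide(wide)


def bray_curtis_from_wide(wide: pd.DataFrame) -> DistanceMatrix:
    if wide.shape[0] < 2:
        raise ValidationError("need at least two sampling units")
    zero = wide.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = list(wide.index[zero])
        raise ValidationError(
            f"Bray-Curtis undefined between all-zero units: {bad}"
        )
    d = squareform(pdist(wide.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(tuple(wide.index), d, metric="braycurtis")


# ---------------------------------------------------------------------------
# MRPP


@dataclass
class MrppResult:
    """MRPP test of within-group homogeneity of distances.

    T standardizes the observed weighted within-group mean distance delta
    against its permutation distribution; A = 1 - delta/E[delta] is the
    chance-corrected within-group agreement; p is the fraction of
    permutations at least as concentrated as observed.
    """

    T: float
    A: float
    p: float
    delta: float
    n_perm: int
    seed: int | None
    method: str


def _weighted_within_delta(
    d: np.ndarray, group_indices: list[np.ndarray], n: int
) -> float:
    delta = 0.0
    for idx in group_indices:
        sub = d[np.ix_(idx, idx)]
        k = len(idx)
        mean_within = sub.sum() / (k * (k - 1))
        delta += (k / n) * mean_within
    return delta


def mrpp(
    D: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "permutation",
) -> MrppResult:
    """Multi-response permutation procedure with C_g = n_g / N group weights.

    ``method='exhaustive'`` enumerates every distinct relabelling (feasible
    for small unit counts); otherwise ``n_perm`` seeded random relabellings
    are drawn and p = (1 + #{delta_perm <= delta_obs}) / (n_perm + 1).
    """
    groups = np.asarray(groups)
    if len(groups) != D.n:
        raise ValidationError("group labels do not match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValidationError("need >= 2 groups with >= 2 units each")
    d = D.values
    n = D.n
    obs_idx = [np.flatnonzero(groups == g) for g in labels]
    delta_obs = _weighted_within_delta(d, obs_idx, n)

    deltas = []
    if method == "exhaustive":
        deltas = [
            _weighted_within_delta(d, part, n)
            for part in _iter_partitions(n, counts)
        ]
        n_used = len(deltas)
        seed_used = None
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        order = np.arange(n)
        for _ in range(n_perm):
            perm = rng.permutation(order)
            idx = []
            start = 0
            for c in counts:
                idx.append(perm[start : start + c])
                start += c
            deltas.append(_weighted_within_delta(d, idx, n))
        n_used = n_perm
        seed_used = seed
    else:
        raise ValidationError(f"unknown method {method!r}")

    deltas = np.asarray(deltas)
    mean_d = deltas.mean()
    sd_d = deltas.std(ddof=0)
    T = (delta_obs - mean_d) / sd_d if sd_d > 0 else 0.0
    A = 1.0 - delta_obs / mean_d if mean_d > 0 else 0.0
    if method == "exhaustive":
        p = float((deltas <= delta_obs + 1e-12).sum()) / len(deltas)
    else:
        p = (1.0 + float((deltas <= delta_obs + 1e-12).sum())) / (n_perm + 1.0)
    return MrppResult(
        T=float(T),
        A=float(A),
        p=float(p),
        delta=float(delta_obs),
        n_perm=n_used,
        seed=seed_used,
        method=method,
    )


def _iter_partitions(n: int, counts: np.ndarray):
    """Yield every distinct assignment of n units into groups of fixed sizes."""

    def rec(remaining: frozenset, sizes):
        if not sizes:
            yield []
            return
        k = sizes[0]
        rem_sorted = sorted(remaining)
        anchor = rem_sorted[0]
        # fix the smallest remaining unit in the first group iff group sizes tie,
        # otherwise enumerate all subsets; distinctness only matters among
        # equal-size groups, handled by anchoring.
        for combo in combinations(rem_sorted, k):
            if len(sizes) > 1 and sizes[0] == sizes[1] and anchor not in combo:
                continue
            rest = remaining - set(combo)
            for tail in rec(rest, sizes[1:]):
                yield [np.asarray(combo)] + tail

    # Note: anchoring is exact only when all equal-size groups are adjacent in
    # `sizes`; we sort sizes descending to guarantee that.
    order = np.argsort(-counts, kind="stable")
    sizes = tuple(int(c) for c in counts[order])
    yield from rec(frozenset(range(n)), sizes)


# ---------------------------------------------------------------------------
# PCoA and multivariate dispersion


@dataclass
class PcoaResult:
    """Principal-coordinates embedding retaining real and imaginary axes."""

    coords_real: np.ndarray  # units x positive-eigenvalue axes
    coords_imag: np.ndarray  # units x |negative-eigenvalue| axes
    eigenvalues: np.ndarray  # sorted non-increasing


def pcoa(D: DistanceMatrix, eps: float = 1e-10) -> PcoaResult:
    """Gower double-centred eigendecomposition of a distance matrix.

    Axes with positive eigenvalues carry real coordinates scaled by
    sqrt(lambda); negative eigenvalues (non-Euclidean input) yield
    imaginary axes scaled by sqrt(-lambda), retained so squared distances
    can be corrected downstream.
    """
    d = D.values
    a = -0.5 * d**2
    n = d.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    scale = np.abs(vals)
    scale[scale < eps] = 0.0
    coords = vecs * np.sqrt(scale)[None, :]
    pos = vals > eps
    neg = vals < -eps
    return PcoaResult(
        coords_real=coords[:, pos],
        coords_imag=coords[:, neg],
        eigenvalues=vals,
    )


@dataclass
class DispersionResult:
    """Per-unit distances to own-group centroid plus a one-way ANOVA on them."""

    labels: tuple[str, ...]
    groups: tuple[str, ...]
    distances: np.ndarray
    group_means: dict[str, float]
    F: float
    p_parametric: float
    p_permutation: float | None
    eigen_correction: str


def _centroid_distances(
    emb: PcoaResult, groups: np.ndarray
) -> np.ndarray:
    dist2 = np.zeros(len(groups))
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        cr = emb.coords_real[idx].mean(axis=0)
        ci = emb.coords_imag[idx].mean(axis=0)
        d2r = ((emb.coords_real[idx] - cr) ** 2).sum(axis=1)
        d2i = ((emb.coords_imag[idx] - ci) ** 2).sum(axis=1)
        dist2[idx] = d2r - d2i  # imaginary axes subtract
    return np.sqrt(np.maximum(dist2, 0.0))


def multivariate_dispersion(
    D: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 0,
    seed: int = 0,
) -> DispersionResult:
    """Compare group spreads via distances to group centroids in PCoA space.

    F and its parametric p come from a one-way ANOVA on the distances; an
    optional permutation p reshuffles group labels over the distance-bearing
    units.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != D.n:
        raise ValidationError("group labels do not match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValidationError("need >= 2 groups with >= 2 units each")
    emb = pcoa(D)
    dist = _centroid_distances(emb, groups)
    by_group = [dist[groups == g] for g in labels]
    if all(np.allclose(b, b[0]) for b in by_group):
        raise ValidationError("zero-variance distances in every group; F undefined")
    F, p_param = stats.f_oneway(*by_group)

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            shuffled = rng.permutation(groups)
            fb, _ = stats.f_oneway(*(dist[shuffled == g] for g in labels))
            if fb >= F - 1e-12:
                hits += 1
        p_perm = (1.0 + hits) / (n_perm + 1.0)

    return DispersionResult(
        labels=D.labels,
        groups=tuple(groups),
        distances=dist,
        group_means={g: float(dist[groups == g].mean()) for g in labels},
        F=float(F),
        p_parametric=float(p_param),
        p_permutation=p_perm,
        eigen_correction="imaginary-axes-subtracted",
    )
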