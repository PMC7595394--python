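"""Hill-number diversity, sample-size rarefaction/extrapolation, and
Shannon landscape diversity.

Hill numbers qD express diversity as an effective number of equally
abundant species: q=0 is richness S, q=1 the exponential of Shannon
entropy H', q=2 the inverse Simpson concentration. Sensitivity to rare
species decreases with q, so comparing the three orders separates the
contributions of common and uncommon species.

Interpolation (m <= n) of richness uses the exact hypergeometric
expectation; orders 1 and 2 use a seeded Monte-Carlo subsampling
expectation. Extrapolation (n < m <= 2n) of richness approaches the
Chao1-style asymptote through the undetected-species estimate f0; orders
1 and 2 are held at the plug-in estimate. Confidence bands come from a
percentile bootstrap over individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import LandCoverProfile, SurveyTable, ValidationError


def abundance_vector(table: SurveyTable, taxa=None) -> pd.Series:
    """Pool a bee survey into per-species totals (one entry per species)."""
    s = table.data.groupby("taxon")["value"].sum()
    if taxa is not None:
        s = s.reindex(list(taxa), fill_value=0.0)
    return s.astype(float)


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(
        counts.values if isinstance(counts, pd.Series) else counts, dtype=float
    )
    if arr.ndim != 1:
        raise ValidationError("abundance vector must be one-dimensional")
    if np.any(arr < 0) or np.any(arr % 1 != 0):
        raise ValidationError("abundances must be non-negative integers")
    if arr.sum() < 1:
        raise ValidationError("abundance vector must contain >= 1 individual")
    return arr


def hill_number(counts, q: int) -> float:
    """Effective species number of order q in {0, 1, 2}.

    q=0 -> observed richness; q=1 -> exp(-sum p ln p); q=2 -> 1/sum p^2.
    """
    x = _as_counts(counts)
    if q not in (0, 1, 2):
        raise ValidationError(f"order q must be 0, 1 or 2, got {q}")
    p = x[x > 0] / x.sum()
    if q == 0:
        return float(len(p))
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(1.0 / np.sum(p**2))


def rarefy_richness(counts, m: int) -> float:
    """Exact expected richness of a subsample of m individuals (m <= n).

    E[S_m] = S_obs - sum_i C(n - x_i, m) / C(n, m), the hypergeometric
    expectation under subsampling without replacement.
    """
    x = _as_counts(counts)
    x = x[x > 0]
    n = int(x.sum())
    if not 1 <= m <= n:
        raise ValidationError(f"m must satisfy 1 <= m <= n={n}, got {m}")
    # log-space binomial ratios; terms with n - x_i < m vanish
    keep = n - x >= m
    lognum = gammaln(n - x[keep] + 1) - gammaln(m + 1) - gammaln(n - x[keep] - m + 1)
    logden = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    absent = np.exp(lognum - logden)
    return float(len(x) - absent.sum())


def _undetected_species(x: np.ndarray) -> float:
    """Chao1-style estimate f0 of undetected species (iNEXT-style form)."""
    n = x.sum()
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return ((n - 1) / n) * f1 * f1 / (2 * f2)
    return ((n - 1) / n) * f1 * (f1 - 1) / 2


def _extrapolate_richness(x: np.ndarray, m: int) -> float:
    n = int(x.sum())
    s_obs = int((x > 0).sum())
    f0 = _undetected_species(x)
    f1 = int((x == 1).sum())
    if f0 == 0 or f1 == 0:
        return float(s_obs)
    m_star = m - n
    return s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star)


def _mc_hill_interp(
    x: np.ndarray, q: int, m: int, n_sub: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo expectation of qD over subsamples of size m (no replacement)."""
    n = int(x.sum())
    if m == n:
        return hill_number(x, q)
    draws = rng.multivariate_hypergeometric(
        x.astype(int), m, size=n_sub, method="marginals"
    )
    vals = [hill_number(d, q) for d in draws]
    return float(np.mean(vals))


@dataclass
class RarefactionCurve:
    """Point estimates and 95% bootstrap bounds of qD along a sample-size grid."""

    q: int
    table: pd.DataFrame  # columns: m, kind, estimate, lo95, hi95
    n_obs: int
    qd_obs: float


def rarefaction_curve(
    counts,
    q: int,
    m_grid=None,
    n_boot: int = 200,
    seed: int = 0,
    n_sub: int = 100,
) -> RarefactionCurve:
    """Sample-size-based rarefaction/extrapolation curve with bootstrap bands.

    Points beyond twice the observed sample size are refused (dropped with a
    warning): long-range extrapolation of the asymptotic formula is not
    trustworthy and short dotted extensions are all the comparison needs.
    """
    x = _as_counts(counts)
    x = x[x > 0].astype(int)
    n = int(x.sum())
    if q not in (0, 1, 2):
        raise ValidationError(f"order q must be 0, 1 or 2, got {q}")
    if m_grid is None:
        m_grid = np.unique(
            np.concatenate(
                [
                    np.linspace(1, n, 11).astype(int),
                    np.linspace(n, 2 * n, 5).astype(int),
                ]
            )
        )
    m_grid = np.asarray(sorted(set(int(m) for m in m_grid)))
    if m_grid.size == 0:
        raise ValidationError("m_grid must be non-empty")
    if (m_grid < 1).any():
        raise ValidationError("sample sizes must be >= 1")
    if (m_grid > 2 * n).any():
        warnings.warn(
            f"dropping grid points beyond 2n = {2 * n}: long-range "
            "extrapolation refused",
            stacklevel=2,
        )
        m_grid = m_grid[m_grid <= 2 * n]

    rng = np.random.default_rng(seed)

    def estimate(vec: np.ndarray, m: int, r: np.random.Generator) -> float:
        nv = int(vec.sum())
        if m <= nv:
            if q == 0:
                return rarefy_richness(vec, m)
            return _mc_hill_interp(vec, q, m, n_sub, r)
        if q == 0:
            return _extrapolate_richness(vec, m)
        return hill_number(vec, q)  # asymptotic plug-in, held flat

    points = np.array([estimate(x, m, rng) for m in m_grid])

    # percentile bootstrap over individuals (multinomial resampling)
    p = x / n
    boot = np.empty((n_boot, m_grid.size))
    for b in range(n_boot):
        resampled = rng.multinomial(n, p)
        resampled = resampled[resampled > 0]
        boot[b] = [estimate(resampled, m, rng) for m in m_grid]
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    # the interval must bracket the point estimate itself
    lo = np.minimum(lo, points)
    hi = np.maximum(hi, points)

    kind = np.where(
        m_grid < n, "interpolated", np.where(m_grid == n, "observed", "extrapolated")
    )
    table = pd.DataFrame(
        {"m": m_grid, "kind": kind, "estimate": points, "lo95": lo, "hi95": hi}
    )
    return RarefactionCurve(q=q, table=table, n_obs=n, qd_obs=hill_number(x, q))


# ---------------------------------------------------------------------------
# Landscape diversity


def shannon_landscape_diversity(profile: LandCoverProfile) -> float:
    """Shannon diversity H's = -sum(p_i ln p_i) over land-cover categories.

    Zero-proportion categories contribute nothing.
    """
    p = profile.categories["proportion"].to_numpy()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def noncrop_proportion(profile: LandCoverProfile) -> float:
    """Summed proportion of categories flagged non-crop; in [0, 1]."""
    df = profile.categories
    return float(df.loc[df["noncrop"], "proportion"].sum())
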