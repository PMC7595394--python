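"""Correlation-based bee-plant co-occurrence network and derived statistics.

For every bee species b and forb species p, the monthly strip-field
surveys give two series aligned on the shared (site, month, year)
sampling events: the bee's trap count and the plant's proportional
cover. The network stores their Pearson correlation r, the two-sided
p-value from the t transform on n-2 degrees of freedom, a BH-adjusted p,
and the per-pair sample size. A link is selected when r > 0 and the
chosen p-value (unadjusted by default) is strictly below alpha.

Derived outputs: the plant-family x bee-family proportion table of
selected links, native-vs-exotic link ratios per bee group, per-month
bipartite family edge lists, and a validation correlation of the network
against an independently observed visitation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import CommonnessPartition
from .io import (
    SurveyTable,
    TaxonRegistry,
    ValidationError,
    VisitationMatrix,
    survey_matrix,
)

DEFAULT_PAIRING: tuple[str, ...] = ("site", "year", "month")


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int
    defined: bool


def pearson_r_p(x, y) -> PearsonResult:
    """Sample Pearson r with a two-sided t-test p-value on n-2 df.

    Undefined (constant series or n < 3) is reported as a flagged result,
    not an exception, so matrix construction can record it per cell.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be one-dimensional and equal length")
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(np.nan, np.nan, n, False)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return PearsonResult(r, p, n, True)


@dataclass
class CooccurrenceNetwork:
    """Bee x plant matrices of r, p, adjusted p, and per-pair sample size."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    defined: pd.DataFrame
    pairing: tuple[str, ...]
    p_adj: pd.DataFrame | None = None
    sig: pd.DataFrame | None = None
    alpha: float | None = None
    used_adjusted: bool | None = None

    @property
    def bees(self) -> list[str]:
        return list(self.r.index)

    @property
    def plants(self) -> list[str]:
        return list(self.r.columns)

    def n_selected(self) -> int:
        if self.sig is None:
            raise ValidationError("no selection applied yet")
        return int(self.sig.values.sum())

    def to_long(self) -> pd.DataFrame:
        """Long per-pair table: bee, plant, r, p, p_adj, n, defined, significant."""
        rows = self.r.stack(future_stack=True).rename("r").reset_index()
        rows.columns = ["bee", "plant", "r"]
        rows["p"] = self.p.stack(future_stack=True).values
        if self.p_adj is not None:
            rows["p_adj"] = self.p_adj.stack(future_stack=True).values
        rows["n"] = self.n.stack(future_stack=True).values
        rows["defined"] = self.defined.stack(future_stack=True).values
        if self.sig is not None:
            rows["significant"] = self.sig.stack(future_stack=True).values
        return rows


def build_cooccurrence(
    bees: SurveyTable,
    plants: SurveyTable,
    pairing: Sequence[str] = DEFAULT_PAIRING,
    strip_only: bool = True,
) -> CooccurrenceNetwork:
    """Correlate every bee count series against every plant cover series.

    Series are aligned on the pairing keys shared by both tables (absences
    fill as zero); strip-field records only, since cover is surveyed within
    the strips. Cells with n < 3 paired events or a constant series are
    flagged undefined and can never be selected.
    """
    pairing = tuple(pairing)
    b = bees.data
    pl = plants.data
    if strip_only:
        b = b[b["treatment"] == "strip"]
        pl = pl[pl["treatment"] == "strip"]
    if b.empty or pl.empty:
        raise ValidationError("no strip-field records to correlate")

    bt = SurveyTable(b, role=bees.role)
    pt = SurveyTable(pl, role=plants.role)
    wb = survey_matrix(bt, unit_keys=pairing)
    wp = survey_matrix(pt, unit_keys=pairing)
    shared = sorted(set(wb.index) & set(wp.index))
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared pairing keys; need >= 3"
        )
    X = wb.loc[shared].to_numpy(dtype=float)
    Y = wp.loc[shared].to_numpy(dtype=float)
    n = len(shared)

    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    sx = xc.std(axis=0, ddof=1)
    sy = yc.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / ((n - 1) * np.outer(sx, sy))
    r = np.clip(r, -1.0, 1.0)
    defined = (sx > 0)[:, None] & (sy > 0)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    r[~defined] = np.nan
    p[~defined] = np.nan

    bee_ix = list(wb.columns)
    plant_ix = list(wp.columns)
    return CooccurrenceNetwork(
        r=pd.DataFrame(r, index=bee_ix, columns=plant_ix),
        p=pd.DataFrame(p, index=bee_ix, columns=plant_ix),
        n=pd.DataFrame(
            np.full_like(r, n, dtype=int), index=bee_ix, columns=plant_ix
        ),
        defined=pd.DataFrame(defined, index=bee_ix, columns=plant_ix),
        pairing=pairing,
    )


def bh_adjust(p: pd.DataFrame, defined: pd.DataFrame | None = None) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment of a p-value matrix.

    Undefined cells are excluded from the family size m and stay NaN.
    """
    pv = p.to_numpy(dtype=float)
    mask = (
        defined.to_numpy(dtype=bool)
        if defined is not None
        else ~np.isnan(pv)
    )
    out = np.full(pv.shape, np.nan)
    flat = pv[mask]
    if flat.size:
        _, adj, _, _ = multipletests(flat, method="fdr_bh")
        out[mask] = adj
    return pd.DataFrame(out, index=p.index, columns=p.columns)


def select_links(
    net: CooccurrenceNetwork,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Apply the selection rule r > 0 and chosen p < alpha (strict).

    Stores the mask (and the BH-adjusted p matrix if requested) on the
    network and returns the mask.
    """
    if use_adjusted:
        if net.p_adj is None:
            net.p_adj = bh_adjust(net.p, net.defined)
        pmat = net.p_adj
    else:
        pmat = net.p
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        mask = (net.r > 0) & (pmat < alpha) & net.defined
    net.sig = mask.fillna(False).astype(bool)
    net.alpha = alpha
    net.used_adjusted = use_adjusted
    return net.sig


def validate_vs_visitation(
    net: CooccurrenceNetwork,
    visits: VisitationMatrix,
    use: str = "r",
) -> PearsonResult:
    """Correlate the co-occurrence network with observed visitation counts.

    Flattens both matrices over the cells where the network is defined and
    returns the Pearson (r, p). ``use='r'`` correlates the correlation
    coefficients themselves (the default reading); ``use='mask'``
    correlates the binary selection indicator instead.
    """
    v = visits.data.reindex(index=net.bees, columns=net.plants)
    if v.isna().any().any():
        raise ValidationError("visitation matrix does not cover network taxa")
    d = net.defined.to_numpy(dtype=bool)
    if use == "r":
        left = net.r.to_numpy(dtype=float)[d]
    elif use == "mask":
        if net.sig is None:
            raise ValidationError("selection must be applied before use='mask'")
        left = net.sig.to_numpy(dtype=float)[d]
    else:
        raise ValidationError(f"unknown mode {use!r}")
    right = v.to_numpy(dtype=float)[d]
    if left.size < 3:
        raise ValidationError("need >= 3 defined cells for validation")
    return pearson_r_p(left, right)


# ---------------------------------------------------------------------------
# Derived summaries


def family_proportions(
    net: CooccurrenceNetwork, registry: TaxonRegistry
) -> pd.DataFrame:
    """Plant-family x bee-family proportions of selected links.

    Each cell is (#selected links between members of the two families) /
    (total #selected links); "Totals" row and column are computed from the
    unrounded proportions so the grand total is exactly 1.
    """
    if net.sig is None:
        raise ValidationError("selection must be applied first")
    total = net.n_selected()
    bee_fam = registry.family_map("bee")
    plant_fam = registry.family_map("plant")
    if total == 0:
        warnings.warn("no selected links; family table is empty", stacklevel=2)
        return pd.DataFrame()
    links = net.sig.stack(future_stack=True)
    links = links[links].reset_index()
    links.columns = ["bee", "plant", "sig"]
    links["bee_family"] = links["bee"].map(bee_fam)
    links["plant_family"] = links["plant"].map(plant_fam)
    table = (
        links.pivot_table(
            index="plant_family",
            columns="bee_family",
            values="sig",
            aggfunc="size",
            fill_value=0,
        ).astype(float)
        / total
    )
    table["Totals"] = table.sum(axis=1)
    table.loc["Totals"] = table.sum(axis=0)
    return table


class OriginRatio(NamedTuple):
    """Native:exotic selected-link ratio for one bee group.

    ratio > 1 means greater affinity with native prairie forbs, < 1 with
    exotic/weedy forbs; +inf when only native links exist, NaN when the
    group has no selected links at all.
    """

    ratio: float
    n_native: int
    n_exotic: int


def _bee_group_members(
    group: str,
    registry: TaxonRegistry,
    partition: CommonnessPartition | None,
) -> list[str]:
    if group in ("common", "uncommon"):
        if partition is None:
            raise ValidationError(
                f"a CommonnessPartition is required for group {group!r}"
            )
        return list(partition.group(group))
    families = set(registry.data.loc[registry.data["role"] == "bee", "family"])
    if group in families:
        return [t for t, f in registry.family_map("bee").items() if f == group]
    raise ValidationError(f"unknown bee group {group!r}")


def origin_ratio(
    net: CooccurrenceNetwork,
    registry: TaxonRegistry,
    bee_group: str,
    partition: CommonnessPartition | None = None,
) -> OriginRatio:
    """Ratio of selected links to native-prairie vs exotic/weedy forbs."""
    if net.sig is None:
        raise ValidationError("selection must be applied first")
    members = _bee_group_members(bee_group, registry, partition)
    if not members:
        raise ValidationError(f"bee group {bee_group!r} is empty")
    members = [m for m in members if m in net.sig.index]
    origin = registry.origin_map()
    native_plants = [p for p in net.plants if origin.get(p) == "native_prairie"]
    exotic_plants = [p for p in net.plants if origin.get(p) == "exotic_weedy"]
    sub = net.sig.loc[members]
    n_native = int(sub[native_plants].values.sum())
    n_exotic = int(sub[exotic_plants].values.sum())
    if n_exotic == 0:
        ratio = np.inf if n_native > 0 else np.nan
    else:
        ratio = n_native / n_exotic
    return OriginRatio(float(ratio), n_native, n_exotic)


def origin_ratio_table(
    net: CooccurrenceNetwork,
    registry: TaxonRegistry,
    partition: CommonnessPartition,
) -> pd.DataFrame:
    """Origin ratios for every bee family plus the common/uncommon groups."""
    families = sorted(
        set(registry.data.loc[registry.data["role"] == "bee", "family"])
    )
    rows = []
    for group in families + ["common", "uncommon"]:
        res = origin_ratio(net, registry, group, partition)
        rows.append(
            {
                "bee_group": group,
                "ratio": res.ratio,
                "n_native": res.n_native,
                "n_exotic": res.n_exotic,
            }
        )
    return pd.DataFrame(rows)


def monthly_networks(
    bees: SurveyTable,
    plants: SurveyTable,
    registry: TaxonRegistry,
    alpha: float = 0.05,
    pairing: Sequence[str] = ("site", "year"),
) -> pd.DataFrame:
    """Per-month bipartite family edge lists from month-restricted networks.

    For each survey month independently, the co-occurrence network is
    rebuilt on that month's strip samples (paired on site x year), links
    are selected with the unadjusted rule, and species-level links are
    aggregated to plant-family x bee-family edge weights (the number of
    selected species pairs). Months with fewer than three samples are
    skipped with a warning.
    """
    from .io import MONTHS

    bee_fam = registry.family_map("bee")
    plant_fam = registry.family_map("plant")
    edges = []
    for month in MONTHS:
        bm = bees.data[bees.data["month"] == month]
        pm = plants.data[plants.data["month"] == month]
        if bm.empty or pm.empty:
            warnings.warn(f"month {month}: no records, skipped", stacklevel=2)
            continue
        try:
            net = build_cooccurrence(
                SurveyTable(bm, role=bees.role),
                SurveyTable(pm, role=plants.role),
                pairing=pairing,
            )
        except ValidationError as exc:
            warnings.warn(f"month {month}: {exc}; skipped", stacklevel=2)
            continue
        sig = select_links(net, alpha=alpha, use_adjusted=False)
        links = sig.stack(future_stack=True)
        links = links[links].reset_index()
        links.columns = ["bee", "plant", "sig"]
        if links.empty:
            continue
        links["bee_family"] = links["bee"].map(bee_fam)
        links["plant_family"] = links["plant"].map(plant_fam)
        counts = (
            links.groupby(["plant_family", "bee_family"])
            .size()
            .reset_index(name="weight")
        )
        counts.insert(0, "month", month)
        edges.append(counts)
    if not edges:
        return pd.DataFrame(
            columns=["month", "plant_family", "bee_family", "weight"]
        )
    return pd.concat(edges, ignore_index=True)
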