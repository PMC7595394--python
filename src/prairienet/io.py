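"""Data model and readers/writers for the survey tables shared by every stage.

The canonical layout is long ("tidy"): one record per
(site, treatment, year, month, taxon) with a single numeric value — an
integer trap count for bees, a proportional cover in [0, 1] for plants.
Wide matrices (sampling events x taxa) are derived views; absences are
implicit zeros, because trap and quadrat surveys record absence by not
recording anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MONTHS: tuple[str, ...] = ("May", "Jun", "Jul", "Aug")
TREATMENTS: tuple[str, ...] = ("strip", "control")
BEE_FAMILIES: tuple[str, ...] = (
    "Halictidae",
    "Apidae",
    "Andrenidae",
    "Colletidae",
    "Megachilidae",
)
ORIGINS: tuple[str, ...] = ("native_prairie", "exotic_weedy", "not_applicable")

SURVEY_COLUMNS = ["site", "treatment", "year", "month", "taxon", "value"]
REGISTRY_COLUMNS = ["taxon", "role", "family", "origin", "pooled"]


class ValidationError(ValueError):
    """An input violated a data-model invariant; never silently repaired."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def ln_shift_transform(x):
    """Shifted natural log ``ln(x + 0.5)`` used to normalise count responses.

    Accepts scalars or arrays; strictly increasing on x >= 0.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("ln_shift_transform requires x >= 0")
    out = np.log(arr + 0.5)
    return out.item() if np.isscalar(x) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Taxon registry


@dataclass
class TaxonRegistry:
    """Per-taxon metadata: role (bee/plant), family, plant origin, pooled flag.

    ``pooled`` marks the single taxonomically pooled bee taxon (the
    *Lasioglossum* (Dialictus) aggregate); at most one per registry.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(REGISTRY_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"registry missing columns: {sorted(missing)}")
        df = df[REGISTRY_COLUMNS].copy()
        df["pooled"] = df["pooled"].astype(bool)
        if df["taxon"].duplicated().any():
            dups = df.loc[df["taxon"].duplicated(), "taxon"].tolist()
            raise ValidationError(f"duplicate taxa in registry: {dups}")
        bad_role = set(df["role"]) - {"bee", "plant"}
        if bad_role:
            raise ValidationError(f"unknown roles: {sorted(bad_role)}")
        bad_origin = set(df["origin"]) - set(ORIGINS)
        if bad_origin:
            raise ValidationError(f"unknown origins: {sorted(bad_origin)}")
        # origin is a plant concept: bees carry the explicit placeholder
        bees = df["role"] == "bee"
        if (df.loc[bees, "origin"] != "not_applicable").any():
            raise ValidationError("bee taxa must have origin=not_applicable")
        if (df.loc[~bees, "origin"] == "not_applicable").any():
            raise ValidationError("plant taxa must have a native/exotic origin")
        if int(df["pooled"].sum()) > 1:
            raise ValidationError("at most one pooled taxon allowed")
        if df.loc[df["pooled"], "role"].eq("plant").any():
            raise ValidationError("the pooled taxon must be a bee")
        self.data = df.reset_index(drop=True)

    # -- lookups ------------------------------------------------------------
    @property
    def bees(self) -> list[str]:
        return self.data.loc[self.data["role"] == "bee", "taxon"].tolist()

    @property
    def plants(self) -> list[str]:
        return self.data.loc[self.data["role"] == "plant", "taxon"].tolist()

    @property
    def pooled_taxon(self) -> str | None:
        pooled = self.data.loc[self.data["pooled"], "taxon"]
        return None if pooled.empty else pooled.iloc[0]

    def role_of(self, taxon: str) -> str:
        return self._lookup(taxon, "role")

    def family_of(self, taxon: str) -> str:
        return self._lookup(taxon, "family")

    def origin_of(self, taxon: str) -> str:
        return self._lookup(taxon, "origin")

    def _lookup(self, taxon: str, col: str) -> str:
        row = self.data.loc[self.data["taxon"] == taxon, col]
        if row.empty:
            raise KeyError(f"taxon {taxon!r} not in registry")
        return row.iloc[0]

    def family_map(self, role: str) -> dict[str, str]:
        sub = self.data[self.data["role"] == role]
        return dict(zip(sub["taxon"], sub["family"]))

    def origin_map(self) -> dict[str, str]:
        sub = self.data[self.data["role"] == "plant"]
        return dict(zip(sub["taxon"], sub["origin"]))

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "TaxonRegistry":
        df = pd.read_csv(path, dtype={"taxon": str})
        if "pooled" in df.columns:
            df["pooled"] = df["pooled"].map(_parse_bool)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["pooled"] = out["pooled"].astype(int)
        out.sort_values(["role", "taxon"]).to_csv(path, index=False)


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "yes", "x"}
    return bool(v)


# ---------------------------------------------------------------------------
# Survey tables


@dataclass
class SurveyTable:
    """Long-format survey records for one guild (bees or plants).

    Bee values are integer counts per 60-m transect sampling event; plant
    values are mean proportional cover over the ten 1-m2 quadrats of the
    event, already averaged to transect level.
    """

    data: pd.DataFrame
    role: str = "bee"

    def __post_init__(self) -> None:
        df = self.data
        missing = set(SURVEY_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"survey missing columns: {sorted(missing)}")
        df = df[SURVEY_COLUMNS].copy()
        df["site"] = df["site"].astype(str)
        df["year"] = df["year"].astype(int)
        df["value"] = df["value"].astype(float)
        bad_t = set(df["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValidationError(f"unknown treatments: {sorted(bad_t)}")
        bad_m = set(df["month"]) - set(MONTHS)
        if bad_m:
            raise ValidationError(f"unknown months: {sorted(bad_m)}")
        keys = ["site", "treatment", "year", "month", "taxon"]
        if df.duplicated(keys).any():
            first = df[df.duplicated(keys, keep=False)].iloc[0]
            raise ValidationError(
                "duplicate survey key: "
                + "/".join(str(first[k]) for k in keys)
            )
        if (df["value"] < 0).any():
            row = df[df["value"] < 0].iloc[0]
            raise ValidationError(
                f"negative value for taxon {row['taxon']!r}"
            )
        if self.role == "bee":
            frac = df["value"] % 1
            if (frac != 0).any():
                row = df[frac != 0].iloc[0]
                raise ValidationError(
                    f"non-integer bee count {row['value']} for {row['taxon']!r}"
                )
        elif self.role == "plant":
            if (df["value"] > 1).any():
                row = df[df["value"] > 1].iloc[0]
                raise ValidationError(
                    f"plant cover {row['value']} outside [0,1] for {row['taxon']!r}"
                )
        else:
            raise ValidationError(f"unknown survey role {self.role!r}")
        self.data = df.reset_index(drop=True)

    def validate_taxa(self, registry: TaxonRegistry) -> None:
        known = set(
            registry.data.loc[registry.data["role"] == self.role, "taxon"]
        )
        unknown = sorted(set(self.data["taxon"]) - known)
        if unknown:
            raise ValidationError(
                f"taxa not registered as {self.role}: {unknown}"
            )

    def canonical(self) -> pd.DataFrame:
        """Deterministically ordered copy (site, treatment, year, month, taxon)."""
        df = self.data.copy()
        df["_m"] = df["month"].map({m: i for i, m in enumerate(MONTHS)})
        df = df.sort_values(["site", "treatment", "year", "_m", "taxon"])
        return df.drop(columns="_m").reset_index(drop=True)

    def __eq__(self, other) -> bool:  # value semantics for round-trips
        if not isinstance(other, SurveyTable):
            return NotImplemented
        return self.role == other.role and self.canonical().equals(
            other.canonical()
        )

    def total(self) -> float:
        return float(self.data["value"].sum())


def read_survey(
    path: str | Path, registry: TaxonRegistry, role: str = "bee"
) -> SurveyTable:
    """Read and fully validate a long-format survey CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"site": str, "taxon": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    table = SurveyTable(df, role=role)
    table.validate_taxa(registry)
    return table


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write a survey table with deterministic column order and row sort."""
    out = table.canonical()
    out.to_csv(path, index=False)


def survey_matrix(
    table: SurveyTable,
    unit_keys: Sequence[str] = ("site", "treatment", "year", "month"),
    taxa: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Wide view: sampling units (rows) x taxa (columns), absences filled 0.

    Unit labels are "/"-joined key values in ``unit_keys`` order.
    """
    df = table.data
    wide = df.pivot_table(
        index=list(unit_keys),
        columns="taxon",
        values="value",
        aggfunc="sum",
        fill_value=0.0,
    )
    if taxa is not None:
        taxa = list(taxa)
        wide = wide.reindex(columns=taxa, fill_value=0.0)
    wide.index = [
        "/".join(str(v) for v in (ix if isinstance(ix, tuple) else (ix,)))
        for ix in wide.index
    ]
    return wide.sort_index()


# ---------------------------------------------------------------------------
# Visitation matrix


@dataclass
class VisitationMatrix:
    """Observed bee x plant flower-visit counts (rows = bees, cols = plants)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        if (df.values < 0).any():
            raise ValidationError("visitation counts must be >= 0")
        if np.any(df.values % 1 != 0):
            raise ValidationError("visitation counts must be integers")
        self.data = df.astype(int)

    def validate_taxa(self, registry: TaxonRegistry) -> None:
        bad_rows = sorted(set(self.data.index) - set(registry.bees))
        bad_cols = sorted(set(self.data.columns) - set(registry.plants))
        if bad_rows or bad_cols:
            raise ValidationError(
                f"visitation labels not in registry: bees={bad_rows} plants={bad_cols}"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "VisitationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.sort_index().sort_index(axis=1)
        out.to_csv(path, index_label="bee")


# ---------------------------------------------------------------------------
# Land cover


@dataclass
class LandCoverProfile:
    """Proportional land-cover composition within 3 km of one field.

    ``categories`` has columns category, proportion, noncrop; proportions
    sum to 1 (tolerance 1e-9).
    """

    field_id: str
    categories: pd.DataFrame
    _tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        df = self.categories
        need = {"category", "proportion", "noncrop"}
        if not need <= set(df.columns):
            raise ValidationError(
                f"land cover profile needs columns {sorted(need)}"
            )
        df = df[["category", "proportion", "noncrop"]].copy()
        df["proportion"] = df["proportion"].astype(float)
        df["noncrop"] = df["noncrop"].map(_parse_bool)
        if (df["proportion"] < 0).any() or (df["proportion"] > 1).any():
            raise ValidationError("proportions must lie in [0,1]")
        total = df["proportion"].sum()
        if abs(total - 1.0) > self._tol:
            raise ValidationError(
                f"proportions of field {self.field_id!r} sum to {total!r}, not 1"
            )
        self.categories = df.reset_index(drop=True)


def read_landcover(path: str | Path) -> list[LandCoverProfile]:
    df = pd.read_csv(path, dtype={"field": str})
    profiles = []
    for fid, sub in df.groupby("field", sort=True):
        profiles.append(LandCoverProfile(str(fid), sub.reset_index(drop=True)))
    return profiles


def write_landcover(profiles: Iterable[LandCoverProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        sub = prof.categories.copy()
        sub.insert(0, "field", prof.field_id)
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    out["noncrop"] = out["noncrop"].astype(int)
    out.sort_values(["field", "category"]).to_csv(path, index=False)
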