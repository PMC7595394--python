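"""Synthetic field-study generator with known ground truth.

Emulates the structure of a paired prairie-strip experiment: a small
number of sites, each with a strip and a control field, surveyed monthly
(May-Aug) over two seasons. Bee counts are Poisson on a log link with a
lognormal species-abundance distribution steep enough that realized
relative abundances straddle the ~1% common/uncommon boundary; a single
pooled taxon (an intractable subgenus aggregate) is generated by summing
several latent species and dominates the catch. Forb cover within strips
is a Dirichlet composition with heterogeneous concentrations, so a few
families dominate cover. Planted bee-on-plant couplings enter the bee
log-mean as beta * cover and also drive a consistent observed visitation
matrix, giving every downstream stage a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MONTHS,
    LandCoverProfile,
    SurveyTable,
    TaxonRegistry,
    ValidationError,
    VisitationMatrix,
)

# Default design scale: 4 sites x 2 treatments x 2 years x 4 months = 64
# sampling events; 89 bee taxa (88 species + 1 pooled aggregate), 55 forbs.
DEFAULT_N_SITES = 4
DEFAULT_N_YEARS = 2
FIRST_YEAR = 2016

# identified species per bee family (+1 pooled halictid aggregate)
BEE_FAMILY_SIZES = {
    "Halictidae": 32,
    "Apidae": 27,
    "Andrenidae": 17,
    "Colletidae": 5,
    "Megachilidae": 7,
}
POOLED_TAXON = "Lasioglossum_Dialictus"

# forb species per family as (native_prairie, exotic_weedy)
PLANT_FAMILY_SIZES = {
    "Asteraceae": (12, 9),
    "Fabaceae": (6, 4),
    "Amaranthaceae": (0, 3),
    "Polygonaceae": (0, 2),
    "Lamiaceae": (1, 0),
    "Apiaceae": (2, 2),
    "Plantaginaceae": (0, 1),
    "Onagraceae": (1, 0),
    "Brassicaceae": (0, 2),
    "Malvaceae": (0, 1),
    "Apocynaceae": (3, 0),
    "Rosaceae": (1, 0),
    "Oxalidaceae": (0, 1),
    "Urticaceae": (0, 1),
    "Scrophulariaceae": (0, 1),
    "Ranunculaceae": (1, 0),
    "Euphorbiaceae": (0, 1),
}


def default_registry() -> TaxonRegistry:
    """The default 89-bee / 55-forb taxon registry."""
    rows = []
    for fam, k in BEE_FAMILY_SIZES.items():
        for i in range(k):
            rows.append(
                {
                    "taxon": f"{fam}_sp{i + 1:02d}",
                    "role": "bee",
                    "family": fam,
                    "origin": "not_applicable",
                    "pooled": False,
                }
            )
    rows.append(
        {
            "taxon": POOLED_TAXON,
            "role": "bee",
            "family": "Halictidae",
            "origin": "not_applicable",
            "pooled": True,
        }
    )
    for fam, (n_native, n_exotic) in PLANT_FAMILY_SIZES.items():
        for i in range(n_native):
            rows.append(
                {
                    "taxon": f"{fam}_P{i + 1:02d}",
                    "role": "plant",
                    "family": fam,
                    "origin": "native_prairie",
                    "pooled": False,
                }
            )
        for i in range(n_exotic):
            rows.append(
                {
                    "taxon": f"{fam}_EW{i + 1:02d}",
                    "role": "plant",
                    "family": fam,
                    "origin": "exotic_weedy",
                    "pooled": False,
                }
            )
    return TaxonRegistry(pd.DataFrame(rows))


def small_registry(
    bees: dict[str, int] | int = 4,
    plants: int = 4,
    pooled: bool = False,
) -> TaxonRegistry:
    """Compact registry for desk-scale experiments and tests."""
    if isinstance(bees, int):
        fams = list(BEE_FAMILY_SIZES)
        counts: dict[str, int] = {}
        for i in range(bees):
            fam = fams[i % len(fams)]
            counts[fam] = counts.get(fam, 0) + 1
        bees = counts
    rows = []
    for fam, k in bees.items():
        for i in range(k):
            rows.append(
                {
                    "taxon": f"{fam}_sp{i + 1:02d}",
                    "role": "bee",
                    "family": fam,
                    "origin": "not_applicable",
                    "pooled": False,
                }
            )
    if pooled:
        rows.append(
            {
                "taxon": POOLED_TAXON,
                "role": "bee",
                "family": "Halictidae",
                "origin": "not_applicable",
                "pooled": True,
            }
        )
    fams = list(PLANT_FAMILY_SIZES)
    for i in range(plants):
        fam = fams[i % len(fams)]
        origin = "native_prairie" if i % 2 == 0 else "exotic_weedy"
        tag = "P" if origin == "native_prairie" else "EW"
        rows.append(
            {
                "taxon": f"{fam}_{tag}{i + 1:02d}",
                "role": "plant",
                "family": fam,
                "origin": origin,
                "pooled": False,
            }
        )
    return TaxonRegistry(pd.DataFrame(rows))


@dataclass
class SyntheticTruth:
    """Planted generating parameters: the ground truth for recovery tests.

    ``coupling[b, p]`` is the log-linear effect of plant p's cover on bee
    b's expected count within strips; ``coupling_by_month`` (optional,
    shape 4 x B x P) overrides it per survey month. ``bee_base`` holds
    per-bee log baseline counts per sampling event; the pooled taxon's
    baseline is split over ``n_latent_pooled`` latent species at
    generation time.
    """

    coupling: np.ndarray
    bee_base: np.ndarray
    plant_concentration: np.ndarray
    treatment_effect: float
    month_effects: np.ndarray
    n_sites: int
    n_years: int
    seed: int
    commonness_target: float = 0.10
    cover_scale: float = 0.6
    visit_scale: float = 120.0
    n_latent_pooled: int = 5
    coupling_by_month: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.bee_base = np.asarray(self.bee_base, dtype=float)
        self.plant_concentration = np.asarray(
            self.plant_concentration, dtype=float
        )
        self.month_effects = np.asarray(self.month_effects, dtype=float)
        B, P = self.coupling.shape
        if self.bee_base.shape != (B,):
            raise ValidationError("bee_base does not match coupling rows")
        if self.plant_concentration.shape != (P,):
            raise ValidationError(
                "plant_concentration does not match coupling columns"
            )
        if self.month_effects.shape != (len(MONTHS),):
            raise ValidationError(f"need {len(MONTHS)} month effects")
        if self.n_sites < 1 or self.n_years < 1:
            raise ValidationError("n_sites and n_years must be positive")
        if np.any(self.plant_concentration <= 0):
            raise ValidationError("plant concentrations must be positive")
        if self.coupling_by_month is not None:
            self.coupling_by_month = np.asarray(
                self.coupling_by_month, dtype=float
            )
            if self.coupling_by_month.shape != (len(MONTHS), B, P):
                raise ValidationError("coupling_by_month shape mismatch")

    def coupling_for_month(self, month_index: int) -> np.ndarray:
        if self.coupling_by_month is not None:
            return self.coupling_by_month[month_index]
        return self.coupling

    def mean_coupling(self) -> np.ndarray:
        if self.coupling_by_month is not None:
            return self.coupling_by_month.mean(axis=0)
        return self.coupling

    def with_seed(self, seed: int) -> "SyntheticTruth":
        return replace(self, seed=seed)


def default_truth(
    registry: TaxonRegistry,
    seed: int = 0,
    coupled_pairs: int = 25,
    coupling_scale: tuple[float, float] = (8.0, 15.0),
    null: bool = False,
    n_sites: int = DEFAULT_N_SITES,
    n_years: int = DEFAULT_N_YEARS,
) -> SyntheticTruth:
    """Study-scale default scenario; ``null=True`` zeroes every coupling.

    Couplings are planted between high-baseline bees and high-cover
    plants, where beta * sd(cover) is large enough for the pairwise
    Pearson test to have high power at the default 32 paired events.
    """
    rng = np.random.default_rng(seed)
    bees = registry.bees
    plants = registry.plants
    if len(bees) < 2 or len(plants) < 2:
        raise ValidationError("registry must contain >= 2 bees and >= 2 plants")
    B, P = len(bees), len(plants)
    pooled = registry.pooled_taxon
    pooled_ix = bees.index(pooled) if pooled is not None else None

    # steep lognormal abundance: median 0.034 counts/event, sigma 2.2
    log_base = rng.normal(np.log(0.034), 2.2, B)
    if pooled_ix is not None:
        others = np.exp(np.delete(log_base, pooled_ix))
        log_base[pooled_ix] = np.log(0.72 * others.sum())

    conc = rng.lognormal(-1.1, 1.0, P)

    coupling = np.zeros((B, P))
    if not null and coupled_pairs > 0:
        candidates_b = np.argsort(log_base)[::-1]
        if pooled_ix is not None:
            candidates_b = candidates_b[candidates_b != pooled_ix]
        candidates_b = candidates_b[: max(coupled_pairs, 10)]
        candidates_p = np.argsort(conc)[::-1][: max(P // 4, 2)]
        grid = [(b, p) for b in candidates_b for p in candidates_p]
        pick = rng.choice(len(grid), size=min(coupled_pairs, len(grid)), replace=False)
        for k in pick:
            b, p = grid[k]
            coupling[b, p] = rng.uniform(*coupling_scale)

    return SyntheticTruth(
        coupling=coupling,
        bee_base=log_base,
        plant_concentration=conc,
        treatment_effect=0.45,
        month_effects=np.array([-0.3, 0.1, 0.5, 0.2]),
        n_sites=n_sites,
        n_years=n_years,
        seed=seed,
    )


def generate_dataset(
    truth: SyntheticTruth, registry: TaxonRegistry
) -> tuple[SurveyTable, SurveyTable, VisitationMatrix, SyntheticTruth]:
    """Draw one realization: bee counts, strip forb cover, visitation matrix.

    Deterministic for a fixed truth (including its seed): running twice
    yields identical tables.
    """
    bees = registry.bees
    plants = registry.plants
    B, P = truth.coupling.shape
    if (B, P) != (len(bees), len(plants)):
        raise ValidationError("truth dimensions do not match registry")
    if B < 2 or P < 2:
        raise ValidationError("need >= 2 bee and >= 2 plant taxa")
    rng = np.random.default_rng(truth.seed)
    pooled = registry.pooled_taxon
    pooled_ix = bees.index(pooled) if pooled is not None else None
    latent_shares = (
        rng.dirichlet(np.ones(truth.n_latent_pooled))
        if pooled_ix is not None
        else None
    )

    sites = [f"S{i + 1}" for i in range(truth.n_sites)]
    years = [FIRST_YEAR + i for i in range(truth.n_years)]

    bee_rows = []
    plant_rows = []
    cover_sum = np.zeros(P)
    n_strip_events = 0
    log_mu_cap = 9.0  # keeps Poisson means < ~8000 under extreme draws

    for site in sites:
        for year in years:
            for m_ix, month in enumerate(MONTHS):
                # forb cover inside the strip for this sampling event
                cover = rng.dirichlet(truth.plant_concentration) * truth.cover_scale
                cover_sum += cover
                n_strip_events += 1
                beta = truth.coupling_for_month(m_ix)
                for treatment in ("strip", "control"):
                    is_strip = treatment == "strip"
                    log_mu = (
                        truth.bee_base
                        + truth.month_effects[m_ix]
                        + (truth.treatment_effect if is_strip else 0.0)
                        + (beta @ cover if is_strip else 0.0)
                    )
                    mu = np.exp(np.minimum(log_mu, log_mu_cap))
                    counts = rng.poisson(mu)
                    if pooled_ix is not None:
                        # the pooled taxon is the summed catch of latent species
                        latent_mu = latent_shares * mu[pooled_ix]
                        counts[pooled_ix] = rng.poisson(latent_mu).sum()
                    nz = np.flatnonzero(counts)
                    for j in nz:
                        bee_rows.append(
                            (site, treatment, year, month, bees[j], int(counts[j]))
                        )
                    if is_strip:
                        pz = np.flatnonzero(cover > 0)
                        for j in pz:
                            plant_rows.append(
                                (
                                    site,
                                    "strip",
                                    year,
                                    month,
                                    plants[j],
                                    float(cover[j]),
                                )
                            )

    bee_table = SurveyTable(
        pd.DataFrame(
            bee_rows,
            columns=["site", "treatment", "year", "month", "taxon", "value"],
        ),
        role="bee",
    )
    plant_table = SurveyTable(
        pd.DataFrame(
            plant_rows,
            columns=["site", "treatment", "year", "month", "taxon", "value"],
        ),
        role="plant",
    )

    mean_cover = cover_sum / n_strip_events
    lam = truth.visit_scale * np.maximum(truth.mean_coupling(), 0.0) * mean_cover
    visits = VisitationMatrix(
        pd.DataFrame(rng.poisson(lam), index=bees, columns=plants)
    )
    return bee_table, plant_table, visits, truth


def write_truth(truth: SyntheticTruth, registry: TaxonRegistry, path: str | Path) -> None:
    """Serialize the planted coupling matrix (bees x plants) to CSV."""
    df = pd.DataFrame(
        truth.coupling, index=registry.bees, columns=registry.plants
    )
    df.to_csv(path, index_label="bee")


# ---------------------------------------------------------------------------
# Land cover

CROP_CATEGORIES = ["corn", "soybean"]
NONCROP_CATEGORIES = ["grassland", "forest", "wetland", "developed", "water"]


def generate_landcover(
    n_fields: int,
    noncrop_range: tuple[float, float] = (0.08, 0.69),
    n_categories: int = 6,
    seed: int = 0,
) -> list[LandCoverProfile]:
    """Land-cover profiles with total non-crop proportion uniform in a range."""
    low, high = noncrop_range
    if not 0 <= low <= high <= 1:
        raise ValidationError("noncrop_range must satisfy 0 <= low <= high <= 1")
    if n_categories < 2:
        raise ValidationError("need >= 2 land-cover categories")
    if n_fields < 1:
        raise ValidationError("need >= 1 field")
    n_crop = max(1, min(len(CROP_CATEGORIES), n_categories // 3 + 1))
    n_noncrop = n_categories - n_crop
    if n_noncrop < 1:
        n_noncrop, n_crop = 1, n_categories - 1
    crop_names = [CROP_CATEGORIES[i % len(CROP_CATEGORIES)] + ("" if i < len(CROP_CATEGORIES) else f"_{i}") for i in range(n_crop)]
    noncrop_names = [NONCROP_CATEGORIES[i % len(NONCROP_CATEGORIES)] + ("" if i < len(NONCROP_CATEGORIES) else f"_{i}") for i in range(n_noncrop)]

    rng = np.random.default_rng(seed)
    profiles = []
    for f in range(n_fields):
        u = rng.uniform(low, high) if high > low else low
        w_non = rng.dirichlet(np.ones(n_noncrop)) * u
        w_crop = rng.dirichlet(np.ones(n_crop)) * (1.0 - u)
        props = np.concatenate([w_crop, w_non])
        props = props / props.sum()  # exact unit total
        df = pd.DataFrame(
            {
                "category": crop_names + noncrop_names,
                "proportion": props,
                "noncrop": [False] * n_crop + [True] * n_noncrop,
            }
        )
        profiles.append(LandCoverProfile(f"F{f + 1}", df))
    return profiles
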