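"""One-command orchestration: simulate -> diversity -> compare -> network.

A single master seed determines every stochastic stage; per-stage seeds
are derived by hashing the stage name with the master seed, so each
stage is individually reproducible when run standalone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, diversity, network, synth
from .io import (
    ParseError,
    SurveyTable,
    TaxonRegistry,
    ValidationError,
    VisitationMatrix,
    read_landcover,
    read_survey,
    write_landcover,
    write_survey,
)

logger = logging.getLogger("prairienet")

PARTITIONS = ("all", "common8", "common9", "uncommon")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a full run needs; serialized verbatim into the output dir."""

    out_dir: str = "prairienet_run"
    seed: int = 0
    alpha: float = 0.05
    commonness_threshold: float = 0.01
    n_perm: int = 9999
    n_boot: int = 200
    use_fdr: bool = False
    simulate: bool = True
    n_fields: int = 8
    noncrop_low: float = 0.08
    noncrop_high: float = 0.69
    bees_path: str | None = None
    plants_path: str | None = None
    registry_path: str | None = None
    visits_path: str | None = None
    landcover_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _load_inputs(config: RunConfig):
    if config.simulate:
        registry = synth.default_registry()
        truth = synth.default_truth(
            registry, seed=derive_seed(config.seed, "simulate")
        )
        bees, plants, visits, truth = synth.generate_dataset(truth, registry)
        profiles = synth.generate_landcover(
            config.n_fields,
            (config.noncrop_low, config.noncrop_high),
            seed=derive_seed(config.seed, "landcover"),
        )
        return registry, bees, plants, visits, profiles, truth
    registry = TaxonRegistry.from_csv(config.registry_path)
    bees = read_survey(config.bees_path, registry, role="bee")
    plants = read_survey(config.plants_path, registry, role="plant")
    visits = None
    if config.visits_path:
        visits = VisitationMatrix.from_csv(config.visits_path)
        visits.validate_taxa(registry)
    profiles = (
        read_landcover(config.landcover_path) if config.landcover_path else []
    )
    return registry, bees, plants, visits, profiles, None


def validate_inputs(config: RunConfig) -> list[str]:
    """Run every data-model check; returns the list of violations found."""
    violations: list[str] = []
    if config.simulate:
        return violations
    for name, path in [
        ("registry", config.registry_path),
        ("bees", config.bees_path),
        ("plants", config.plants_path),
    ]:
        if not path:
            violations.append(f"{name}: no path configured")
        elif not Path(path).exists():
            violations.append(f"{name}: file not found: {path}")
    if violations:
        return violations
    try:
        _load_inputs(config)
    except (ValidationError, ParseError, FileNotFoundError, KeyError) as exc:
        violations.append(str(exc))
    return violations


def _partition_taxa(
    partition: str,
    bees: SurveyTable,
    registry: TaxonRegistry,
    threshold: float,
):
    if partition == "all":
        return sorted(set(bees.data["taxon"]))
    if partition == "common8":
        part = community.classify_commonness(
            bees, registry, threshold, mode="exclude_pooled"
        )
        return list(part.common)
    part = community.classify_commonness(
        bees, registry, threshold, mode="include_pooled"
    )
    if partition == "common9":
        return list(part.common)
    if partition == "uncommon":
        return list(part.uncommon)
    raise ValidationError(f"unknown partition {partition!r}")


def compare_partition(
    bees: SurveyTable,
    registry: TaxonRegistry,
    partition: str,
    threshold: float = 0.01,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """MRPP + multivariate dispersion between treatments for one bee group."""
    taxa = _partition_taxa(partition, bees, registry, threshold)
    if len(taxa) < 1:
        raise ValidationError(f"partition {partition!r} selects no taxa")
    from .io import survey_matrix

    wide = survey_matrix(bees, taxa=taxa)
    nonzero = wide.sum(axis=1) > 0
    dropped = list(wide.index[~nonzero])
    wide = wide.loc[nonzero]
    D = community.bray_curtis_from_wide(wide)
    groups = [label.split("/")[1] for label in D.labels]  # treatment key
    mr = community.mrpp(D, groups, n_perm=n_perm, seed=seed)
    disp = community.multivariate_dispersion(D, groups)
    return {
        "partition": partition,
        "n_taxa": len(taxa),
        "n_units": D.n,
        "dropped_units": dropped,
        "mrpp": {"T": mr.T, "A": mr.A, "p": mr.p, "delta": mr.delta},
        "dispersion": {
            "F": disp.F,
            "p": disp.p_parametric,
            "group_mean_distance": disp.group_means,
        },
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage, write all artifacts, return the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"seed": config.seed, "alpha": config.alpha}

    stage = "inputs"
    try:
        problems = validate_inputs(config)
        if problems:
            raise ValidationError("; ".join(problems))
        registry, bees, plants, visits, profiles, truth = _load_inputs(config)
        logger.info(
            "inputs: %d bee records, %d plant records, %d taxa",
            len(bees.data),
            len(plants.data),
            len(registry.data),
        )
        if config.simulate:
            registry.to_csv(out / "registry.csv")
            write_survey(bees, out / "bees.csv")
            write_survey(plants, out / "plants.csv")
            visits.to_csv(out / "visits.csv")
            synth.write_truth(truth, registry, out / "truth.csv")
            if profiles:
                write_landcover(profiles, out / "landcover.csv")

        stage = "diversity"
        curves = []
        for treatment, sub in bees.data.groupby("treatment"):
            counts = diversity.abundance_vector(
                SurveyTable(sub, role="bee")
            )
            for q in (0, 1, 2):
                curve = diversity.rarefaction_curve(
                    counts,
                    q,
                    n_boot=config.n_boot,
                    seed=derive_seed(config.seed, f"diversity:{treatment}:{q}"),
                )
                tab = curve.table.copy()
                tab.insert(0, "q", q)
                tab.insert(0, "group", treatment)
                curves.append(tab)
                report.setdefault("diversity", {}).setdefault(treatment, {})[
                    f"q{q}"
                ] = {"n": curve.n_obs, "qD_obs": curve.qd_obs}
        pd.concat(curves, ignore_index=True).to_csv(
            out / "curves.csv", index=False
        )
        logger.info("diversity: wrote curves.csv")

        stage = "compare"
        report["composition"] = {}
        for partition in PARTITIONS:
            res = compare_partition(
                bees,
                registry,
                partition,
                threshold=config.commonness_threshold,
                n_perm=config.n_perm,
                seed=derive_seed(config.seed, f"compare:{partition}"),
            )
            report["composition"][partition] = res
        logger.info("compare: MRPP + dispersion on %s", ", ".join(PARTITIONS))

        stage = "network"
        net = network.build_cooccurrence(bees, plants)
        net.p_adj = network.bh_adjust(net.p, net.defined)
        network.select_links(net, alpha=config.alpha, use_adjusted=config.use_fdr)
        net.to_long().to_csv(out / "cooccurrence.csv", index=False)
        fam = network.family_proportions(net, registry)
        fam.to_csv(out / "family_proportions.csv")
        part9 = community.classify_commonness(
            bees, registry, config.commonness_threshold, mode="include_pooled"
        )
        ratios = network.origin_ratio_table(net, registry, part9)
        ratios.to_csv(out / "origin_ratios.csv", index=False)
        edges = network.monthly_networks(
            bees, plants, registry, alpha=config.alpha
        )
        edges.to_csv(out / "monthly_edges.csv", index=False)
        report["network"] = {
            "n_defined": int(net.defined.values.sum()),
            "n_selected": net.n_selected(),
            "n_selected_fdr": int(
                ((net.r > 0) & (net.p_adj < config.alpha)).fillna(False).values.sum()
            ),
            "monthly_edge_weight": int(edges["weight"].sum())
            if len(edges)
            else 0,
            "origin_ratios": {
                row.bee_group: None if np.isnan(row.ratio) else row.ratio
                for row in ratios.itertuples()
                if not np.isinf(row.ratio)
            },
        }
        if visits is not None:
            val = network.validate_vs_visitation(net, visits, use="r")
            report["network"]["visitation_validation"] = {
                "r": val.r,
                "p": val.p,
                "n_cells": int(net.defined.values.sum()),
            }
            with open(out / "validation.json", "w") as fh:
                json.dump(report["network"]["visitation_validation"], fh, indent=2)
        logger.info("network: %d selected links", net.n_selected())

        stage = "landscape"
        if profiles:
            rows = []
            for prof in profiles:
                rows.append(
                    {
                        "field": prof.field_id,
                        "shannon_H": diversity.shannon_landscape_diversity(prof),
                        "noncrop": diversity.noncrop_proportion(prof),
                    }
                )
            land = pd.DataFrame(rows)
            land.to_csv(out / "landscape.csv", index=False)
            report["landscape"] = {
                "n_fields": len(land),
                "shannon_H_mean": float(land["shannon_H"].mean()),
                "noncrop_min": float(land["noncrop"].min()),
                "noncrop_max": float(land["noncrop"].max()),
            }
    except StageError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("report written to %s", out / "report.json")
    return report
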