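"""Synthetic multi-study screen worlds with planted ground truth.

The generator emulates the statistical structure the discovery/validation
analysis assumes: several studies screening partially overlapping cell-line
panels; per-line tissue and MSI labels that shift sensitivity scores in a
gene-specific way (creating the tissue-confounding hazard the covariate model
exists to absorb); binary driver alterations at a configurable frequency;
planted driver->target sensitivity interactions and self "addiction" effects;
Gaussian measurement noise independent per study; and a background PPI
network in which planted pairs are included as edges at a configurable
enrichment over the background rate.  Everything flows from one seed through
named substreams, so identical configs yield byte-identical worlds.

It does not attempt to emulate CERES/DEMETER2 score distributions,
guide-level structure, or the copy-number artefacts of CRISPR screens.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alterations import (
    AlterationMatrix,
    DriverGeneRule,
    LOF_MUTATION,
    RECURRENT_MUTATION,
    read_alteration_matrix,
    write_alteration_matrix,
    write_driver_rules,
    read_driver_rules,
)
from .core_data import (
    CellLineAnnotation,
    DataError,
    ScreenDataset,
    read_annotations,
    read_sensitivity_matrix,
    write_annotations,
    write_sensitivity_matrix,
)
from .ppi_enrichment import PPINetwork, build_network, read_ppi_edges, write_ppi_edges


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic world.

    Defaults describe a four-study design of 120-line panels drawing half of
    each panel from a shared pool, with 10 drivers altered in 20% of lines,
    200 candidate target genes, 20 planted sensitivity interactions of one
    score unit against measurement noise of SD 0.5, and a PPI network where
    planted pairs are five times more likely than background pairs to be
    edges.
    """

    seed: int = 0
    n_studies: int = 4
    lines_per_study: int = 120
    overlap_fraction: float = 0.5
    n_tissues: int = 4
    msi_fraction: float = 0.15
    n_target_genes: int = 200
    n_driver_genes: int = 10
    driver_alteration_freq: float = 0.2
    n_planted_interactions: int = 20
    planted_effect_size: float = -1.0
    n_self_addictions: int = 0
    addiction_effect_size: float = -1.5
    noise_sd: float = 0.5
    tissue_effect_sd: float = 0.3
    msi_effect_sd: float = 0.2
    baseline_sd: float = 0.25
    ppi_n_background_edges: int = 1750
    ppi_planting_enrichment: float = 5.0

    def validate(self) -> None:
        for name in ("overlap_fraction", "msi_fraction", "driver_alteration_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.n_studies < 1 or self.lines_per_study < 2:
            raise DataError("need >=1 study of >=2 lines")
        if self.n_tissues < 1:
            raise DataError("n_tissues must be >= 1")
        if self.n_planted_interactions > self.n_driver_genes * self.n_target_genes:
            raise DataError("more planted interactions than driver x target pairs")
        if self.n_self_addictions > self.n_driver_genes:
            raise DataError("more self addictions than drivers")
        for name in ("noise_sd", "tissue_effect_sd", "msi_effect_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")
        if self.ppi_planting_enrichment < 1.0:
            raise DataError("ppi_planting_enrichment must be >= 1")
        n_genes = self.n_target_genes + self.n_driver_genes
        if self.ppi_n_background_edges > n_genes * (n_genes - 1) // 2:
            raise DataError("ppi_n_background_edges exceeds the number of gene pairs")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class PlantedInteraction:
    driver: str
    target: str
    effect_size: float
    on_ppi: bool = False

    @property
    def direction(self) -> str:
        return "sensitivity" if self.effect_size < 0 else "resistance"


@dataclass
class GroundTruth:
    planted_interactions: list[PlantedInteraction]
    planted_addictions: list[PlantedInteraction]  # driver == target

    @property
    def interaction_pairs(self) -> set[tuple[str, str]]:
        return {(p.driver, p.target) for p in self.planted_interactions}


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    datasets: list[ScreenDataset]
    alterations: AlterationMatrix  # world-level, all lines x all drivers
    network: PPINetwork
    truth: GroundTruth
    driver_rules: list[DriverGeneRule]

    @property
    def driver_genes(self) -> list[str]:
        return list(self.alterations.genes)

    @property
    def target_genes(self) -> list[str]:
        drivers = set(self.alterations.genes)
        return [g for g in self.datasets[0].genes if g not in drivers]


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate a full synthetic world (screens, alterations, PPI, truth)."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_panel = np.random.default_rng(streams[0])
    rng_alt = np.random.default_rng(streams[1])
    rng_eff = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])
    rng_net = np.random.default_rng(streams[4])

    drivers = [f"DRV{i + 1:02d}" for i in range(config.n_driver_genes)]
    targets = [f"TGT{i + 1:03d}" for i in range(config.n_target_genes)]
    genes = targets + drivers
    gene_idx = {g: i for i, g in enumerate(genes)}

    # --- panels: one shared pool plus per-study exclusive lines -------------
    n_pool = int(round(config.overlap_fraction * config.lines_per_study))
    n_excl = config.lines_per_study - n_pool
    n_lines_total = n_pool + config.n_studies * n_excl
    all_lines = [f"CL{i + 1:04d}" for i in range(n_lines_total)]
    pool = all_lines[:n_pool]
    panels = []
    for s in range(config.n_studies):
        start = n_pool + s * n_excl
        panels.append(pool + all_lines[start:start + n_excl])

    tissues = rng_panel.integers(0, config.n_tissues, size=n_lines_total)
    msi = rng_panel.random(n_lines_total) < config.msi_fraction
    annotations = {
        line: CellLineAnnotation(
            cell_line_id=line,
            tissue=f"TISSUE_{tissues[i] + 1}",
            msi=bool(msi[i]),
        )
        for i, line in enumerate(all_lines)
    }

    # --- driver alterations --------------------------------------------------
    alt_mat = rng_alt.random((n_lines_total, config.n_driver_genes)) < config.driver_alteration_freq
    # oncogene status for addiction drivers, tumour suppressor otherwise
    addiction_drivers = drivers[: config.n_self_addictions]
    rules = [
        DriverGeneRule(
            d,
            "oncogene" if d in addiction_drivers else "tumour_suppressor",
            frozenset({600}) if d in addiction_drivers else frozenset(),
        )
        for d in drivers
    ]
    reason_of = {
        d: RECURRENT_MUTATION if d in addiction_drivers else LOF_MUTATION
        for d in drivers
    }
    calls = pd.DataFrame(alt_mat, index=all_lines, columns=drivers)
    reasons = pd.DataFrame(
        np.where(alt_mat, [reason_of[d] for d in drivers], ""),
        index=all_lines, columns=drivers,
    )
    alterations = AlterationMatrix("driver", calls, reasons)

    # --- gene-level effects --------------------------------------------------
    baseline = rng_eff.normal(0.0, config.baseline_sd, size=len(genes))
    tissue_eff = rng_eff.normal(0.0, config.tissue_effect_sd,
                                size=(config.n_tissues, len(genes)))
    msi_eff = rng_eff.normal(0.0, config.msi_effect_sd, size=len(genes))

    # planted driver -> target interactions (distinct pairs)
    n_pairs_possible = config.n_driver_genes * config.n_target_genes
    pair_idx = rng_eff.choice(n_pairs_possible, size=config.n_planted_interactions,
                              replace=False)
    planted = [
        PlantedInteraction(
            driver=drivers[int(k) // config.n_target_genes],
            target=targets[int(k) % config.n_target_genes],
            effect_size=config.planted_effect_size,
        )
        for k in sorted(pair_idx)
    ]
    addictions = [
        PlantedInteraction(driver=d, target=d, effect_size=config.addiction_effect_size)
        for d in addiction_drivers
    ]

    # --- per-study score matrices -------------------------------------------
    # biology (baseline, tissue, MSI, planted effects) is shared across
    # studies; measurement noise is independent per study
    signal = np.empty((len(genes), n_lines_total))
    for i, line in enumerate(all_lines):
        signal[:, i] = baseline + tissue_eff[tissues[i]] + msi_eff * msi[i]
    alt_by_driver = {d: alt_mat[:, j].astype(float) for j, d in enumerate(drivers)}
    for p in planted + addictions:
        signal[gene_idx[p.target]] += p.effect_size * alt_by_driver[p.driver]

    datasets = []
    line_pos = {line: i for i, line in enumerate(all_lines)}
    for s, panel in enumerate(panels):
        cols = [line_pos[l] for l in panel]
        noise = rng_noise.normal(0.0, config.noise_sd, size=(len(genes), len(panel))) \
            if config.noise_sd > 0 else np.zeros((len(genes), len(panel)))
        scores = pd.DataFrame(signal[:, cols] + noise, index=genes, columns=panel)
        datasets.append(
            ScreenDataset(
                dataset_id=f"STUDY_{chr(ord('A') + s)}",
                scores=scores,
                annotations={l: annotations[l] for l in panel},
            )
        )

    # --- PPI network ---------------------------------------------------------
    network, planted = _build_ppi(config, genes, planted, rng_net)
    truth = GroundTruth(planted_interactions=planted, planted_addictions=addictions)
    return SyntheticWorld(
        config=config, datasets=datasets, alterations=alterations,
        network=network, truth=truth, driver_rules=rules,
    )


def _build_ppi(
    config: SyntheticConfig,
    genes: Sequence[str],
    planted: list[PlantedInteraction],
    rng: np.random.Generator,
) -> tuple[PPINetwork, list[PlantedInteraction]]:
    """Background edges at rate p plus planted pairs at rate min(1, enrichment*p)."""
    n = len(genes)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    planted_keys = {
        tuple(sorted((genes.index(p.driver), genes.index(p.target)))) for p in planted
    }
    background_universe = [p for p in all_pairs if p not in planted_keys]
    p_bg = config.ppi_n_background_edges / len(all_pairs)
    n_bg = min(config.ppi_n_background_edges, len(background_universe))
    chosen = rng.choice(len(background_universe), size=n_bg, replace=False)
    edges = [
        (genes[background_universe[k][0]], genes[background_universe[k][1]], 0.9)
        for k in sorted(int(c) for c in chosen)
    ]
    p_planted = min(1.0, config.ppi_planting_enrichment * p_bg)
    on_ppi_draws = rng.random(len(planted)) < p_planted
    updated = []
    for p, on in zip(planted, on_ppi_draws):
        if on:
            edges.append((p.driver, p.target, 0.9))
        updated.append(
            PlantedInteraction(p.driver, p.target, p.effect_size, on_ppi=bool(on))
        )
    network = build_network(edges)
    network.graph.add_nodes_from(genes)  # isolated genes stay in the node set
    return network, updated


def generate_tissue_confounded(
    seed: int,
    n_lines: int = 100,
    n_tissues: int = 4,
    enriched_tissue_freq: float = 0.8,
    base_freq: float = 0.05,
    tissue_effect: float = -1.0,
    noise_sd: float = 0.25,
) -> tuple[ScreenDataset, AlterationMatrix]:
    """A deliberately confounded single-gene world.

    The driver is strongly enriched in one tissue while the target's
    sensitivity is driven by that tissue alone — the driver has no effect
    given tissue.  A naive two-group comparison is fooled; the
    covariate-adjusted model should not be.  Returns a one-gene dataset
    ("TGT001") and a one-driver alteration matrix ("DRV01").
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F0]))
    lines = [f"CL{i + 1:04d}" for i in range(n_lines)]
    tissues = rng.integers(0, n_tissues, size=n_lines)
    freq = np.where(tissues == 0, enriched_tissue_freq, base_freq)
    altered = rng.random(n_lines) < freq
    scores = tissue_effect * (tissues == 0) + rng.normal(0.0, noise_sd, n_lines)
    annotations = {
        l: CellLineAnnotation(l, f"TISSUE_{tissues[i] + 1}", msi=False)
        for i, l in enumerate(lines)
    }
    ds = ScreenDataset(
        "CONFOUNDED",
        pd.DataFrame([scores], index=["TGT001"], columns=lines),
        annotations,
    )
    calls = pd.DataFrame({"DRV01": altered}, index=lines)
    reasons = pd.DataFrame({"DRV01": np.where(altered, LOF_MUTATION, "")}, index=lines)
    return ds, AlterationMatrix("driver", calls, reasons)


# ---------------------------------------------------------------------------
# On-disk round trip
# ---------------------------------------------------------------------------

def world_to_files(world: SyntheticWorld, directory: str | Path) -> None:
    """Write the world in the exact file formats the other modules consume."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    world.config.to_json(d / "config.json")
    write_annotations(
        {l: a for ds in world.datasets for l, a in ds.annotations.items()},
        d / "annotations.tsv",
    )
    for ds in world.datasets:
        write_sensitivity_matrix(ds, d / f"{ds.dataset_id}.tsv")
    write_alteration_matrix(
        world.alterations, d / "driver_alterations.tsv", d / "driver_alteration_reasons.tsv"
    )
    write_driver_rules(world.driver_rules, d / "driver_rules.tsv")
    write_ppi_edges(world.network, d / "ppi_edges.tsv")
    rows = [
        {
            "driver": p.driver, "target": p.target,
            "effect_size": repr(p.effect_size),
            "direction": p.direction, "on_ppi": str(p.on_ppi).lower(),
            "kind": kind,
        }
        for kind, plist in (
            ("interaction", world.truth.planted_interactions),
            ("addiction", world.truth.planted_addictions),
        )
        for p in plist
    ]
    pd.DataFrame(
        rows, columns=["driver", "target", "effect_size", "direction", "on_ppi", "kind"]
    ).to_csv(d / "ground_truth.tsv", sep="\t", index=False)


def world_from_files(directory: str | Path) -> SyntheticWorld:
    """Re-read a written world; reproduces the in-memory world exactly."""
    d = Path(directory)
    config = SyntheticConfig.from_json(d / "config.json")
    annotations = read_annotations(d / "annotations.tsv")
    datasets = []
    for s in range(config.n_studies):
        sid = f"STUDY_{chr(ord('A') + s)}"
        datasets.append(
            read_sensitivity_matrix(d / f"{sid}.tsv", annotations, dataset_id=sid)
        )
    alterations = read_alteration_matrix(
        d / "driver_alterations.tsv", "driver", d / "driver_alteration_reasons.tsv"
    )
    rules = read_driver_rules(d / "driver_rules.tsv")
    network = read_ppi_edges(d / "ppi_edges.tsv", format="string_scored", min_score=0.4)
    network.graph.add_nodes_from(datasets[0].genes)
    gt = pd.read_csv(d / "ground_truth.tsv", sep="\t", dtype=str).fillna("")
    planted, addictions = [], []
    for r in gt.itertuples(index=False):
        p = PlantedInteraction(
            r.driver, r.target, float(r.effect_size), on_ppi=r.on_ppi == "true"
        )
        (planted if r.kind == "interaction" else addictions).append(p)
    return SyntheticWorld(
        config=config, datasets=datasets, alterations=alterations,
        network=network,
        truth=GroundTruth(planted_interactions=planted, planted_addictions=addictions),
        driver_rules=rules,
    )
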