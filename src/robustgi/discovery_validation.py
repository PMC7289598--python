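"""Discovery/validation engine for robust genetic interactions.

Each ordered pair of screen datasets is analysed in turn: the validation
panel is purged of every cell line present in the discovery panel, the
analysis is limited to the (driver, target) pairs testable in both resulting
panels, associations discovered in the discovery dataset (BH FDR below
threshold) are re-tested in the validation dataset, and an association is
reproduced when (1) its validation FDR is below the threshold, (2) its
uncorrected validation p-value is below 0.05 and (3) the direction
(sensitivity/resistance) agrees.  An interaction validated in at least one
dataset pair is called robust.  Self (driver = target) associations are
classified separately: an oncogene whose alteration sensitizes to its own
inhibition is an oncogene-addiction effect, not a genetic interaction, and is
excluded from the genetic-interaction view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alterations import (
    AlterationMatrix,
    DriverGeneRule,
    recurrently_altered_drivers,
    DEFAULT_MIN_ALTERED,
)
from .association import (
    AssociationResult,
    run_screen_associations,
    with_fdr,
    SENSITIVITY,
)
from .core_data import DataError, GeneSet, ScreenDataset

logger = logging.getLogger("robustgi")

DEFAULT_FDR_THRESHOLD = 0.2
VALIDATION_P_THRESHOLD = 0.05

ONCOGENE_ADDICTION = "oncogene_addiction"
SELF_TUMOUR_SUPPRESSOR = "self_tumour_suppressor"
SYNTHETIC_LETHALITY = "synthetic_lethality"
RESISTANCE_CLASS = "resistance"


@dataclass
class DatasetPair:
    """A discovery dataset and an overlap-purged validation dataset.

    ``mode`` is ``independent`` (panels disjoint — the standard robustness
    setting) or ``common_lines`` (identical panels screened on different
    platforms — the technical-reproducibility setting).
    """

    discovery: ScreenDataset
    validation: ScreenDataset
    testable_targets: GeneSet
    testable_drivers: GeneSet | None = None
    mode: str = "independent"

    def __post_init__(self) -> None:
        if self.mode == "independent":
            shared = set(self.discovery.cell_line_ids) & set(self.validation.cell_line_ids)
            if shared:
                raise DataError(
                    f"discovery and validation panels share lines: {sorted(shared)[:5]}"
                )

    @property
    def pair_id(self) -> tuple[str, str]:
        return (self.discovery.dataset_id, self.validation.dataset_id)


@dataclass(frozen=True)
class ValidationRecord:
    """One association reproduced in one discovery/validation dataset pair."""

    driver: str
    target: str
    direction: str
    discovery_id: str
    validation_id: str
    discovery_fdr: float
    validation_fdr: float
    validation_p: float


@dataclass
class RobustInteraction:
    """A (driver, target, direction) association validated in >=1 dataset pair."""

    driver: str
    target: str
    direction: str
    validated_pairs: list[ValidationRecord]
    interaction_class: str

    @property
    def is_self(self) -> bool:
        return self.driver == self.target

    @property
    def n_pairs(self) -> int:
        return len(self.validated_pairs)

    @property
    def best_validation_p(self) -> float:
        return min(r.validation_p for r in self.validated_pairs)

    @property
    def best_discovery_fdr(self) -> float:
        return min(r.discovery_fdr for r in self.validated_pairs)


# ---------------------------------------------------------------------------
# Pair construction
# ---------------------------------------------------------------------------

def make_pair(
    discovery: ScreenDataset,
    validation_src: ScreenDataset,
    alt_discovery: AlterationMatrix,
    alt_validation: AlterationMatrix,
    min_altered: int = DEFAULT_MIN_ALTERED,
) -> DatasetPair:
    """Build the standard pair: purge overlap, intersect testable universes."""
    disc_lines = set(discovery.cell_line_ids)
    exclusive = [l for l in validation_src.cell_line_ids if l not in disc_lines]
    if not exclusive:
        raise DataError(
            f"no exclusive validation lines: {validation_src.dataset_id} panel is "
            f"contained in {discovery.dataset_id}"
        )
    validation = validation_src.restrict_lines(exclusive)
    drivers_d = recurrently_altered_drivers(
        alt_discovery, min_altered, panel=discovery.cell_line_ids
    )
    drivers_v = recurrently_altered_drivers(
        alt_validation, min_altered, panel=validation.cell_line_ids
    )
    testable_drivers = GeneSet(
        "testable_drivers", drivers_d.members & drivers_v.members
    )
    testable_targets = GeneSet(
        "testable_targets",
        frozenset(discovery.genes) & frozenset(validation.genes),
    )
    return DatasetPair(discovery, validation, testable_targets, testable_drivers)


def split_common_lines(
    ds_a: ScreenDataset,
    ds_b: ScreenDataset,
    alt_a: AlterationMatrix | None = None,
    alt_b: AlterationMatrix | None = None,
    min_altered: int = DEFAULT_MIN_ALTERED,
) -> DatasetPair:
    """Technical-reproducibility pair: both datasets restricted to shared lines.

    The overlap purge is deliberately not applied — the same cell lines are
    screened by two platforms, so reproducibility here is across technologies
    rather than across genetic backgrounds.
    """
    common = [l for l in ds_a.cell_line_ids if l in set(ds_b.cell_line_ids)]
    if not common:
        raise DataError(
            f"no common lines between {ds_a.dataset_id} and {ds_b.dataset_id}"
        )
    disc = ds_a.restrict_lines(common)
    val = ds_b.restrict_lines(common)
    drivers = None
    if alt_a is not None and alt_b is not None:
        drivers = GeneSet(
            "testable_drivers",
            recurrently_altered_drivers(alt_a, min_altered, panel=common).members
            & recurrently_altered_drivers(alt_b, min_altered, panel=common).members,
        )
    targets = GeneSet(
        "testable_targets", frozenset(disc.genes) & frozenset(val.genes)
    )
    return DatasetPair(disc, val, targets, drivers, mode="common_lines")


def split_within_dataset(
    ds: ScreenDataset,
    partition: Mapping[str, str] | Sequence[str],
    alt: AlterationMatrix | None = None,
    min_altered: int = DEFAULT_MIN_ALTERED,
) -> DatasetPair:
    """Split one dataset into disjoint discovery/validation sub-panels.

    ``partition`` is either a mapping line -> {"discovery", "validation"}
    covering the whole panel, or a reference panel of line ids: lines shared
    with the reference become the validation half and the remainder the
    discovery half.
    """
    panel = ds.cell_line_ids
    if isinstance(partition, Mapping):
        missing = [l for l in panel if l not in partition]
        if missing:
            raise DataError(f"partition omits lines: {missing[:5]}")
        bad = {v for v in partition.values()} - {"discovery", "validation"}
        if bad:
            raise DataError(f"unknown partition labels: {sorted(bad)}")
        disc_lines = [l for l in panel if partition[l] == "discovery"]
        val_lines = [l for l in panel if partition[l] == "validation"]
    else:
        ref = set(partition)
        disc_lines = [l for l in panel if l not in ref]
        val_lines = [l for l in panel if l in ref]
    if not disc_lines or not val_lines:
        raise DataError("both partition halves must be non-empty")
    disc = ds.restrict_lines(disc_lines, suffix="[discovery]")
    val = ds.restrict_lines(val_lines, suffix="[validation]")
    drivers = None
    if alt is not None:
        drivers = GeneSet(
            "testable_drivers",
            recurrently_altered_drivers(alt, min_altered, panel=disc_lines).members
            & recurrently_altered_drivers(alt, min_altered, panel=val_lines).members,
        )
    targets = GeneSet("testable_targets", frozenset(ds.genes))
    return DatasetPair(disc, val, targets, drivers)


# ---------------------------------------------------------------------------
# Validation of discovered hits
# ---------------------------------------------------------------------------

def validate_pair(
    pair: DatasetPair,
    discovery_results: Sequence[AssociationResult],
    validation_results: Sequence[AssociationResult],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[ValidationRecord]:
    """Apply the three reproduction criteria to the discovered associations.

    Discovered = discovery FDR below threshold; reproduced = validation FDR
    below threshold AND validation p < 0.05 AND same direction.  A discovered
    pair with no validation record (skipped fit) counts as not validated.
    """
    universe = {
        (r.driver, r.target): r
        for r in validation_results
        if r.target in pair.testable_targets
        and (pair.testable_drivers is None or r.driver in pair.testable_drivers)
    }
    validated: list[ValidationRecord] = []
    for d in discovery_results:
        if d.target not in pair.testable_targets:
            continue
        if pair.testable_drivers is not None and d.driver not in pair.testable_drivers:
            continue
        if d.fdr is None or d.fdr >= fdr_threshold:
            continue
        v = universe.get((d.driver, d.target))
        if v is None:
            logger.info(
                "discovered pair %s/%s has no validation fit in %s",
                d.driver, d.target, pair.validation.dataset_id,
            )
            continue
        if (
            v.fdr is not None
            and v.fdr < fdr_threshold
            and v.p_value < VALIDATION_P_THRESHOLD
            and v.direction == d.direction
        ):
            validated.append(
                ValidationRecord(
                    driver=d.driver,
                    target=d.target,
                    direction=d.direction,
                    discovery_id=pair.discovery.dataset_id,
                    validation_id=pair.validation.dataset_id,
                    discovery_fdr=float(d.fdr),
                    validation_fdr=float(v.fdr),
                    validation_p=float(v.p_value),
                )
            )
    return validated


def classify_interaction(
    driver: str, target: str, direction: str, gene_class: str | None
) -> str:
    if driver == target:
        if direction == SENSITIVITY and gene_class in {
            "oncogene", "oncogene_amplification_only"
        }:
            return ONCOGENE_ADDICTION
        if gene_class == "tumour_suppressor":
            return SELF_TUMOUR_SUPPRESSOR
        return ONCOGENE_ADDICTION if direction == SENSITIVITY else RESISTANCE_CLASS
    return SYNTHETIC_LETHALITY if direction == SENSITIVITY else RESISTANCE_CLASS


def aggregate_robust(
    all_pair_validations: Sequence[ValidationRecord],
    driver_rules: Sequence[DriverGeneRule] = (),
) -> list[RobustInteraction]:
    """Collapse per-pair validations into one record per (driver, target, direction)."""
    class_of = {r.gene: r.gene_class for r in driver_rules}
    grouped: dict[tuple[str, str, str], list[ValidationRecord]] = {}
    for rec in all_pair_validations:
        grouped.setdefault((rec.driver, rec.target, rec.direction), []).append(rec)
    robust = [
        RobustInteraction(
            driver=driver,
            target=target,
            direction=direction,
            validated_pairs=records,
            interaction_class=classify_interaction(
                driver, target, direction, class_of.get(driver)
            ),
        )
        for (driver, target, direction), records in sorted(grouped.items())
    ]
    return robust


def exclude_self(robust: Sequence[RobustInteraction]) -> list[RobustInteraction]:
    """Genetic-interaction view: self (driver = target) associations removed."""
    return [r for r in robust if not r.is_self]


def most_significant_dependency(
    robust: Sequence[RobustInteraction], driver: str
) -> RobustInteraction | None:
    """The driver's most significant validated dependency (smallest validation p)."""
    mine = [r for r in robust if r.driver == driver]
    if not mine:
        return None
    return min(mine, key=lambda r: (r.best_validation_p, r.best_discovery_fdr))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything a full discovery/validation run produces."""

    per_dataset: dict[str, list[AssociationResult]]
    pair_validations: dict[tuple[str, str], list[ValidationRecord]]
    robust: list[RobustInteraction]
    tested_pairs: set[tuple[str, str]] = field(default_factory=set)
    discovered_pairs: set[tuple[str, str]] = field(default_factory=set)
    validated_pairs: set[tuple[str, str]] = field(default_factory=set)

    @property
    def robust_interactions(self) -> list[RobustInteraction]:
        return exclude_self(self.robust)

    def summary(self) -> dict[str, int]:
        return {
            "n_tested": len(self.tested_pairs),
            "n_discovered": len(self.discovered_pairs),
            "n_validated": len(self.validated_pairs),
            "n_robust_total": len(self.robust),
            "n_robust_self": sum(r.is_self for r in self.robust),
            "n_robust_interactions": len(self.robust_interactions),
        }


def run_pipeline(
    datasets: Sequence[ScreenDataset],
    alterations: Mapping[str, AlterationMatrix] | AlterationMatrix,
    targets: GeneSet,
    driver_rules: Sequence[DriverGeneRule] = (),
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_altered: int = DEFAULT_MIN_ALTERED,
    validation_family: str = "full",
) -> PipelineResult:
    """Run every ordered dataset pair through discovery and validation.

    ``alterations`` may be one world-level matrix (restricted per panel) or a
    mapping dataset_id -> matrix.  ``validation_family`` chooses the BH family
    for validation FDRs: ``full`` (all associations testable in the pair's
    validation run, the default) or ``discovered`` (only the discovered
    subset).
    """
    if validation_family not in {"full", "discovered"}:
        raise ValueError(f"unknown validation_family {validation_family!r}")

    def alt_for(ds: ScreenDataset) -> AlterationMatrix:
        if isinstance(alterations, AlterationMatrix):
            return alterations
        return alterations[ds.dataset_id]

    # one full association run per dataset; per-pair families are re-derived
    per_dataset: dict[str, list[AssociationResult]] = {}
    for ds in datasets:
        per_dataset[ds.dataset_id] = run_screen_associations(
            ds, alt_for(ds).restrict_lines(ds.cell_line_ids), targets,
            min_altered=min_altered,
        )

    pair_validations: dict[tuple[str, str], list[ValidationRecord]] = {}
    tested: set[tuple[str, str]] = set()
    discovered: set[tuple[str, str]] = set()
    all_records: list[ValidationRecord] = []
    for disc_ds in datasets:
        for val_ds in datasets:
            if disc_ds.dataset_id == val_ds.dataset_id:
                continue
            pair = make_pair(
                disc_ds, val_ds,
                alt_for(disc_ds).restrict_lines(disc_ds.cell_line_ids),
                alt_for(val_ds).restrict_lines(val_ds.cell_line_ids),
                min_altered=min_altered,
            )
            disc_results = with_fdr([
                r for r in per_dataset[disc_ds.dataset_id]
                if r.target in pair.testable_targets
                and r.driver in pair.testable_drivers
            ])
            val_results = run_screen_associations(
                pair.validation,
                alt_for(val_ds).restrict_lines(pair.validation.cell_line_ids),
                GeneSet("t", pair.testable_targets.members),
                min_altered=min_altered,
                drivers=sorted(pair.testable_drivers.members),
            )
            if validation_family == "discovered":
                discovered_keys = {
                    (r.driver, r.target) for r in disc_results
                    if r.fdr is not None and r.fdr < fdr_threshold
                }
                val_results = with_fdr([
                    r for r in val_results
                    if (r.driver, r.target) in discovered_keys
                ])
            tested.update((r.driver, r.target) for r in disc_results)
            discovered.update(
                (r.driver, r.target) for r in disc_results
                if r.fdr is not None and r.fdr < fdr_threshold
            )
            records = validate_pair(pair, disc_results, val_results, fdr_threshold)
            pair_validations[pair.pair_id] = records
            all_records.extend(records)

    robust = aggregate_robust(all_records, driver_rules)
    validated = {(r.driver, r.target) for r in all_records}
    return PipelineResult(
        per_dataset=per_dataset,
        pair_validations=pair_validations,
        robust=robust,
        tested_pairs=tested,
        discovered_pairs=discovered,
        validated_pairs=validated,
    )
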