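"""Extensions: chemogenetic screens, passenger-gene search, pathway ORA, siRNA normalization.

Four analyses built on the same machinery as the main discovery/validation
engine: (1) grouping genes by how many chemogenetic screens call them a hit
and asking whether PPI partners of the inhibited target concentrate in the
reproducible groups; (2) restricting the passenger-gene interaction search to
PPI partners of recurrently lost passengers, with a random-pair null for the
resulting robust-hit count; (3) hypergeometric over-representation of gene
sets (GMT) against the selectively-lethal background; (4) control-anchored
normalization of siRNA viability measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .alterations import AlterationMatrix
from .association import benjamini_hochberg
from .core_data import DataError, GeneSet
from .ppi_enrichment import PPINetwork, fisher_exact_2x2, canonical_pair

logger = logging.getLogger("robustgi")

DEFAULT_MIN_LOST = 10
DEFAULT_N_NULL_REPS = 100
CONTROL_NEGATIVE = "siCTRL"  # non-targeting scramble control
CONTROL_POSITIVE = "siPLK1"  # kills essentially all cells; defines viability 0


# ---------------------------------------------------------------------------
# Chemogenetic screens
# ---------------------------------------------------------------------------

@dataclass
class ChemogeneticScreenSet:
    """Per-cell-line hit lists from screens run against one inhibited target."""

    target_gene: str
    hits_per_line: dict[str, frozenset[str]]
    universe: GeneSet

    def __post_init__(self) -> None:
        if not self.hits_per_line:
            raise DataError("need at least one cell line screen")
        for line, hits in self.hits_per_line.items():
            stray = hits - self.universe.members
            if stray:
                raise DataError(
                    f"{line}: hits outside the screened universe: {sorted(stray)[:5]}"
                )

    @property
    def n_lines(self) -> int:
        return len(self.hits_per_line)

    def hit_counts(self) -> dict[str, int]:
        """Number of cell-line screens calling each universe gene a hit."""
        counts = {g: 0 for g in self.universe.members}
        for hits in self.hits_per_line.values():
            for g in hits:
                counts[g] += 1
        return counts


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[int, int]
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def chemogenetic_group_analysis(
    screens: ChemogeneticScreenSet, network: PPINetwork
) -> dict[str, object]:
    """PPI-partnership fraction per hit-count group, with pairwise Fisher tests.

    Every screened gene is assigned the number of cell-line screens in which
    it was a hit (0..n_lines); per group we report the fraction of genes that
    are PPI partners of the inhibited target, and every pair of groups is
    compared by Fisher's exact test.
    """
    if screens.n_lines < 2:
        raise DataError("need at least two cell line screens")
    if screens.target_gene not in network.graph:
        raise DataError(f"target gene {screens.target_gene!r} absent from the PPI network")
    partners = network.partners_of(screens.target_gene)
    counts = screens.hit_counts()
    groups: dict[int, list[str]] = {k: [] for k in range(screens.n_lines + 1)}
    for gene, k in counts.items():
        groups[k].append(gene)
    fractions = {}
    tallies = {}
    for k, genes in groups.items():
        n_partner = sum(g in partners for g in genes)
        tallies[k] = (n_partner, len(genes) - n_partner)
        fractions[k] = n_partner / len(genes) if genes else float("nan")
    comparisons = []
    for k_lo, k_hi in combinations(sorted(groups), 2):
        table = (tallies[k_hi], tallies[k_lo])
        if tallies[k_hi][0] + tallies[k_hi][1] == 0 or tallies[k_lo][0] + tallies[k_lo][1] == 0:
            continue
        odds, p = fisher_exact_2x2(table)
        comparisons.append(
            GroupComparison(groups=(k_hi, k_lo), table=table, odds_ratio=odds, p_value=p)
        )
    return {"group_sizes": {k: len(v) for k, v in groups.items()},
            "fractions": fractions, "comparisons": comparisons}


# ---------------------------------------------------------------------------
# Passenger-gene search
# ---------------------------------------------------------------------------

def passenger_candidate_pairs(
    passenger_alt: AlterationMatrix,
    network: PPINetwork,
    targets: GeneSet,
    min_lost: int = DEFAULT_MIN_LOST,
) -> list[tuple[str, str]]:
    """(passenger, target) pairs to test: PPI-adjacent, recurrent loss, lethal target.

    Restricting to PPI partners shrinks the all-against-all search space by
    orders of magnitude, which is what makes passenger interactions testable
    at a sane multiple-testing burden.
    """
    lost_counts = passenger_alt.calls.sum(axis=0)
    recurrent = [g for g in passenger_alt.genes if lost_counts[g] >= min_lost]
    pairs = []
    for passenger in recurrent:
        for partner in sorted(network.partners_of(passenger)):
            if partner in targets and partner != passenger:
                pairs.append((passenger, partner))
    return pairs


@dataclass
class NullSummary:
    counts: list[int]

    @property
    def median(self) -> float:
        return float(np.median(self.counts))

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def min(self) -> int:
        return int(np.min(self.counts))

    @property
    def max(self) -> int:
        return int(np.max(self.counts))


def random_pair_null(
    universe_pairs: Sequence[tuple[str, str]],
    n_pairs: int,
    count_robust: Callable[[Sequence[tuple[str, str]]], int],
    n_reps: int = DEFAULT_N_NULL_REPS,
    seed: int = 0,
) -> NullSummary:
    """Null distribution of robust-hit counts over random same-size pair samples.

    Per replicate, ``n_pairs`` pairs are drawn uniformly without replacement
    from ``universe_pairs`` (the same search space as the observed analysis)
    and passed through ``count_robust`` — a closure over the identical
    discovery/validation pipeline.  Replicates are independent; everything is
    reproducible from ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_pairs > len(universe_pairs):
        raise ValueError(
            f"cannot sample {n_pairs} pairs from a universe of {len(universe_pairs)}"
        )
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_reps):
        idx = rng.choice(len(universe_pairs), size=n_pairs, replace=False)
        sample = [universe_pairs[i] for i in idx]
        counts.append(int(count_robust(sample)))
    return NullSummary(counts)


# ---------------------------------------------------------------------------
# Pathway over-representation
# ---------------------------------------------------------------------------

@dataclass
class PathwayGeneSets:
    """Named gene sets restricted to a declared background universe."""

    sets: dict[str, GeneSet]
    background: GeneSet

    def __post_init__(self) -> None:
        if not self.background.members:
            raise DataError("background gene set must be non-empty")
        self.sets = {
            name: GeneSet(name, gs.members & self.background.members)
            for name, gs in self.sets.items()
        }


@dataclass(frozen=True)
class ORAResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    q_value: float


def pathway_ora(query: GeneSet, gene_sets: PathwayGeneSets) -> list[ORAResult]:
    """One-sided hypergeometric over-representation of the query in each set.

    The query must lie within the background (e.g. the selectively lethal
    genes); p-values are upper-tail hypergeometric, BH-corrected across sets,
    and results come back sorted by p so the top row is the most enriched
    pathway.
    """
    stray = query.members - gene_sets.background.members
    if stray:
        raise DataError(f"query genes outside background: {sorted(stray)[:5]}")
    M = len(gene_sets.background)
    N = len(query)
    rows = []
    for name, gs in gene_sets.sets.items():
        K = len(gs.members)
        k = len(query.members & gs.members)
        # P(overlap >= k) with K marked genes among M, drawing N
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append((name, k, K, p))
    if not rows:
        return []
    q = benjamini_hochberg([r[3] for r in rows])
    results = [
        ORAResult(
            set_name=name, overlap=k, set_size=K,
            query_size=N, background_size=M,
            p_value=p, q_value=float(qi),
        )
        for (name, k, K, p), qi in zip(rows, q)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


# ---------------------------------------------------------------------------
# siRNA viability normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViabilityMeasurement:
    cell_line_id: str
    sirna_target: str  # gene symbol or a control label (siCTRL / siPLK1)
    raw_viability: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.raw_viability < 0:
            raise DataError("raw viability (luminescence) cannot be negative")


def normalize_viability(
    measurements: Sequence[ViabilityMeasurement],
) -> dict[str, dict[str, object]]:
    """Anchor viability between the negative and positive controls per line.

    normalized = 1 - (mean(siCTRL) - raw) / (mean(siCTRL) - mean(siPLK1)),
    so the scramble-control mean maps to 1 and the PLK1 (lethal) control mean
    to 0.  Returns, per cell line and siRNA target, the per-replicate
    normalized values and their mean.  The transform is invariant to a common
    rescaling of the raw luminescence of a line.
    """
    by_line: dict[str, list[ViabilityMeasurement]] = {}
    for m in measurements:
        by_line.setdefault(m.cell_line_id, []).append(m)
    out: dict[str, dict[str, object]] = {}
    for line, ms in by_line.items():
        neg = [m.raw_viability for m in ms if m.sirna_target == CONTROL_NEGATIVE]
        pos = [m.raw_viability for m in ms if m.sirna_target == CONTROL_POSITIVE]
        if not neg or not pos:
            raise DataError(f"{line}: both {CONTROL_NEGATIVE} and {CONTROL_POSITIVE} required")
        ctrl, plk1 = float(np.mean(neg)), float(np.mean(pos))
        if ctrl == plk1:
            raise DataError(f"{line}: control means equal ({ctrl}); cannot normalize")
        span = ctrl - plk1
        per_target: dict[str, dict[str, object]] = {}
        for m in ms:
            norm = 1.0 - (ctrl - m.raw_viability) / span
            per_target.setdefault(m.sirna_target, {"values": []})["values"].append(norm)
        for t, d in per_target.items():
            d["mean"] = float(np.mean(d["values"]))
        out[line] = per_target
    return out
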