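"""Protein-protein interaction networks and enrichment analyses.

Robust genetic interactions tend to connect genes whose protein products
physically interact.  This module ingests scored PPI edge lists (STRING-style
0-1000 integer scores are auto-detected and rescaled to 0-1), computes the
"ladder" of PPI fractions across nested gene-pair groups (all tested pairs,
pairs discovered in at least one screen, pairs validated in at least one
discovery/validation pair) with Fisher exact tests between adjacent groups,
and provides degree-matched network randomization so that hub/ascertainment
bias can be controlled with an empirical null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .core_data import DataError

logger = logging.getLogger("robustgi")

DEFAULT_MIN_SCORE = 0.4  # medium-confidence cut on the 0-1 scale; strict ">"
DEFAULT_N_RANDOM_NETWORKS = 100
SWAPS_PER_EDGE = 10


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair, canonicalized lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PPINetwork:
    """Undirected simple gene graph with confidence-scored edges (0-1 scale)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise DataError(f"self-loops not allowed: {loops[:3]}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def partners_of(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene)) if gene in self.graph else set()

    def degree_sequence(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_pair(u, v) for u, v in self.graph.edges()}


def build_network(edges: Iterable[tuple[str, str, float]]) -> PPINetwork:
    """Build a simple undirected network, collapsing reciprocal/duplicate rows
    (keeping the maximum score) and dropping self-loops."""
    g = nx.Graph()
    n_loops = 0
    for a, b, score in edges:
        if a == b:
            n_loops += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=float(score))
    if n_loops:
        logger.info("dropped %d self-loop edges", n_loops)
    return PPINetwork(g)


def read_ppi_edges(
    path: str | Path,
    format: str = "string_scored",
    min_score: float = DEFAULT_MIN_SCORE,
) -> PPINetwork:
    """Read a PPI edge list TSV (gene1, gene2[, score]).

    ``string_scored`` expects a score column; integer scores above 1 are taken
    to be on the STRING 0-1000 scale and divided by 1000.  Only edges with
    score strictly above ``min_score`` are kept.  ``generic_pairs`` reads
    two-column lists, assigning every edge score 1.0.
    """
    if format not in {"string_scored", "generic_pairs"}:
        raise ValueError(f"unknown PPI format {format!r}")
    rows: list[tuple[str, str, float]] = []
    text = Path(path).read_text().splitlines()
    start = 0
    if text and not _is_edge_row(text[0], format):
        start = 1  # header row
    for lineno, line in enumerate(text[start:], start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if format == "generic_pairs":
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected two columns")
            rows.append((parts[0], parts[1], 1.0))
        else:
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected gene1, gene2, score")
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad score {parts[2]!r}") from exc
            rows.append((parts[0], parts[1], score))
    if format == "string_scored" and rows and max(r[2] for r in rows) > 1.0:
        rows = [(a, b, s / 1000.0) for a, b, s in rows]
    if format == "string_scored":
        rows = [r for r in rows if r[2] > min_score]
    return build_network(rows)


def _is_edge_row(line: str, format: str) -> bool:
    parts = line.rstrip("\n").split("\t")
    if format == "generic_pairs":
        return len(parts) >= 2 and parts[0].lower() not in {"gene1", "protein1"}
    if len(parts) < 3:
        return False
    try:
        float(parts[2])
        return True
    except ValueError:
        return False


def write_ppi_edges(network: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tscore\n")
        for a, b in sorted(network.edge_set()):
            fh.write(f"{a}\t{b}\t{network.graph[a][b].get('score', 1.0):g}\n")


# ---------------------------------------------------------------------------
# Fisher exact test and enrichment ladder
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (odds_ratio, p).  The odds ratio is the plain cross-product ratio
    a*d / (b*c): infinite when b*c = 0 with a*d > 0, NaN when both products
    vanish.  The p-value sums hypergeometric probabilities of tables (margins
    fixed) no more probable than the observed one.
    """
    ((a, b), (c, d)) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def haldane_odds_ratio(table: Sequence[Sequence[int]]) -> float:
    """Haldane-Anscombe corrected OR (+0.5 to every cell) for plotting."""
    ((a, b), (c, d)) = table
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


@dataclass(frozen=True)
class EnrichmentResult:
    group_labels: tuple[str, str]
    table: tuple[tuple[int, int], tuple[int, int]]  # rows = groups, cols = (ppi, not ppi)
    odds_ratio: float
    p_value: float

    @property
    def fractions(self) -> tuple[float, float]:
        (a, b), (c, d) = self.table
        return (a / (a + b) if a + b else math.nan,
                c / (c + d) if c + d else math.nan)


def ppi_fraction(pairs: Iterable[tuple[str, str]], network: PPINetwork) -> float:
    pairs = list(pairs)
    if not pairs:
        return math.nan
    hits = sum(network.has_edge(a, b) for a, b in pairs)
    return hits / len(pairs)


def _count_ppi(pairs: set[tuple[str, str]], network: PPINetwork) -> tuple[int, int]:
    hits = sum(network.has_edge(a, b) for a, b in pairs)
    return hits, len(pairs) - hits


def enrichment_ladder(
    tested_pairs: Iterable[tuple[str, str]],
    discovered_pairs: Iterable[tuple[str, str]],
    validated_pairs: Iterable[tuple[str, str]],
    network: PPINetwork,
    exclude_driver: str | None = None,
) -> dict[str, object]:
    """PPI fractions across the nested tested ⊇ discovered ⊇ validated groups.

    Fractions are reported on the nested groups (as in a stacked bar chart);
    the two Fisher tests compare disjoint complements so the comparisons are
    independent: tested-only vs discovered, and discovered-only vs validated.
    When ``exclude_driver`` is given, every pair involving that gene is
    removed first (the TP53-exclusion analysis).
    """
    def canon(pairs: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
        out = {canonical_pair(a, b) for a, b in pairs}
        if exclude_driver is not None:
            out = {p for p in out if exclude_driver not in p}
        return out

    tested, discovered, validated = map(canon, (tested_pairs, discovered_pairs, validated_pairs))
    if not (validated <= discovered <= tested):
        raise DataError("expected validated ⊆ discovered ⊆ tested")
    if not tested or not discovered or not validated:
        raise DataError("all three groups must be non-empty")

    fractions = {
        "tested": ppi_fraction(tested, network),
        "discovered": ppi_fraction(discovered, network),
        "validated": ppi_fraction(validated, network),
    }
    comparisons = []
    for (lo_name, lo), (hi_name, hi) in [
        (("tested_only", tested - discovered), ("discovered", discovered)),
        (("discovered_only", discovered - validated), ("validated", validated)),
    ]:
        if not lo:
            logger.info("skipping %s comparison: complement group empty", lo_name)
            continue
        t_hi = _count_ppi(hi, network)
        t_lo = _count_ppi(lo, network)
        table = (t_hi, t_lo)
        odds, p = fisher_exact_2x2(table)
        comparisons.append(
            EnrichmentResult(
                group_labels=(hi_name, lo_name),
                table=table,
                odds_ratio=odds,
                p_value=p,
            )
        )
    return {"fractions": fractions, "comparisons": comparisons}


# ---------------------------------------------------------------------------
# Degree-matched randomization
# ---------------------------------------------------------------------------

def degree_matched_randomize(
    network: PPINetwork,
    n_networks: int = DEFAULT_N_RANDOM_NETWORKS,
    seed: int = 0,
) -> list[PPINetwork]:
    """Generate degree-preserving randomized copies via double-edge swaps.

    Each copy keeps the exact node set and per-node degree; rewiring uses
    10 swaps per edge.  Fully reproducible from ``seed``; networks with fewer
    than two edges are returned unchanged with a warning.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if network.n_edges < 2 or network.n_nodes < 4:
        logger.warning("network too small to rewire; returning unrandomized copies")
        return [PPINetwork(network.graph.copy()) for _ in range(n_networks)]
    out = []
    rng = np.random.default_rng(seed)
    nswap = SWAPS_PER_EDGE * network.n_edges
    for i in range(n_networks):
        g = network.graph.copy()
        sub_seed = int(rng.integers(0, 2**31 - 1))
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=sub_seed)
        out.append(PPINetwork(g))
    return out


def empirical_enrichment_p(observed_count: int, null_counts: Sequence[int]) -> float:
    """Add-one empirical upper-tail p: (1 + #{null >= observed}) / (1 + n_null)."""
    null_counts = list(null_counts)
    if not null_counts:
        raise ValueError("null_counts must be non-empty")
    ge = sum(1 for c in null_counts if c >= observed_count)
    return (1 + ge) / (1 + len(null_counts))


def ppi_overlap_count(pairs: Iterable[tuple[str, str]], network: PPINetwork) -> int:
    """Number of gene pairs that are edges of the network."""
    return sum(network.has_edge(a, b) for a, b in {canonical_pair(a, b) for a, b in pairs})
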