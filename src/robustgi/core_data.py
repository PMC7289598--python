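"""Data model and I/O for loss-of-function screen datasets.

A screen dataset is a genes × cell-lines matrix of gene sensitivity scores
(lower = stronger fitness defect on inhibition) together with per-line
annotations (tissue, microsatellite-instability status, aliases).  This module
handles reading/writing those matrices, harmonizing cell-line identifiers
across studies, accounting for panel overlap between studies, and selecting
the "selectively lethal" genes whose inhibition kills some but not all lines —
the only genes for which a sensitive/resistant contrast can be tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("robustgi")

# Default filtering constants for selectively lethal genes: a gene qualifies
# with a sensitivity score below SCORE_THRESHOLD in at least MIN_LINES lines
# but in no more than half of the screened panel.
DEFAULT_SCORE_THRESHOLD = -0.6
DEFAULT_MIN_LINES = 10
DEFAULT_MAX_FRACTION = 0.5


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class CellLineAnnotation:
    """Annotation for one screened cell line.

    ``tissue`` and ``msi`` are the two covariates of the association model;
    ``aliases`` records alternative identifiers used by other studies.
    """

    cell_line_id: str
    tissue: str
    msi: bool = False
    aliases: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.cell_line_id:
            raise DataError("cell_line_id must be non-empty")
        if not self.tissue:
            raise DataError(f"tissue must be non-empty for {self.cell_line_id!r}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class ScreenDataset:
    """One study's sensitivity matrix plus its annotated cell-line panel.

    ``scores`` is a DataFrame indexed by gene symbol with one column per
    cell-line id (canonical orientation genes × lines); NaN marks a missing
    score.  ``annotations`` maps cell_line_id -> CellLineAnnotation and covers
    every column.
    """

    dataset_id: str
    scores: pd.DataFrame
    annotations: dict[str, CellLineAnnotation]

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            dup = self.scores.index[self.scores.index.duplicated()][0]
            raise DataError(f"duplicate gene symbol {dup!r} in {self.dataset_id}")
        if self.scores.columns.has_duplicates:
            dup = self.scores.columns[self.scores.columns.duplicated()][0]
            raise DataError(f"duplicate cell line id {dup!r} in {self.dataset_id}")
        missing_ann = [c for c in self.scores.columns if c not in self.annotations]
        if missing_ann:
            raise DataError(
                f"{self.dataset_id}: cell lines without annotation: {missing_ann[:5]}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_genes(self) -> int:
        return self.scores.shape[0]

    @property
    def n_lines(self) -> int:
        return self.scores.shape[1]

    def tissue_of(self, line: str) -> str:
        return self.annotations[line].tissue

    def msi_of(self, line: str) -> bool:
        return self.annotations[line].msi

    def restrict_lines(self, lines: Sequence[str], suffix: str = "") -> "ScreenDataset":
        """Return a copy restricted to ``lines`` (order preserved from self)."""
        keep = [c for c in self.scores.columns if c in set(lines)]
        if not keep:
            raise DataError(f"{self.dataset_id}: restriction leaves no cell lines")
        return ScreenDataset(
            dataset_id=self.dataset_id + suffix,
            scores=self.scores[keep].copy(),
            annotations={c: self.annotations[c] for c in keep},
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_annotations(path: str | Path) -> dict[str, CellLineAnnotation]:
    """Read a cell-line annotation table.

    Expected columns: ``cell_line_id``, ``tissue``, ``msi`` (true/false) and
    optionally ``aliases`` (semicolon-separated).
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str).fillna("")
    required = {"cell_line_id", "tissue", "msi"}
    if not required.issubset(df.columns):
        raise DataError(f"annotation file {path} missing columns {required - set(df.columns)}")
    out: dict[str, CellLineAnnotation] = {}
    for row in df.itertuples(index=False):
        cid = row.cell_line_id
        if cid in out:
            raise DataError(f"duplicate cell line id {cid!r} in annotations {path}")
        aliases = frozenset(
            a for a in getattr(row, "aliases", "").split(";") if a
        )
        out[cid] = CellLineAnnotation(
            cell_line_id=cid,
            tissue=row.tissue,
            msi=str(row.msi).strip().lower() in {"true", "1", "yes"},
            aliases=aliases,
        )
    return out


def write_annotations(annotations: Mapping[str, CellLineAnnotation], path: str | Path) -> None:
    rows = [
        {
            "cell_line_id": a.cell_line_id,
            "tissue": a.tissue,
            "msi": str(a.msi).lower(),
            "aliases": ";".join(sorted(a.aliases)),
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_sensitivity_matrix(
    path: str | Path,
    annotations: Mapping[str, CellLineAnnotation],
    orientation: str = "genes_in_rows",
    dataset_id: str | None = None,
) -> ScreenDataset:
    """Read a delimited sensitivity matrix into a ScreenDataset.

    ``orientation`` is one of ``genes_in_rows`` / ``lines_in_rows``; the
    internal canonical orientation is genes × lines.  Unparseable numeric
    cells become missing values.  Duplicate identifiers or an empty matrix
    raise :class:`DataError`.
    """
    if orientation not in {"genes_in_rows", "lines_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_cols = pd.Index(header)
    if dup_cols.has_duplicates:
        dup = dup_cols[dup_cols.duplicated()][0]
        raise DataError(f"duplicate column identifier {dup!r} in {path}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.columns = header  # undo any pandas mangling of near-duplicate names
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise DataError(f"empty matrix in {path}")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise DataError(f"duplicate row identifier {dup!r} in {path}")

    def _parse(cell: object) -> float:
        # python float() parses exactly; pd.to_numeric's fast path does not
        try:
            return float(cell)
        except (TypeError, ValueError):
            return float("nan")

    scores = raw.apply(lambda col: col.map(_parse))
    if orientation == "lines_in_rows":
        scores = scores.T
    ds = ScreenDataset(
        dataset_id=dataset_id or Path(path).stem,
        scores=scores,
        annotations={c: annotations[c] for c in scores.columns},
    )
    n_missing = int(scores.isna().sum().sum())
    logger.info(
        "read %s: %d genes x %d lines, %d missing",
        ds.dataset_id, ds.n_genes, ds.n_lines, n_missing,
    )
    return ds


def write_sensitivity_matrix(ds: ScreenDataset, path: str | Path) -> None:
    """Write genes × lines scores; missing values as empty cells.

    Uses 17 significant digits so that a read-back reproduces every finite
    value exactly.
    """
    ds.scores.to_csv(path, sep=_sep_for(path), float_format="%.17g", na_rep="")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list."""
    members = frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
    return GeneSet(name=name or Path(path).stem, members=members)


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        name, _desc, *genes = parts
        sets[name] = GeneSet(name=name, members=frozenset(g for g in genes if g))
    return sets


# ---------------------------------------------------------------------------
# Filtering and harmonization
# ---------------------------------------------------------------------------

def filter_cell_lines_by_missingness(
    ds: ScreenDataset, max_missing_fraction: float
) -> tuple[ScreenDataset, list[str]]:
    """Drop cell lines whose fraction of missing gene scores exceeds the cap.

    The boundary is inclusive: a line with fraction exactly equal to
    ``max_missing_fraction`` is retained.  Returns the filtered dataset and
    the list of removed line ids.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = ds.scores.isna().mean(axis=0)
    removed = [c for c in ds.scores.columns if frac[c] > max_missing_fraction]
    if len(removed) == ds.n_lines:
        raise DataError(f"{ds.dataset_id}: all cell lines exceed missingness cap")
    if not removed:
        return ds, []
    kept = [c for c in ds.scores.columns if c not in set(removed)]
    logger.info("%s: removed %d lines for missingness", ds.dataset_id, len(removed))
    return ds.restrict_lines(kept), removed


def harmonize_cell_lines(
    datasets: Iterable[ScreenDataset], alias_map: Mapping[str, str]
) -> list[ScreenDataset]:
    """Map cell-line ids to canonical names across studies.

    Ids absent from ``alias_map`` pass through unchanged.  Two lines of one
    dataset collapsing onto the same canonical id is an error (it would merge
    distinct screens).  Applying the same map twice is a no-op provided the
    map is idempotent on its own values.
    """
    out = []
    for ds in datasets:
        new_ids = [alias_map.get(c, c) for c in ds.scores.columns]
        seen: dict[str, str] = {}
        for old, new in zip(ds.scores.columns, new_ids):
            if new in seen:
                raise DataError(
                    f"{ds.dataset_id}: {old!r} and {seen[new]!r} both map to {new!r}"
                )
            seen[new] = old
        scores = ds.scores.copy()
        scores.columns = new_ids
        annotations = {
            new: replace(ds.annotations[old], cell_line_id=new)
            for old, new in zip(ds.scores.columns, new_ids)
        }
        out.append(ScreenDataset(ds.dataset_id, scores, annotations))
    return out


def compute_panel_overlap(datasets: Sequence[ScreenDataset]) -> dict[frozenset[str], int]:
    """Count cell lines per exact membership pattern across dataset panels.

    Returns a mapping from a frozenset of dataset_ids (the studies a line
    appears in, exactly) to the number of such lines; counts sum to the size
    of the union of the panels.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    membership: dict[str, set[str]] = {}
    for ds in datasets:
        for c in ds.cell_line_ids:
            membership.setdefault(c, set()).add(ds.dataset_id)
    counts: dict[frozenset[str], int] = {}
    for pattern in membership.values():
        key = frozenset(pattern)
        counts[key] = counts.get(key, 0) + 1
    return counts


def identify_selectively_lethal(
    ds: ScreenDataset,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    min_lines: int = DEFAULT_MIN_LINES,
    max_fraction: float = DEFAULT_MAX_FRACTION,
    outlier_genes: GeneSet | None = None,
    common_essentials: GeneSet | None = None,
) -> GeneSet:
    """Select genes with a usable sensitive/resistant contrast.

    A gene qualifies when its score falls below ``score_threshold`` in at
    least ``min_lines`` lines but in no more than
    ``floor(max_fraction * n_lines)`` lines of the full panel (missing scores
    never count as below threshold).  The set is augmented with
    ``outlier_genes`` present in the dataset and finally purged of
    ``common_essentials``.
    """
    if min_lines < 1:
        raise ValueError("min_lines must be >= 1")
    if not 0 < max_fraction <= 1:
        raise ValueError("max_fraction must be in (0, 1]")
    below = (ds.scores < score_threshold).sum(axis=1)
    cap = int(np.floor(max_fraction * ds.n_lines))
    selected = set(below.index[(below >= min_lines) & (below <= cap)])
    if outlier_genes is not None:
        selected |= set(outlier_genes.members) & set(ds.genes)
    if common_essentials is not None:
        selected -= set(common_essentials.members)
    return GeneSet(name=f"selectively_lethal[{ds.dataset_id}]", members=frozenset(selected))
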