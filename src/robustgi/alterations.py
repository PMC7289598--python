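"""Binary functional-alteration calling for driver and passenger genes.

Driver genes are called altered from mutation and copy-number data according
to their class: most oncogenes require a protein-altering mutation at a
recurrently altered residue; a few oncogenes (ERBB2-like) count only when
amplified; tumour suppressors count any protein-coding (non-silent) mutation
or a homozygous deletion.  Passenger genes use a stricter rule — only clear
loss-of-function events (nonsense/frameshift/splice mutations or homozygous
deletion) count, and driver genes are excluded entirely.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import DataError, GeneSet

logger = logging.getLogger("robustgi")

CONSEQUENCE_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "inframe", "silent", "other"}
)
#: consequence classes treated as clear loss of function for passenger calling
LOF_CLASSES = frozenset({"nonsense", "frameshift", "splice"})

DEFAULT_HOM_DEL_THRESHOLD = -1.28  # relative copy-number below this = homozygous deletion
DEFAULT_AMP_THRESHOLD = 1.0  # amplification cut-off (same scale); no canonical value exists
DEFAULT_MIN_ALTERED = 5

# reason codes
RECURRENT_MUTATION = "recurrent_mutation"
AMPLIFICATION = "amplification"
LOF_MUTATION = "lof_mutation"
HOM_DEL = "homozygous_deletion"

_RESIDUE_RE = re.compile(r"^p\.?[A-Za-z*]{1,3}?(\d+)")


@dataclass(frozen=True)
class MutationRecord:
    cell_line_id: str
    gene: str
    protein_change: str
    consequence_class: str

    def __post_init__(self) -> None:
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise DataError(
                f"unknown consequence class {self.consequence_class!r} for "
                f"{self.gene} in {self.cell_line_id}"
            )

    @property
    def is_protein_altering(self) -> bool:
        return self.consequence_class not in {"silent"}

    @property
    def residue(self) -> int | None:
        """Numeric residue position parsed from the protein change, if any."""
        m = _RESIDUE_RE.match(self.protein_change or "")
        return int(m.group(1)) if m else None


@dataclass(frozen=True)
class DriverGeneRule:
    gene: str
    gene_class: str  # oncogene | oncogene_amplification_only | tumour_suppressor
    recurrent_residues: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.gene_class not in {
            "oncogene", "oncogene_amplification_only", "tumour_suppressor"
        }:
            raise DataError(f"unknown gene class {self.gene_class!r} for {self.gene}")
        if self.recurrent_residues and self.gene_class != "oncogene":
            raise DataError(
                f"{self.gene}: recurrent residues only apply to plain oncogenes"
            )


@dataclass
class AlterationMatrix:
    """Binary cell-line × gene matrix of functional-alteration calls.

    ``calls`` is a boolean DataFrame indexed by cell_line_id with gene
    columns; ``reasons`` has the same shape with a reason code wherever a
    call is True and empty string elsewhere.
    """

    role: str  # driver | passenger
    calls: pd.DataFrame
    reasons: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in {"driver", "passenger"}:
            raise DataError(f"unknown role {self.role!r}")
        if self.calls.shape != self.reasons.shape:
            raise DataError("calls and reasons shapes differ")
        bad = (self.calls.to_numpy() & (self.reasons.to_numpy() == "")).any()
        if bad:
            raise DataError("every positive call needs a reason code")

    @property
    def genes(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.calls.index)

    def status(self, gene: str, lines: Sequence[str]) -> np.ndarray:
        """Boolean alteration vector for ``gene`` over ``lines`` (missing lines = wild type)."""
        s = self.calls[gene] if gene in self.calls.columns else None
        return np.array(
            [bool(s[l]) if s is not None and l in s.index else False for l in lines]
        )

    def restrict_lines(self, lines: Sequence[str]) -> "AlterationMatrix":
        keep = [l for l in lines if l in self.calls.index]
        return AlterationMatrix(
            self.role, self.calls.loc[keep].copy(), self.reasons.loc[keep].copy()
        )


def _empty_alteration_frame(lines: Sequence[str], genes: Sequence[str]):
    calls = pd.DataFrame(False, index=list(lines), columns=list(genes))
    reasons = pd.DataFrame("", index=list(lines), columns=list(genes))
    return calls, reasons


def call_driver_alterations(
    mutations: Iterable[MutationRecord],
    cn: pd.DataFrame,
    rules: Sequence[DriverGeneRule],
    cell_lines: Sequence[str] | None = None,
    hom_del_threshold: float = DEFAULT_HOM_DEL_THRESHOLD,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> AlterationMatrix:
    """Call driver-gene functional alterations per the class-specific rules.

    ``cn`` is a genes × lines copy-number DataFrame (relative/log scale);
    missing values never trigger amplification or deletion calls.  Each
    positive call carries a reason code; when multiple rules fire, mutation
    evidence takes precedence over copy number for reporting.
    """
    muts = list(mutations)
    if cell_lines is None:
        lines = sorted(
            {m.cell_line_id for m in muts} | set(map(str, cn.columns))
        )
    else:
        lines = list(cell_lines)
    line_set = set(lines)
    calls, reasons = _empty_alteration_frame(lines, [r.gene for r in rules])

    by_gene: dict[str, list[MutationRecord]] = {}
    for m in muts:
        if m.cell_line_id in line_set:
            by_gene.setdefault(m.gene, []).append(m)

    for rule in rules:
        g = rule.gene
        if g not in by_gene and g not in cn.index:
            logger.warning("driver rule for %s matches no mutation or CN data", g)
            continue
        cn_row = cn.loc[g] if g in cn.index else None
        for m in by_gene.get(g, []):
            if rule.gene_class == "oncogene":
                res = m.residue
                if res is None and m.protein_change:
                    logger.debug("unparseable protein change %r for %s", m.protein_change, g)
                if (
                    m.is_protein_altering
                    and res is not None
                    and res in rule.recurrent_residues
                ):
                    calls.at[m.cell_line_id, g] = True
                    reasons.at[m.cell_line_id, g] = RECURRENT_MUTATION
            elif rule.gene_class == "tumour_suppressor":
                if m.is_protein_altering:
                    calls.at[m.cell_line_id, g] = True
                    reasons.at[m.cell_line_id, g] = LOF_MUTATION
        if cn_row is not None:
            for line in lines:
                if line not in cn_row.index:
                    continue
                v = cn_row[line]
                if pd.isna(v) or calls.at[line, g]:
                    continue
                if rule.gene_class == "oncogene_amplification_only" and v >= amp_threshold:
                    calls.at[line, g] = True
                    reasons.at[line, g] = AMPLIFICATION
                elif rule.gene_class == "tumour_suppressor" and v < hom_del_threshold:
                    calls.at[line, g] = True
                    reasons.at[line, g] = HOM_DEL
    return AlterationMatrix("driver", calls, reasons)


def call_passenger_loss(
    mutations: Iterable[MutationRecord],
    cn: pd.DataFrame,
    driver_genes: GeneSet,
    cell_lines: Sequence[str] | None = None,
    hom_del_threshold: float = DEFAULT_HOM_DEL_THRESHOLD,
) -> AlterationMatrix:
    """Call passenger-gene loss: clear LOF mutation or homozygous deletion.

    Driver genes are excluded from the output entirely; missense and other
    ambiguous mutation classes never count.
    """
    muts = [m for m in mutations if m.gene not in driver_genes]
    genes = sorted(
        ({m.gene for m in muts} | set(map(str, cn.index))) - set(driver_genes.members)
    )
    if cell_lines is None:
        lines = sorted({m.cell_line_id for m in muts} | set(map(str, cn.columns)))
    else:
        lines = list(cell_lines)
    line_set = set(lines)
    calls, reasons = _empty_alteration_frame(lines, genes)
    for m in muts:
        if m.cell_line_id in line_set and m.consequence_class in LOF_CLASSES:
            calls.at[m.cell_line_id, m.gene] = True
            reasons.at[m.cell_line_id, m.gene] = LOF_MUTATION
    cn_sub = cn.loc[[g for g in genes if g in cn.index], [l for l in lines if l in cn.columns]]
    deleted = cn_sub < hom_del_threshold
    for g in deleted.index:
        for line in deleted.columns:
            if deleted.at[g, line] and not calls.at[line, g]:
                calls.at[line, g] = True
                reasons.at[line, g] = HOM_DEL
    return AlterationMatrix("passenger", calls, reasons)


def recurrently_altered_drivers(
    alt: AlterationMatrix,
    min_altered: int = DEFAULT_MIN_ALTERED,
    panel: Sequence[str] | None = None,
) -> GeneSet:
    """Genes altered in at least ``min_altered`` lines of the (restricted) matrix."""
    if min_altered < 1:
        raise ValueError("min_altered must be >= 1")
    calls = alt.calls
    if panel is not None:
        keep = [l for l in panel if l in calls.index]
        calls = calls.loc[keep]
    counts = calls.sum(axis=0)
    members = frozenset(counts.index[counts >= min_altered])
    return GeneSet(name=f"recurrent_{alt.role}s", members=members)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-like TSV with columns sample, gene, protein_change, consequence_class."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample", "gene", "protein_change", "consequence_class"}
    if not required.issubset(df.columns):
        raise DataError(f"mutation file {path} missing columns {required - set(df.columns)}")
    return [
        MutationRecord(r.sample, r.gene, r.protein_change, r.consequence_class)
        for r in df.itertuples(index=False)
    ]


def write_mutations(mutations: Sequence[MutationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": m.cell_line_id,
                "gene": m.gene,
                "protein_change": m.protein_change,
                "consequence_class": m.consequence_class,
            }
            for m in mutations
        ],
        columns=["sample", "gene", "protein_change", "consequence_class"],
    ).to_csv(path, sep="\t", index=False)


def read_copy_number(path: str | Path) -> pd.DataFrame:
    """Read a genes × lines copy-number TSV matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.apply(pd.to_numeric, errors="coerce")


def read_driver_rules(path: str | Path) -> list[DriverGeneRule]:
    """Read driver rules TSV: gene, class, recurrent_residues (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rules = []
    for r in df.itertuples(index=False):
        residues = frozenset(int(x) for x in r.recurrent_residues.split(";") if x)
        rules.append(DriverGeneRule(r.gene, r.gene_class, residues))
    return rules


def write_driver_rules(rules: Sequence[DriverGeneRule], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "gene_class": r.gene_class,
                "recurrent_residues": ";".join(str(x) for x in sorted(r.recurrent_residues)),
            }
            for r in rules
        ],
        columns=["gene", "gene_class", "recurrent_residues"],
    ).to_csv(path, sep="\t", index=False)


def write_alteration_matrix(alt: AlterationMatrix, calls_path: str | Path, reasons_path: str | Path | None = None) -> None:
    alt.calls.astype(int).to_csv(calls_path, sep="\t")
    if reasons_path is not None:
        alt.reasons.to_csv(reasons_path, sep="\t")


def read_alteration_matrix(
    calls_path: str | Path, role: str, reasons_path: str | Path | None = None
) -> AlterationMatrix:
    calls = pd.read_csv(calls_path, sep="\t", index_col=0).astype(bool)
    if reasons_path is not None:
        reasons = pd.read_csv(reasons_path, sep="\t", index_col=0, dtype=str).fillna("")
        reasons = reasons.reindex(index=calls.index, columns=calls.columns).fillna("")
    else:
        reasons = pd.DataFrame(
            np.where(calls.to_numpy(), "unspecified", ""),
            index=calls.index, columns=calls.columns,
        )
    return AlterationMatrix(role, calls, reasons)
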