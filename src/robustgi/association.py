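"""Covariate-adjusted driver/sensitivity association testing.

For each (driver gene Y, target gene X) pair within one screen dataset we fit
the linear model

    sensitivity(X) ~ MSI_status + C(Tissue) + driver_status(Y)

by ordinary least squares and report the driver-term coefficient (the mean
sensitivity-score shift in altered lines after covariate adjustment), its
two-sided p-value, a common-language effect size computed on the raw scores,
and a Benjamini-Hochberg FDR over all tests of the run.  Tissue and MSI enter
as covariates so that tissue-restricted essentialities (the SOX10-in-melanoma
kind of artefact) are not mistaken for driver associations.

``fit_association`` fits one pair through statsmodels; ``run_screen_associations``
uses a vectorized normal-equations engine that shares the design matrix across
all targets with the same missingness pattern — numerically identical (tested)
but fast enough for thousands of targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alterations import AlterationMatrix, recurrently_altered_drivers, DEFAULT_MIN_ALTERED
from .core_data import DataError, GeneSet, ScreenDataset

logger = logging.getLogger("robustgi")

SENSITIVITY = "sensitivity"
RESISTANCE = "resistance"


class NoContrastError(DataError):
    """Driver altered in all or none of the retained cell lines."""


@dataclass(frozen=True)
class AssociationResult:
    """One driver -> target association test within one dataset."""

    dataset_id: str
    driver: str
    target: str
    n_altered: int
    n_wt: int
    coefficient: float
    p_value: float
    cles: float
    fdr: float | None = None

    @property
    def direction(self) -> str:
        return SENSITIVITY if self.coefficient < 0 else RESISTANCE

    @property
    def is_self(self) -> bool:
        return self.driver == self.target


def common_language_effect_size(
    altered_scores: Sequence[float], wt_scores: Sequence[float]
) -> float:
    """P(random altered score < random wild-type score), ties counting half.

    Larger values mean altered lines are more sensitive (lower scores).
    Equals the Mann-Whitney U statistic of the wild-type group divided by
    n1*n2; computed exactly over all pairs via midranks.
    """
    a = np.asarray(altered_scores, dtype=float)
    w = np.asarray(wt_scores, dtype=float)
    if a.size == 0 or w.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, w]))
    r1 = ranks[: a.size].sum()
    u1 = r1 - a.size * (a.size + 1) / 2.0  # #(a>w) + 0.5 #(a==w)
    return float(1.0 - u1 / (a.size * w.size))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _covariate_matrix(ds: ScreenDataset, lines: Sequence[str]) -> pd.DataFrame:
    """Intercept + binary MSI + one-hot tissue (lexicographically first level dropped).

    Constant columns (MSI uniform, single tissue) are omitted; the intercept
    always stays.
    """
    msi = np.array([ds.msi_of(l) for l in lines], dtype=float)
    tissues = [ds.tissue_of(l) for l in lines]
    X = pd.DataFrame({"const": np.ones(len(lines))}, index=list(lines))
    if len(set(msi)) > 1:
        X["msi"] = msi
    levels = sorted(set(tissues))
    for lvl in levels[1:]:  # first level is the reference
        X[f"tissue[{lvl}]"] = [1.0 if t == lvl else 0.0 for t in tissues]
    return X


def _first_collinear_column(X: np.ndarray, names: Sequence[str]) -> str:
    """Name of the first column lying in the span of the preceding ones."""
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            return names[j]
    return names[-1]


def fit_association(
    ds: ScreenDataset,
    alt: AlterationMatrix,
    driver: str,
    target: str,
) -> AssociationResult:
    """Fit the covariate-adjusted model for one (driver, target) pair.

    Lines with a missing target score are dropped before fitting; both
    alteration groups must be non-empty afterwards.  The p-value is the
    two-sided test of the driver coefficient (equivalent to the 1-df ANOVA
    F-test for that term).
    """
    if target not in ds.scores.index:
        raise DataError(f"target {target!r} not screened in {ds.dataset_id}")
    if driver not in alt.calls.columns:
        raise DataError(f"driver {driver!r} absent from alteration matrix")
    y_all = ds.scores.loc[target]
    keep = [l for l in ds.cell_line_ids if pd.notna(y_all[l])]
    status = alt.status(driver, keep)
    n_alt, n_wt = int(status.sum()), int(len(keep) - status.sum())
    if n_alt == 0 or n_wt == 0:
        raise NoContrastError(
            f"{ds.dataset_id}: driver {driver} altered in {n_alt}/{len(keep)} retained lines"
        )
    X = _covariate_matrix(ds, keep)
    X["driver"] = status.astype(float)
    Xv = X.to_numpy()
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise DataError(
            f"singular design matrix: collinear term "
            f"{_first_collinear_column(Xv, list(X.columns))!r}"
        )
    y = y_all[keep].to_numpy(dtype=float)
    res = sm.OLS(y, Xv).fit()
    j = X.columns.get_loc("driver")
    cles = common_language_effect_size(y[status], y[~status])
    return AssociationResult(
        dataset_id=ds.dataset_id,
        driver=driver,
        target=target,
        n_altered=n_alt,
        n_wt=n_wt,
        coefficient=float(res.params[j]),
        p_value=float(res.pvalues[j]),
        cles=cles,
    )


# ---------------------------------------------------------------------------
# Batched screen-wide runs
# ---------------------------------------------------------------------------

def _batch_driver_fit(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """OLS of every column of Y on X; returns (coef, p) for the last X column.

    Returns None when the design is rank-deficient or has no residual df.
    """
    n, p = X.shape
    if n - p <= 0 or np.linalg.matrix_rank(X) < p:
        return None
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid * resid).sum(axis=0) / (n - p)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[-1, -1], 0.0))
    coef = beta[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), n - p)
    return coef, pvals


def _batch_cles(Y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Common-language effect size per column of Y for group split ``mask``."""
    n1 = int(mask.sum())
    n2 = Y.shape[0] - n1
    ranks = stats.rankdata(Y, axis=0)
    r1 = ranks[mask].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return 1.0 - u1 / (n1 * n2)


def run_screen_associations(
    ds: ScreenDataset,
    alt: AlterationMatrix,
    targets: GeneSet | Sequence[str],
    min_altered: int = DEFAULT_MIN_ALTERED,
    drivers: Sequence[str] | None = None,
) -> list[AssociationResult]:
    """Test every recurrently altered driver against every target gene.

    Drivers default to those altered in at least ``min_altered`` lines of this
    panel.  Targets absent from the dataset are skipped.  BH correction is
    applied once across all tests of this call; degenerate fits (no contrast,
    collinear design) are skipped with a log entry.
    """
    target_list = [t for t in (targets.members if isinstance(targets, GeneSet) else targets)
                   if t in ds.scores.index]
    target_list = sorted(target_list)
    if drivers is None:
        drivers = sorted(
            recurrently_altered_drivers(alt, min_altered, panel=ds.cell_line_ids).members
        )
    lines = ds.cell_line_ids
    Y_full = ds.scores.loc[target_list, lines].to_numpy(dtype=float).T  # lines x targets
    cov = _covariate_matrix(ds, lines)

    # group targets by missingness pattern so each group shares one design
    miss = np.isnan(Y_full)
    patterns: dict[bytes, list[int]] = {}
    for j in range(Y_full.shape[1]):
        patterns.setdefault(miss[:, j].tobytes(), []).append(j)

    results: list[AssociationResult] = []
    for driver in drivers:
        status_full = alt.status(driver, lines)
        for key, cols in patterns.items():
            row_keep = ~np.frombuffer(key, dtype=bool)
            if row_keep.sum() < 3:
                logger.debug("%s/%s: too few lines after missingness", ds.dataset_id, driver)
                continue
            status = status_full[row_keep]
            n_alt = int(status.sum())
            n_wt = int(row_keep.sum() - n_alt)
            if n_alt == 0 or n_wt == 0:
                logger.debug("%s: no contrast for %s in a missingness group",
                             ds.dataset_id, driver)
                continue
            sub_cov = cov.loc[np.array(lines)[row_keep]]
            # re-drop covariate columns that became constant in this subset
            keep_cols = [c for c in sub_cov.columns
                         if c == "const" or sub_cov[c].nunique() > 1]
            X = np.column_stack([sub_cov[keep_cols].to_numpy(), status.astype(float)])
            fitted = _batch_driver_fit(X, Y_full[np.ix_(row_keep, cols)])
            if fitted is None:
                logger.info("%s: skipping driver %s (singular design)", ds.dataset_id, driver)
                continue
            coefs, pvals = fitted
            cles = _batch_cles(Y_full[np.ix_(row_keep, cols)], status)
            for k, j in enumerate(cols):
                results.append(
                    AssociationResult(
                        dataset_id=ds.dataset_id,
                        driver=driver,
                        target=target_list[j],
                        n_altered=n_alt,
                        n_wt=n_wt,
                        coefficient=float(coefs[k]),
                        p_value=float(pvals[k]),
                        cles=float(cles[k]),
                    )
                )
    return with_fdr(results)


def with_fdr(results: Sequence[AssociationResult]) -> list[AssociationResult]:
    """Attach BH q-values computed over exactly this family of tests."""
    if not results:
        return []
    q = benjamini_hochberg([r.p_value for r in results])
    return [replace(r, fdr=float(qi)) for r, qi in zip(results, q)]


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tabular view of association results (one row per driver/target pair)."""
    return pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id,
                "driver": r.driver,
                "target": r.target,
                "n_altered": r.n_altered,
                "n_wt": r.n_wt,
                "coefficient": r.coefficient,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "cles": r.cles,
                "direction": r.direction,
            }
            for r in results
        ]
    )


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided heteroscedastic (Welch) t-test; returns (t, p)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)
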