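import numpy as np
import pandas as pd
import pytest

from robustgi.core_data import CellLineAnnotation, ScreenDataset
from robustgi.alterations import AlterationMatrix, LOF_MUTATION


def make_dataset(
    scores: np.ndarray,
    genes=None,
    lines=None,
    tissues=None,
    msi=None,
    dataset_id="DS",
) -> ScreenDataset:
    """Small hand-rolled dataset; defaults to one tissue, MSI-negative."""
    scores = np.asarray(scores, dtype=float)
    n_genes, n_lines = scores.shape
    genes = genes or [f"g{i + 1}" for i in range(n_genes)]
    lines = lines or [f"c{i + 1}" for i in range(n_lines)]
    tissues = tissues or ["lung"] * n_lines
    msi = msi if msi is not None else [False] * n_lines
    ann = {
        l: CellLineAnnotation(l, t, m)
        for l, t, m in zip(lines, tissues, msi)
    }
    return ScreenDataset(dataset_id, pd.DataFrame(scores, index=genes, columns=lines), ann)


def make_alterations(status: dict, lines) -> AlterationMatrix:
    """AlterationMatrix from {driver: bool list aligned to lines}."""
    calls = pd.DataFrame(status, index=list(lines)).astype(bool)
    reasons = pd.DataFrame(
        np.where(calls.to_numpy(), LOF_MUTATION, ""),
        index=calls.index, columns=calls.columns,
    )
    return AlterationMatrix("driver", calls, reasons)


@pytest.fixture
def two_group_dataset():
    """Single tissue, constant MSI: altered=[-2.0,-1.8,-2.2], wt=[0.0,0.2,-0.2]."""
    ds = make_dataset(np.array([[-2.0, -1.8, -2.2, 0.0, 0.2, -0.2]]), genes=["tgt"])
    alt = make_alterations({"drv": [True, True, True, False, False, False]}, ds.cell_line_ids)
    return ds, alt
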