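"""Shared design-matrix helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from longmed.data_model import COVARIATE_COLUMNS


def dummy_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Dummy-code baseline covariates, largest category as reference.

    Covariates constant in ``df`` contribute no columns.
    """
    cols, labels = [], []
    for cov in COVARIATE_COLUMNS:
        counts = df[cov].value_counts()
        for level in counts.index[1:]:
            cols.append((df[cov] == level).to_numpy(dtype=float))
            labels.append(f"{cov}[{level}]")
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), labels
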