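"""Delimited-text dataset I/O (samples in rows, one label column)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def load_dataset(path: str, label_col: str = "label") -> tuple[np.ndarray, np.ndarray]:
    """Read a CSV/TSV feature table and split off the label column.

    If ``label_col`` is absent the last column is used.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if label_col not in df.columns:
        label_col = df.columns[-1]
    y = df[label_col].to_numpy()
    X = df.drop(columns=[label_col]).to_numpy(dtype=float)
    return X, y


def save_dataset(path: str, X: np.ndarray, y: np.ndarray, label_col: str = "label") -> None:
    df = pd.DataFrame(np.asarray(X), columns=[f"g{j}" for j in range(np.shape(X)[1])])
    df[label_col] = np.asarray(y)
    df.to_csv(path, sep=_sep_for(path), index=False)
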