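"""Design-matrix construction shared by the longitudinal and joint models.

Fixed-effect terms are named columns of the input table, with two reserved
names: ``intercept`` (a column of ones) and ``time`` (years since baseline,
the only term that varies within subject). Random-effect terms are a subset
of ``{intercept, time}``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RESERVED = {"intercept": lambda df: np.ones(len(df)), "time": lambda df: df["time"].to_numpy(float)}


def build_design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Stack the named terms into an (n, p) design matrix."""
    cols = []
    for t in terms:
        if t in RESERVED:
            cols.append(RESERVED[t](df))
        else:
            if t not in df.columns:
                raise KeyError(f"design term {t!r} is not a column of the table")
            cols.append(df[t].to_numpy(float))
    return np.column_stack(cols)


def check_full_rank(X: np.ndarray, terms: list[str]) -> None:
    """Raise with the offending column names if X is column-rank deficient."""
    Xc = X - X.mean(axis=0, keepdims=True)
    # keep the intercept column un-centered so it still carries rank
    for j, t in enumerate(terms):
        if t == "intercept":
            Xc[:, j] = 1.0
    s = np.linalg.svd(Xc, compute_uv=False)
    if s[-1] < 1e-10 * max(s[0], 1.0):
        # identify a minimal collinear set by greedy QR
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(terms[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
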