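"""Tissue-to-tissue GDMR correlations with exact Pearson p-values.

Reproductive tissues exist in one sex only, so the animal x tissue matrix is
structurally incomplete: correlations use pairwise-complete animals
(listwise deletion would leave nothing), and cross-sex tissue pairs (e.g.
ovary x testis) have zero complete pairs and are reported missing.  Pairs
with fewer than 3 complete animals are likewise reported missing rather
than raising.

P-values are the classical two-sided Student-t transform

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   p = 2 * P(T_{n-2} >= |t|),

reported nominally (no multiplicity correction, matching the way such
correlation screens are usually tabulated); Benjamini-Hochberg adjustment
is available as an option on the tidy pair table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation of ``r`` over ``n`` pairs."""
    if n < 3:
        raise ValueError("pearson_p requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class CorrelationMatrix:
    """Pairwise r, n and p matrices (tissue x tissue) plus a tidy pair table."""

    r: pd.DataFrame
    n: pd.DataFrame
    p: pd.DataFrame
    pairs: pd.DataFrame

    @property
    def tissues(self) -> list[str]:
        return list(self.r.columns)


def pivot_tissue_table(
    table: pd.DataFrame,
    *,
    index: str = "animal",
    columns: str = "tissue",
    values: str = "gdmr",
) -> pd.DataFrame:
    """Long (animal, tissue, gdmr) records to a wide animal x tissue matrix."""
    dup = table.duplicated(subset=[index, columns])
    if dup.any():
        raise ValueError(
            f"duplicate ({index}, {columns}) records at rows {table.index[dup].tolist()[:5]}"
        )
    return table.pivot(index=index, columns=columns, values=values)


def correlate(
    table: pd.DataFrame,
    *,
    min_n: int = 3,
    bh_adjust: bool = False,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations of a wide animal x column table.

    Long input (with ``animal``/``tissue``/``gdmr`` columns) is pivoted
    automatically.  Diagonal r is 1 with p missing-by-convention; pairs with
    fewer than ``min_n`` complete animals get missing r/p and are flagged in
    the tidy table.  ``bh_adjust=True`` adds a Benjamini-Hochberg adjusted
    p column over the valid off-diagonal pairs.
    """
    if {"animal", "tissue", "gdmr"} <= set(table.columns):
        wide = pivot_tissue_table(table)
    else:
        wide = table
    cols = list(wide.columns)
    k = len(cols)
    r_mat = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    p_mat = np.full((k, k), np.nan)
    rows = []
    X = wide.to_numpy(dtype=float)
    finite = np.isfinite(X)
    for i in range(k):
        r_mat[i, i] = 1.0
        n_mat[i, i] = int(finite[:, i].sum())
        for j in range(i + 1, k):
            mask = finite[:, i] & finite[:, j]
            n = int(mask.sum())
            n_mat[i, j] = n_mat[j, i] = n
            flag = ""
            r = p = np.nan
            if n < min_n:
                flag = "insufficient_pairs"
            else:
                xi, xj = X[mask, i], X[mask, j]
                if np.std(xi) == 0 or np.std(xj) == 0:
                    flag = "constant_input"
                else:
                    r = float(np.corrcoef(xi, xj)[0, 1])
                    r = min(1.0, max(-1.0, r))
                    p = pearson_p(r, n)
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p
            rows.append(
                {"tissue_1": cols[i], "tissue_2": cols[j], "r": r, "n": n, "p": p, "flag": flag}
            )
    pairs = pd.DataFrame(rows, columns=["tissue_1", "tissue_2", "r", "n", "p", "flag"])
    if bh_adjust:
        pairs = pairs.assign(p_bh=_bh(pairs["p"].to_numpy()))
    as_df = lambda m, dtype=float: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationMatrix(r=as_df(r_mat), n=as_df(n_mat), p=as_df(p_mat), pairs=pairs)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, NaN-aware."""
    out = np.full_like(p, np.nan, dtype=float)
    valid = np.isfinite(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    adj = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[valid] = res
    return out
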