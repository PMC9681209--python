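"""Rank correlation and gene-list overlap statistics.

Spearman's rho is computed on average ranks; its p-value is exact (full
permutation enumeration) for n <= 9 and uses the t approximation otherwise.
Gene-list overlap significance is the hypergeometric upper tail
(over-representation); a two-sided variant via Fisher's exact test is
available behind a flag.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_N_MAX = 9


def _rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Spearman rank correlation (rho, p).

    Average ranks on ties. For n <= 9 the p-value enumerates all n!
    permutations of one margin; beyond that the t approximation is used.
    A constant vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho(rx, ry)
    n = len(x)
    if n <= EXACT_N_MAX:
        count = 0
        total = 0
        for perm in permutations(ry):
            r = _rho(rx, np.asarray(perm))
            total += 1
            if alternative == "two-sided":
                count += abs(r) >= abs(rho) - 1e-12
            elif alternative == "greater":
                count += r >= rho - 1e-12
            elif alternative == "less":
                count += r <= rho + 1e-12
            else:
                raise ValueError(f"unknown alternative: {alternative}")
        p = count / total
    else:
        res = sps.spearmanr(x, y, alternative=alternative)
        p = float(res.pvalue)
    return rho, float(p)


def overlap_test(
    k: int, n1: int, n2: int, N: int, alternative: str = "greater"
) -> float:
    """Significance of an overlap of ``k`` genes between lists of sizes
    ``n1`` and ``n2`` drawn from a universe of ``N`` genes.

    The universe size must be supplied explicitly — there is no sensible
    silent default. One-sided ('greater') is the hypergeometric upper tail
    P(X >= k); 'two-sided' delegates to Fisher's exact test on the 2x2
    table.
    """
    if not (0 <= k <= min(n1, n2) <= N):
        raise ValueError("require 0 <= k <= min(n1, n2) <= N")
    if max(n1, n2) > N:
        raise ValueError("list sizes exceed the universe")
    if alternative == "greater":
        return float(sps.hypergeom.sf(k - 1, N, n1, n2))
    if alternative == "two-sided":
        table = [[k, n1 - k], [n2 - k, N - n1 - n2 + k]]
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown alternative: {alternative}")


def correlate_composition(
    ratios: pd.Series, composition: pd.DataFrame, alternative: str = "two-sided"
) -> pd.DataFrame:
    """Spearman correlation of a per-patient score (e.g. ACS/OPC ratio)
    against each cell-type fraction column, over patients present in both."""
    shared = ratios.index.intersection(composition.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 patients shared between inputs")
    rows = []
    for col in composition.columns:
        rho, p = spearman(
            ratios.loc[shared].to_numpy(),
            composition.loc[shared, col].to_numpy(),
            alternative=alternative,
        )
        rows.append({"cell_type": col, "rho": rho, "p": p, "n": len(shared)})
    return pd.DataFrame(rows)
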