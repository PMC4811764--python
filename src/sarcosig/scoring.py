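"""Per-sample signature scores, normal-panel z-scores and score comparisons.

The score of a sample is the algebraic sum of its expression over the
signature genes: expression is added for up genes and subtracted for down
genes.  Scores can optionally be computed on per-gene standardized values
so that genes on different scales contribute comparably.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import GeneSignature

__all__ = [
    "signature_score",
    "rank_scores",
    "zscore_vs_normals",
    "compare_scores",
    "TTestResult",
]


def validate_matrix(x: pd.DataFrame) -> None:
    """Check an expression matrix: unique IDs, all values finite."""
    if x.index.has_duplicates:
        dups = x.index[x.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dups}")
    if x.columns.has_duplicates:
        dups = x.columns[x.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dups}")
    values = x.to_numpy(float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")


def rank_scores(scores: pd.Series) -> pd.Series:
    """Ranks 1..n, 1 = highest score; ties broken by sample ID (lexicographic)."""
    order = sorted(scores.index, key=lambda s: (-scores[s], str(s)))
    return pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order, name=scores.index.name)
    ).reindex(scores.index)


def signature_score(
    x: pd.DataFrame, sig: GeneSignature, standardize: bool = False
) -> pd.DataFrame:
    """Signed-sum signature score for every sample of ``x``.

    For each sample ``s``, ``score(s) = sum_g direction(g) * v(g, s)`` over
    the signature genes present in ``x``; ``v`` is the raw matrix value or,
    with ``standardize=True``, the per-gene standardized value (mean 0,
    sd 1 over samples, n-1 denominator).

    Returns a DataFrame indexed by sample with columns ``score``, ``rank``
    (1 = highest, ties broken by sample ID).  Coverage (fraction of
    signature genes found) and the used genes are stored in ``.attrs``.

    Raises
    ------
    ValueError
        If no signature gene is present in the matrix.
    """
    validate_matrix(x)
    present = [g for g in x.index if g in sig]
    missing = sig.genes - set(present)
    if not present:
        raise ValueError(
            f"no gene of signature {sig.name!r} is present in the matrix"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) of {sig.name} absent from the matrix"
        )

    sub = x.loc[present]
    if standardize:
        sd = sub.std(axis=1, ddof=1)
        degenerate = sd[sd == 0].index.tolist()
        if degenerate:
            warnings.warn(
                f"skipping zero-variance gene(s) under standardize: {degenerate}"
            )
            sub = sub.drop(index=degenerate)
            present = [g for g in present if g not in set(degenerate)]
            if sub.empty:
                raise ValueError("no usable signature gene after dropping "
                                 "zero-variance genes")
            sd = sd.drop(index=degenerate)
        sub = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)

    directions = np.array([sig.direction(g) for g in present], dtype=float)
    scores = pd.Series(directions @ sub.to_numpy(float), index=x.columns,
                       name="score")
    table = pd.DataFrame({"score": scores, "rank": rank_scores(scores)})
    table.index.name = "sample_id"
    table.attrs["signature"] = sig.name
    table.attrs["used_genes"] = list(present)
    table.attrs["coverage"] = len(present) / len(sig)
    table.attrs["standardized"] = bool(standardize)
    return table


def zscore_vs_normals(
    values: pd.Series | Sequence[float], panel: Sequence[float]
) -> pd.DataFrame:
    """Z-score each sample's value against a normal-tissue panel.

    ``z(s) = (value(s) - mean(panel)) / sd(panel)`` with the n-1 sd
    denominator.  The panel must have >= 2 values and positive sd.
    """
    panel = np.asarray(panel, dtype=float)
    if panel.size < 2:
        raise ValueError("normal panel needs at least 2 values")
    mu = panel.mean()
    sd = panel.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate normal panel (sd = 0)")
    if not isinstance(values, pd.Series):
        values = pd.Series(np.asarray(values, dtype=float))
    out = pd.DataFrame(
        {"z": (values - mu) / sd, "panel_mean": mu, "panel_sd": sd}
    )
    out.index.name = "sample_id"
    return out


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    tails: int
    variance: str


def compare_scores(
    group_a: Iterable[float],
    group_b: Iterable[float],
    tails: int = 2,
    variance: str = "heteroscedastic",
    direction: str = "greater",
) -> TTestResult:
    """Two-sample t-test of signature scores between two groups.

    Parameters
    ----------
    tails:
        2 for a two-sided test; 1 for a one-sided test in the hypothesized
        ``direction`` ("greater": A > B, "less": A < B).
    variance:
        "pooled" for the classic equal-variance test, "heteroscedastic" for
        Welch's test with Satterthwaite degrees of freedom.

    Both groups constant and equal gives t = 0 with two-tailed p = 1
    (one-tailed p = 0.5) instead of the 0/0 failure of the raw formula.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variance not in ("pooled", "heteroscedastic"):
        raise ValueError(f"unknown variance model {variance!r}")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")

    equal_var = variance == "pooled"
    alternative = "two-sided" if tails == 2 else direction

    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = a.size + b.size - 2 if equal_var else float(a.size + b.size - 2)
        return TTestResult(0.0, float(df), 1.0 if tails == 2 else 0.5,
                           tails, variance)

    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    df = float(res.df) if hasattr(res, "df") else _satterthwaite_df(a, b, equal_var)
    pvalue = float(res.pvalue)
    if math.isnan(pvalue):  # infinite t from zero variance, unequal means
        pvalue = 0.0
    return TTestResult(float(res.statistic), df, pvalue, tails, variance)


def _satterthwaite_df(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if equal_var:
        return float(a.size + b.size - 2)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    return float(
        (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    )
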