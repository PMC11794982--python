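"""Marker-signature spot labelling and rank-based differential expression.

The cell-type readout mirrors how spatial studies pick out a cell
population without clustering: score every spot by the mean normalised
expression of a marker panel (e.g. the keratinocyte panel KRT5, KRT1,
KRT10, DSP, LOR), label spots in the strict upper quantile of the score
(default Q75), then test each feature for differential expression
between labelled and unlabelled spots with a two-sided Wilcoxon
rank-sum (Mann-Whitney U) test and Benjamini-Hochberg adjustment.
Spatial concordance between a feature and the marker signature is
quantified with Spearman rank correlation across spots.

Test conventions: mid-ranks for ties; the exact null distribution when
both groups have at most 8 observations and the pooled values are
untied, otherwise the normal approximation with tie and continuity
corrections; features whose values are fully tied across both groups
get p = 1.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import SpotMatrix

__all__ = [
    "signature_score",
    "label_spots",
    "wilcoxon_de",
    "bh_adjust",
    "spatial_concordance",
    "ConcordanceResult",
]

EXACT_MAX_N = 8


def signature_score(matrix: SpotMatrix, markers: list[str]) -> pd.Series:
    """Per-spot mean of normalised expression over a marker panel.

    Every marker must be present in the matrix; a missing one raises a
    ``KeyError`` naming it.
    """
    if not markers:
        raise ValueError("marker list is empty")
    rows = []
    for m in markers:
        rows.append(matrix.feature_index(m))  # raises KeyError naming it
    dense = np.asarray(matrix.counts[rows, :].todense())
    return pd.Series(dense.mean(axis=0), index=matrix.barcodes, name="score")


def label_spots(scores: pd.Series, quantile: float = 0.75) -> pd.Series:
    """Positive iff the score is strictly above the given score quantile.

    The strict inequality means an all-constant score vector labels no
    spot (no spurious "high-expression" population).
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must lie in [0, 1)")
    threshold = float(np.quantile(scores.to_numpy(), quantile))
    return (scores > threshold).rename("label")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for the first group) and p."""
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    untied = len(np.unique(pooled)) == len(pooled)
    if len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N and untied:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_de(
    matrix: SpotMatrix,
    labels: pd.Series,
    min_detect_frac: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between labelled and unlabelled spots.

    Features detected (count > 0) in fewer than ``min_detect_frac`` of
    spots are filtered out before testing; BH adjustment runs across the
    tested features only.  Returns one row per tested feature with
    columns ``feature, kind, n1, n2, U, p, q, log2fc, direction,
    significant`` where ``log2fc`` is the log2 ratio of group means of
    the (normalised) values with pseudocount 1 and ``significant`` is
    ``q < alpha``.
    """
    lab = labels.reindex(matrix.barcodes)
    if lab.isna().any():
        raise ValueError("labels must cover every barcode in the matrix")
    lab = lab.to_numpy(dtype=bool)
    n1, n2 = int(lab.sum()), int((~lab).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"both groups must be nonempty (labelled={n1}, other={n2})"
        )

    dense = np.asarray(matrix.counts.todense())
    detect = (dense > 0).mean(axis=1)
    tested = np.flatnonzero(detect >= min_detect_frac)

    recs = []
    for i in tested:
        a = dense[i, lab]
        b = dense[i, ~lab]
        u, p = _rank_test(a, b)
        m1, m2 = a.mean(), b.mean()
        recs.append(
            (
                matrix.features["id"].iat[i],
                matrix.features["kind"].iat[i],
                n1,
                n2,
                u,
                p,
                np.log2((m1 + 1.0) / (m2 + 1.0)),
            )
        )
    table = pd.DataFrame(
        recs, columns=["feature", "kind", "n1", "n2", "U", "p", "log2fc"]
    )
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    table["significant"] = table["q"] < alpha
    return table[
        ["feature", "kind", "n1", "n2", "U", "p", "q", "log2fc",
         "direction", "significant"]
    ]


class ConcordanceResult(NamedTuple):
    rho: float
    p: float
    n: int
    defined: bool


def spatial_concordance(scores: pd.Series, values) -> ConcordanceResult:
    """Spearman rank correlation between a signature and a feature.

    Mid-ranks for ties, two-sided p via the t approximation (scipy).  If
    either vector has zero variance the correlation is undefined and the
    result is flagged (``defined=False``, rho/p NaN).  Requires n >= 5.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score and feature vectors must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 spots for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConcordanceResult(float("nan"), float("nan"), x.size, False)
    rho, p = stats.spearmanr(x, y)
    return ConcordanceResult(float(rho), float(p), x.size, True)
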