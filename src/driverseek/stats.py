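"""Shared rank statistics.

Two tests are used throughout the pipeline: the two-sided Mann-Whitney
(Wilcoxon rank-sum) test — for gene-level screen significance, for the
copy-number/expression filter, and for the metastasis-expression filter —
and Spearman's rank correlation for expression/expression and
dependency/dependency comparisons.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps

from .errors import ValidationError

__all__ = ["mann_whitney", "spearman"]

#: largest group size for which the exact null distribution is enumerated
EXACT_MAX_N = 8


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``x`` versus ``y``.

    Parameters
    ----------
    x, y : array-like
        The two samples; each must be non-empty.
    mode : {"auto", "exact", "normal"}
        ``exact`` enumerates the null distribution of U (refuses ties and
        falls back to the normal approximation if any are present);
        ``normal`` uses the tie-corrected normal approximation with a 0.5
        continuity correction; ``auto`` picks ``exact`` whenever both
        groups have at most ``EXACT_MAX_N`` values and there are no ties.

    Returns
    -------
    (U, p) : tuple of float
        U statistic of ``x`` and the two-sided p-value, clipped to (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney requires two non-empty samples")
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mann_whitney mode {mode!r}")

    combined = np.concatenate([x, y])
    # Degenerate case: every value identical -> the test has no discrimination.
    if np.all(combined == combined[0]):
        return float(x.size * y.size / 2.0), 1.0

    has_ties = np.unique(combined).size < combined.size
    use_exact = (
        mode == "exact" or (mode == "auto" and x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N)
    ) and not has_ties

    method = "exact" if use_exact else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    p = max(p, np.finfo(float).tiny)  # keep p strictly positive
    return float(res.statistic), p


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Rho is computed on midranks; the p-value uses the t approximation with
    n - 2 degrees of freedom, appropriate for the cohort sizes (~100
    samples) this package targets. Constant input yields ``(nan, nan)`` —
    the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("spearman requires equal-length samples")
    if x.size < 3:
        raise ValidationError("spearman requires at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = _sps.spearmanr(x, y)
    return float(rho), float(p)
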