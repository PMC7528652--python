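"""Paired nonparametric tests used by the duplex-ratio analysis.

The two-tailed Wilcoxon signed-rank test is implemented here directly so the
null distribution is under the package's control: exact (by convolution over
the observed rank multiset) for n <= 25, normal approximation with
continuity correction and tie correction above.  Zero differences are
dropped before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_N_MAX = 25


@dataclass
class PairedTestResult:
    n: int
    statistic: float        # W+ : sum of ranks of positive differences
    p_value: float
    median_shift: float     # linear fold, 2**median(log2 differences)
    method: str
    degenerate: bool = False


def _exact_sf_counts(ranks: np.ndarray) -> np.ndarray:
    """Distribution of W+ over all sign assignments of the given ranks.

    Ranks may be half-integers (average ranks under ties); they are doubled
    to integers.  Returns counts over W+ in doubled units; the total mass is
    2**n.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    return counts


def signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ and the ranks of |d| (average ranks for ties), zeros dropped."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks


def wilcoxon_signed_rank(diffs) -> PairedTestResult:
    """Two-tailed one-sample Wilcoxon signed-rank test on paired differences.

    For n <= 25 the p-value is exact, computed from the full convolution of
    the observed rank multiset over all 2**n sign assignments (this handles
    tied ranks exactly, conditioning on the observed |d| pattern).  For
    larger n the normal approximation with continuity correction 0.5 and the
    usual tie correction is used.
    """
    d_all = np.asarray(diffs, dtype=float)
    median_shift = float(2 ** np.median(d_all)) if d_all.size else float("nan")
    d = d_all[d_all != 0]
    n = d.size
    if n == 0:
        return PairedTestResult(0, 0.0, 1.0, median_shift, "degenerate", True)
    w_plus, ranks = signed_rank_statistic(d)
    if n <= EXACT_N_MAX:
        counts = _exact_sf_counts(ranks)
        w2 = int(round(w_plus * 2))
        total = counts.sum()
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        if var <= 0:
            return PairedTestResult(n, w_plus, 1.0, median_shift, "degenerate", True)
        delta = w_plus - mu
        z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal"
    return PairedTestResult(n, w_plus, float(p), median_shift, method)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties."""
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
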