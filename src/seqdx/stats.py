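"""Group-comparison statistics used in the cohort report.

``group_association`` is a two-sided Fisher exact test on a 2 x k
contingency table (k <= 5), computed by full enumeration: under fixed
margins, the p-value sums the hypergeometric probabilities of all tables
no more probable than the observed one.  ``mean_difference_test`` is the
two-sided Welch t-test.  P-values are reported unadjusted.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import ttest_ind

from .exceptions import ConfigurationError, DegenerateDataError

_LOG_TOL = 1e-7  # tables within this log-probability slack of the observed count as "no more probable"


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def group_association(counts) -> float:
    """Two-sided Fisher exact p for a 2 x k table by full enumeration.

    The probability of a table with first row ``a`` given column totals
    ``c`` and first-row total ``r`` is prod_j C(c_j, a_j) / C(N, r); all
    first rows consistent with the margins are enumerated (vectorized over
    the last free cell) and those with probability <= that of the observed
    table are summed.
    """
    table = np.asarray(counts)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ConfigurationError("group_association expects a 2 x k table")
    if table.shape[1] < 2 or table.shape[1] > 5:
        raise ConfigurationError("group_association supports 2 <= k <= 5 columns")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ConfigurationError("counts must be integers")
        table = np.round(table).astype(np.int64)
    if (table < 0).any():
        raise ConfigurationError("counts must be non-negative")
    col = table.sum(axis=0)
    r = int(table[0].sum())
    n_tot = int(table.sum())
    if n_tot == 0:
        raise DegenerateDataError("empty contingency table")

    log_obs = float(np.sum(_log_binom(col, table[0])))
    k = table.shape[1]

    # enumerate a_1 .. a_{k-2} recursively; vectorize over a_{k-1}
    # (a_k is then fixed by the row margin)
    total_p = 0.0
    c_last2, c_last = int(col[k - 2]), int(col[k - 1])
    lb_last2 = _log_binom(c_last2, np.arange(c_last2 + 1))
    lb_last = _log_binom(c_last, np.arange(c_last + 1))

    denom = float(_log_binom(n_tot, r))

    def recurse(j: int, remaining: int, log_acc: float) -> float:
        if j == k - 2:
            a = np.arange(max(0, remaining - c_last), min(c_last2, remaining) + 1)
            if len(a) == 0:
                return 0.0
            logs = log_acc + lb_last2[a] + lb_last[remaining - a]
            keep = logs <= log_obs + _LOG_TOL
            return float(np.exp(logs[keep] - denom).sum())
        cj = int(col[j])
        acc = 0.0
        for a in range(0, min(cj, remaining) + 1):
            acc += recurse(j + 1, remaining - a, log_acc + float(_log_binom(cj, a)))
        return acc

    total_p = recurse(0, r, 0.0)
    return min(1.0, total_p)


def mean_difference_test(values_a, values_b) -> float:
    """Two-sided Welch t-test p-value for a difference in group means."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("each group needs at least 2 observations")
    if (len(a) == 2 and np.var(a) == 0.0) or (len(b) == 2 and np.var(b) == 0.0):
        raise DegenerateDataError("a group of size 2 has zero variance (degenerate)")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 1.0
        raise DegenerateDataError("both groups have zero variance (degenerate)")
    return float(ttest_ind(a, b, equal_var=False).pvalue)
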