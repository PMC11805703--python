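"""Full-information maximum likelihood for multivariate normal data with missingness.

Twin likelihoods evaluate the same mean vector / covariance matrix against many
rows that share a handful of missingness patterns.  Rows are therefore compressed
once into per-pattern sufficient statistics (count, sum, sum of outer products),
after which each -2LL evaluation costs O(#patterns * p^3) regardless of sample
size.  With no missing data there is a single pattern and the value coincides
with the complete-data Gaussian -2LL exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PatternStats:
    """Sufficient statistics for one observed-variable pattern."""

    idx: np.ndarray        # observed column indices, sorted
    n: int                 # number of rows with this pattern
    total: np.ndarray      # sum of observed rows, shape (p,)
    outer: np.ndarray      # sum of outer products x x^T, shape (p, p)


def compress(data: np.ndarray) -> list[PatternStats]:
    """Group rows of an (n, k) array (NaN = missing) by missingness pattern.

    Rows with no observed entries are dropped: they carry no likelihood.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-dimensional (rows x variables)")
    observed = ~np.isnan(data)
    out: list[PatternStats] = []
    # encode each row's pattern as bits for grouping
    codes = observed @ (1 << np.arange(data.shape[1]))
    for code in np.unique(codes):
        if code == 0:
            continue
        rows = data[codes == code]
        idx = np.flatnonzero(observed[codes == code][0])
        x = rows[:, idx]
        out.append(
            PatternStats(idx=idx, n=x.shape[0], total=x.sum(axis=0), outer=x.T @ x)
        )
    return out


def neg2ll(patterns: list[PatternStats], mean: np.ndarray, cov: np.ndarray) -> float:
    """-2 log likelihood of N(mean, cov) over compressed patterns.

    Returns +inf for covariance matrices that are not positive definite on an
    observed sub-block, so optimizers treat them as infeasible.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    total = 0.0
    for p in patterns:
        m = mean[p.idx]
        s = cov[np.ix_(p.idx, p.idx)]
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0 or not np.isfinite(logdet):
            return np.inf
        try:
            sinv = np.linalg.inv(s)
        except np.linalg.LinAlgError:
            return np.inf
        # sum_i (x_i - m)' S^-1 (x_i - m) via the pattern's moment matrices
        centered = (
            p.outer
            - np.outer(p.total, m)
            - np.outer(m, p.total)
            + p.n * np.outer(m, m)
        )
        total += p.n * (len(p.idx) * _LOG_2PI + logdet) + float(np.sum(sinv * centered))
    return total


def n_observations(patterns: list[PatternStats]) -> int:
    """Total scalar observations (for saturated degrees of freedom)."""
    return int(sum(p.n * len(p.idx) for p in patterns))


def pattern_counts(patterns: list[PatternStats]) -> dict[tuple[int, ...], int]:
    return {tuple(int(i) for i in p.idx): p.n for p in patterns}
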