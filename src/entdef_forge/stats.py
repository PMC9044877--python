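"""Shared statistical primitives.

- Benjamini-Hochberg FDR (wraps statsmodels).
- Paired Wilcoxon signed-rank test: exact null distribution (dynamic
  programming over doubled mid-ranks) for <= 25 non-zero pairs with Pratt
  handling of zero differences, normal approximation with tie correction
  above.
- Rank-based inverse normal transform (Blom offset 3/8).
- Harmonic-mean p-value combination.
- Firth-penalized logistic regression (fallback under separation).
- Natural cubic spline basis (for the locus-length adjustment).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import expit
from statsmodels.stats.multitest import multipletests


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _exact_signed_rank_cdf(ranks2: np.ndarray) -> tuple[np.ndarray, int]:
    """Distribution of W+ (on doubled ranks, so sums are integers) over all
    2^n equiprobable sign assignments, via dynamic programming.

    Returns (counts, total) where counts[s] = number of assignments with
    doubled rank-sum s.
    """
    max_sum = int(ranks2.sum())
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_sum + 1 - r]
        counts = counts + shifted
    return counts, 2 ** len(ranks2)


def wilcoxon_signed_rank(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    exact_limit: int = 25,
) -> tuple[float, float]:
    """Two-sided paired signed-rank test of x vs y.

    Zero differences are handled by Pratt's method: they take part in the
    ranking of |d| and are then discarded.  Ties get mid-ranks.  The exact
    permutation distribution is used when the number of non-zero pairs is
    <= exact_limit; otherwise the normal approximation with tie and zero
    corrections.

    Returns (W_plus, p).  All-zero differences give p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size == 0:
        raise ValueError("no pairs")
    ranks = sps.rankdata(np.abs(d))  # zeros included (Pratt)
    nonzero = d != 0
    n = int(nonzero.sum())
    if n == 0:
        return 0.0, 1.0
    r_nz = ranks[nonzero]
    w_plus = float(r_nz[d[nonzero] > 0].sum())
    if n <= exact_limit:
        ranks2 = np.round(r_nz * 2).astype(int)
        counts, total = _exact_signed_rank_cdf(ranks2)
        w2 = int(round(w_plus * 2))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, float(p)
    # normal approximation, Pratt zero correction + tie correction
    n_all = d.size
    n_zero = n_all - n
    mean = (n_all * (n_all + 1) - n_zero * (n_zero + 1)) / 4.0
    var = (n_all * (n_all + 1) * (2 * n_all + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
    _, tie_counts = np.unique(ranks[nonzero], return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return w_plus, 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# rank-based inverse normal transform
# ---------------------------------------------------------------------------


def rank_inverse_normal(values: np.ndarray | list[float], offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom-style INT: Phi^-1((rank - c) / (n + 1 - 2c)) with mid-ranks for ties.

    All-identical inputs map to all-zero scores.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.all(values == values[0]):
        return np.zeros(n)
    ranks = sps.rankdata(values)
    return sps.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))


def harmonic_mean_p(pvalues: np.ndarray | list[float]) -> float:
    """Unweighted harmonic-mean combined p-value: n / sum(1/p_i)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(p.size / np.sum(1.0 / p))


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Logistic regression with Jeffreys-prior penalty (Firth's correction).

    Returns (beta, se).  Used as the fallback when ordinary ML separates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        XtW = X.T * w
        fisher = XtW @ X
        try:
            fisher_inv = np.linalg.inv(fisher)
        except np.linalg.LinAlgError:
            fisher_inv = np.linalg.pinv(fisher)
        # hat-diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], fisher_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = fisher_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    se = np.sqrt(np.diag(np.linalg.pinv((X.T * (expit(X @ beta) * (1 - expit(X @ beta)))) @ X)))
    return beta, se


# ---------------------------------------------------------------------------
# natural cubic spline basis
# ---------------------------------------------------------------------------


def natural_cubic_basis(x: np.ndarray, df: int = 5) -> np.ndarray:
    """Natural cubic regression spline basis with df columns (no intercept).

    Knots at quantiles of x; linear beyond the boundary knots.  Degenerate
    (near-constant) inputs fall back to a single centred linear column padded
    with zeros.
    """
    x = np.asarray(x, dtype=float)
    if df < 3:
        raise ValueError("spline df must be >= 3")
    knots = np.quantile(x, np.linspace(0, 1, df + 1))
    knots = np.unique(knots)
    if knots.size < 3:
        out = np.zeros((x.size, df))
        out[:, 0] = x - x.mean()
        return out
    K = knots.size

    def d(j):
        num = np.maximum(x - knots[j], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[j])

    cols = [x]
    dK1 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK1)
    basis = np.column_stack(cols)
    if basis.shape[1] < df:
        basis = np.hstack([basis, np.zeros((x.size, df - basis.shape[1]))])
    return basis[:, :df]
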