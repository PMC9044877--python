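"""Gene-set enrichment over an assignment profile.

Methods:

  nb_score  - negative-binomial regression of per-gene peak counts on set
              membership with a locus-length adjustment; one-degree score
              test of the membership coefficient computed from the null
              (intercept + length) fit only.  Fast: the null model is fit
              once per profile and every term costs a few matrix products.
  nb_lrt    - the same regression tested by likelihood ratio (chi-square,
              1 df), refitting the alternative model per term with the
              dispersion held at its null estimate.
  fisher    - two-sided Fisher's exact test on has_peak x membership.
  binomial  - GREAT-style binomial test: k peaks in set loci out of n
              assigned, against p0 = set locus bp / total locus bp,
              one-sided upper; depletion flagged when k/n < p0.

The NB dispersion (theta = 1/alpha) is estimated once per profile on the
null model by profile maximum likelihood and reused across terms.
Counts are modeled as log mu = b0 + b1 * membership + f(log10 length),
f a natural cubic spline (df=5) by default.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .locus import AssignmentProfile
from .ontology import GeneSetCollection
from .stats import bh_fdr, natural_cubic_basis

METHODS = ("nb_score", "nb_lrt", "fisher", "binomial")
LENGTH_ADJUSTMENTS = ("none", "linear_log_length", "spline_log_length")


@dataclasses.dataclass
class GSEModelSpec:
    method: str = "nb_score"
    length_adjustment: str = "spline_log_length"
    spline_df: int = 5
    dispersion: Optional[float] = None  # NB theta; None = estimate from the data
    weight_column: Optional[str] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown GSE method {self.method!r}")
        if self.length_adjustment not in LENGTH_ADJUSTMENTS:
            raise ValueError(f"unknown length adjustment {self.length_adjustment!r}")
        if self.length_adjustment == "spline_log_length" and self.spline_df < 3:
            raise ValueError("spline df must be >= 3")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion theta must be positive")


@dataclasses.dataclass
class GSEResult:
    table: pd.DataFrame  # term_id, n_set_genes, statistic, direction, p_value, fdr
    method: str
    theta: Optional[float] = None
    skipped: dict[str, str] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def pvalues(self) -> pd.Series:
        return self.table.set_index("term_id")["p_value"]

    def significant_enriched(self, alpha: float = 0.05) -> set[str]:
        t = self.table
        return set(t.loc[(t.fdr < alpha) & (t.direction == "enriched"), "term_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# negative-binomial machinery
# ---------------------------------------------------------------------------


def _design_matrix(profile: AssignmentProfile, spec: GSEModelSpec) -> np.ndarray:
    n = len(profile.genes)
    loglen = np.log10(profile.genes["locus_length"].to_numpy(dtype=float))
    if spec.length_adjustment == "none":
        return np.ones((n, 1))
    if spec.length_adjustment == "linear_log_length":
        basis = (loglen - loglen.mean())[:, None]
    else:
        basis = natural_cubic_basis(loglen, df=spec.spline_df)
        basis = basis - basis.mean(axis=0)
    # constant lengths make the basis degenerate; keep only informative columns
    basis = basis[:, basis.std(axis=0) > 1e-12]
    return np.column_stack([np.ones(n), basis])


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (alpha = 1/theta); alpha -> 0 recovers Poisson."""
    if alpha < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _fit_null(y: np.ndarray, X: np.ndarray, theta: Optional[float]):
    """Null GLM fit with profile-ML dispersion.

    Returns (mu, alpha, llf, params).  alpha == 0 denotes the Poisson
    fallback (theta = infinity).
    """
    if theta is not None:
        alpha = 1.0 / theta
        res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        return res.mu, alpha, _nb_loglik(y, res.mu, alpha), res.params

    try:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    except Exception:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(method="lbfgs")
    mu = res.mu
    alpha = 0.0
    for _ in range(30):
        opt = minimize_scalar(
            lambda la: -_nb_loglik(y, mu, np.exp(la)), bounds=(-12, 6), method="bounded"
        )
        alpha_new = float(np.exp(opt.x))
        if _nb_loglik(y, mu, alpha_new) <= _nb_loglik(y, mu, 0.0) + 1e-9:
            alpha_new = 0.0  # Poisson at least as good: no overdispersion
        if alpha_new == 0.0:
            alpha = 0.0
            break
        res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha_new)).fit(
            start_params=res.params
        )
        mu = res.mu
        if alpha > 0 and abs(np.log(alpha_new) - np.log(alpha)) < 1e-6:
            alpha = alpha_new
            break
        alpha = alpha_new
    if alpha == 0.0:
        warnings.warn("no overdispersion detected; falling back to Poisson (theta = inf)")
    return mu, alpha, _nb_loglik(y, mu, alpha), res.params


def _score_tests(
    y: np.ndarray, X: np.ndarray, mu: np.ndarray, alpha: float, M: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-degree GLM score tests for each column of M added to X.

    Log link; Var = mu + alpha mu^2; working weight W = mu / (1 + alpha mu).
    Each candidate column is residualized against X in the W-metric, then
    z = U / sqrt(V) with U = x~' (y - mu)/(1 + alpha mu), V = x~' W x~.
    """
    w = mu / (1.0 + alpha * mu)
    s = (y - mu) / (1.0 + alpha * mu)
    XtW = X.T * w
    try:
        A = np.linalg.solve(XtW @ X, XtW @ M)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(XtW @ X) @ (XtW @ M)
    M_res = M - X @ A
    U = M_res.T @ s
    V = np.einsum("ij,i,ij->j", M_res, w, M_res)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(V > 0, U / np.sqrt(np.maximum(V, 1e-300)), 0.0)
    return z, U


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------


def gse_test(
    profile: AssignmentProfile,
    sets: GeneSetCollection,
    spec: Optional[GSEModelSpec] = None,
    min_size: int = 15,
    max_size: int = 2000,
) -> GSEResult:
    """Test every term (size-filtered against the profile's gene universe)."""
    spec = spec or GSEModelSpec()
    universe = profile.gene_universe
    n_universe = len(universe)
    gene_index = {g: i for i, g in enumerate(profile.genes.index)}

    terms: list[str] = []
    skipped: dict[str, str] = {}
    memberships: list[np.ndarray] = []
    set_sizes: list[int] = []
    for term in sets.term_ids():
        genes_in = sets.genes(term) & universe
        k = len(genes_in)
        if k == 0:
            skipped[term] = "no genes in universe"
            continue
        if k == n_universe:
            skipped[term] = "all genes in universe"
            continue
        if not (min_size <= k <= max_size):
            skipped[term] = f"size {k} outside [{min_size}, {max_size}]"
            continue
        m = np.zeros(n_universe)
        m[[gene_index[g] for g in genes_in]] = 1.0
        terms.append(term)
        memberships.append(m)
        set_sizes.append(k)

    if not terms:
        return GSEResult(
            pd.DataFrame(columns=["term_id", "n_set_genes", "statistic", "direction",
                                  "p_value", "fdr"]),
            method=spec.method, skipped=skipped,
        )

    M = np.column_stack(memberships)
    y = profile.genes["peak_count"].to_numpy(dtype=float)

    if spec.method in ("nb_score", "nb_lrt"):
        X = _design_matrix(profile, spec)
        mu, alpha, llf0, params0 = _fit_null(y, X, spec.dispersion)
        theta = (1.0 / alpha) if alpha > 0 else float("inf")
        if spec.method == "nb_score":
            z, _ = _score_tests(y, X, mu, alpha, M)
            pvals = 2.0 * sps.norm.sf(np.abs(z))
            stats_ = z
            directions = np.where(z >= 0, "enriched", "depleted")
        else:
            family = (
                sm.families.NegativeBinomial(alpha=alpha) if alpha > 0 else sm.families.Poisson()
            )
            stats_ = np.empty(len(terms))
            pvals = np.empty(len(terms))
            directions = np.empty(len(terms), dtype=object)
            start = np.append(params0, 0.0)
            for j in range(M.shape[1]):
                Xa = np.column_stack([X, M[:, j]])
                try:
                    res = sm.GLM(y, Xa, family=family).fit(start_params=start)
                    llf1 = _nb_loglik(y, res.mu, alpha)
                    beta1 = res.params[-1]
                except Exception:
                    llf1, beta1 = llf0, 0.0
                lr = max(0.0, 2.0 * (llf1 - llf0))
                stats_[j] = np.sign(beta1) * np.sqrt(lr)
                pvals[j] = sps.chi2.sf(lr, 1) if lr > 0 else 1.0
                directions[j] = "enriched" if beta1 >= 0 else "depleted"
    elif spec.method == "fisher":
        theta = None
        has_peak = profile.genes["has_peak"].to_numpy(dtype=bool)
        stats_ = np.empty(len(terms))
        pvals = np.empty(len(terms))
        directions = np.empty(len(terms), dtype=object)
        for j in range(M.shape[1]):
            member = M[:, j].astype(bool)
            a = int(np.sum(has_peak & member))
            b = int(np.sum(has_peak & ~member))
            c = int(np.sum(~has_peak & member))
            d = int(np.sum(~has_peak & ~member))
            odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            stats_[j] = odds
            pvals[j] = p
            directions[j] = "enriched" if a * d >= b * c else "depleted"
    else:  # binomial (GREAT-style)
        theta = None
        n = profile.n_assigned_peaks
        if n == 0:
            raise ValueError("no assigned peaks; binomial test undefined")
        total_bp_ = float(sum(profile.locus_bp.values()))
        hits_by_gene = profile.hits.groupby("gene_id")["peak_idx"].apply(set)
        stats_ = np.empty(len(terms))
        pvals = np.empty(len(terms))
        directions = np.empty(len(terms), dtype=object)
        gene_list = list(profile.genes.index)
        for j, term in enumerate(terms):
            member_genes = [g for g, m in zip(gene_list, M[:, j]) if m]
            peak_ids: set[int] = set()
            for g in member_genes:
                peak_ids |= hits_by_gene.get(g, set())
            k = len(peak_ids)
            p0 = sum(profile.locus_bp[g] for g in member_genes) / total_bp_
            pvals[j] = sps.binomtest(k, n, p0, alternative="greater").pvalue
            stats_[j] = k
            directions[j] = "enriched" if (k / n) >= p0 else "depleted"

    table = pd.DataFrame(
        {
            "term_id": terms,
            "n_set_genes": set_sizes,
            "statistic": stats_,
            "direction": directions,
            "p_value": np.clip(pvals, np.finfo(float).tiny, 1.0),
        }
    )
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    return GSEResult(table, method=spec.method, theta=theta, skipped=skipped)
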