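"""Interceding-gene analysis.

For each enhancer-target link, the query span runs from the outermost
coordinates of the enhancer and the target's gene body; interceding genes
are the other genes whose bodies overlap that span by >= 1 bp.  Genes are
scored by their mean interceding count over their links, transformed by a
rank-based inverse normal transform, and tested per term with logistic
regression (membership ~ score).  Results from several definitions combine
by harmonic-mean p-values, followed by a DAG redundancy filter.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .build import EnTDef
from .core import GeneRegistry
from .ontology import GeneSetCollection
from .stats import bh_fdr, firth_logistic, harmonic_mean_p, rank_inverse_normal


@dataclasses.dataclass
class IntercedingProfile:
    """Per-gene mean interceding count and its inverse-normal score.

    Only genes with >= 1 non-fallback link are included.
    """

    table: pd.DataFrame  # index gene_id; columns mean_interceding, int_score

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def mean_interceding_per_gene(entdef: EnTDef, registry: GeneRegistry) -> IntercedingProfile:
    """Mean number of interceding genes per target gene (scores unset until
    `set_int_scores`).  Fallback records are excluded: nearest-TSS territory
    says nothing about looping over genes."""
    df = entdef.records[~entdef.records["fallback"]]
    if df.empty:
        raise ValueError("definition has no non-fallback links")
    bodies: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in registry.chroms():
        genes = registry.by_chrom(chrom)
        starts = np.sort(np.array([g.body.start for g in genes]))
        ends = np.sort(np.array([g.body.end for g in genes]))
        bodies[chrom] = (starts, ends)

    counts: dict[str, list[int]] = {}
    for chrom, start, end, gid in zip(df.chrom, df.start, df.end, df.gene_id):
        target = registry.get(gid)
        q_start = min(int(start), target.body.start)
        q_end = max(int(end), target.body.end)
        starts, ends = bodies[chrom]
        # bodies overlapping [q_start, q_end): start < q_end and end > q_start;
        # the two non-overlap conditions are disjoint, so counting works on
        # independently sorted starts and ends
        n_overlap = (
            int(np.searchsorted(starts, q_end, side="left"))
            - int(np.searchsorted(ends, q_start, side="right"))
        )
        # the target's own body always lies inside the span
        counts.setdefault(gid, []).append(max(0, n_overlap - 1))
    table = pd.DataFrame(
        {"mean_interceding": {g: float(np.mean(v)) for g, v in counts.items()}}
    )
    table.index.name = "gene_id"
    table["int_score"] = np.nan
    return IntercedingProfile(table.sort_index())


def set_int_scores(profile: IntercedingProfile) -> IntercedingProfile:
    """Fill int_score with the Blom rank-based inverse normal transform of
    mean_interceding (higher score = more interceding genes)."""
    profile.table["int_score"] = rank_inverse_normal(
        profile.table["mean_interceding"].to_numpy()
    )
    return profile


def logistic_enrichment(
    profile: IntercedingProfile,
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 1000,
) -> pd.DataFrame:
    """Per-term logistic regression membership ~ int_score (Wald, two-sided).

    The reported coefficient is the *negated* slope on int_score, so positive
    coefficients mark functions enriched among genes with FEWER interceding
    genes (matching the sign convention stated in the output metadata).
    Separation triggers a Firth-penalized refit, flagged in the output.
    Returns columns: term_id, n_genes, coef, direction, p_value, fdr, firth.
    """
    if profile.table["int_score"].isna().any():
        raise ValueError("int scores unset; call set_int_scores first")
    universe = frozenset(profile.table.index)
    scores = profile.table["int_score"].to_numpy()
    X = np.column_stack([np.ones(len(scores)), scores])
    gene_pos = {g: i for i, g in enumerate(profile.table.index)}
    rows = []
    for term in sets.term_ids():
        genes_in = sets.genes(term) & universe
        k = len(genes_in)
        if not (min_size <= k <= max_size) or k == len(universe):
            continue
        y = np.zeros(len(scores))
        y[[gene_pos[g] for g in genes_in]] = 1.0
        if np.all(scores == scores[0]):
            slope, p, used_firth = 0.0, 1.0, False
        else:
            used_firth = False
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error")
                    res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                if not np.all(np.isfinite(res.bse)) or res.bse[1] > 1e3:
                    raise ValueError("separation suspected")
                slope, se = float(res.params[1]), float(res.bse[1])
            except Exception:
                beta, bse = firth_logistic(X, y)
                slope, se = float(beta[1]), float(bse[1])
                used_firth = True
            from scipy.stats import norm

            p = float(2 * norm.sf(abs(slope / se))) if se > 0 else 1.0
        coef = -slope  # positive = fewer interceding genes
        rows.append(
            (term, k, coef, "fewer_interceding" if coef >= 0 else "more_interceding",
             min(1.0, max(p, np.finfo(float).tiny)), used_firth)
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "n_genes", "coef", "direction", "p_value", "firth"]
    )
    out["fdr"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out


@dataclasses.dataclass
class CombinedTermResult:
    table: pd.DataFrame  # term_id, direction, hm_p, hm_fdr, rank, kept_after_redundancy


def combine_and_filter(
    results: Sequence[pd.DataFrame],
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> CombinedTermResult:
    """Harmonic-mean combination across definitions plus redundancy filtering.

    hm_p(term) = n / sum(1/p_i); BH FDR over all terms; significant terms
    (hm_fdr < alpha) are ranked by hm_p ascending within each direction
    (majority vote of per-definition signs) and a term is filtered when any
    parent, child or sibling ranks higher in that direction's list.
    """
    if len(results) < 2:
        raise ValueError("need results from at least 2 definitions")
    term_sets = [set(r.term_id) for r in results]
    if any(s != term_sets[0] for s in term_sets[1:]):
        raise ValueError("all results must share the same term universe")
    terms = sorted(term_sets[0])
    p_by_term = {t: [] for t in terms}
    dir_votes = {t: 0 for t in terms}
    for r in results:
        idx = r.set_index("term_id")
        for t in terms:
            p_by_term[t].append(float(idx.loc[t, "p_value"]))
            dir_votes[t] += 1 if idx.loc[t, "direction"] == "fewer_interceding" else -1
    hm = {t: harmonic_mean_p(p_by_term[t]) for t in terms}
    fdr = dict(zip(terms, bh_fdr([hm[t] for t in terms])))
    direction = {
        t: ("fewer_interceding" if dir_votes[t] >= 0 else "more_interceding") for t in terms
    }

    rank: dict[str, int] = {}
    for d in ("fewer_interceding", "more_interceding"):
        sig = [t for t in terms if fdr[t] < alpha and direction[t] == d]
        for i, t in enumerate(sorted(sig, key=lambda t: (hm[t], t)), start=1):
            rank[t] = i
    kept = {}
    for t in terms:
        if t not in rank:
            kept[t] = False
            continue
        relatives = sets.parents(t) | sets.children(t) | sets.siblings(t)
        kept[t] = not any(
            r in rank and direction[r] == direction[t] and rank[r] < rank[t]
            for r in relatives
        )
    table = pd.DataFrame(
        {
            "term_id": terms,
            "direction": [direction[t] for t in terms],
            "hm_p": [hm[t] for t in terms],
            "hm_fdr": [fdr[t] for t in terms],
            "rank": [rank.get(t, np.nan) for t in terms],
            "kept_after_redundancy": [kept[t] for t in terms],
        }
    )
    return CombinedTermResult(table)
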