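"""F1-based evaluation and ranking of definitions against TF term annotations.

For each (definition, TF ChIP-seq peak set) pair: assign peaks, run gene-set
enrichment, compare the significantly enriched terms against the TF's
annotated terms (positives) and size-matched sampled negatives, and score by
precision/recall/F1.  Definitions are ranked by mean F1 across TFs; the top
set is cut where a paired signed-rank test against rank 1 first drops below
p < 0.01.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .build import EnTDef, EnTDefConfig
from .core import GeneRegistry, PeakSet
from .gse import GSEModelSpec, GSEResult, gse_test
from .locus import LocusDefinition, assign_peaks, build_locusdef
from .ontology import GeneSetCollection
from .stats import bh_fdr, wilcoxon_signed_rank

# ---------------------------------------------------------------------------
# TF annotations and negative sampling
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TFAnnotation:
    tf_id: str
    positive_terms: frozenset[str]
    scheme: str = "standard"
    assigned_terms: frozenset[str] = frozenset()  # the raw assignments


def build_positive_terms(
    tf_id: str,
    tf_terms: set[str],
    sets: GeneSetCollection,
    scheme: str = "standard",
    iea_only: Optional[set[str]] = None,
    min_size: int = 15,
    max_size: int = 2000,
    universe: Optional[frozenset[str]] = None,
) -> TFAnnotation:
    """Positive term set for a TF.

    standard: the lowest-level assigned terms (leaves within the assignment)
    plus all of their DAG ancestors.
    conservative_no_iea: terms flagged as IEA-only are removed first; the
    positives are the assigned leaves plus their parents and grandparents.

    The result is size-filtered to [min_size, max_size] genes (after
    intersecting with `universe` if given).
    """
    if scheme not in ("standard", "conservative_no_iea"):
        raise ValueError(f"unknown scheme {scheme!r}")
    missing = tf_terms - set(sets.terms)
    if missing:
        raise ValueError(f"TF {tf_id}: assigned terms absent from collection: {sorted(missing)}")
    assigned = set(tf_terms)
    if scheme == "conservative_no_iea":
        assigned -= set(iea_only or ())
    leaves = sets.leaves(within=assigned)
    positives: set[str] = set(leaves)
    if scheme == "standard":
        for leaf in leaves:
            positives |= sets.ancestors(leaf)
    else:
        for leaf in leaves:
            parents = sets.parents(leaf)
            positives |= parents
            for p in parents:
                positives |= sets.parents(p)
    positives = {
        t for t in positives if min_size <= sets.size(t, universe) <= max_size
    }
    if not positives:
        raise ValueError(f"TF {tf_id}: no positive terms remain after size filtering")
    return TFAnnotation(tf_id, frozenset(positives), scheme, frozenset(tf_terms))


@dataclasses.dataclass
class NegativeSamplingPlan:
    bin_size: int = 20
    n_repetitions: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        if self.bin_size < 1 or self.n_repetitions < 1:
            raise ValueError("bin_size and n_repetitions must be >= 1")

    def rng(self, tf_id: str, repetition: int) -> np.random.Generator:
        salt = zlib.crc32(tf_id.encode()) % (2**31)
        return np.random.default_rng([self.rng_seed, salt, repetition])


def negative_pool(
    annotation: TFAnnotation,
    sets: GeneSetCollection,
    min_size: int = 15,
    max_size: int = 2000,
    universe: Optional[frozenset[str]] = None,
) -> list[str]:
    """Terms eligible as sampled negatives for a TF.

    standard: everything not positive, excluding offspring of the assigned
    terms and their siblings.
    conservative_no_iea: additionally excluding ancestors of positives,
    siblings of the positives' ancestors, and offspring of positives.
    """
    excluded: set[str] = set(annotation.positive_terms) | set(annotation.assigned_terms)
    for t in annotation.assigned_terms:
        excluded |= sets.offspring(t)
        excluded |= sets.siblings(t)
    if annotation.scheme == "conservative_no_iea":
        for t in annotation.positive_terms:
            ancestors = sets.ancestors(t)
            excluded |= ancestors
            excluded |= sets.offspring(t)
            for a in ancestors:
                excluded |= sets.siblings(a)
    pool = [
        t
        for t in sets.term_ids()
        if t not in excluded and min_size <= sets.size(t, universe) <= max_size
    ]
    return pool


def sample_negative_terms(
    annotation: TFAnnotation,
    sets: GeneSetCollection,
    plan: NegativeSamplingPlan,
    repetition: int,
    min_size: int = 15,
    max_size: int = 2000,
    universe: Optional[frozenset[str]] = None,
) -> list[str]:
    """One size-matched negative per positive term, without replacement.

    Sizes are binned into fixed half-open windows of width `bin_size`
    ([0,20), [20,40), ...); an empty bin falls back to the nearest non-empty
    one.  Deterministic given (rng_seed, tf_id, repetition).
    """
    pool = negative_pool(annotation, sets, min_size, max_size, universe)
    positives = sorted(annotation.positive_terms)
    if len(pool) < len(positives):
        raise ValueError(
            f"TF {annotation.tf_id}: negative pool ({len(pool)}) smaller than "
            f"#positives ({len(positives)})"
        )
    rng = plan.rng(annotation.tf_id, repetition)
    by_bin: dict[int, list[str]] = {}
    for t in pool:
        by_bin.setdefault(sets.size(t, universe) // plan.bin_size, []).append(t)
    chosen: list[str] = []
    taken: set[str] = set()
    for pos in positives:
        want = sets.size(pos, universe) // plan.bin_size
        candidates_by_dist = sorted(by_bin, key=lambda b: (abs(b - want), b))
        pick = None
        for b in candidates_by_dist:
            avail = [t for t in by_bin[b] if t not in taken]
            if avail:
                pick = avail[int(rng.integers(len(avail)))]
                break
        if pick is None:  # pool exhausted (cannot happen given the size check)
            raise ValueError("negative pool exhausted")
        chosen.append(pick)
        taken.add(pick)
    return chosen


# ---------------------------------------------------------------------------
# confusion counts and F1
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ConfusionRow:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def confusion_and_f1(
    gse: GSEResult,
    annotation: TFAnnotation,
    negatives: Sequence[str],
    alpha: float = 0.05,
) -> ConfusionRow:
    """Call each positive/negative term significant-enriched (FDR < alpha AND
    direction enriched) or not; terms absent from the GSE table count as
    not significant.  Depleted positives count as FN regardless of FDR."""
    sig = gse.significant_enriched(alpha)
    tp = sum(1 for t in annotation.positive_terms if t in sig)
    fn = len(annotation.positive_terms) - tp
    fp = sum(1 for t in negatives if t in sig)
    tn = len(negatives) - fp
    return ConfusionRow(TP=tp, FP=fp, TN=tn, FN=fn)


# ---------------------------------------------------------------------------
# full evaluation over definitions
# ---------------------------------------------------------------------------

Definition = Union[EnTDef, LocusDefinition]


@dataclasses.dataclass
class EvaluationResult:
    rows: pd.DataFrame  # definition, tf, peakset, repetition, TP..FN, precision, recall, f1

    def per_definition_tf(self) -> pd.DataFrame:
        """Mean F1 per (definition, TF): reps averaged first, then peak sets."""
        by_rep = self.rows.groupby(["definition", "tf", "peakset"], sort=True)["f1"].mean()
        return by_rep.groupby(["definition", "tf"]).mean().reset_index()

    def f1_matrix(self) -> pd.DataFrame:
        """definition x tf matrix of mean F1."""
        return self.per_definition_tf().pivot(index="definition", columns="tf", values="f1")

    def mean_f1(self) -> pd.Series:
        """Mean F1 per definition (descending)."""
        return self.f1_matrix().mean(axis=1).sort_values(ascending=False)


def _as_locusdef(definition: Definition, registry: GeneRegistry, window: int) -> LocusDefinition:
    if isinstance(definition, LocusDefinition):
        return definition
    return build_locusdef("entdef", registry, window, entdef=definition)


def evaluate_definitions(
    definitions: Sequence[Definition],
    peaksets: Sequence[PeakSet],
    sets: GeneSetCollection,
    annotations: dict[str, TFAnnotation],
    registry: GeneRegistry,
    spec: Optional[GSEModelSpec] = None,
    plan: Optional[NegativeSamplingPlan] = None,
    min_size: int = 15,
    max_size: int = 2000,
    alpha: float = 0.05,
    promoter_window: int = 5000,
) -> EvaluationResult:
    """The core evaluation loop: assign -> GSE -> repeated size-matched
    negative sampling -> confusion/F1 rows.

    Per-peak-set failures are recorded and skipped, not propagated.
    """
    spec = spec or GSEModelSpec()
    plan = plan or NegativeSamplingPlan()
    rows = []
    for definition in definitions:
        locdef = _as_locusdef(definition, registry, promoter_window)
        for ps in peaksets:
            tf = ps.tf or ps.name
            if tf not in annotations:
                raise ValueError(f"peak set {ps.name!r}: no annotation for TF {tf!r}")
            ann = annotations[tf]
            try:
                profile = assign_peaks(locdef, ps)
                gse = gse_test(profile, sets, spec, min_size, max_size)
                universe = profile.gene_universe
                for rep in range(plan.n_repetitions):
                    negatives = sample_negative_terms(
                        ann, sets, plan, rep, min_size, max_size, universe
                    )
                    c = confusion_and_f1(gse, ann, negatives, alpha)
                    rows.append(
                        (locdef.name, tf, ps.name, rep, c.TP, c.FP, c.TN, c.FN,
                         c.precision, c.recall, c.f1)
                    )
            except ValueError as exc:
                warnings.warn(f"skipping {locdef.name!r} x {ps.name!r}: {exc}")
    return EvaluationResult(
        pd.DataFrame(
            rows,
            columns=["definition", "tf", "peakset", "repetition", "TP", "FP", "TN",
                     "FN", "precision", "recall", "f1"],
        )
    )


# ---------------------------------------------------------------------------
# ranking, top-set selection and contrasts
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RankingOutcome:
    order: list[str]  # definitions by mean F1, descending
    mean_f1: pd.Series
    top_set_cutoff_rank: Optional[int]  # 1-based rank of the first significantly worse definition
    top_set: list[str]
    pvalues_vs_rank1: dict[str, float]


def select_top_set(
    results: EvaluationResult,
    order: Optional[Sequence[str]] = None,
    p_threshold: float = 0.01,
) -> RankingOutcome:
    """Walk ranks 2, 3, ... comparing per-TF F1 vectors against rank 1 with a
    paired two-sided signed-rank test; the first rank with p < p_threshold is
    the cutoff and the top set is everything strictly above it.

    An explicit `order` must be descending by mean F1 (validated)."""
    matrix = results.f1_matrix()
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 definitions")
    mean_f1 = matrix.mean(axis=1).sort_values(ascending=False, kind="mergesort")
    if order is not None:
        order = list(order)
        means = [float(mean_f1.loc[n]) for n in order]
        if any(a < b - 1e-12 for a, b in zip(means[:-1], means[1:])):
            raise ValueError("order must be descending by mean F1")
        mean_f1 = mean_f1.loc[order]
    order = list(mean_f1.index)
    best = matrix.loc[order[0]]
    pvals: dict[str, float] = {}
    cutoff: Optional[int] = None
    for rank, name in enumerate(order[1:], start=2):
        _, p = wilcoxon_signed_rank(best.to_numpy(), matrix.loc[name].to_numpy())
        pvals[name] = p
        if cutoff is None and p < p_threshold:
            cutoff = rank
    top_set = order if cutoff is None else order[: cutoff - 1]
    return RankingOutcome(order, mean_f1, cutoff, top_set, pvals)


def compare_to_baseline(
    results: EvaluationResult, baseline_id: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired signed-rank test of every definition against a baseline across
    TFs; BH FDR; better = FDR < alpha and positive mean difference."""
    matrix = results.f1_matrix()
    if baseline_id not in matrix.index:
        raise ValueError(f"baseline {baseline_id!r} not evaluated")
    base = matrix.loc[baseline_id]
    names = [n for n in matrix.index if n != baseline_id]
    pvals, deltas = [], []
    for name in names:
        row = matrix.loc[name]
        if row.isna().any() or base.isna().any():
            raise ValueError("TF mismatch between definition and baseline")
        _, p = wilcoxon_signed_rank(row.to_numpy(), base.to_numpy())
        pvals.append(p)
        deltas.append(float((row - base).mean()))
    fdr = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "definition": names,
            "p": pvals,
            "fdr": fdr,
            "mean_diff": deltas,
            "better": [(f < alpha) and (d > 0) for f, d in zip(fdr, deltas)],
        }
    )


def method_contribution(
    results: EvaluationResult,
    configs: dict[str, EnTDefConfig],
    method: str,
    p_threshold: float = 0.05,
) -> dict:
    """Paired contrast isolating one method label.

    Configs are paired when their feature sets differ exactly by {method};
    for each pair a paired signed-rank test across TFs is run, and
    percent_improved is the share of pairs where the with-method member is
    significantly higher."""
    matrix = results.f1_matrix()
    by_features: dict[frozenset, str] = {}
    for name, cfg in configs.items():
        if name in matrix.index:
            by_features[cfg.feature_set()] = name
    pairs = []
    for feats, with_name in by_features.items():
        if method in feats:
            without = by_features.get(feats - {method})
            if without is not None:
                pairs.append((with_name, without))
    if not pairs:
        raise ValueError(f"no config pairs differ exactly by {method!r}")
    n_improved = 0
    for with_name, without_name in pairs:
        a = matrix.loc[with_name].to_numpy()
        b = matrix.loc[without_name].to_numpy()
        _, p = wilcoxon_signed_rank(a, b)
        if p < p_threshold and (a - b).mean() > 0:
            n_improved += 1
    return {"percent_improved": 100.0 * n_improved / len(pairs), "n_pairs": len(pairs)}


# ---------------------------------------------------------------------------
# ROC / PR over cutoffs and regulome-vs-expression concordance
# ---------------------------------------------------------------------------


def roc_pr_over_cutoffs(
    gse: GSEResult, annotation: TFAnnotation, negatives: Sequence[str]
) -> dict[str, float]:
    """AUROC (trapezoidal) and AUPRC (step interpolation) sweeping thresholds
    over the observed GSE p-values, positives vs sampled negatives."""
    pvals = gse.pvalues()
    labels, scores = [], []
    for t in sorted(annotation.positive_terms):
        labels.append(1)
        scores.append(-float(pvals.get(t, 1.0)))
    for t in negatives:
        labels.append(0)
        scores.append(-float(pvals.get(t, 1.0)))
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("need both positive and negative labels")
    scores = np.asarray(scores)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
    }


def concordance_auc(
    regulome_gse: GSEResult,
    expression_gse: GSEResult,
    sets: GeneSetCollection,
    n_top: int = 100,
    n_neg: int = 100,
    n_samplings: int = 100,
    seed: int = 0,
    bin_size: int = 20,
    universe: Optional[frozenset[str]] = None,
) -> float:
    """Mean AUROC of the regulome result recovering the expression result.

    True positives: the top n_top expression terms with q < 0.05 (fewer if
    fewer exist).  Each sampling draws n_neg size-matched insignificant
    expression terms (p > 0.5) as true negatives; the score is the regulome
    significance (FDR-based); AUROC is averaged over samplings.
    """
    expr = expression_gse.table
    sig = expr[expr.fdr < 0.05].sort_values("p_value")
    tps = list(sig.term_id.head(n_top))
    if len(tps) < 2:
        raise ValueError("fewer than 2 significant expression terms")
    pool = [t for t in expr.loc[expr.p_value > 0.5, "term_id"] if t not in set(tps)]
    if not pool:
        raise ValueError("empty true-negative pool")
    by_bin: dict[int, list[str]] = {}
    for t in pool:
        by_bin.setdefault(sets.size(t, universe) // bin_size, []).append(t)
    reg_fdr = regulome_gse.table.set_index("term_id")["fdr"]
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_samplings):
        taken: set[str] = set()
        tns: list[str] = []
        for pos in tps[:n_neg]:
            want = sets.size(pos, universe) // bin_size
            for b in sorted(by_bin, key=lambda b: (abs(b - want), b)):
                avail = [t for t in by_bin[b] if t not in taken]
                if avail:
                    pick = avail[int(rng.integers(len(avail)))]
                    tns.append(pick)
                    taken.add(pick)
                    break
        labels = np.array([1] * len(tps) + [0] * len(tns))
        scores = np.array([-float(reg_fdr.get(t, 1.0)) for t in tps + tns])
        aucs.append(roc_auc_score(labels, scores))
    return float(np.mean(aucs))
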