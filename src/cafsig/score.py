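"""The signed z-score risk statistic, tertile cutoff, pooling, collagen score.

The recurrence score of a sample is the sum of the per-dataset z-scores of
the classifier genes, each weighted +1 (risk) or -1 (protective) — no
fitted coefficients, every gene carries the same biological weight. The
high/low-risk cutoff is the third tertile (66.66th percentile) of the
training-set scores, applied unchanged to every validation cohort. Pooling
multiple datasets z-scores each dataset separately first, which removes
centre/platform location-scale bias. The collagen score (mean standardized
expression of COL1A1 and COL3A1) proxies stromal *quantity*, deliberately
orthogonal to what the classifier measures (stromal *state*).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .signature import Classifier
from .synthetic import Cohort, COLLAGEN_GENE_NAMES

__all__ = [
    "zscore_genes",
    "compute_score",
    "derive_cutoff",
    "classify",
    "pool_metacohort",
    "collagen_score",
    "filter_by_collagen",
    "score_cohort",
    "TERTILE_QUANTILE",
]

#: The 3rd-tertile quantile used for the published cutoff (percentile 66.66).
TERTILE_QUANTILE = 2.0 / 3.0


def zscore_genes(expression: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene to mean 0, sample SD 1 within the dataset.

    Zero-variance genes are standardized to all-zeros with a warning, so
    they contribute nothing to a downstream score instead of aborting the
    cohort.
    """
    if expression.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mu = expression.mean(axis=0)
    sd = expression.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        for g in expression.columns[zero]:
            warnings.warn(f"gene {g}: zero variance, z-scores set to 0")
        sd = sd.mask(zero, 1.0)
    z = (expression - mu) / sd
    return z.mask(pd.DataFrame(np.broadcast_to(zero.values, z.shape),
                               index=z.index, columns=z.columns), 0.0)


def compute_score(standardized: pd.DataFrame, classifier: Classifier) -> pd.Series:
    """Per-sample score S = sum_g coefficient(g) * z(g, sample)."""
    classifier.validate()
    missing = [g for g in classifier.gene_ids if g not in standardized.columns]
    if missing:
        raise KeyError(f"classifier genes missing from expression matrix: {missing}")
    score = pd.Series(0.0, index=standardized.index, name="score")
    for g, c in classifier.genes:
        score += c * standardized[g]
    return score


def derive_cutoff(training_scores, quantile: float = TERTILE_QUANTILE) -> float:
    """Tertile cutoff: the ``quantile`` point of the training scores.

    Linear interpolation between order statistics; the returned value is
    then applied unchanged to every validation cohort.
    """
    scores = np.asarray(training_scores, dtype=float)
    if scores.size < 3:
        raise ValueError(f"need at least 3 training scores, got {scores.size}")
    return float(np.quantile(scores, quantile, method="linear"))


def classify(scores, cutoff: float) -> pd.Series:
    """Dichotomize scores: strictly above the cutoff is high risk.

    A score exactly at the cutoff is low risk (deterministic tie rule).
    """
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    s = pd.Series(scores)
    return pd.Series(np.where(s > cutoff, "high", "low"), index=s.index,
                     name="risk_class")


def pool_metacohort(cohorts: list[Cohort]) -> Cohort:
    """Pool cohorts into a meta-cohort of per-dataset z-scores.

    Each dataset is z-scored separately (removing centre/hospital
    location-scale bias), genes are intersected, samples concatenated.
    Clinical columns are outer-joined; a ``dataset`` column records
    provenance. Duplicated sample ids across cohorts are an error.
    """
    if len(cohorts) < 2:
        raise ValueError("pooling needs at least 2 cohorts")
    shared = None
    for c in cohorts:
        cols = set(c.expression.columns)
        shared = cols if shared is None else shared & cols
    if not shared:
        raise ValueError("cohorts share no genes")
    order = [g for g in cohorts[0].expression.columns if g in shared]

    all_ids: list = []
    z_parts, clin_parts = [], []
    for c in cohorts:
        dup = set(all_ids) & set(c.expression.index)
        if dup:
            raise ValueError(f"duplicated sample ids across cohorts: {sorted(dup)}")
        all_ids += list(c.expression.index)
        z_parts.append(zscore_genes(c.expression[order]))
        clin = c.clinical.copy()
        clin["dataset"] = c.dataset_id
        clin_parts.append(clin)

    expr = pd.concat(z_parts, axis=0)
    clinical = pd.concat(clin_parts, axis=0, join="outer")
    pooled = Cohort(expr, clinical.loc[expr.index], dataset_id="metacohort")
    pooled.validate()
    return pooled


def collagen_score(expression: pd.DataFrame,
                   genes=COLLAGEN_GENE_NAMES,
                   standardized: bool = True) -> pd.Series:
    """Per-sample collagen score: mean expression of the collagen genes.

    Standardized expression by default, for cross-platform comparability —
    the same convention as the classifier score; ``standardized=False``
    averages raw values.
    """
    missing = [g for g in genes if g not in expression.columns]
    if missing:
        raise KeyError(f"collagen genes missing from expression matrix: {missing}")
    block = expression[list(genes)]
    if standardized:
        block = zscore_genes(block)
    return block.mean(axis=1).rename("collagen_score")


def filter_by_collagen(cohort: Cohort, collagen: pd.Series,
                       percentile: float = 25.0) -> Cohort:
    """Drop samples below the given percentile of the collagen score.

    The retained set is the top ``ceil((1 - percentile/100) * n)`` samples
    by collagen score (ties at the threshold value are all retained), so a
    25th-percentile filter on 142 samples keeps 107.
    """
    if not 0.0 <= percentile < 100.0:
        raise ValueError(f"percentile must be in [0, 100), got {percentile}")
    if percentile == 0.0:
        return cohort.subset(cohort.expression.index)
    scores = collagen.loc[cohort.expression.index]
    n = len(scores)
    n_keep = int(np.ceil((1.0 - percentile / 100.0) * n))
    threshold = np.sort(scores.to_numpy())[::-1][n_keep - 1]
    keep = scores.index[scores >= threshold]
    return cohort.subset(keep)


def score_cohort(cohort: Cohort, classifier: Classifier,
                 cutoff: float | None = None,
                 with_collagen: bool = True,
                 already_standardized: bool = False) -> pd.DataFrame:
    """Convenience: z-score, score, classify and (optionally) collagen-score.

    Returns the per-sample risk profile with columns ``score``,
    ``risk_class`` and (when the collagen genes are present)
    ``collagen_score``. If ``cutoff`` is None the classifier's stored
    cutoff is used; if that is also None, the cohort's own tertile cutoff
    is derived (training-set usage). Pass ``already_standardized=True``
    for a pooled meta-cohort whose expression holds per-dataset z-scores —
    re-standardizing globally would partly undo the batch correction.
    """
    z = cohort.expression if already_standardized else zscore_genes(cohort.expression)
    score = compute_score(z, classifier)
    if cutoff is None:
        cutoff = classifier.cutoff
    if cutoff is None:
        cutoff = derive_cutoff(score)
    profile = pd.DataFrame({"score": score, "risk_class": classify(score, cutoff)})
    if with_collagen and all(g in cohort.expression.columns for g in COLLAGEN_GENE_NAMES):
        profile["collagen_score"] = collagen_score(cohort.expression)
    profile.attrs["cutoff"] = float(cutoff)
    return profile
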