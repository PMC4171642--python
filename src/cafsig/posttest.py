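"""Likelihood ratios and Bayes post-test recurrence probabilities.

A dichotomized risk classifier is a diagnostic test for the binary event
"recurrence". Its clinical value is summarized by the positive and
negative likelihood ratios, LR+ = sens/(1-spec) and LR- = (1-sens)/spec,
and by the post-test probabilities obtained by Bayes updating of the
pre-test (prevalence) odds:

    odds_post = odds_pre * LR,   p_post = odds_post / (1 + odds_post).

A high-risk call multiplies the odds by LR+; a low-risk call by LR-. The
spread between the two post-test probabilities is what the classifier adds
over staging alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "PostTestSummary",
    "confusion",
    "likelihood_ratios",
    "posttest_probability",
    "posttest_table",
    "prevalence_ci",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts; high-risk AND recurrent is a true positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def validate(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ZeroDivisionError("no positives; sensitivity undefined")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.fp + self.tn == 0:
            raise ZeroDivisionError("no negatives; specificity undefined")
        return self.tn / (self.fp + self.tn)


@dataclass
class PostTestSummary:
    """One row of a clinical-utility table."""

    label: str
    n: int
    prevalence: float
    prevalence_ci: tuple
    lr_pos: float
    lr_pos_ci: tuple
    lr_neg: float
    lr_neg_ci: tuple
    posttest_pos: float
    posttest_pos_ci: tuple
    posttest_neg: float
    posttest_neg_ci: tuple
    flags: list

    @property
    def difference(self) -> float:
        return self.posttest_pos - self.posttest_neg

    def to_row(self) -> dict:
        return {
            "stratum": self.label,
            "n": self.n,
            "prevalence": round(self.prevalence, 2),
            "lr_pos": round(self.lr_pos, 2),
            "lr_neg": round(self.lr_neg, 2),
            "posttest_pos": round(self.posttest_pos, 2),
            "posttest_neg": round(self.posttest_neg, 2),
            "difference": round(self.difference, 2),
            "posttest_pos_pct": int(round(self.posttest_pos * 100)),
            "posttest_neg_pct": int(round(self.posttest_neg * 100)),
            "flags": ";".join(self.flags),
        }


def confusion(risk_classes, recurrence) -> ConfusionCounts:
    """Tally the 2x2 table of risk class against recurrence.

    Missing values are not silently dropped: they raise, so the caller
    decides explicitly which samples enter the table.
    """
    rc = pd.Series(risk_classes)
    y = pd.Series(recurrence)
    if len(rc) != len(y):
        raise ValueError(f"length mismatch: {len(rc)} risk classes vs {len(y)} outcomes")
    if len(rc) == 0:
        raise ValueError("empty input")
    if rc.isna().any() or y.isna().any():
        raise ValueError("missing values in risk classes or recurrence")
    high = rc.to_numpy() == "high"
    rec = y.to_numpy().astype(int) == 1
    counts = ConfusionCounts(
        tp=int((high & rec).sum()),
        fp=int((high & ~rec).sum()),
        fn=int((~high & rec).sum()),
        tn=int((~high & ~rec).sum()),
    )
    counts.validate()
    return counts


def prevalence_ci(k: int, n: int, level: float = 0.95) -> tuple:
    """Clopper-Pearson exact interval for a binomial proportion."""
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def likelihood_ratios(counts: ConfusionCounts, level: float = 0.95
                      ) -> tuple[tuple, tuple]:
    """(LR+ with CI, LR- with CI), CIs by the log-transform SE method.

    Degenerate margins give infinite ratios with a one-sided CI and a
    warning rather than an error.
    """
    counts.validate()
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("sensitivity/specificity undefined: a margin is empty")
    sens, spec = counts.sensitivity, counts.specificity
    zq = stats.norm.ppf(0.5 + level / 2.0)

    def _log_ci(lr, var):
        if not np.isfinite(lr) or lr == 0.0 or not np.isfinite(var):
            return None
        half = zq * np.sqrt(var)
        return (float(lr * np.exp(-half)), float(lr * np.exp(half)))

    if spec == 1.0:
        warnings.warn("specificity = 1; LR+ infinite, one-sided CI")
        lr_pos, lr_pos_ci = np.inf, (np.nan, np.inf)
    else:
        lr_pos = sens / (1.0 - spec)
        # Simel et al. variance of log LR+
        var = ((1 - sens) / tp if tp else np.inf) + (spec / fp if fp else np.inf)
        lr_pos_ci = _log_ci(lr_pos, var) or (0.0, np.inf)

    if spec == 0.0:
        warnings.warn("specificity = 0; LR- infinite, one-sided CI")
        lr_neg, lr_neg_ci = np.inf, (np.nan, np.inf)
    else:
        lr_neg = (1.0 - sens) / spec
        var = (sens / fn if fn else np.inf) + ((1 - spec) / tn if tn else np.inf)
        lr_neg_ci = _log_ci(lr_neg, var) or (0.0, np.inf)

    return (float(lr_pos), lr_pos_ci), (float(lr_neg), lr_neg_ci)


def posttest_probability(prevalence: float, lr: float) -> float:
    """Bayes update: pre-test odds times the likelihood ratio."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be strictly inside (0, 1), got {prevalence}")
    if lr < 0:
        raise ValueError(f"likelihood ratio must be >= 0, got {lr}")
    if np.isinf(lr):
        return 1.0
    odds = prevalence / (1.0 - prevalence) * lr
    return odds / (1.0 + odds)


def _summary_from_counts(label: str, counts: ConfusionCounts) -> PostTestSummary:
    flags = []
    prev = counts.prevalence
    prev_ci = prevalence_ci(counts.tp + counts.fn, counts.total)
    (lr_pos, lr_pos_ci), (lr_neg, lr_neg_ci) = likelihood_ratios(counts)
    pp = posttest_probability(prev, lr_pos)
    pn = posttest_probability(prev, lr_neg)
    pp_ci = tuple(sorted(posttest_probability(prev, l) if np.isfinite(l) and l > 0
                         else (0.0 if l == 0 else 1.0) for l in lr_pos_ci))
    pn_ci = tuple(sorted(posttest_probability(prev, l) if np.isfinite(l) and l > 0
                         else (0.0 if l == 0 else 1.0) for l in lr_neg_ci))
    return PostTestSummary(label, counts.total, prev, prev_ci,
                           lr_pos, lr_pos_ci, lr_neg, lr_neg_ci,
                           pp, pp_ci, pn, pn_ci, flags)


def posttest_table(clinical: pd.DataFrame, profile: pd.DataFrame,
                   strata: list | None = None) -> list[PostTestSummary]:
    """One post-test summary per stage stratum ('all' first, then stages).

    A stratum missing one outcome class (or one risk class) yields a
    flagged summary with NaN statistics instead of crashing.
    """
    if strata is None:
        stages = sorted(clinical["stage"].dropna().unique().tolist())
        strata = ["all"] + stages
    rows = []
    for stratum in strata:
        ids = clinical.index if stratum == "all" else clinical.index[clinical["stage"] == stratum]
        label = "all stages" if stratum == "all" else f"stage {stratum}"
        rc = profile.loc[ids, "risk_class"]
        y = clinical.loc[ids, "recurrence"]
        try:
            counts = confusion(rc, y)
            if counts.tp + counts.fn == 0 or counts.fp + counts.tn == 0:
                raise ValueError("single outcome class in stratum")
            rows.append(_summary_from_counts(label, counts))
        except (ValueError, ZeroDivisionError) as exc:
            nan_ci = (np.nan, np.nan)
            rows.append(PostTestSummary(label, len(ids), np.nan, nan_ci,
                                        np.nan, nan_ci, np.nan, nan_ci,
                                        np.nan, nan_ci, np.nan, nan_ci,
                                        flags=[f"degenerate: {exc}"]))
    return rows
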