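"""Outcome evaluation: ROC/AUC, Kaplan-Meier, log-rank, Cox models.

Wraps lifelines for the survival machinery (product-limit estimator,
log-rank test, Efron-tie Cox fits) and adds what the evaluation of a
dichotomized risk score needs on top: DeLong confidence intervals for the
AUC, five-year rates off the KM step function, per-SD continuous hazard
ratios, collagen-stratified fits and the score-by-collagen interaction
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .synthetic import Cohort

__all__ = [
    "SurvivalFit",
    "CoxModelSpec",
    "roc_auc",
    "km_logrank",
    "cox_fit",
    "five_year_rate",
    "stratified_by_collagen",
    "collagen_interaction",
    "select_multivariate_covariates",
]


@dataclass
class SurvivalFit:
    """Kaplan-Meier curves per group plus the two-group comparison stats."""

    groups: list
    km_curves: dict  # group -> DataFrame(index=time, column 'survival')
    logrank_p: float
    hr: float | None
    hr_ci: tuple | None
    cox_p: float | None
    n_per_group: dict

    def validate(self) -> None:
        for g, curve in self.km_curves.items():
            s = curve["survival"].to_numpy()
            if s.size and (s[0] > 1.0 + 1e-12 or np.any(np.diff(s) > 1e-12)):
                raise ValueError(f"KM curve for {g!r} is not a non-increasing "
                                 "function starting at <= 1")
        if self.hr is not None:
            if self.hr <= 0:
                raise ValueError("hazard ratio must be positive")
            lo, hi = self.hr_ci
            if not lo <= self.hr <= hi:
                raise ValueError("hazard ratio outside its own CI")


@dataclass
class CoxModelSpec:
    """What to put in a proportional-hazards model."""

    outcome: str = "DFS"  # or "DSS"
    covariates: list = field(default_factory=list)  # clinical column names
    score_form: str = "dichotomized"  # or "continuous_per_sd"

    def validate(self, clinical: pd.DataFrame) -> None:
        if self.outcome not in ("DFS", "DSS"):
            raise ValueError(f"outcome must be 'DFS' or 'DSS', got {self.outcome!r}")
        if self.score_form not in ("dichotomized", "continuous_per_sd"):
            raise ValueError(f"unknown score_form {self.score_form!r}")
        missing = [c for c in self.covariates if c not in clinical.columns]
        if missing:
            raise ValueError(f"covariates absent from clinical table: {missing}")


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong confidence interval
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")

def roc_auc(scores, outcome, ci_level: float = 0.95) -> tuple[float, tuple]:
    """AUC (probability a random positive outscores a random negative,
    ties counted 1/2) with a DeLong confidence interval.

    The point estimate is the Mann-Whitney statistic; the variance comes
    from the DeLong structural-component decomposition. The CI is clipped
    to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two outcome classes, got {classes}")
    pos = s[y == classes.max()]
    neg = s[y == classes.min()]
    m, n = len(pos), len(neg)

    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components (per-observation placement values)
    v_pos = (all_r[:m] - pos_r) / n
    v_neg = 1.0 - (all_r[m:] - neg_r) / m
    var = np.var(v_pos, ddof=1) / m + np.var(v_neg, ddof=1) / n
    zq = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = zq * np.sqrt(max(var, 0.0))
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank + two-group Cox summary
# ---------------------------------------------------------------------------

def km_logrank(time, event, group) -> SurvivalFit:
    """Product-limit curves per group with a two-sided log-rank test.

    For exactly two groups, a univariate Cox model (Efron ties) of the
    group indicator supplies the hazard ratio of the second group label
    (sorted order) relative to the first, with its 95% CI and Wald p.
    """
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int),
                       "group": np.asarray(group)})
    labels = sorted(df["group"].unique().tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if set(labels) == {"high", "low"}:
        labels = ["low", "high"]  # report HR of high vs low, not alphabetical

    curves, n_per_group = {}, {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        curves[g] = pd.DataFrame(
            {"survival": kmf.survival_function_.iloc[:, 0].to_numpy()},
            index=kmf.survival_function_.index.to_numpy(),
        )
        n_per_group[g] = len(sub)

    degenerate = [g for g, sub in df.groupby("group") if sub["event"].sum() == 0]
    if degenerate:
        warnings.warn(f"group(s) {degenerate} are fully censored; "
                      "log-rank test degenerates")
    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
    logrank_p = float(lr.p_value)

    hr = hr_ci = cox_p = None
    events_per_group = df.groupby("group")["event"].sum()
    if len(labels) == 2 and (events_per_group > 0).all():
        design = pd.DataFrame({
            "time": df["time"],
            "event": df["event"],
            "g": (df["group"] == labels[1]).astype(float),
        })
        try:
            cph = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(design, duration_col="time", event_col="event")
        except ConvergenceError:
            cph = CoxPHFitter(penalizer=0.1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(design, duration_col="time", event_col="event")
            warnings.warn("monotone likelihood in two-group Cox fit; "
                          "penalized fallback used")
        hr = float(np.exp(cph.params_["g"]))
        ci = cph.confidence_intervals_.loc["g"]
        hr_ci = (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])))
        cox_p = float(cph.summary.loc["g", "p"])

    fit = SurvivalFit(labels, curves, logrank_p, hr, hr_ci, cox_p, n_per_group)
    fit.validate()
    return fit


def five_year_rate(fit: SurvivalFit, group, at_months: float = 60.0) -> float:
    """KM survival estimate at 60 months (last value carried forward)."""
    curve = fit.km_curves[group]
    times = curve.index.to_numpy(dtype=float)
    surv = curve["survival"].to_numpy()
    at_or_before = times <= at_months
    if not at_or_before.any():
        return 1.0  # step function starts at S(0) = 1
    if times.max() < at_months and not np.isclose(times.max(), at_months):
        warnings.warn(f"follow-up in group {group!r} ends at "
                      f"{times.max():.1f} < {at_months} months; "
                      "returning the last estimate")
    return float(surv[at_or_before][-1])


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

def _outcome_cols(outcome: str) -> tuple[str, str]:
    return ("dfs_time", "dfs_event") if outcome == "DFS" else ("dss_time", "dss_event")


def _encode(clinical: pd.DataFrame, covariates: list) -> pd.DataFrame:
    """Reference-coded covariate columns (first sorted level = reference)."""
    out = {}
    for c in covariates:
        col = clinical[c]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique().tolist())
            for lev in levels[1:]:
                out[f"{c}[{lev}]"] = (col == lev).astype(float)
        else:
            out[c] = col.astype(float)
    return pd.DataFrame(out, index=clinical.index)


def cox_fit(cohort: Cohort, profile: pd.DataFrame, spec: CoxModelSpec) -> pd.DataFrame:
    """Proportional-hazards fit of the risk score (plus covariates).

    ``dichotomized`` enters the high-vs-low risk class; ``continuous_per_sd``
    rescales the score by its cohort SD, so the HR is per +1 SD and
    invariant to affine rescaling of the raw score. Efron tie handling.
    Returns a table of (HR, CI low, CI high, p) per model term. Monotone
    likelihood falls back to a weakly penalized fit with a warning.
    """
    spec.validate(cohort.clinical)
    tcol, ecol = _outcome_cols(spec.outcome)
    clin = cohort.clinical
    if (clin[tcol] <= 0).any():
        raise ValueError(f"non-positive times in {tcol}")
    if clin[ecol].sum() == 0:
        raise ValueError("no events; Cox model undefined")

    if spec.score_form == "dichotomized":
        score_col = (profile["risk_class"].loc[clin.index] == "high").astype(float)
        term = "classifier[high]"
    else:
        s = profile["score"].loc[clin.index].astype(float)
        score_col = s / s.std(ddof=1)
        term = "classifier[per_sd]"

    design = _encode(clin, spec.covariates)
    design.insert(0, term, score_col)
    design["time"] = clin[tcol].astype(float)
    design["event"] = clin[ecol].astype(int)

    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError:
        warnings.warn("monotone likelihood / separation in Cox fit; "
                      "penalized fallback used")
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event")

    summary = cph.summary
    out = pd.DataFrame({
        "hr": np.exp(summary["coef"]),
        "ci_low": np.exp(summary["coef lower 95%"]),
        "ci_high": np.exp(summary["coef upper 95%"]),
        "p": summary["p"],
    })
    out.index.name = "term"
    return out


def select_multivariate_covariates(cohort: Cohort, candidates: list,
                                   outcome: str = "DFS",
                                   p_entry: float = 0.05) -> list:
    """Clinical covariates that enter the multivariate model.

    Reproduces the conventional model-building rule behind published
    multivariate tables: each candidate is fitted alone in a univariate
    Cox model and kept when its (first term's) Wald p is below
    ``p_entry``. The classifier itself is added by the caller.
    """
    tcol, ecol = _outcome_cols(outcome)
    clin = cohort.clinical
    kept = []
    for cov in candidates:
        if cov not in clin.columns:
            warnings.warn(f"covariate {cov!r} absent; skipped")
            continue
        design = _encode(clin, [cov])
        if design.shape[1] == 0 or design.nunique().max() < 2:
            continue
        design["time"] = clin[tcol].astype(float)
        design["event"] = clin[ecol].astype(int)
        try:
            cph = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(design, duration_col="time", event_col="event")
        except ConvergenceError:
            continue
        if float(cph.summary["p"].min()) < p_entry:
            kept.append(cov)
    return kept


# ---------------------------------------------------------------------------
# Collagen stratification and interaction
# ---------------------------------------------------------------------------

def stratified_by_collagen(cohort: Cohort, profile: pd.DataFrame,
                           split: str = "median") -> dict:
    """Risk-class survival fits within collagen strata.

    ``split`` is ``"median"`` (low/high) or ``"tertile"`` (three strata).
    Returns {stratum label: SurvivalFit of high vs low risk within it}.
    """
    if "collagen_score" not in profile:
        raise ValueError("profile lacks collagen scores")
    coll = profile["collagen_score"].loc[cohort.clinical.index]
    if split == "median":
        edges = [np.median(coll)]
        labels = ["low_collagen", "high_collagen"]
    elif split == "tertile":
        edges = list(np.quantile(coll, [1 / 3, 2 / 3]))
        labels = ["low_collagen", "mid_collagen", "high_collagen"]
    else:
        raise ValueError(f"split must be 'median' or 'tertile', got {split!r}")

    stratum = pd.Series(labels[0], index=coll.index)
    for lab, edge in zip(labels[1:], edges):
        stratum[coll > edge] = lab

    fits = {}
    clin = cohort.clinical
    for lab in labels:
        ids = stratum.index[stratum == lab]
        if len(ids) == 0:
            raise ValueError(f"empty collagen stratum {lab!r}")
        fits[lab] = km_logrank(clin.loc[ids, "dfs_time"],
                               clin.loc[ids, "dfs_event"],
                               profile.loc[ids, "risk_class"])
    return fits


def collagen_interaction(cohort: Cohort, profile: pd.DataFrame,
                         outcome: str = "DFS") -> dict:
    """Cox model with score, collagen score and their product.

    Returns the product term's coefficient, 95% CI and p — a positive
    coefficient means the score's hazard effect grows with stromal
    content. Covariates are centered before the product is formed (the
    product term's test is invariant to this, but the main effects stay
    interpretable). Severe collinearity is flagged.
    """
    tcol, ecol = _outcome_cols(outcome)
    clin = cohort.clinical
    s = profile["score"].loc[clin.index].astype(float)
    c = profile["collagen_score"].loc[clin.index].astype(float)
    sc, cc = s - s.mean(), c - c.mean()
    design = pd.DataFrame({
        "score": sc,
        "collagen": cc,
        "score_x_collagen": sc * cc,
        "time": clin[tcol].astype(float),
        "event": clin[ecol].astype(int),
    })
    corr = np.abs(np.corrcoef(design[["score", "collagen", "score_x_collagen"]],
                              rowvar=False))
    np.fill_diagonal(corr, 0.0)
    if corr.max() > 0.99:
        warnings.warn("near-collinear terms in interaction model "
                      f"(max |r| = {corr.max():.3f})")
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError:
        warnings.warn("interaction Cox fit did not converge; penalized fallback")
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event")
    row = cph.summary.loc["score_x_collagen"]
    return {
        "coef": float(row["coef"]),
        "ci": (float(row["coef lower 95%"]), float(row["coef upper 95%"])),
        "p": float(row["p"]),
    }
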