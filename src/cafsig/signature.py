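"""Differential-gene filtering and resampling-based stability selection.

The discovery algorithm mirrors how sparse prognostic signatures are built
from a candidate gene list: repeatedly split the cohort into stage-balanced
training/test sets, screen candidates by univariate logistic regression on
recurrence, fit an L1-penalized multivariate logistic model on the training
split, and keep, as the consensus classifier, the genes selected in more
than half of the resampled signatures. Per-gene coefficients from the
penalized fits are deliberately discarded: the consensus classifier weighs
every gene equally (signed +/-1), which is the point of the design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .synthetic import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "DegCriteria",
    "StabilityParams",
    "ResampleRecord",
    "Classifier",
    "filter_degs",
    "exclude_short_followup",
    "stratified_resample",
    "univariate_screen",
    "fit_l1_signature",
    "stability_select",
]


@dataclass(frozen=True)
class DegCriteria:
    """Thresholds for the paired CAF-vs-NCF differential expression filter."""

    min_mean_log_expr: float = 4.0
    min_sd_log_expr: float = 0.1
    max_q: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    require_gene_symbol: bool = True

    def validate(self) -> None:
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ValueError(f"need fc_down < 1 < fc_up, got {self.fc_down}, {self.fc_up}")
        if min(self.min_mean_log_expr, self.min_sd_log_expr, self.fc_down) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.max_q < 1.0:
            raise ValueError(f"max_q must be in (0, 1), got {self.max_q}")


@dataclass(frozen=True)
class StabilityParams:
    """Controls for the resampling-based selection loop."""

    n_iterations: int = 1000
    train_fraction: float = 2.0 / 3.0
    univariate_p: float = 0.01
    frequency_threshold: float = 0.5
    min_followup_years: float = 3.0
    stratify_by: str = "stage"
    #: "train" screens candidates on the training split of each iteration
    #: (anti-overfitting default); "full" screens once on the whole cohort.
    screen_scope: str = "train"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        for name in ("univariate_p", "frequency_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.screen_scope not in ("train", "full"):
            raise ValueError(f"screen_scope must be 'train' or 'full', got {self.screen_scope!r}")


@dataclass
class ResampleRecord:
    """What one resampling iteration produced (coefficients are discarded)."""

    iteration: int
    train_ids: list
    test_ids: list
    screened_genes: list
    selected_genes: list
    test_auc: float


@dataclass
class Classifier:
    """Equal-weight signed gene classifier: genes with +/-1 coefficients."""

    genes: list  # ordered (gene id, coefficient in {+1, -1})
    cutoff: float | None = None

    def validate(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated gene ids in classifier")
        if any(c not in (+1, -1) for _, c in self.genes):
            raise ValueError("classifier coefficients must be +1 or -1")
        if self.cutoff is not None and not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    @property
    def gene_ids(self) -> list:
        return [g for g, _ in self.genes]

    def to_dict(self) -> dict:
        return {"genes": [{"id": g, "coefficient": int(c)} for g, c in self.genes],
                "cutoff": self.cutoff}

    @classmethod
    def from_dict(cls, d: dict) -> "Classifier":
        clf = cls([(g["id"], int(g["coefficient"])) for g in d["genes"]],
                  d.get("cutoff"))
        clf.validate()
        return clf


# ---------------------------------------------------------------------------
# Differential expression filter on paired fibroblast profiles
# ---------------------------------------------------------------------------

def _split_pairs(paired: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if not isinstance(paired.columns, pd.MultiIndex) or paired.columns.nlevels != 2:
        raise ValueError("paired profiles need two-level columns (pair id, arm)")
    arms = paired.columns.get_level_values(1)
    if not set(arms) <= {"NCF", "CAF"}:
        raise ValueError(f"column arms must be 'NCF'/'CAF', got {sorted(set(arms))}")
    ncf = paired.xs("NCF", axis=1, level=1)
    caf = paired.xs("CAF", axis=1, level=1)
    if list(ncf.columns) != list(caf.columns):
        raise ValueError("unpaired columns: NCF and CAF pair ids differ")
    return ncf, caf


def filter_degs(paired: pd.DataFrame, criteria: DegCriteria = DegCriteria()) -> list:
    """Genes differentially expressed between paired CAF and NCF profiles.

    A gene passes when it has a symbol, mean log2 expression above
    ``min_mean_log_expr``, SD above ``min_sd_log_expr``, a
    Benjamini-Hochberg q-value below ``max_q`` from a paired two-sided
    t-test, and a mean per-pair linear-scale fold change strictly above
    ``fc_up`` (up) or strictly below ``fc_down`` (down). All criteria use
    strict inequalities.
    """
    criteria.validate()
    ncf, caf = _split_pairs(paired)
    if ncf.shape[1] < 3:
        raise ValueError(f"need >= 3 pairs, got {ncf.shape[1]}")

    genes = paired.index
    has_symbol = pd.Series(True, index=genes)
    if criteria.require_gene_symbol:
        has_symbol = pd.Series(
            [isinstance(g, str) and g.strip() not in ("", "---", "NA") for g in genes],
            index=genes,
        )

    mean_expr = paired.mean(axis=1)
    sd_expr = paired.std(axis=1, ddof=1)

    diff = caf.values - ncf.values
    zero_var = diff.std(axis=1, ddof=1) == 0
    if zero_var.any():
        for g in genes[zero_var]:
            warnings.warn(f"gene {g}: zero variance under paired test, skipped")

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_rel(caf.values, ncf.values, axis=1)
    pvals = np.where(zero_var, np.nan, pvals)
    qvals = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]

    # Mean over pairs of the per-pair linear-scale ratio CAF/NCF.
    fold = np.mean(2.0 ** diff, axis=1)

    keep = (
        has_symbol.values
        & (mean_expr.values > criteria.min_mean_log_expr)
        & (sd_expr.values > criteria.min_sd_log_expr)
        & ~zero_var
        & (qvals < criteria.max_q)
        & ((fold > criteria.fc_up) | (fold < criteria.fc_down))
    )
    return list(genes[keep])


# ---------------------------------------------------------------------------
# Cohort eligibility and resampling
# ---------------------------------------------------------------------------

def exclude_short_followup(cohort: Cohort, min_years: float = 3.0) -> Cohort:
    """Drop non-recurrent samples followed for less than ``min_years`` years.

    Recurrent samples are always retained: the rule exists to keep samples
    whose absence of relapse has actually been observed long enough.
    """
    clin = cohort.clinical
    if "recurrence" not in clin or "dfs_time" not in clin:
        raise ValueError("clinical table needs 'recurrence' and 'dfs_time' columns")
    nonrec = clin["recurrence"] == 0
    missing = clin.index[nonrec & clin["dfs_time"].isna()]
    if len(missing):
        raise ValueError(f"missing follow-up time for non-recurrent samples: {list(missing)}")
    keep = ~(nonrec & (clin["dfs_time"] < min_years * 12.0))
    return cohort.subset(clin.index[keep])


def stratified_resample(cohort: Cohort, train_fraction: float = 2.0 / 3.0,
                        stratify_by: str = "stage",
                        seed: int | np.random.Generator = 0) -> tuple[list, list]:
    """Stage-proportional random train/test split.

    Within each stratum, ``round(train_fraction * n_stratum)`` ids are
    sampled for training; the remainder form the test set.
    """
    strata = cohort.clinical[stratify_by]
    if strata.isna().any():
        raise ValueError(f"missing values in stratification covariate {stratify_by!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train, test = [], []
    for _, ids in strata.groupby(strata).groups.items():
        ids = list(ids)
        if len(ids) < 2:
            raise ValueError(f"stratum of size {len(ids)} cannot be split")
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))
        n_train = min(max(n_train, 1), len(ids) - 1)
        chosen = rng.choice(len(ids), size=n_train, replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[chosen] = True
        train += [ids[i] for i in range(len(ids)) if mask[i]]
        test += [ids[i] for i in range(len(ids)) if not mask[i]]
    return train, test


# ---------------------------------------------------------------------------
# Univariate logistic screen (vectorized across genes)
# ---------------------------------------------------------------------------

def _logistic_wald_vectorized(x: np.ndarray, y: np.ndarray,
                              max_iter: int = 60, tol: float = 1e-10,
                              ridge: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene single-covariate logistic fits, Newton-Raphson in parallel.

    ``x`` is samples x genes (each column standardized by the caller);
    returns (slope, two-sided Wald p) per gene. A tiny ridge keeps the
    2x2 Hessians invertible.
    """
    n, g = x.shape
    b0 = np.zeros(g)
    b1 = np.zeros(g)
    for _ in range(max_iter):
        eta = b0[None, :] + x * b1[None, :]
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (x * r).sum(axis=0)
        h00 = w.sum(axis=0) + ridge
        h01 = (w * x).sum(axis=0)
        h11 = (w * x * x).sum(axis=0) + ridge
        det = h00 * h11 - h01 * h01
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(initial=0.0), np.abs(d1).max(initial=0.0)) < tol:
            break
    eta = b0[None, :] + x * b1[None, :]
    mu = special.expit(eta)
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=0) + ridge
    h01 = (w * x).sum(axis=0)
    h11 = (w * x * x).sum(axis=0) + ridge
    det = h00 * h11 - h01 * h01
    var_b1 = h00 / det
    with np.errstate(invalid="ignore", divide="ignore"):
        zstat = b1 / np.sqrt(var_b1)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    return b1, pvals


def univariate_screen(cohort: Cohort, genes=None, p_threshold: float = 0.01,
                      return_all: bool = False) -> pd.DataFrame:
    """Screen genes by single-covariate logistic regression on recurrence.

    Returns a frame (index = gene) with columns ``coef``, ``p`` and
    ``passed``. Genes are standardized internally for numerical stability
    (the slope's Wald p is invariant to positive rescaling). Constant genes
    are excluded with a warning. Genes with quasi-complete separation are
    flagged as passing with p = 0: the Wald statistic of an unpenalized fit
    degenerates there (Hauck-Donner), and a gene that perfectly predicts
    recurrence must not be discarded by its own strength.
    """
    y = cohort.clinical["recurrence"].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("recurrence must be binary 0/1")
    if genes is None:
        genes = list(cohort.expression.columns)
    X = cohort.expression[list(genes)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing expression values in screened genes")

    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        for g in np.asarray(genes)[constant]:
            warnings.warn(f"gene {g}: constant expression, excluded from screen")
    keep = ~constant
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    coefs, pvals = _logistic_wald_vectorized(Xs, y)

    # Quasi-complete separation: the MLE diverges, so the slope keeps
    # growing with iterations; |slope| >> 1 on standardized data flags it.
    separated = np.abs(coefs) > 12.0
    pvals = np.where(separated, 0.0, pvals)

    out = pd.DataFrame({"coef": coefs, "p": pvals},
                       index=np.asarray(genes)[keep])
    out["passed"] = out["p"] < p_threshold
    if return_all:
        return out
    return out[out["passed"]]


# ---------------------------------------------------------------------------
# L1-penalized multivariate selection
# ---------------------------------------------------------------------------

def fit_l1_signature(expr_train: pd.DataFrame, y_train: np.ndarray,
                     seed: int = 0, n_folds: int = 10,
                     Cs: np.ndarray | None = None,
                     penalty_rule: str = "dense_1se") -> list:
    """Genes with nonzero coefficients in an L1 logistic fit on the train set.

    Expression columns are standardized; the penalty is chosen by
    stratified k-fold cross-validation (deviance loss) on the training data
    only. ``penalty_rule`` controls where on the CV curve the penalty is
    taken:

    - ``"dense_1se"`` (default): the *weakest* penalty whose mean CV
      deviance is within one standard error of the minimum. Signature
      genes that share a latent factor are strongly collinear, and the
      deviance-minimizing penalty then splits selection arbitrarily among
      them across resamples; since specificity is already enforced by the
      univariate screen, the selection stage deliberately resolves the
      flat region of the CV curve toward the denser model.
    - ``"cv_min"``: the penalty at the minimum mean CV deviance.

    An empty selection (full shrinkage) is a valid result.
    """
    genes = list(expr_train.columns)
    if len(genes) < 1:
        return []
    if penalty_rule not in ("dense_1se", "cv_min"):
        raise ValueError(f"unknown penalty_rule {penalty_rule!r}")
    y = np.asarray(y_train, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome has a single class; cannot fit")
    X = expr_train.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    if Cs is None:
        Cs = np.logspace(-2.0, 2.0, 8)
    Cs = np.sort(np.asarray(Cs))  # ascending C = decreasing penalty
    n_minority = int(np.bincount(y).min())
    folds = min(n_folds, n_minority)
    if folds < 2:
        raise ValueError("too few minority-class samples for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True,
                         random_state=int(seed) % (2**32))

    est = LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=500)
    deviance = np.zeros((folds, len(Cs)))
    eps = 1e-12
    for i, (tr, va) in enumerate(cv.split(X, y)):
        for j, c in enumerate(Cs):
            est.C = float(c)
            est.fit(X[tr], y[tr])
            eta = X[va] @ est.coef_.ravel() + est.intercept_[0]
            p = np.clip(special.expit(eta), eps, 1.0 - eps)
            deviance[i, j] = -np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log1p(-p))

    mean_dev = deviance.mean(axis=0)
    j_min = int(np.argmin(mean_dev))
    if penalty_rule == "cv_min":
        j_star = j_min
    else:
        se = deviance[:, j_min].std(ddof=1) / np.sqrt(folds)
        within = np.flatnonzero(mean_dev <= mean_dev[j_min] + se)
        j_star = int(within.max())  # weakest penalty within one SE

    est.C = float(Cs[j_star])
    est.fit(X, y)
    coef = est.coef_.ravel()
    return [g for g, c in zip(genes, coef) if abs(c) > 1e-8]


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------

def _consensus_directions(consensus: list, cohort: Cohort,
                          paired_profiles: pd.DataFrame | None,
                          screen_full: pd.DataFrame) -> list:
    """Assign the +/-1 coefficient of each consensus gene.

    Preferred: sign of the mean CAF-minus-NCF difference in paired
    fibroblast profiles (the biological definition of risk vs protective).
    Fallback: sign of the gene's univariate logistic coefficient against
    recurrence, with a warning.
    """
    signed = []
    for g in consensus:
        if paired_profiles is not None and g in paired_profiles.index:
            ncf, caf = _split_pairs(paired_profiles.loc[[g]])
            delta = float((caf.values - ncf.values).mean())
            signed.append((g, +1 if delta >= 0 else -1))
        else:
            if paired_profiles is not None:
                warnings.warn(f"gene {g} absent from paired profiles; "
                              "direction taken from outcome association")
            else:
                warnings.warn(f"no paired profiles; direction of {g} taken "
                              "from outcome association")
            coef = float(screen_full.loc[g, "coef"])
            signed.append((g, +1 if coef >= 0 else -1))
    return signed


def stability_select(cohort: Cohort, params: StabilityParams = StabilityParams(),
                     candidate_genes=None,
                     paired_profiles: pd.DataFrame | None = None,
                     ) -> tuple[pd.DataFrame, Classifier, list]:
    """Run the full resampled-selection loop and build the consensus classifier.

    Per iteration: stage-proportional train/test split, univariate logistic
    screen (on the training split by default), L1-penalized multivariate
    logistic selection on the training split, and a test-set AUC recorded
    for reporting only (the test split never feeds selection). Returns the
    per-gene selection-frequency table, the consensus
    :class:`Classifier` (genes selected in strictly more than
    ``frequency_threshold`` of completed iterations, equal signed weights),
    and the list of :class:`ResampleRecord`.
    """
    params.validate()
    eligible = exclude_short_followup(cohort, params.min_followup_years)
    if candidate_genes is None:
        candidate_genes = list(eligible.expression.columns)
    candidate_genes = list(candidate_genes)

    screen_full = univariate_screen(eligible, candidate_genes,
                                    params.univariate_p, return_all=True)

    records: list[ResampleRecord] = []
    counts = pd.Series(0, index=candidate_genes, dtype=int)
    failures = []
    split_rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 77]))

    for it in range(params.n_iterations):
        try:
            train_ids, test_ids = stratified_resample(
                eligible, params.train_fraction, params.stratify_by, split_rng)
            train = eligible.subset(train_ids)
            if params.screen_scope == "train":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    screened = list(univariate_screen(
                        train, candidate_genes, params.univariate_p).index)
            else:
                screened = list(screen_full[screen_full["passed"]].index)

            if len(screened) == 0:
                selected = []
            else:
                y_tr = train.clinical["recurrence"].to_numpy(dtype=int)
                selected = fit_l1_signature(train.expression[screened], y_tr,
                                            seed=params.seed * 100003 + it)

            test_auc = np.nan
            if selected:
                test = eligible.subset(test_ids)
                z_tr = train.expression[selected]
                mu, sd = z_tr.mean(), z_tr.std(ddof=1).replace(0.0, 1.0)
                score = (((test.expression[selected] - mu) / sd)).mean(axis=1)
                y_te = test.clinical["recurrence"].to_numpy(dtype=int)
                if len(np.unique(y_te)) == 2:
                    test_auc = float(roc_auc_score(y_te, score))

            counts[selected] += 1
            records.append(ResampleRecord(it, train_ids, test_ids,
                                          screened, selected, test_auc))
        except Exception as exc:  # pragma: no cover - defensive logging path
            failures.append((it, repr(exc)))
            logger.warning("iteration %d failed: %r", it, exc)

    if not records:
        raise RuntimeError(f"no resampling iteration completed; failures: {failures}")

    n_done = len(records)
    table = pd.DataFrame({
        "count": counts,
        "frequency": counts / n_done,
    }).sort_values("frequency", ascending=False)

    consensus = list(table.index[table["frequency"] > params.frequency_threshold])
    # Keep candidate-list order for the classifier gene order.
    consensus = [g for g in candidate_genes if g in consensus]
    with warnings.catch_warnings():
        if paired_profiles is not None:
            warnings.simplefilter("ignore")
        signed = _consensus_directions(consensus, eligible, paired_profiles,
                                       screen_full)
    classifier = Classifier(signed, cutoff=None)
    classifier.validate()
    return table, classifier, records
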