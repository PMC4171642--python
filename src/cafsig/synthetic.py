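"""Synthetic cohorts with the statistical structure of stroma-rich tumor series.

The generator emulates bulk expression of tumors whose stromal compartment
carries the prognostic signal: each sample has a latent stromal fraction
(how much fibroblast-derived mRNA the bulk profile contains) and a latent
CAF activation state (the physiological state of those fibroblasts).
Planted risk/protective genes load on ``fraction x activation``, collagen
genes load on fraction alone, and recurrence depends on activation only —
so stromal *quantity* is visible in expression but carries no outcome
information, while stromal *state* drives relapse and is only detectable
when enough stroma is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "Cohort",
    "generate_cohort",
    "generate_paired_fibroblast_profiles",
    "generate_epithelial_cohort",
    "RISK_GENE_NAMES",
    "PROTECTIVE_GENE_NAMES",
    "COLLAGEN_GENE_NAMES",
]

# Canonical gene names used when the planted counts match the published
# classifier (4 risk + 1 protective) and the two-gene collagen proxy.
RISK_GENE_NAMES = ("PDLIM3", "AMIGO2", "SLC7A2", "ULBP2")
PROTECTIVE_GENE_NAMES = ("CCL11",)
COLLAGEN_GENE_NAMES = ("COL1A1", "COL3A1")

_STAGES = ("I", "II", "III")

# Sub-stream tags: one global seed, one named child stream per random
# component, so toggling a component never perturbs the others.
_STREAMS = {
    "baseline": 11,
    "stroma": 12,
    "activation": 13,
    "noise": 14,
    "stage": 15,
    "outcome": 16,
    "survival": 17,
    "censor": 18,
    "covariates": 19,
    "pairs": 20,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class SyntheticParams:
    """Data-generating parameters for a synthetic stroma-rich cohort.

    Defaults mirror the study design the pipeline targets: 135 Stage II/III
    samples (47/53% split), 108 candidate genes of which 5 are planted
    (4 risk, 1 protective) plus 2 collagen genes, recurrence prevalence
    ~35%, and administrative censoring guaranteeing mostly >3-year
    follow-up. Effect sizes are calibrated by Monte-Carlo so that the
    latent risk separates recurrent from non-recurrent samples with
    AUC ~ 0.80 (see ``outcome_logit_slope``).
    """

    n_samples: int = 135
    n_genes: int = 110  # 108 candidates + 2 collagen genes
    n_risk_genes: int = 4
    n_protective_genes: int = 1
    n_collagen_genes: int = 2
    #: Beta(a, b) for the per-sample stromal (fibroblast mRNA) fraction.
    stromal_fraction_dist: tuple[float, float] = (60.0, 90.0)
    #: Beta(a, b) for the latent CAF activation state in [0, 1].
    caf_activation_dist: tuple[float, float] = (2.0, 2.0)
    #: log2-scale shift of a planted gene per unit (fraction x activation).
    caf_activation_effect: float = 5.0
    #: log-odds of recurrence per 1 SD of latent risk (Monte-Carlo
    #: calibrated so that AUC(latent risk vs recurrence) ~ 0.80).
    outcome_logit_slope: float = 1.3
    baseline_recurrence_rate: float = 0.35
    #: Weibull relapse-time parameters (months) and log-HR per SD of risk.
    hazard_scale: float = 48.0
    hazard_shape: float = 1.3
    hazard_loghr: float = 0.8
    #: probability of early drop-out censoring (follow-up < 36 months)
    #: instead of administrative censoring on [36, 96] months.
    censor_rate: float = 0.10
    stage_probs: dict = field(default_factory=lambda: {"II": 0.474, "III": 0.526})
    #: log2-scale SD of i.i.d. measurement noise.
    noise_sd: float = 0.10
    #: SD of the per-(gene, pair) shared component in paired profiles.
    pair_sd: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_genes", "n_risk_genes",
                     "n_protective_genes", "n_collagen_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        n_planted = self.n_risk_genes + self.n_protective_genes + self.n_collagen_genes
        if n_planted > self.n_genes:
            raise ValueError(
                "n_risk_genes + n_protective_genes + n_collagen_genes "
                f"({n_planted}) exceeds n_genes ({self.n_genes})"
            )
        for name in ("stromal_fraction_dist", "caf_activation_dist"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} Beta parameters must be > 0, got ({a}, {b})")
        for name in ("baseline_recurrence_rate", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.hazard_scale <= 0 or self.hazard_shape <= 0:
            raise ValueError("hazard_scale and hazard_shape must be > 0")
        probs = self.stage_probs
        if any(p < 0 for p in probs.values()) or not np.isclose(sum(probs.values()), 1.0):
            raise ValueError(f"stage_probs must be non-negative and sum to 1, got {probs}")
        if any(s not in _STAGES for s in probs):
            raise ValueError(f"stage_probs keys must be among {_STAGES}, got {tuple(probs)}")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    planted_genes: list  # (gene id, direction in {+1, -1})
    stromal_fraction: np.ndarray
    caf_activation: np.ndarray
    latent_risk: np.ndarray

    def validate(self, n_samples: int | None = None) -> None:
        for g, d in self.planted_genes:
            if d not in (+1, -1):
                raise ValueError(f"direction for {g} must be +1 or -1, got {d}")
        if np.any((self.stromal_fraction < 0) | (self.stromal_fraction > 1)):
            raise ValueError("stromal_fraction outside [0, 1]")
        n = len(self.stromal_fraction)
        if not (len(self.caf_activation) == len(self.latent_risk) == n):
            raise ValueError("truth vectors have mismatched lengths")
        if n_samples is not None and n != n_samples:
            raise ValueError("truth vectors do not match cohort sample count")


@dataclass
class Cohort:
    """Expression matrix (samples x genes, log2 scale) + aligned clinical table."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    dataset_id: str = "synthetic"

    def validate(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError("duplicated sample ids in expression matrix")
        if self.expression.columns.has_duplicates:
            raise ValueError("duplicated gene ids in expression matrix")
        if set(self.expression.index) != set(self.clinical.index):
            raise ValueError("expression and clinical sample ids differ")
        for col in ("dfs_time", "dss_time"):
            if col in self.clinical and (self.clinical[col].dropna() < 0).any():
                raise ValueError(f"negative times in {col}")
        for tcol, ecol in (("dfs_time", "dfs_event"), ("dss_time", "dss_event")):
            if ecol in self.clinical and tcol in self.clinical:
                bad = self.clinical[(self.clinical[ecol] == 1) & self.clinical[tcol].isna()]
                if len(bad):
                    raise ValueError(f"{ecol}=1 without {tcol} for {list(bad.index)}")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    def subset(self, sample_ids) -> "Cohort":
        ids = list(sample_ids)
        return Cohort(self.expression.loc[ids].copy(),
                      self.clinical.loc[ids].copy(), self.dataset_id)


def _gene_names(params: SyntheticParams) -> tuple[list, list, list, list]:
    def named(defaults, n, prefix):
        out = list(defaults[:n])
        out += [f"{prefix}{i}" for i in range(len(out) + 1, n + 1)]
        return out

    risk = named(RISK_GENE_NAMES, params.n_risk_genes, "RISKG")
    prot = named(PROTECTIVE_GENE_NAMES, params.n_protective_genes, "PROTG")
    coll = named(COLLAGEN_GENE_NAMES, params.n_collagen_genes, "COLG")
    n_null = params.n_genes - len(risk) - len(prot) - len(coll)
    null = [f"G{i:03d}" for i in range(1, n_null + 1)]
    return risk, prot, coll, null


def _beta_moments(a: float, b: float) -> tuple[float, float]:
    mean = a / (a + b)
    sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    return mean, sd


def _expression_matrix(params, fraction, activation, seed, dataset_id):
    risk, prot, coll, null = _gene_names(params)
    genes = risk + prot + coll + null
    n, g = params.n_samples, params.n_genes

    baseline = _rng(seed, "baseline").uniform(5.0, 9.0, size=g)
    noise = _rng(seed, "noise").normal(0.0, params.noise_sd, size=(n, g))

    loading = np.zeros((n, g))
    state = fraction * activation
    e = params.caf_activation_effect
    for j, gene in enumerate(genes):
        if gene in risk:
            loading[:, j] = e * state
        elif gene in prot:
            loading[:, j] = -e * state
        elif gene in coll:
            loading[:, j] = e * fraction

    expr = baseline[None, :] + loading + noise
    sample_ids = [f"{dataset_id}-S{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame(expr, index=sample_ids, columns=genes), risk, prot


def _marginal_intercept(params: SyntheticParams) -> float:
    """Logistic intercept giving E[recurrence] = baseline_recurrence_rate.

    Gauss-Legendre quadrature over the Beta activation density; bisection
    on the intercept. Deterministic (no sampling involved).
    """
    from scipy import optimize, special, stats

    a, b = params.caf_activation_dist
    mu, sd = _beta_moments(a, b)
    nodes, weights = np.polynomial.legendre.leggauss(200)
    x = 0.5 * (nodes + 1.0)  # map to (0, 1)
    w = 0.5 * weights * stats.beta.pdf(x, a, b)
    z = (x - mu) / sd

    def marginal(c):
        return float(np.sum(w * special.expit(c + params.outcome_logit_slope * z)))

    target = params.baseline_recurrence_rate
    return optimize.brentq(lambda c: marginal(c) - target, -20.0, 20.0)


def _clinical_table(params, latent_risk, seed, sample_ids):
    n = params.n_samples
    stages = list(params.stage_probs)
    stage = _rng(seed, "stage").choice(stages, size=n, p=[params.stage_probs[s] for s in stages])

    # Binary recurrence from a logistic model on latent risk. The intercept
    # is solved (by quadrature over the activation distribution) so the
    # *marginal* recurrence probability equals baseline_recurrence_rate.
    if params.baseline_recurrence_rate in (0.0, 1.0):
        p_rec = np.full(n, params.baseline_recurrence_rate)
    else:
        intercept = _marginal_intercept(params)
        p_rec = 1.0 / (1.0 + np.exp(-(intercept + params.outcome_logit_slope * latent_risk)))
    rng_out = _rng(seed, "outcome")
    recurrence = (rng_out.uniform(size=n) < p_rec).astype(int)

    # Follow-up: administrative censoring on [36, 96] months, with a small
    # early drop-out fraction censored on [6, 36) months.
    rng_c = _rng(seed, "censor")
    censor = rng_c.uniform(36.0, 96.0, size=n)
    early = rng_c.uniform(size=n) < params.censor_rate
    censor[early] = rng_c.uniform(6.0, 36.0, size=int(early.sum()))

    # Relapse times: Weibull proportional hazards in latent risk, truncated
    # to the observed follow-up window for patients flagged as recurrent.
    rng_s = _rng(seed, "survival")
    k, lam = params.hazard_shape, params.hazard_scale
    hr = np.exp(params.hazard_loghr * latent_risk)
    dfs_time = censor.copy()
    dfs_event = np.zeros(n, dtype=int)
    cum_at_c = (censor / lam) ** k * hr
    f_at_c = 1.0 - np.exp(-cum_at_c)  # P(T <= censor)
    u = rng_s.uniform(size=n) * f_at_c
    t_rel = lam * (-np.log1p(-u) / hr) ** (1.0 / k)
    rec = recurrence == 1
    dfs_time[rec] = t_rel[rec]
    dfs_event[rec] = 1

    # Disease-specific death: only after relapse, with a lag.
    dies = rec & (rng_s.uniform(size=n) < 0.7)
    lag = rng_s.weibull(1.5, size=n) * 18.0
    death = t_rel + lag
    dss_time = censor.copy()
    dss_event = np.zeros(n, dtype=int)
    obs_death = dies & (death <= censor)
    dss_time[obs_death] = death[obs_death]
    dss_event[obs_death] = 1

    rng_cov = _rng(seed, "covariates")
    clinical = pd.DataFrame(
        {
            "stage": stage,
            "recurrence": recurrence,
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "dss_time": dss_time,
            "dss_event": dss_event,
            "age": np.round(rng_cov.normal(65.0, 10.0, size=n), 1),
            "gender": rng_cov.choice(["male", "female"], size=n, p=[0.56, 0.44]),
            "location": rng_cov.choice(["colon", "rectum"], size=n, p=[0.75, 0.25]),
            "grade": rng_cov.choice(["low", "high"], size=n, p=[0.9, 0.1]),
            "nodes": rng_cov.poisson(15.0, size=n),
            "lymphatic_invasion": rng_cov.integers(0, 2, size=n),
            "adjuvant": rng_cov.integers(0, 2, size=n),
        },
        index=sample_ids,
    )
    return clinical


def generate_cohort(params: SyntheticParams, seed: int | None = None,
                    dataset_id: str = "synthetic") -> tuple[Cohort, SyntheticTruth]:
    """Generate one whole-tumor cohort plus its ground truth.

    Expression: ``x(s, g) = baseline(g) + loading(g, s) + noise`` on a log2
    scale, where risk/protective genes load on ``stromal_fraction x
    caf_activation`` with their planted sign, and collagen genes load on
    ``stromal_fraction`` alone. Recurrence is Bernoulli with log-odds linear
    in the standardized activation (the latent risk); relapse times are
    Weibull proportional-hazards in the same latent risk; censoring is
    administrative on [36, 96] months with a small early-drop-out fraction.
    """
    params.validate()
    if seed is None:
        seed = params.seed

    fraction = _rng(seed, "stroma").beta(*params.stromal_fraction_dist, size=params.n_samples)
    activation = _rng(seed, "activation").beta(*params.caf_activation_dist, size=params.n_samples)
    mu_a, sd_a = _beta_moments(*params.caf_activation_dist)
    latent_risk = (activation - mu_a) / sd_a

    expr, risk, prot = _expression_matrix(params, fraction, activation, seed, dataset_id)
    clinical = _clinical_table(params, latent_risk, seed, list(expr.index))

    cohort = Cohort(expr, clinical, dataset_id)
    truth = SyntheticTruth(
        planted_genes=[(g, +1) for g in risk] + [(g, -1) for g in prot],
        stromal_fraction=fraction,
        caf_activation=activation,
        latent_risk=latent_risk,
    )
    cohort.validate()
    truth.validate(params.n_samples)
    return cohort, truth


def generate_epithelial_cohort(params: SyntheticParams, seed: int | None = None,
                               dataset_id: str = "synthetic-epithelial"
                               ) -> tuple[Cohort, SyntheticTruth]:
    """Cohort of epithelial-enriched (microdissected-like) samples.

    Identical to :func:`generate_cohort` except the stromal fraction is
    collapsed near zero, so the latent risk still drives recurrence but is
    essentially invisible in the expression matrix — the negative control
    for stromal specificity of a classifier.
    """
    params = replace(params, stromal_fraction_dist=(0.05, 200.0))
    return generate_cohort(params, seed=seed, dataset_id=dataset_id)


def generate_paired_fibroblast_profiles(params: SyntheticParams, n_pairs: int,
                                        seed: int | None = None) -> pd.DataFrame:
    """Paired NCF/CAF expression profiles (genes x 2*n_pairs).

    Columns carry a two-level index (pair id, arm) with arms ``NCF`` and
    ``CAF``. Planted genes differ between arms by ``caf_activation_effect``
    (log2 scale) in their planted direction; all other genes differ only by
    noise. A per-(gene, pair) shared component makes the pairing
    informative, as for fibroblasts isolated from the same patient.
    """
    params.validate()
    if n_pairs < 3:
        raise ValueError(f"n_pairs must be >= 3 for a meaningful paired test, got {n_pairs}")
    if seed is None:
        seed = params.seed

    risk, prot, coll, null = _gene_names(params)
    genes = risk + prot + coll + null
    g = len(genes)
    baseline = _rng(seed, "baseline").uniform(5.0, 9.0, size=g)

    direction = np.zeros(g)
    for j, gene in enumerate(genes):
        if gene in risk:
            direction[j] = +1.0
        elif gene in prot:
            direction[j] = -1.0
        elif gene in coll:
            # Collagen output tracks fibroblast quantity, not activation
            # state: equal in purified NCF and CAF preparations.
            direction[j] = 0.0

    rng = _rng(seed, "pairs")
    shared = rng.normal(0.0, params.pair_sd, size=(g, n_pairs))
    ncf = baseline[:, None] + shared + rng.normal(0.0, params.noise_sd, size=(g, n_pairs))
    caf = (baseline[:, None] + shared
           + direction[:, None] * params.caf_activation_effect
           + rng.normal(0.0, params.noise_sd, size=(g, n_pairs)))

    cols = pd.MultiIndex.from_tuples(
        [(f"P{i:02d}", arm) for i in range(1, n_pairs + 1) for arm in ("NCF", "CAF")],
        names=["pair", "arm"],
    )
    data = np.empty((g, 2 * n_pairs))
    data[:, 0::2] = ncf
    data[:, 1::2] = caf
    return pd.DataFrame(data, index=genes, columns=cols)
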