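"""qPCR processing: standard curves, reference-gene stability, normalization.

Quantification cycles (Cq) are converted to relative cDNA amounts through a
per-gene standard curve fitted on serial dilutions; candidate reference
genes are ranked for stability with two pairwise-ratio methods (the geNorm
M statistic and the mean pairwise-dCt SD); target amounts are divided by
the geometric mean of the chosen reference genes, log2-transformed and
z-scored per gene, yielding expression directly usable by the signed
z-score classifier.

The two stability methods are implemented from their definitions; both are
invariant to per-sample global scaling, which is exactly why they are used
to pick normalizers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .score import zscore_genes

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify",
    "genorm_stability",
    "genorm_ranking",
    "delta_ct_stability",
    "normalize_to_references",
    "log_standardize",
    "rank_reference_candidates",
    "cq_to_relative_quantity",
]


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Cq = slope * log10(amount) + intercept."""

    slope: float
    intercept: float
    efficiency: float
    r2: float


def fit_standard_curve(points) -> StandardCurve:
    """Fit a standard curve to (log10 dilution, Cq) points.

    Amplification efficiency is ``10**(-1/slope) - 1``: a perfectly
    doubling reaction has slope -3.3219 and efficiency 1.0 (100%).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (log10 dilution, Cq) points")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 2:
        raise ValueError("standard-curve dilutions must be distinct")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(f"non-physical standard curve: slope {res.slope:.3f} >= 0 "
                         "(Cq must fall as template amount rises)")
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(float(res.slope), float(res.intercept),
                         float(efficiency), float(res.rvalue ** 2))


def quantify(cq, curve: StandardCurve):
    """Relative amount from a Cq value: ``10 ** ((cq - intercept) / slope)``."""
    cq = np.asarray(cq, dtype=float)
    amount = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return float(amount) if amount.ndim == 0 else amount


def cq_to_relative_quantity(cq_table: pd.DataFrame,
                            efficiency: float = 1.0) -> pd.DataFrame:
    """Relative quantities from raw Cq values (samples x genes).

    Without a standard curve, the conventional transform sets each gene's
    lowest Cq to quantity 1: ``(1 + E) ** (Cq_min - Cq)``.
    """
    E = 1.0 + efficiency
    return E ** (cq_table.min(axis=0) - cq_table)


def genorm_stability(quantities: pd.DataFrame) -> pd.Series:
    """geNorm M per gene on relative quantities (samples x genes).

    M(g) is the mean, over all other genes h, of the SD across samples of
    log2(q_g / q_h). Lower M = more stable. Ratio-based, so multiplying
    any sample's row by a constant leaves every M unchanged.
    """
    if quantities.shape[1] < 3:
        raise ValueError("geNorm needs >= 3 candidate genes")
    if quantities.shape[0] < 5:
        raise ValueError("geNorm needs >= 5 samples")
    if (quantities <= 0).any().any():
        raise ValueError("non-positive quantities: log-ratio undefined")
    logq = np.log2(quantities)
    genes = list(quantities.columns)
    m = {}
    for g in genes:
        sds = [float((logq[g] - logq[h]).std(ddof=1)) for h in genes if h != g]
        m[g] = float(np.mean(sds))
    return pd.Series(m, name="genorm_m")


def genorm_ranking(quantities: pd.DataFrame) -> list:
    """Iterative geNorm ranking: repeatedly drop the least stable gene.

    Returns genes from least to most stable; the final two (inseparable by
    the method) share the best rank and come last.
    """
    remaining = quantities.copy()
    dropped = []
    while remaining.shape[1] > 2:
        m = genorm_stability(remaining) if remaining.shape[1] >= 3 else None
        worst = m.idxmax()
        dropped.append(worst)
        remaining = remaining.drop(columns=[worst])
    return dropped + list(remaining.columns)


def delta_ct_stability(cq_table: pd.DataFrame) -> pd.Series:
    """Mean pairwise-dCt SD per gene on a Cq table (samples x genes).

    For gene g: mean over partners h of SD across samples of
    (Cq_g - Cq_h). Missing Cq values are handled pairwise-complete with a
    warning reporting the counts used.
    """
    genes = list(cq_table.columns)
    if len(genes) < 2:
        raise ValueError("pairwise dCt needs >= 2 candidate genes")
    n_missing = int(cq_table.isna().sum().sum())
    if n_missing:
        warnings.warn(f"{n_missing} missing Cq values; pairwise-complete SDs used")
    out = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            d = (cq_table[g] - cq_table[h]).dropna()
            if len(d) < 2:
                continue
            sds.append(float(d.std(ddof=1)))
        out[g] = float(np.mean(sds)) if sds else np.nan
    return pd.Series(out, name="delta_ct_sd")


def normalize_to_references(amounts: pd.DataFrame,
                            reference_genes=("ACTB", "PMM1")) -> pd.DataFrame:
    """Divide each target amount by the geometric mean of the references.

    ``amounts`` is samples x genes on the linear scale. Reference columns
    are dropped from the output. Zero or negative reference amounts are an
    error naming the offending sample.
    """
    refs = list(reference_genes)
    missing = [g for g in refs if g not in amounts.columns]
    if missing:
        raise KeyError(f"reference genes missing: {missing}")
    ref_block = amounts[refs]
    bad = ref_block.index[(ref_block <= 0).any(axis=1)]
    if len(bad):
        raise ValueError(f"non-positive reference amounts for samples: {list(bad)}")
    geo = np.exp(np.log(ref_block).mean(axis=1))
    targets = amounts.drop(columns=refs)
    return targets.div(geo, axis=0)


def log_standardize(normalized: pd.DataFrame) -> pd.DataFrame:
    """log2 then per-gene z-score: classifier-ready expression."""
    if (normalized <= 0).any().any():
        raise ValueError("non-positive normalized values cannot be log-transformed")
    return zscore_genes(np.log2(normalized))


def rank_reference_candidates(cq_table: pd.DataFrame, candidates=None,
                              efficiency: float = 1.0) -> pd.DataFrame:
    """Stability ranking of candidate reference genes.

    Runs geNorm (on relative quantities derived from Cq assuming the given
    efficiency) and the pairwise-dCt method (on Cq directly); the combined
    rank is the geometric mean of the two per-method ranks. Returns a
    frame sorted by combined rank (most stable first) with columns
    ``genorm_m``, ``delta_ct_sd``, ``rank_genorm``, ``rank_delta_ct``,
    ``combined_rank``. Candidates a method cannot score are excluded with
    a warning.
    """
    if candidates is None:
        candidates = list(cq_table.columns)
    candidates = list(candidates)
    if len(candidates) < 3:
        raise ValueError("need >= 3 candidate reference genes")
    missing = [g for g in candidates if g not in cq_table.columns]
    if missing:
        raise KeyError(f"candidates missing from Cq table: {missing}")
    sub = cq_table[candidates]

    quantities = cq_to_relative_quantity(sub, efficiency)
    m = genorm_stability(quantities)
    d = delta_ct_stability(sub)

    dropped = [g for g in candidates if not (np.isfinite(m.get(g, np.nan))
                                             and np.isfinite(d.get(g, np.nan)))]
    for g in dropped:
        warnings.warn(f"candidate {g} excluded: a stability method failed on it")
    kept = [g for g in candidates if g not in dropped]

    table = pd.DataFrame({"genorm_m": m[kept], "delta_ct_sd": d[kept]})
    table["rank_genorm"] = table["genorm_m"].rank(method="average")
    table["rank_delta_ct"] = table["delta_ct_sd"].rank(method="average")
    table["combined_rank"] = np.sqrt(table["rank_genorm"] * table["rank_delta_ct"])
    return table.sort_values("combined_rank")
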