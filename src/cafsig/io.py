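"""Readers, writers, configuration and the end-to-end pipeline driver.

Tables are tab-separated UTF-8 with '.' decimals by default. Internally
samples are always rows; files may be oriented either way and declare it
(or let it be auto-detected against the clinical table's sample ids).
Every pipeline run writes a manifest recording inputs, parameters, seeds
and output checksums so any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .posttest import posttest_table
from .published import PUBLISHED_CLASSIFIER
from .score import score_cohort
from .signature import Classifier, StabilityParams, exclude_short_followup, stability_select
from .survival import CoxModelSpec, cox_fit, five_year_rate, km_logrank, roc_auc
from .synthetic import Cohort, SyntheticParams, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "read_classifier",
    "write_classifier",
    "PipelineConfig",
    "run_pipeline",
]

_VALID_STAGES = {"I", "II", "III"}
_REQUIRED_CLINICAL = ("stage", "recurrence")


def read_expression(path, orientation: str = "auto",
                    sample_ids=None) -> pd.DataFrame:
    """Read an expression table into a samples x genes matrix.

    ``orientation`` is ``"samples_rows"``, ``"genes_rows"`` or ``"auto"``
    (decided by overlap of row/column labels with ``sample_ids`` when
    given, else by which axis is longer — expression matrices have many
    more genes than samples).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated row ids in {path.name}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicated column ids in {path.name}: {dups}")

    non_numeric = df.columns[~df.apply(
        lambda c: pd.to_numeric(c, errors="coerce").notna() | c.isna()).all()]
    if len(non_numeric):
        raise ValueError(f"non-numeric cells in {path.name}, columns: "
                         f"{list(non_numeric)}")
    df = df.astype(float)

    if orientation == "auto":
        if sample_ids is not None:
            ids = set(sample_ids)
            in_rows = len(ids & set(df.index))
            in_cols = len(ids & set(df.columns))
            orientation = "samples_rows" if in_rows >= in_cols else "genes_rows"
        else:
            orientation = "samples_rows" if df.shape[0] <= df.shape[1] else "genes_rows"
    if orientation == "genes_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def write_expression(matrix: pd.DataFrame, path,
                     orientation: str = "samples_rows") -> None:
    path = Path(path)
    out = matrix if orientation == "samples_rows" else matrix.T
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out.to_csv(path, sep=sep)


def read_clinical(path, require_survival: bool = False) -> pd.DataFrame:
    """Read and validate a clinical table (CSV/TSV, sample ids in column 1)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    clin = pd.read_csv(path, sep=sep, index_col=0)
    for col in _REQUIRED_CLINICAL:
        if col not in clin.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    bad_stage = set(clin["stage"].dropna().astype(str)) - _VALID_STAGES
    if bad_stage:
        raise ValueError(f"unknown stage labels {sorted(bad_stage)}; "
                         f"expected one of {sorted(_VALID_STAGES)}")
    for col in ("recurrence", "dfs_event", "dss_event"):
        if col in clin.columns:
            vals = set(clin[col].dropna().unique())
            if not vals <= {0, 1}:
                raise ValueError(f"{col} must be binary 0/1, got {sorted(vals)}")
    if require_survival:
        for col in ("dfs_time", "dfs_event"):
            if col not in clin.columns:
                raise ValueError(f"survival analysis requested but {col!r} missing")
    optional = ("age", "gender", "location", "grade", "nodes",
                "lymphatic_invasion", "adjuvant")
    absent = [c for c in optional if c not in clin.columns]
    if absent:
        warnings.warn(f"optional covariates absent: {absent}; "
                      "covariate-adjusted analyses will degrade gracefully")
    return clin


def read_classifier(path) -> Classifier:
    with open(path) as fh:
        return Classifier.from_dict(json.load(fh))


def write_classifier(classifier: Classifier, path) -> None:
    with open(path, "w") as fh:
        json.dump(classifier.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Pipeline configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; loadable from YAML."""

    outdir: str = "cafsig_out"
    seed: int = 0
    log_level: str = "INFO"
    # inputs: either simulate, or point to files
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)  # SyntheticParams overrides
    expression_path: str | None = None
    clinical_path: str | None = None
    expression_orientation: str = "auto"
    # discovery
    run_discovery: bool = True
    stability: dict = field(default_factory=dict)  # StabilityParams overrides
    classifier_path: str | None = None  # used when run_discovery is False
    # scoring
    cutoff: float | None = None  # override; else derived from the cohort
    # evaluation toggles
    run_validation: bool = True
    run_posttest: bool = True
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig) -> Cohort:
    if cfg.simulate:
        params = SyntheticParams(**{**cfg.synthetic, "seed": cfg.seed})
        cohort, _ = generate_cohort(params, seed=cfg.seed)
        return cohort
    if not (cfg.expression_path and cfg.clinical_path):
        raise ValueError("simulate=false needs expression_path and clinical_path")
    clinical = read_clinical(cfg.clinical_path)
    expr = read_expression(cfg.expression_path, cfg.expression_orientation,
                           sample_ids=clinical.index)
    cohort = Cohort(expr, clinical.loc[expr.index], dataset_id=Path(cfg.expression_path).stem)
    cohort.validate()
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate/load -> discover -> score -> validate -> posttest.

    Returns the result bundle (also written to ``outdir``): classifier,
    per-sample risk profile, evaluation metrics, post-test table and a
    manifest with parameters, seeds and output checksums.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(),
                      "stages": [], "outputs": {}, "complete": False}
    results: dict = {}

    def _fail(stage, exc):
        manifest["stages"].append({"stage": stage, "status": f"failed: {exc!r}"})
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed") from exc

    # --- simulate / load -----------------------------------------------
    try:
        cohort = _load_inputs(config)
        manifest["stages"].append({"stage": "inputs", "status": "ok",
                                   "n_samples": cohort.n_samples})
    except Exception as exc:
        _fail("inputs", exc)

    write_expression(cohort.expression, outdir / "expression.tsv")
    cohort.clinical.to_csv(outdir / "clinical.csv")

    # --- discover ------------------------------------------------------
    try:
        if config.run_discovery:
            sp = StabilityParams(**{**config.stability, "seed": config.seed})
            eligible = exclude_short_followup(cohort, sp.min_followup_years)
            table, classifier, records = stability_select(eligible, sp)
            table.to_csv(outdir / "stability_table.tsv", sep="\t")
            with open(outdir / "iterations.jsonl", "w") as fh:
                for r in records:
                    fh.write(json.dumps({
                        "iteration": r.iteration,
                        "n_train": len(r.train_ids),
                        "n_screened": len(r.screened_genes),
                        "selected": r.selected_genes,
                        "test_auc": None if np.isnan(r.test_auc) else r.test_auc,
                    }) + "\n")
            results["stability_table"] = table
        elif config.classifier_path:
            classifier = read_classifier(config.classifier_path)
        else:
            classifier = PUBLISHED_CLASSIFIER
        manifest["stages"].append({"stage": "discover", "status": "ok",
                                   "genes": classifier.gene_ids})
    except Exception as exc:
        _fail("discover", exc)

    # --- score ---------------------------------------------------------
    try:
        profile = score_cohort(cohort, classifier, cutoff=config.cutoff)
        classifier.cutoff = profile.attrs["cutoff"]
        write_classifier(classifier, outdir / "classifier.json")
        profile.to_csv(outdir / "risk_profile.csv")
        results["classifier"] = classifier
        results["profile"] = profile
        manifest["stages"].append({"stage": "score", "status": "ok",
                                   "cutoff": classifier.cutoff})
    except Exception as exc:
        _fail("score", exc)

    # --- validate ------------------------------------------------------
    metrics: dict = {}
    if config.run_validation:
        try:
            clin = cohort.clinical
            auc, auc_ci = roc_auc(profile["score"], clin["recurrence"])
            metrics["auc"] = auc
            metrics["auc_ci"] = list(auc_ci)
            fit = km_logrank(clin["dfs_time"], clin["dfs_event"], profile["risk_class"])
            metrics["logrank_p"] = fit.logrank_p
            metrics["hr_high_vs_low"] = fit.hr
            metrics["hr_ci"] = list(fit.hr_ci) if fit.hr_ci else None
            metrics["five_year_dfs"] = {g: five_year_rate(fit, g) for g in fit.groups}
            for form in ("dichotomized", "continuous_per_sd"):
                tab = cox_fit(cohort, profile, CoxModelSpec(score_form=form))
                term = tab.index[0]
                metrics[f"cox_{form}"] = {
                    "hr": float(tab.loc[term, "hr"]),
                    "ci": [float(tab.loc[term, "ci_low"]), float(tab.loc[term, "ci_high"])],
                    "p": float(tab.loc[term, "p"]),
                }
            if config.make_plots:
                _plots(outdir, profile, clin, fit)
            manifest["stages"].append({"stage": "validate", "status": "ok"})
        except Exception as exc:
            _fail("validate", exc)
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        results["metrics"] = metrics

    # --- posttest ------------------------------------------------------
    if config.run_posttest:
        try:
            rows = posttest_table(cohort.clinical, profile)
            tab = pd.DataFrame([r.to_row() for r in rows])
            tab.to_csv(outdir / "posttest.csv", index=False)
            results["posttest"] = rows
            manifest["stages"].append({"stage": "posttest", "status": "ok"})
        except Exception as exc:
            _fail("posttest", exc)

    manifest["complete"] = True
    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


def _plots(outdir: Path, profile: pd.DataFrame, clin: pd.DataFrame, fit) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(4, 4))
    fpr, tpr, _ = roc_curve(clin["recurrence"], profile["score"])
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "--", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.savefig(outdir / "roc.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for g, curve in fit.km_curves.items():
        ax.step(curve.index, curve["survival"], where="post", label=str(g))
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("months")
    ax.set_ylabel("disease-free survival")
    ax.legend()
    fig.savefig(outdir / "km.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
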