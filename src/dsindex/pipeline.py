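"""End-to-end analysis pipelines.

``run_dementia_analysis``: cohort (simulated or loaded) -> inclusion
filters -> univariate screening -> Disease State Index fit -> repeated
k-fold cross-validation -> three-level report.  ``run_pathology_analysis``
adds the autopsy branch: outcome derivation from the raw panel, one
screening + model + CV loop per binary outcome, and the centered PCA whose
component scores are evaluated as dementia predictors.

Each run writes machine-readable JSON, a plain-text report and a provenance
record (seed, configuration hash, package versions) sufficient to reproduce
the bundle bit-identically.  Stage boundaries are logged with subject and
factor counts, mirroring the study's accounting flowchart.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import apply_inclusion_filters, read_cohort
from .model import fit_model
from .pathology import OUTCOME_NAMES, derive_outcomes, pc_dementia_auc, run_pca
from .screening import screen_factors
from .synthetic import default_params, generate_cohort, generate_pathology_panel
from .validation import CVConfig, cross_validate, render_report
from .variables import Group, default_hierarchy, load_hierarchy

logger = logging.getLogger(__name__)


class NoFactorsSelected(ValueError):
    """Raised when screening leaves no factors for the model."""

    def __init__(self, message: str, screening_table: pd.DataFrame):
        super().__init__(message)
        self.screening_table = screening_table


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    cohort_path: Optional[str] = None  # None -> simulate with defaults
    hierarchy_path: Optional[str] = None  # None -> default hierarchy
    outcome: str = "outcome"
    alpha: float = 0.05
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 42  # simulation seed (CV uses cv.seed)
    pca_binary: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    # the output location is not an analysis parameter
    d = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    import pandas
    import scipy
    return {
        "dsindex_version": __version__,
        "config": {k: v for k, v in config.to_dict().items()
                   if k != "out_dir"},
        "config_hash": _config_hash(config),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def _write_json(obj, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _load_or_simulate(config: RunConfig, model_kind: str,
                      hierarchy: Group) -> pd.DataFrame:
    if config.cohort_path is not None:
        specs = hierarchy.leaves()
        if model_kind == "pathology":
            from .pathology import panel_variable_specs
            specs = specs + panel_variable_specs()
        table = read_cohort(config.cohort_path, specs)
        logger.info("loaded cohort: %d subjects (%d parse warnings)",
                    len(table), table.warnings)
        return table.data
    params = default_params(model_kind)
    gen = (generate_cohort if model_kind == "dementia"
           else generate_pathology_panel)
    data = gen(params, seed=config.seed)
    logger.info("simulated %s cohort: %d subjects (seed %d)",
                model_kind, len(data), config.seed)
    return data


def run_dementia_analysis(config: RunConfig) -> dict:
    """Run the dementia-prediction pipeline; returns the report bundle."""
    os.makedirs(config.out_dir, exist_ok=True)
    hierarchy = (load_hierarchy(config.hierarchy_path)
                 if config.hierarchy_path else default_hierarchy("dementia"))
    data = _load_or_simulate(config, "dementia", hierarchy)
    filtered, tally = apply_inclusion_filters(data, "dementia")
    screening = screen_factors(filtered, hierarchy, outcome=config.outcome,
                               alpha=config.alpha)
    pruned = screening.pruned_hierarchy()
    if pruned is None:
        raise NoFactorsSelected("no factors selected at alpha="
                                f"{config.alpha}", screening.table)
    result = cross_validate(filtered, pruned, outcome=config.outcome,
                            cv=config.cv)
    model = fit_model(filtered, pruned, outcome=config.outcome)
    doc, text = render_report({"dementia": result})
    bundle = {
        "inclusion": tally,
        "screening": screening.to_dict(),
        "results": doc,
        "provenance": _provenance(config),
    }
    _write_json(bundle["screening"], os.path.join(config.out_dir, "screening.json"))
    _write_json(doc, os.path.join(config.out_dir, "results.json"))
    _write_json(bundle["provenance"], os.path.join(config.out_dir,
                                                   "provenance.json"))
    model.to_json(os.path.join(config.out_dir, "model.json"))
    with open(os.path.join(config.out_dir, "report.txt"), "w",
              encoding="utf-8") as fh:
        fh.write(text)
    return bundle


def run_pathology_analysis(config: RunConfig) -> dict:
    """Run the pathology branch: per-outcome models plus the PCA stage."""
    os.makedirs(config.out_dir, exist_ok=True)
    hierarchy = (load_hierarchy(config.hierarchy_path)
                 if config.hierarchy_path else default_hierarchy("pathology"))
    data = _load_or_simulate(config, "pathology", hierarchy)
    filtered, tally = apply_inclusion_filters(data, "pathology")
    outcomes = derive_outcomes(filtered)
    results, screens, skipped = {}, {}, {}
    for name in OUTCOME_NAMES:
        y = outcomes[name]
        frame = filtered.copy()
        frame["outcome_" + name] = y
        frame = frame.loc[y.notna()]
        n1 = int((y == 1).sum())
        n0 = int((y == 0).sum())
        if n1 < 2 or n0 < 2:
            skipped[name] = f"only {n1} present / {n0} absent subjects"
            logger.warning("outcome %s skipped: %s", name, skipped[name])
            continue
        screening = screen_factors(frame, hierarchy,
                                   outcome="outcome_" + name,
                                   alpha=config.alpha)
        screens[name] = screening.to_dict()
        pruned = screening.pruned_hierarchy()
        if pruned is None:
            skipped[name] = "no significant predictors"
            logger.info("outcome %s: no significant predictors", name)
            continue
        results[name] = cross_validate(frame, pruned,
                                       outcome="outcome_" + name,
                                       cv=config.cv)
    doc, text = (render_report(results) if results
                 else ({}, "no outcome had significant predictors\n"))

    pca_input = outcomes[["amyloid", "tangles", "caa", "macroinfarcts",
                          "microinfarcts", "alpha_synuclein", "hs", "tdp43"]]
    pca = run_pca(pca_input)
    dementia = pd.to_numeric(filtered[config.outcome], errors="coerce")
    pc_auc = pc_dementia_auc(pca, dementia)
    pca_doc = {
        "n_complete": len(pca.index),
        "n_dropped": pca.n_dropped,
        "variance_explained": [float(v) for v in pca.variance_explained],
        "loadings": pca.loadings.round(6).to_dict(orient="index"),
        "dementia_auc": pc_auc.to_dict(orient="records"),
    }
    bundle = {
        "inclusion": tally,
        "screening": screens,
        "skipped": skipped,
        "results": doc,
        "pca": pca_doc,
        "provenance": _provenance(config),
    }
    _write_json(screens, os.path.join(config.out_dir, "screening.json"))
    _write_json({"results": doc, "skipped": skipped},
                os.path.join(config.out_dir, "results.json"))
    _write_json(pca_doc, os.path.join(config.out_dir, "pca.json"))
    _write_json(bundle["provenance"], os.path.join(config.out_dir,
                                                   "provenance.json"))
    with open(os.path.join(config.out_dir, "report.txt"), "w",
              encoding="utf-8") as fh:
        fh.write(text)
        fh.write("\n=== pathology components ===\n")
        fh.write(f"complete cases: {len(pca.index)} "
                 f"({pca.n_dropped} dropped)\n")
        for _, r in pc_auc.iterrows():
            fh.write(f"{r['component']}: variance "
                     f"{r['variance_explained']:.2f}, dementia AUC "
                     f"{r['auc']:.2f}\n")
    return bundle
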