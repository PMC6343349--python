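"""Neuropathology outcome derivation and the pathology-component analysis.

Binary autopsy outcomes are derived from the raw panel with strict "> 0"
rules for the quantitative measures (amyloid load, tangle count, CAA,
macro- and microinfarct counts), staging rules for alpha-synuclein and
hippocampal sclerosis, and the NIA-AA likelihood lookup combining Braak
stage with CERAD score for neuropathological AD (present = intermediate or
high likelihood).

The component analysis is a centered (not variance-scaled) PCA of the
pathology panel in complete cases; each component's subject scores are then
evaluated as dementia predictors by AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .validation import auc

logger = logging.getLogger(__name__)

BRAAK_STAGES = ("0", "I", "II", "III", "IV", "V", "VI")
CERAD_SCORES = ("none", "sparse", "moderate", "frequent")
ALPHA_SYNUCLEIN_STAGES = ("absent", "brainstem", "limbic", "diffuse_neocortical")
HS_SEVERITIES = ("no_minor", "severe_marked_total")

#: raw panel columns (missing entries permitted)
PANEL_COLUMNS = (
    "amyloid_load", "tangle_count", "caa_percent",
    "macroinfarct_count", "cortical_macroinfarct_count",
    "wm_macroinfarct_count", "microinfarct_count",
    "alpha_synuclein", "hs_severity", "tdp43_positive",
    "braak_stage", "cerad_score",
)

#: derived binary outcomes, in reporting order
OUTCOME_NAMES = (
    "amyloid", "tangles", "neuropath_ad", "caa",
    "macroinfarcts", "cortical_macroinfarcts", "wm_macroinfarcts",
    "microinfarcts", "alpha_synuclein", "hs", "tdp43",
)


def panel_variable_specs() -> list:
    """Variable declarations for the raw panel columns (for cohort I/O)."""
    from .variables import VariableSpec
    specs = [VariableSpec(c, "continuous", "panel") for c in (
        "amyloid_load", "tangle_count", "caa_percent", "macroinfarct_count",
        "cortical_macroinfarct_count", "wm_macroinfarct_count",
        "microinfarct_count")]
    specs += [VariableSpec(c, "categorical", "panel") for c in (
        "alpha_synuclein", "hs_severity", "braak_stage", "cerad_score")]
    specs.append(VariableSpec("tdp43_positive", "binary", "panel"))
    return specs


def default_niaaa_matrix() -> dict:
    """Default (Braak stage, CERAD score) -> AD likelihood lookup.

    High likelihood: Braak V-VI with moderate/frequent plaques; intermediate:
    Braak III-IV with moderate/frequent, or Braak V-VI with sparse; all other
    combinations low.  Override by passing a mapping to
    :func:`niaaa_likelihood` / :func:`derive_outcomes`.
    """
    out = {}
    for b in BRAAK_STAGES:
        grp = 0 if b in ("0", "I", "II") else (1 if b in ("III", "IV") else 2)
        for c in CERAD_SCORES:
            if grp == 2 and c in ("moderate", "frequent"):
                lik = "high"
            elif (grp == 1 and c in ("moderate", "frequent")) or \
                    (grp == 2 and c == "sparse"):
                lik = "intermediate"
            else:
                lik = "low"
            out[(b, c)] = lik
    return out


def niaaa_likelihood(braak, cerad, mapping: Optional[dict] = None) -> str:
    """AD likelihood (low/intermediate/high) from Braak stage and CERAD
    score via the configurable lookup matrix."""
    if braak not in BRAAK_STAGES:
        raise ValueError(f"unknown Braak stage {braak!r}")
    if cerad not in CERAD_SCORES:
        raise ValueError(f"unknown CERAD score {cerad!r}")
    return (mapping or default_niaaa_matrix())[(braak, cerad)]


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or \
        (isinstance(v, np.floating) and np.isnan(v))


def _gt_zero(v, name: str):
    if _is_missing(v):
        return float("nan")
    v = float(v)
    if v < 0:
        raise ValueError(f"{name} must be non-negative, got {v}")
    return float(v > 0)


def derive_outcomes(panel: pd.DataFrame,
                    niaaa_mapping: Optional[dict] = None) -> pd.DataFrame:
    """Derive the binary outcome panel from raw pathology measures.

    One column per outcome (0/1, NaN where the required input is missing);
    deterministic and idempotent.  Exactly the value 0 maps to absent for
    the quantitative measures.
    """
    rows = []
    for _, r in panel.iterrows():
        out = {}
        out["amyloid"] = _gt_zero(r.get("amyloid_load"), "amyloid_load")
        out["tangles"] = _gt_zero(r.get("tangle_count"), "tangle_count")
        out["caa"] = _gt_zero(r.get("caa_percent"), "caa_percent")
        out["macroinfarcts"] = _gt_zero(r.get("macroinfarct_count"),
                                        "macroinfarct_count")
        out["cortical_macroinfarcts"] = _gt_zero(
            r.get("cortical_macroinfarct_count"), "cortical_macroinfarct_count")
        out["wm_macroinfarcts"] = _gt_zero(r.get("wm_macroinfarct_count"),
                                           "wm_macroinfarct_count")
        out["microinfarcts"] = _gt_zero(r.get("microinfarct_count"),
                                        "microinfarct_count")
        asyn = r.get("alpha_synuclein")
        if _is_missing(asyn):
            out["alpha_synuclein"] = float("nan")
        elif asyn not in ALPHA_SYNUCLEIN_STAGES:
            raise ValueError(f"unknown alpha-synuclein stage {asyn!r}")
        else:
            out["alpha_synuclein"] = float(asyn != "absent")
        hs = r.get("hs_severity")
        if _is_missing(hs):
            out["hs"] = float("nan")
        elif hs not in HS_SEVERITIES:
            raise ValueError(f"unknown HS severity {hs!r}")
        else:
            out["hs"] = float(hs == "severe_marked_total")
        tdp = r.get("tdp43_positive")
        out["tdp43"] = float("nan") if _is_missing(tdp) else float(bool(tdp))
        braak, cerad = r.get("braak_stage"), r.get("cerad_score")
        if _is_missing(braak) or _is_missing(cerad):
            out["neuropath_ad"] = float("nan")
        else:
            lik = niaaa_likelihood(braak, cerad, niaaa_mapping)
            out["neuropath_ad"] = float(lik in ("intermediate", "high"))
        rows.append(out)
    out_df = pd.DataFrame(rows, index=panel.index)
    return out_df[list(OUTCOME_NAMES)]


@dataclass
class PCAResult:
    """Centered-PCA decomposition of the pathology panel."""

    loadings: pd.DataFrame  # components x variables
    scores: pd.DataFrame  # subjects x components (complete cases only)
    variance_explained: np.ndarray
    n_dropped: int
    index: pd.Index  # retained (complete-case) subject index

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def run_pca(matrix: pd.DataFrame,
            n_components: Optional[int] = None) -> PCAResult:
    """PCA of a subjects-by-variables matrix, centered but not scaled.

    Rows with any missing value are dropped (count reported); the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    X = matrix.apply(pd.to_numeric, errors="coerce")
    complete = X.dropna(axis=0)
    n_dropped = len(X) - len(complete)
    if n_dropped:
        logger.info("PCA: dropped %d incomplete rows (%d retained)",
                    n_dropped, len(complete))
    if len(complete) < 2:
        raise ValueError("PCA needs at least 2 complete rows")
    A = complete.to_numpy(dtype=float)
    A = A - A.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    total = (S ** 2).sum()
    k = len(S) if n_components is None else min(n_components, len(S))
    # deterministic sign: largest |loading| of each component positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(Vt[:k], index=comp_names, columns=complete.columns)
    scores = pd.DataFrame(U[:, :k] * S[:k], index=complete.index,
                          columns=comp_names)
    var_exp = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(loadings=loadings, scores=scores,
                     variance_explained=var_exp,
                     n_dropped=n_dropped, index=complete.index)


def pc_dementia_auc(pca: PCAResult, dementia_labels) -> pd.DataFrame:
    """AUC of each principal-component score as a dementia predictor.

    ``dementia_labels`` must align with the retained complete-case rows
    (either positionally or by sharing the PCA index).  Components whose raw
    AUC falls below 0.5 are flagged ``inverted`` and also reported on the
    oriented scale max(a, 1 - a).
    """
    if isinstance(dementia_labels, pd.Series):
        y = dementia_labels.reindex(pca.index).to_numpy(dtype=float)
    else:
        y = np.asarray(dementia_labels, dtype=float)
        if len(y) != len(pca.index):
            raise ValueError("labels do not align with retained PCA rows")
    if np.isnan(y).any():
        raise ValueError("missing dementia labels for retained rows")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("dementia labels contain a single class")
    rows = []
    for comp in pca.scores.columns:
        a = auc(pca.scores[comp].to_numpy(), y)
        rows.append({"component": comp, "auc": a,
                     "inverted": bool(a < 0.5),
                     "oriented_auc": max(a, 1.0 - a),
                     "variance_explained": float(
                         pca.variance_explained[list(pca.scores.columns).index(comp)])})
    return pd.DataFrame(rows)
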