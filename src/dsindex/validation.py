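"""Model evaluation: rank AUC, operating point at the 0.5 cutoff, and
repeated k-fold cross-validation with per-node reporting.

The published workflow is 10 repeats of 10-fold cross-validation: each
repeat draws a fresh random partition into ten subgroups, nine train the
model and one is scored, and the mean AUC with a 95% interval is taken over
the 100 fold-level values.  Sensitivity and specificity are reported at the
fixed index cutoff 0.5 (score >= cutoff is called a case, matching the
threshold convention of the fitness sweep), averaged across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import fit_model
from .screening import screen_factors
from .variables import Group

logger = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney statistic / (n_case * n_control)).

    Ties count 1/2.  Records with a missing score are dropped; if either
    class is then absent, NaN is returned with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    keep = ~np.isnan(s) & ~np.isnan(y)
    s, y = s[keep], y[keep]
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        logger.warning("AUC undefined: one class absent")
        return float("nan")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def sens_spec_at(scores, labels, cutoff: float = 0.5) -> tuple[float, float]:
    """Sensitivity and specificity calling a case when score >= cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    keep = ~np.isnan(s) & ~np.isnan(y)
    s, y = s[keep], y[keep]
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        logger.warning("sensitivity/specificity undefined: one class absent")
        return float("nan"), float("nan")
    pos = s >= cutoff
    return float(pos[y == 1].mean()), float((~pos)[y == 0].mean())


@dataclass
class CVConfig:
    """Cross-validation settings (defaults follow the 10 x 10-fold design)."""

    k: int = 10
    repeats: int = 10
    seed: int = 0
    stratified: bool = False
    cutoff: float = 0.5
    ci: str = "percentile"  # or "normal"
    nested_screening: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CVResult:
    """Fold-level AUCs per node plus aggregated operating characteristics."""

    config: CVConfig
    node_fold_aucs: dict  # node path -> np.ndarray (k * repeats, NaN = excluded)
    fold_sens: np.ndarray
    fold_spec: np.ndarray
    fold_test_indices: list  # positional test-row indices per fold
    fold_train_indices: list
    root: str = "model"

    @property
    def fold_aucs(self) -> np.ndarray:
        return self.node_fold_aucs[self.root]

    def _ci(self, values: np.ndarray) -> tuple[float, float]:
        v = values[~np.isnan(values)]
        if len(v) == 0:
            return float("nan"), float("nan")
        if self.config.ci == "normal":
            m, se = v.mean(), v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
            return float(m - 1.96 * se), float(m + 1.96 * se)
        lo, hi = np.percentile(v, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.fold_aucs))

    @property
    def ci(self) -> tuple[float, float]:
        return self._ci(self.fold_aucs)

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.fold_sens))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.fold_spec))

    def table(self) -> pd.DataFrame:
        """Three-level table: entire model, each group, each factor."""
        rows = []
        for path, values in self.node_fold_aucs.items():
            depth = path.count("/")
            level = "model" if depth == 0 else ("group" if depth == 1 else "factor")
            lo, hi = self._ci(values)
            row = {"node": path, "level": level,
                   "mean_auc": float(np.nanmean(values)) if
                   np.isfinite(values).any() else float("nan"),
                   "ci_low": lo, "ci_high": hi,
                   "n_folds": int(np.isfinite(values).sum())}
            if depth == 0:
                lo_s, hi_s = self._ci(self.fold_sens)
                lo_p, hi_p = self._ci(self.fold_spec)
                row.update({"sensitivity": self.mean_sensitivity,
                            "sens_ci_low": lo_s, "sens_ci_high": hi_s,
                            "specificity": self.mean_specificity,
                            "spec_ci_low": lo_p, "spec_ci_high": hi_p})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.table()
        lines = [f"{self.config.repeats} x {self.config.k}-fold cross-validation "
                 f"(seed {self.config.seed}, cutoff {self.config.cutoff})",
                 f"{'node':<44}{'AUC [95% CI]':<24}",
                 "-" * 68]
        for _, r in tab.iterrows():
            indent = "  " * r["node"].count("/")
            name = indent + r["node"].split("/")[-1]
            lines.append(f"{name:<44}{r['mean_auc']:.2f} "
                         f"[{r['ci_low']:.2f}-{r['ci_high']:.2f}]")
        lines.append("")
        lines.append(f"sensitivity {self.mean_sensitivity:.2f}  "
                     f"specificity {self.mean_specificity:.2f} "
                     f"at cutoff {self.config.cutoff}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        tab = self.table()
        return {
            "config": {"k": self.config.k, "repeats": self.config.repeats,
                       "seed": self.config.seed,
                       "stratified": self.config.stratified,
                       "cutoff": self.config.cutoff, "ci": self.config.ci},
            "mean_auc": self.mean_auc,
            "ci": list(self.ci),
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "nodes": tab.to_dict(orient="records"),
        }


def _partition(n: int, y: np.ndarray, cv: CVConfig,
               rng: np.random.Generator) -> list[np.ndarray]:
    """One random split of range(n) into k near-equal folds."""
    if not cv.stratified:
        perm = rng.permutation(n)
        return [f for f in np.array_split(perm, cv.k)]
    folds: list[list[int]] = [[] for _ in range(cv.k)]
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for j, part in enumerate(np.array_split(idx, cv.k)):
            folds[j].extend(part.tolist())
    return [np.asarray(f, dtype=int) for f in folds]


def cross_validate(data: pd.DataFrame, hierarchy: Group,
                   outcome: str = "outcome",
                   cv: Optional[CVConfig] = None) -> CVResult:
    """Repeated k-fold cross-validation of a DSI model.

    Each repeat draws a fresh seeded partition; the model is refitted on the
    k-1 training folds and the held-out fold is scored at every node.  A
    fold whose test split lacks one class is excluded from aggregation with
    a warning.  With ``cv.nested_screening`` the factor screening is redone
    inside each training fold and the fold's model uses only the factors
    selected there.
    """
    cv = cv or CVConfig()
    y = pd.to_numeric(data[outcome], errors="coerce").to_numpy()
    n = len(data)
    n_cases, n_controls = int((y == 1).sum()), int((y == 0).sum())
    if n_cases < cv.k or n_controls < cv.k:
        logger.warning("fewer than k=%d subjects in a class (%d cases, "
                       "%d controls); folds may lack a class",
                       cv.k, n_cases, n_controls)
    rng = np.random.default_rng(cv.seed)

    paths = [p for p, _ in _walk_paths(hierarchy)]
    node_aucs: dict[str, list[float]] = {p: [] for p in paths}
    fold_sens, fold_spec = [], []
    test_record, train_record = [], []

    for _rep in range(cv.repeats):
        folds = _partition(n, y, cv, rng)
        for test_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            train = data.iloc[train_mask.nonzero()[0]]
            test = data.iloc[test_idx]
            y_train, y_test = y[train_mask], y[test_idx]
            test_record.append(np.sort(test_idx))
            train_record.append(np.flatnonzero(train_mask))
            if (y_train == 1).sum() == 0 or (y_train == 0).sum() == 0:
                logger.warning("fold skipped: training split lacks a class")
                for p in paths:
                    node_aucs[p].append(float("nan"))
                fold_sens.append(float("nan"))
                fold_spec.append(float("nan"))
                continue
            fold_tree = hierarchy
            if cv.nested_screening:
                pruned = screen_factors(train, hierarchy, outcome=outcome,
                                        alpha=cv.alpha).pruned_hierarchy()
                fold_tree = pruned if pruned is not None else hierarchy
            model = fit_model(train, fold_tree, outcome=outcome)
            scores = model.score_nodes(test)
            if (y_test == 1).sum() == 0 or (y_test == 0).sum() == 0:
                logger.warning("fold excluded from metrics: test split lacks "
                               "a class")
                for p in paths:
                    node_aucs[p].append(float("nan"))
                fold_sens.append(float("nan"))
                fold_spec.append(float("nan"))
                continue
            scored = set(scores.columns)
            for p in paths:
                node_aucs[p].append(auc(scores[p].to_numpy(), y_test)
                                    if p in scored else float("nan"))
            se, sp = sens_spec_at(scores[hierarchy.name].to_numpy(),
                                  y_test, cv.cutoff)
            fold_sens.append(se)
            fold_spec.append(sp)

    return CVResult(config=cv,
                    node_fold_aucs={p: np.asarray(v, dtype=float)
                                    for p, v in node_aucs.items()},
                    fold_sens=np.asarray(fold_sens, dtype=float),
                    fold_spec=np.asarray(fold_spec, dtype=float),
                    fold_test_indices=test_record,
                    fold_train_indices=train_record,
                    root=hierarchy.name)


def _walk_paths(group: Group, prefix: str = ""):
    from .variables import Group as G
    path = group.name if prefix == "" else f"{prefix}/{group.name}"
    yield path, group
    for m in group.members:
        if isinstance(m, G):
            yield from _walk_paths(m, path)
        else:
            yield f"{path}/{m.name}", m


def render_report(results: dict) -> tuple[dict, str]:
    """Render a map of outcome -> CVResult as (JSON document, text tables)."""
    if not results:
        raise ValueError("no results to report")
    doc = {outcome: res.to_dict() for outcome, res in results.items()}
    blocks = []
    for outcome, res in results.items():
        blocks.append(f"=== {outcome} ===")
        blocks.append(res.summary())
        blocks.append("")
    return doc, "\n".join(blocks)
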