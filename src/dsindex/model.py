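"""The Disease State Index model: relevance-weighted hierarchical scoring.

Individual factors are combined into a concept-group value through a
weighted average of their fitness values, with relevance values as weights;
the same rule is applied recursively to combine group values into the total
index.  Missing values are simply dropped from the average, so a subject is
scored from whatever measurements are available; the score is missing only
when every leaf is missing.

The public surface follows the model/results convention: build a
:class:`DiseaseStateIndex` from a cohort table and a hierarchy, call
:meth:`~DiseaseStateIndex.fit` to obtain :class:`DSIResults`, and use the
results object for scoring, inspection and serialization.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .factor import FactorModel, fit_factor, max_youden
from .variables import Group, VariableSpec

logger = logging.getLogger(__name__)


def aggregate_group(values: Sequence, relevances: Sequence) -> float:
    """Relevance-weighted mean of child values, ignoring missing entries.

    Returns NaN when every child is missing.  If every non-missing child has
    relevance 0, the unweighted mean of the non-missing children is used.
    Negative relevances are rejected.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(relevances, dtype=float)
    if len(v) != len(w):
        raise ValueError("values and relevances must have equal length")
    if (w < 0).any():
        raise ValueError("negative relevance")
    return float(_aggregate_matrix(v[:, None], w)[0])


def _aggregate_matrix(V: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Column-wise weighted mean of ``V`` (children x records) with weights
    ``w``, skipping NaNs; zero total weight falls back to unweighted mean."""
    if (w < 0).any():
        raise ValueError("negative relevance")
    present = ~np.isnan(V)
    Vz = np.where(present, V, 0.0)
    W = np.where(present, w[:, None], 0.0)
    wsum = W.sum(axis=0)
    nsum = present.sum(axis=0)
    out = np.full(V.shape[1], np.nan)
    weighted = wsum > 0
    # normalise weights first: robust to very small relevance values
    Wn = np.divide(W, np.where(weighted, wsum, 1.0)[None, :])
    out[weighted] = (Vz * Wn).sum(axis=0)[weighted]
    fallback = (~weighted) & (nsum > 0)
    if fallback.any():
        out[fallback] = Vz.sum(axis=0)[fallback] / nsum[fallback]
    return out


@dataclass
class GroupNode:
    """A fitted node of the hierarchy: children plus the node's relevance."""

    name: str
    children: list  # GroupNode | FactorModel
    relevance: float

    def walk(self, prefix: str = ""):
        path = self.name if prefix == "" else f"{prefix}/{self.name}"
        yield path, self
        for c in self.children:
            if isinstance(c, GroupNode):
                yield from c.walk(path)
            else:
                yield f"{path}/{c.spec.name}", c

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "relevance": self.relevance,
            "children": [c.to_dict() if isinstance(c, GroupNode)
                         else {"factor": c.to_dict()} for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupNode":
        children = []
        for c in d["children"]:
            if "factor" in c:
                children.append(FactorModel.from_dict(c["factor"]))
            else:
                children.append(cls.from_dict(c))
        return cls(name=d["name"], relevance=float(d["relevance"]),
                   children=children)


class DSIModel:
    """A fitted Disease State Index hierarchy."""

    def __init__(self, root: GroupNode):
        self.root = root

    # -- scoring -----------------------------------------------------------
    def _node_values(self, node, data: pd.DataFrame) -> np.ndarray:
        if isinstance(node, FactorModel):
            name = node.spec.name
            if name not in data.columns:
                return np.full(len(data), np.nan)
            return node.fitness_array(data[name].to_numpy())
        child_vals = [self._node_values(c, data) for c in node.children]
        rels = np.asarray([c.relevance for c in node.children], dtype=float)
        return _aggregate_matrix(np.vstack(child_vals), rels)

    def score(self, data: pd.DataFrame) -> pd.Series:
        """Total index in [0, 1] per record (NaN if every leaf missing).

        Extra columns in ``data`` are ignored.
        """
        return pd.Series(self._node_values(self.root, data),
                         index=data.index, name="dsi")

    def score_nodes(self, data: pd.DataFrame) -> pd.DataFrame:
        """Index value of every node (total, each group, each leaf fitness)."""
        out = {}
        for path, node in self.root.walk():
            out[path] = self._node_values(node, data)
        return pd.DataFrame(out, index=data.index)

    # -- inspection --------------------------------------------------------
    def relevance_table(self) -> pd.DataFrame:
        rows = []
        for path, node in self.root.walk():
            if isinstance(node, FactorModel):
                rows.append({"node": path, "level": "factor",
                             "kind": node.spec.kind,
                             "orientation": node.orientation,
                             "relevance": node.relevance})
            else:
                level = "model" if path == self.root.name else "group"
                rows.append({"node": path, "level": level, "kind": "",
                             "orientation": "", "relevance": node.relevance})
        return pd.DataFrame(rows)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: Optional[str] = None) -> str:
        doc = json.dumps({"format": "dsindex-model", "version": 1,
                          "root": self.root.to_dict()}, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, source: str) -> "DSIModel":
        try:
            doc = json.loads(source)
        except (json.JSONDecodeError, ValueError):
            with open(source, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
        else:
            if isinstance(doc, str):  # a path that happened to parse
                with open(doc, "r", encoding="utf-8") as fh:
                    doc = json.load(fh)
        return cls(GroupNode.from_dict(doc["root"]))


def _fit_node(group: Group, cases: pd.DataFrame, controls: pd.DataFrame
              ) -> tuple[GroupNode, np.ndarray, np.ndarray]:
    """Fit one hierarchy node; returns the node plus its aggregated training
    values for cases and controls (used for the parent's relevance)."""
    children, case_vals, ctrl_vals, rels = [], [], [], []
    for m in group.members:
        if isinstance(m, Group):
            child, cv, kv = _fit_node(m, cases, controls)
        else:
            child = fit_factor(cases[m.name].to_numpy(),
                               controls[m.name].to_numpy(), m)
            cv = child.fitness_array(cases[m.name].to_numpy())
            kv = child.fitness_array(controls[m.name].to_numpy())
        children.append(child)
        case_vals.append(cv)
        ctrl_vals.append(kv)
        rels.append(child.relevance)
    rels = np.asarray(rels, dtype=float)
    agg_cases = _aggregate_matrix(np.vstack(case_vals), rels)
    agg_ctrls = _aggregate_matrix(np.vstack(ctrl_vals), rels)
    ok_c, ok_k = agg_cases[~np.isnan(agg_cases)], agg_ctrls[~np.isnan(agg_ctrls)]
    if len(ok_c) == 0 or len(ok_k) == 0:
        logger.warning("group %s: a class has no scorable training records; "
                       "relevance set to 0", group.name)
        relevance = 0.0
    else:
        relevance, _ = max_youden(ok_c, ok_k)
    node = GroupNode(name=group.name, children=children, relevance=relevance)
    return node, agg_cases, agg_ctrls


def fit_model(data: pd.DataFrame, hierarchy: Group,
              outcome: str = "outcome") -> DSIModel:
    """Fit a DSI model: every leaf factor, then each group's relevance from
    its aggregated training values, recursively up to the root."""
    hierarchy.validate()
    missing = [s.name for s in hierarchy.leaves() if s.name not in data.columns]
    if missing:
        raise ValueError(f"hierarchy references absent columns: {missing}")
    y = pd.to_numeric(data[outcome], errors="coerce")
    cases = data.loc[y == 1]
    controls = data.loc[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("training data must contain both cases and controls")
    root, _, _ = _fit_node(hierarchy, cases, controls)
    return DSIModel(root)


class DiseaseStateIndex:
    """Disease State Index model bound to a cohort table and a hierarchy.

    Parameters
    ----------
    data
        Subject-by-variable table including the binary outcome column.
    hierarchy
        Concept-group tree of :class:`~dsindex.variables.VariableSpec`
        leaves; every leaf must name a column of ``data``.
    outcome
        Name of the 0/1 outcome column (default ``"outcome"``).
    """

    def __init__(self, data: pd.DataFrame, hierarchy: Group,
                 outcome: str = "outcome"):
        if outcome not in data.columns:
            raise ValueError(f"outcome column {outcome!r} not in data")
        self.data = data
        self.hierarchy = hierarchy
        self.outcome = outcome

    @classmethod
    def from_csv(cls, cohort_path: str, hierarchy_path: str,
                 outcome: str = "outcome") -> "DiseaseStateIndex":
        from .cohort import read_cohort
        from .variables import load_hierarchy
        hierarchy = load_hierarchy(hierarchy_path)
        table = read_cohort(cohort_path, hierarchy.leaves())
        return cls(table.data, hierarchy, outcome=outcome)

    def fit(self) -> "DSIResults":
        model = fit_model(self.data, self.hierarchy, outcome=self.outcome)
        return DSIResults(self, model)

    def cross_validate(self, cv=None) -> "CVResult":  # noqa: F821
        from .validation import CVConfig, cross_validate
        return cross_validate(self.data, self.hierarchy,
                              outcome=self.outcome,
                              cv=cv if cv is not None else CVConfig())


class DSIResults:
    """Results of fitting a :class:`DiseaseStateIndex`.

    Carries the fitted hierarchy, per-node relevances and in-sample scores;
    :meth:`score` applies the model to new records.
    """

    def __init__(self, model_spec: DiseaseStateIndex, model: DSIModel):
        self.model_spec = model_spec
        self.model = model

    @property
    def relevance_table(self) -> pd.DataFrame:
        return self.model.relevance_table()

    def score(self, data: Optional[pd.DataFrame] = None) -> pd.Series:
        if data is None:
            data = self.model_spec.data
        return self.model.score(data)

    def score_nodes(self, data: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        if data is None:
            data = self.model_spec.data
        return self.model.score_nodes(data)

    def training_auc(self) -> float:
        from .validation import auc
        y = pd.to_numeric(self.model_spec.data[self.model_spec.outcome],
                          errors="coerce")
        return auc(self.score().to_numpy(), y.to_numpy())

    def summary(self) -> str:
        buf = io.StringIO()
        tab = self.relevance_table
        n = len(self.model_spec.data)
        y = pd.to_numeric(self.model_spec.data[self.model_spec.outcome],
                          errors="coerce")
        buf.write("Disease State Index model\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"subjects: {n}  cases: {int((y == 1).sum())}  "
                  f"controls: {int((y == 0).sum())}\n")
        buf.write(f"training AUC: {self.training_auc():.3f}\n\n")
        buf.write(f"{'node':<42}{'level':<8}{'relevance':>10}\n")
        buf.write("-" * 60 + "\n")
        for _, row in tab.iterrows():
            buf.write(f"{row['node']:<42}{row['level']:<8}"
                      f"{row['relevance']:>10.3f}\n")
        return buf.getvalue()

    def save(self, path: str) -> None:
        self.model.to_json(path)
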