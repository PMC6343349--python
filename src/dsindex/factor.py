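"""Per-factor fitness curves and relevance values.

The fitness function of a factor evaluates, at each observed measurement
value ``x`` used as a classification threshold, the share of false-negative
errors among all errors, ``f(x) = FN / (FN + FP)``.  Values seen only among
controls get fitness 0 and values seen only among cases get fitness 1, so a
subject's fitness reads as similarity to the case distribution.

Relevance is the Youden index ``max_t sensitivity(t) + specificity(t) - 1``
over the same threshold sweep, taken over both possible orientations
(cases tending high or low).  Identical case/control distributions give
relevance 0; disjoint distributions give relevance 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .variables import VariableSpec

logger = logging.getLogger(__name__)

MISSING = float("nan")

Number = Union[int, float]


def _clean(values: Sequence) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def _orientation_curves(cases: np.ndarray, controls: np.ndarray,
                        support: np.ndarray, orientation: str):
    """Return (youden, fn, fp) arrays over ``support`` thresholds.

    Tie convention: for ``cases_high`` a subject is classified as a case iff
    its value >= threshold (mirrored for ``cases_low``), so the threshold
    value itself sits on the case side.
    """
    cs = np.sort(cases)
    ks = np.sort(controls)
    n1, n0 = len(cs), len(ks)
    if orientation == "cases_high":
        cases_ge = n1 - np.searchsorted(cs, support, side="left")
        ctrl_ge = n0 - np.searchsorted(ks, support, side="left")
        sens = cases_ge / n1
        spec = (n0 - ctrl_ge) / n0
        fn = n1 - cases_ge
        fp = ctrl_ge
    elif orientation == "cases_low":
        cases_le = np.searchsorted(cs, support, side="right")
        ctrl_le = np.searchsorted(ks, support, side="right")
        sens = cases_le / n1
        spec = (n0 - ctrl_le) / n0
        fn = n1 - cases_le
        fp = ctrl_le
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown orientation {orientation!r}")
    return sens + spec - 1.0, fn.astype(float), fp.astype(float)


def max_youden(case_values: Sequence[Number],
               control_values: Sequence[Number]) -> tuple[float, str]:
    """Maximum Youden index over all observed thresholds and orientations.

    Returns ``(relevance, orientation)``; ties between orientations resolve
    to ``cases_high``.
    """
    cases = _clean(case_values)
    controls = _clean(control_values)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes need at least one non-missing value")
    support = np.unique(np.concatenate([cases, controls]))
    j_high, _, _ = _orientation_curves(cases, controls, support, "cases_high")
    j_low, _, _ = _orientation_curves(cases, controls, support, "cases_low")
    hi, lo = float(j_high.max()), float(j_low.max())
    if hi >= lo:
        return max(hi, 0.0), "cases_high"
    return max(lo, 0.0), "cases_low"


@dataclass
class FactorModel:
    """Fitted fitness curve and relevance for a single factor.

    For continuous/ordinal factors ``support`` holds the sorted distinct
    training values and ``fitness_at_support`` the fitness at each; scoring
    interpolates linearly between support points and clamps beyond the
    extremes.  For binary/categorical factors ``support`` holds the observed
    categories and fitness is a per-category value.
    """

    spec: VariableSpec
    orientation: str  # cases_high | cases_low | per_category
    support: np.ndarray
    fitness_at_support: np.ndarray
    relevance: float
    n_cases: int = 0
    n_controls: int = 0
    _warned_categories: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.relevance <= 1.0):
            raise ValueError(f"relevance {self.relevance} outside [0, 1]")
        fit = np.asarray(self.fitness_at_support, dtype=float)
        ok = fit[~np.isnan(fit)]
        if len(ok) and (ok.min() < -1e-12 or ok.max() > 1 + 1e-12):
            raise ValueError("fitness values outside [0, 1]")
        if len(self.support) == 0:
            raise ValueError("empty support")

    # -- scoring -----------------------------------------------------------
    def fitness(self, x) -> float:
        """Fitness of a single value ``x`` (NaN for missing/unseen)."""
        return float(self.fitness_array(np.asarray([x], dtype=object))[0])

    def fitness_array(self, values) -> np.ndarray:
        """Vectorised fitness for a sequence of raw values."""
        if self.orientation == "per_category":
            lut = {c: f for c, f in zip(self.support.tolist(),
                                        self.fitness_at_support.tolist())}
            out = np.full(len(values), np.nan)
            unseen = set()
            for i, v in enumerate(np.asarray(values, dtype=object)):
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    continue
                key = _category_key(v)
                if key in lut:
                    out[i] = lut[key]
                else:
                    unseen.add(key)
            new = unseen - self._warned_categories
            if new:
                self._warned_categories |= new
                logger.warning(
                    "factor %s: unseen categories treated as missing: %s",
                    self.spec.name, sorted(map(str, new)))
            return out
        arr = np.asarray(values, dtype=float)
        out = np.full(arr.shape, np.nan)
        mask = ~np.isnan(arr)
        out[mask] = np.interp(arr[mask],
                              self.support.astype(float),
                              self.fitness_at_support.astype(float))
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.spec.name,
            "kind": self.spec.kind,
            "group": self.spec.group,
            "orientation": self.orientation,
            "support": self.support.tolist(),
            "fitness_at_support": self.fitness_at_support.tolist(),
            "relevance": self.relevance,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModel":
        spec = VariableSpec(name=d["name"], kind=d["kind"], group=d.get("group", ""))
        support = np.asarray(d["support"],
                             dtype=object if d["orientation"] == "per_category"
                             else float)
        return cls(spec=spec, orientation=d["orientation"], support=support,
                   fitness_at_support=np.asarray(d["fitness_at_support"], float),
                   relevance=float(d["relevance"]),
                   n_cases=int(d.get("n_cases", 0)),
                   n_controls=int(d.get("n_controls", 0)))


def _category_key(v):
    """Canonical dict key for a category value (so 1 and 1.0 match)."""
    if isinstance(v, (bool, np.bool_)):
        return float(v)
    if isinstance(v, (int, float, np.integer, np.floating)):
        return float(v)
    return str(v)


def _fit_numeric(cases: np.ndarray, controls: np.ndarray,
                 spec: VariableSpec) -> FactorModel:
    support = np.unique(np.concatenate([cases, controls]))
    j_high, fn_h, fp_h = _orientation_curves(cases, controls, support, "cases_high")
    j_low, fn_l, fp_l = _orientation_curves(cases, controls, support, "cases_low")
    if float(j_high.max()) >= float(j_low.max()):
        orientation, j, fn, fp = "cases_high", j_high, fn_h, fp_h
    else:
        orientation, j, fn, fp = "cases_low", j_low, fn_l, fp_l
    denom = fn + fp
    # a perfectly separating threshold has FN = FP = 0; the threshold value
    # then lies on the case side of the rule, hence fitness 1
    fitness = np.where(denom > 0, np.divide(fn, np.where(denom > 0, denom, 1.0)), 1.0)
    return FactorModel(spec=spec, orientation=orientation, support=support,
                       fitness_at_support=fitness,
                       relevance=max(float(j.max()), 0.0),
                       n_cases=len(cases), n_controls=len(controls))


def _fit_categorical(case_values, control_values, spec: VariableSpec) -> FactorModel:
    cases = [_category_key(v) for v in case_values
             if v is not None and not (isinstance(v, float) and math.isnan(v))]
    controls = [_category_key(v) for v in control_values
                if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not cases or not controls:
        raise ValueError(
            f"factor {spec.name!r}: one class has no non-missing values")
    categories = sorted(set(cases) | set(controls), key=str)
    n1, n0 = len(cases), len(controls)
    fitness = []
    for c in categories:
        p1 = cases.count(c) / n1
        p0 = controls.count(c) / n0
        fitness.append(p1 / (p1 + p0) if (p1 + p0) > 0 else np.nan)
    fitness = np.asarray(fitness, dtype=float)
    # relevance: Youden index of "predict case iff fitness(value) > 0.5"
    case_side = fitness > 0.5
    sens = sum(cases.count(c) for c, hit in zip(categories, case_side) if hit) / n1
    spec_ = sum(controls.count(c) for c, hit in zip(categories, case_side) if not hit) / n0
    relevance = max(sens + spec_ - 1.0, 0.0)
    return FactorModel(spec=spec, orientation="per_category",
                       support=np.asarray(categories, dtype=object),
                       fitness_at_support=fitness, relevance=relevance,
                       n_cases=n1, n_controls=n0)


def fit_factor(case_values: Sequence, control_values: Sequence,
               spec: VariableSpec) -> FactorModel:
    """Fit the fitness curve and relevance of one factor.

    Missing values (NaN/None) are dropped per class; a class left empty is
    an error.  Continuous and ordinal factors use the threshold sweep with
    the data-chosen orientation; binary and categorical factors get
    per-category fitness ``p_case / (p_case + p_control)``.
    """
    if spec.kind in ("binary", "categorical"):
        return _fit_categorical(case_values, control_values, spec)
    cases = _clean(case_values)
    controls = _clean(control_values)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError(
            f"factor {spec.name!r}: one class has no non-missing values")
    return _fit_numeric(cases, controls, spec)


def fitness_value(model: FactorModel, x) -> float:
    """Fitness of value ``x`` under a fitted factor model (see
    :meth:`FactorModel.fitness`)."""
    return model.fitness(x)
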