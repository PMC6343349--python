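"""Univariate factor screening before model building.

Only factors differing between outcome groups at p < alpha (default 0.05)
enter the final model: continuous and ordinal factors are compared with the
Mann-Whitney U test, binary and categorical ones with the Pearson chi-square
test on the observed contingency table.  No multiple-testing correction is
applied.  APOE carrier binaries inherit their selection from the single
full-genotype chi-square test, so the genotype block contributes one
p-value.

Screening is performed once on the full analysis population before
cross-validation, mirroring the published workflow; ``nested=True`` in
:func:`dsindex.validation.cross_validate` repeats it inside each training
fold for leak-free estimates.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variables import Group, VariableSpec

logger = logging.getLogger(__name__)

#: combined sample size at or below which the exact permutation null is used
EXACT_N = 10


def _tie_adjusted_u(case_mask: np.ndarray, pooled: np.ndarray) -> float:
    """Mann-Whitney U of the case group (ties counted 1/2)."""
    cases = pooled[case_mask]
    controls = pooled[~case_mask]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return float(wins) + 0.5 * float(ties)


def mann_whitney_p(values_cases: Sequence, values_controls: Sequence) -> float:
    """Two-sided Mann-Whitney U p-value with tie handling.

    For combined n <= 10 the exact permutation distribution of U is
    enumerated over all case/control assignments of the pooled values;
    larger samples use the tie-corrected normal approximation.
    """
    cases = np.asarray(values_cases, dtype=float)
    controls = np.asarray(values_controls, dtype=float)
    cases = cases[~np.isnan(cases)]
    controls = controls[~np.isnan(controls)]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("a group is empty after removing missing values")
    n1, n0 = len(cases), len(controls)
    if n1 + n0 <= EXACT_N:
        pooled = np.concatenate([cases, controls])
        n = n1 + n0
        mu = n1 * n0 / 2.0
        obs_mask = np.zeros(n, dtype=bool)
        obs_mask[:n1] = True
        dev_obs = abs(_tie_adjusted_u(obs_mask, pooled) - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            total += 1
            if abs(_tie_adjusted_u(mask, pooled) - mu) >= dev_obs - 1e-12:
                hits += 1
        return hits / total
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(cases, controls, alternative="two-sided",
                                 method="asymptotic")
    return float(res.pvalue)


def chi_square_p(table) -> float:
    """Pearson chi-square p-value (no continuity correction).

    Rows/columns with zero marginal are dropped; a table degenerate after
    dropping (a single row or column) yields p = 1 with a warning.
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if t.sum() <= 0:
        raise ValueError("contingency table has zero total")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        logger.warning("degenerate contingency table %s; p set to 1", t.shape)
        return 1.0
    _, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(p)


@dataclass
class ScreeningResult:
    """Per-factor screening outcome and the pruned hierarchy."""

    table: pd.DataFrame  # name, group, test, p_value, selected, reason
    alpha: float
    hierarchy: Group

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "name"])

    def pruned_hierarchy(self) -> Optional[Group]:
        """Hierarchy restricted to selected factors; empty groups pruned.

        Returns ``None`` when nothing was selected.
        """
        return self.hierarchy.prune(set(self.selected))

    def to_dict(self) -> dict:
        return {"alpha": self.alpha,
                "factors": self.table.to_dict(orient="records")}


def _factor_p(data: pd.DataFrame, spec: VariableSpec, y: pd.Series
              ) -> tuple[str, float, str]:
    """Return (test_name, p_value, failure_reason) for one factor."""
    col = data[spec.name]
    if spec.kind in ("continuous", "ordinal"):
        vals = pd.to_numeric(col, errors="coerce")
        try:
            p = mann_whitney_p(vals[y == 1], vals[y == 0])
        except ValueError as e:
            return "mann_whitney", float("nan"), str(e)
        return "mann_whitney", p, ""
    mask = col.notna()
    if mask.sum() == 0 or (y[mask] == 1).sum() == 0 or (y[mask] == 0).sum() == 0:
        return "chi_square", float("nan"), "a group is empty after removing missing values"
    tab = pd.crosstab(col[mask].astype(str), y[mask])
    return "chi_square", chi_square_p(tab.to_numpy()), ""


def screen_factors(data: pd.DataFrame, hierarchy: Group,
                   outcome: str = "outcome",
                   alpha: float = 0.05) -> ScreeningResult:
    """Screen every factor of the hierarchy against the outcome.

    A factor whose ``screen_with`` points at another variable inherits that
    variable's test result.  Factors whose test fails (e.g. a class entirely
    missing) are recorded as unselected with the reason.
    """
    y = pd.to_numeric(data[outcome], errors="coerce")
    if y.isna().any():
        raise ValueError("outcome must be present (0/1) for every subject")
    specs = hierarchy.leaves()
    cache: dict[str, tuple[str, float, str]] = {}
    by_name = {s.name: s for s in specs}

    def result_for(name: str) -> tuple[str, float, str]:
        if name not in cache:
            cache[name] = _factor_p(data, by_name[name], y)
        return cache[name]

    rows = []
    for spec in specs:
        source = spec.screen_with if (spec.screen_with and
                                      spec.screen_with in by_name and
                                      spec.screen_with in data.columns) \
            else spec.name
        test, p, reason = result_for(source)
        selected = bool(p < alpha) if not np.isnan(p) else False
        rows.append({"name": spec.name, "group": spec.group, "test": test,
                     "p_value": p, "selected": selected,
                     "screened_via": source if source != spec.name else "",
                     "reason": reason})
    table = pd.DataFrame(rows)
    logger.info("screening: %d/%d factors selected at alpha=%g",
                int(table["selected"].sum()), len(table), alpha)
    return ScreeningResult(table=table, alpha=alpha, hierarchy=hierarchy)
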