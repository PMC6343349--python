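"""Synthetic oldest-old cohort generation.

The generator emulates the statistical structure of the study population:
baseline variables drawn per outcome group from the published group means,
SDs and proportions; APOE genotypes from the published genotype tables;
exact class counts; the printed per-variable missing-data counts; and a
pathology panel whose amyloid/tangle/CAA presence, Braak/CERAD-derived AD
likelihood and dementia-at-death share one latent AD-severity factor
(Gaussian threshold model), so the qualitative co-occurrence structure of
the autopsy findings is reproduced without claiming the real cohort's joint
covariance.

Continuous variables are truncated normals on the instruments' hard ranges;
the pre-truncation location is moment-matched so the *truncated* mean hits
the published group mean.  Ordinal scales are the same draw rounded onto
the discrete support (the small rounding bias is accepted).  Predictors are
independent within group by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import APOE_GENOTYPES, add_apoe_columns
from .pathology import (ALPHA_SYNUCLEIN_STAGES, BRAAK_STAGES, CERAD_SCORES,
                        default_niaaa_matrix)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TruncNormalVar:
    """Truncated-normal variable with per-group mean/SD on [lo, hi]."""
    name: str
    kind: str  # continuous | ordinal
    case: tuple[float, float]  # (mean, sd)
    control: tuple[float, float]
    lo: float
    hi: float

    def validate(self) -> None:
        for mean, sd in (self.case, self.control):
            if sd < 0:
                raise ValueError(f"{self.name}: negative sd")
            if not (self.lo <= mean <= self.hi):
                raise ValueError(
                    f"{self.name}: target mean {mean} outside [{self.lo}, {self.hi}]")
        if self.lo >= self.hi:
            raise ValueError(f"{self.name}: infeasible truncation range")


@dataclass(frozen=True)
class BernoulliVar:
    name: str
    case: float
    control: float
    kind: str = "binary"

    def validate(self) -> None:
        for p in (self.case, self.control):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{self.name}: probability {p} outside [0, 1]")


@dataclass(frozen=True)
class CategoricalVar:
    name: str
    levels: tuple
    case: tuple  # probability vector
    control: tuple
    kind: str = "categorical"

    def validate(self) -> None:
        for p in (self.case, self.control):
            if len(p) != len(self.levels):
                raise ValueError(f"{self.name}: probability vector length mismatch")
            if any(x < 0 or x > 1 for x in p):
                raise ValueError(f"{self.name}: probabilities outside [0, 1]")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: probabilities must sum to 1")


@dataclass
class PathologySection:
    """Targets and couplings for the autopsy panel."""
    prevalence: dict = field(default_factory=dict)  # outcome -> target
    ad_coupling: float = 0.6  # pairwise latent corr of amyloid/tangles/CAA
    dementia_coupling: float = 0.6
    asyn_split: tuple = (0.40, 0.37, 0.23)  # brainstem/limbic/diffuse | present
    #: lognormal (meanlog, sdlog) of the quantitative magnitude when present
    magnitudes: dict = field(default_factory=lambda: {
        "amyloid_load": (math.log(0.12), 0.7),
        "tangle_count": (math.log(3.0), 0.8),
        "caa_percent": (math.log(20.0), 0.7),
    })
    #: genotype distributions conditional on neuropathological AD (from the
    #: published absent/present genotype tables)
    genotype_by_ad: dict = field(default_factory=lambda: {
        0: (0, 17, 2, 59, 6, 0),
        1: (0, 5, 2, 45, 23, 0),
    })


@dataclass
class SyntheticParams:
    """Full specification of a synthetic cohort."""
    model_kind: str
    n_cases: int
    n_controls: int
    variables: list
    missing_counts: dict = field(default_factory=dict)
    n_died_within_2y: int = 0
    n_baseline_dementia: int = 0
    follow_up: TruncNormalVar = None
    pathology: Optional[PathologySection] = None

    @property
    def n_included(self) -> int:
        return self.n_cases + self.n_controls

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("negative class count")
        for v in self.variables:
            v.validate()
        if self.pathology is not None:
            for k, p in self.pathology.prevalence.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prevalence {k}={p} outside [0, 1]")


def _table1_variables() -> list:
    """Baseline variable distributions of the dementia-prediction population
    (control group = no dementia at death, case group = dementia at death)."""
    t = TruncNormalVar
    b = BernoulliVar
    return [
        t("age", "continuous", (88.3, 2.6), (88.4, 2.6), 85.0, 106.0),
        b("male", 0.20, 0.22),
        t("education_years", "continuous", (3.7, 2.0), (4.6, 3.3), 0.0, 20.0),
        t("social_class", "ordinal", (6.2, 1.3), (6.0, 1.5), 1.0, 10.0),
        t("mmse_total", "continuous", (22.2, 4.5), (25.3, 3.3), 0.0, 30.0),
        t("mmse_orientation", "ordinal", (8.7, 1.6), (9.5, 0.8), 0.0, 10.0),
        t("mmse_wordlist", "ordinal", (4.2, 1.3), (5.0, 1.1), 0.0, 6.0),
        t("mmse_calculation", "ordinal", (2.9, 1.6), (3.4, 1.6), 0.0, 5.0),
        t("mmse_other", "ordinal", (6.7, 1.4), (7.4, 1.2), 0.0, 9.0),
        t("spmsq_errors", "ordinal", (1.8, 1.9), (0.8, 1.4), 0.0, 10.0),
        t("adl_sum", "continuous", (31.6, 10.1), (29.7, 10.2), 0.0, 80.0),
        t("competence_daily", "ordinal", (3.2, 1.4), (2.6, 1.3), 1.0, 6.0),
        t("memory_decline", "ordinal", (1.9, 0.7), (1.7, 0.6), 1.0, 3.0),
        CategoricalVar("apoe_genotype", APOE_GENOTYPES,
                       case=_norm((0, 18, 5, 53, 18, 1)),
                       control=_norm((0, 17, 1, 101, 27, 0))),
        b("cardiovascular", 0.68, 0.77),
        b("cerebrovascular", 0.20, 0.15),
        b("diabetes", 0.29, 0.20),
        t("total_cholesterol", "continuous", (5.7, 1.1), (5.9, 1.3), 1.0, 12.0),
        t("ldl_cholesterol", "continuous", (3.8, 1.0), (4.0, 1.2), 0.3, 10.0),
        t("hdl_cholesterol", "continuous", (1.1, 0.3), (1.0, 0.3), 0.2, 4.0),
        t("systolic_bp", "continuous", (157.0, 27.0), (161.0, 25.0), 70.0, 260.0),
        t("diastolic_bp", "continuous", (84.0, 12.0), (85.0, 11.0), 40.0, 160.0),
        t("bmi", "continuous", (24.9, 3.6), (25.4, 4.4), 12.0, 60.0),
        b("no_alcohol", 0.69, 0.67),
        b("nonsmoker", 0.98, 0.97),
        t("zung_depression", "continuous", (26.7, 5.5), (26.8, 5.8), 20.0, 80.0),
    ]


def _norm(counts: Sequence[float]) -> tuple:
    total = float(sum(counts))
    return tuple(c / total for c in counts)


def _pooled(variables: list, age_mean: float, edu_mean: float) -> list:
    """Collapse per-group distributions to a single pooled one (used for the
    pathology cohort, whose baseline factors are outcome-independent)."""
    out = []
    for v in variables:
        if isinstance(v, TruncNormalVar):
            m = 0.4 * v.case[0] + 0.6 * v.control[0]
            sd = 0.4 * v.case[1] + 0.6 * v.control[1]
            if v.name == "age":
                m = age_mean
            elif v.name == "education_years":
                m = edu_mean
            out.append(replace(v, case=(m, sd), control=(m, sd)))
        elif isinstance(v, BernoulliVar):
            p = 0.4 * v.case + 0.6 * v.control
            out.append(replace(v, case=p, control=p))
        else:
            p = tuple(0.4 * a + 0.6 * b for a, b in zip(v.case, v.control))
            p = _norm(p)
            out.append(replace(v, case=p, control=p))
    return out


def default_params(model_kind: str = "dementia") -> SyntheticParams:
    """Default synthetic-cohort parameters.

    ``dementia``: 97 cases / 148 controls (245 included) plus 94 subjects
    who died within 2 years of follow-up (339 baseline non-demented before
    filtering), group distributions from the published baseline table, and
    the printed missing counts (3 education, 3 APOE).  ``pathology``: 163
    autopsy subjects, 59 with dementia at death, panel prevalences from the
    published outcome table.
    """
    if model_kind == "dementia":
        return SyntheticParams(
            model_kind="dementia",
            n_cases=97, n_controls=148,
            n_died_within_2y=94,
            variables=_table1_variables(),
            missing_counts={"education_years": 3, "apoe_genotype": 3},
            follow_up=TruncNormalVar("follow_up_years", "continuous",
                                     (5.8, 2.6), (5.4, 2.7), 2.0, 11.0),
        )
    if model_kind == "pathology":
        return SyntheticParams(
            model_kind="pathology",
            n_cases=59, n_controls=104,  # dementia at death: 59/163 (36%)
            variables=_pooled(_table1_variables(), age_mean=88.7, edu_mean=4.3),
            missing_counts={
                "caa_percent": 4, "microinfarct_count": 4,
                "apoe_genotype": 4, "mmse_total": 5, "mmse_orientation": 5,
                "mmse_wordlist": 5, "mmse_calculation": 5, "mmse_other": 5,
                "memory_decline": 6, "education_years": 3, "social_class": 1,
                "nonsmoker": 1, "zung_depression": 3,
                "total_cholesterol": 10, "ldl_cholesterol": 10,
                "hdl_cholesterol": 10, "bmi": 39,
            },
            follow_up=TruncNormalVar("follow_up_years", "continuous",
                                     (4.1, 2.5), (4.1, 2.5), 0.1, 11.0),
            pathology=PathologySection(prevalence={
                "amyloid": 0.77, "tangles": 0.61, "neuropath_ad": 0.47,
                "caa": 0.65, "macroinfarcts": 0.49,
                "cortical_macroinfarcts": 0.29, "wm_macroinfarcts": 0.14,
                "microinfarcts": 0.17, "alpha_synuclein": 0.30,
                "hs": 0.07, "tdp43": 0.13,
            }),
        )
    raise ValueError(f"unknown model kind {model_kind!r}")


def _matched_loc(target: float, sd: float, lo: float, hi: float) -> float:
    """Pre-truncation location whose truncated-normal mean equals ``target``."""
    if sd == 0:
        return target

    def f(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target

    span = 10 * sd + (hi - lo)
    return float(optimize.brentq(f, target - span, target + span, xtol=1e-10))


def _draw_truncnorm(rng, n, mean, sd, lo, hi, integer=False) -> np.ndarray:
    if sd == 0:
        vals = np.full(n, float(mean))
    else:
        loc = _matched_loc(mean, sd, lo, hi)
        a, b = (lo - loc) / sd, (hi - loc) / sd
        vals = stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n,
                                   random_state=rng)
    if integer:
        vals = np.clip(np.rint(vals), lo, hi)
    return vals.astype(float)


def _draw_variable(rng, v, group: int, n: int):
    params = v.case if group == 1 else v.control
    if isinstance(v, TruncNormalVar):
        mean, sd = params
        return _draw_truncnorm(rng, n, mean, sd, v.lo, v.hi,
                               integer=(v.kind == "ordinal"))
    if isinstance(v, BernoulliVar):
        return (rng.random(n) < params).astype(float)
    if isinstance(v, CategoricalVar):
        return rng.choice(np.asarray(v.levels, dtype=object), size=n,
                          p=np.asarray(params, dtype=float))
    raise TypeError(f"unknown variable family {type(v)!r}")


def generate_cohort(params: SyntheticParams, seed: int) -> pd.DataFrame:
    """Draw a cohort table with exact class counts.

    Included subjects get exactly ``n_cases``/``n_controls`` outcomes; the
    optional blocks of subjects who died within 2 years or had baseline
    dementia carry the exclusion flags so the inclusion filters reproduce
    the study's accounting.  Deterministic given the seed.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    p_case = params.n_cases / max(params.n_included, 1)
    blocks = [
        (params.n_cases, 1, dict(died_within_2y=False, baseline_dementia=False)),
        (params.n_controls, 0, dict(died_within_2y=False, baseline_dementia=False)),
        (params.n_died_within_2y, None, dict(died_within_2y=True,
                                             baseline_dementia=False)),
        (params.n_baseline_dementia, None, dict(died_within_2y=False,
                                                baseline_dementia=True)),
    ]
    frames = []
    for n, group, aux in blocks:
        if n == 0:
            continue
        groups = (np.full(n, group) if group is not None
                  else (rng.random(n) < p_case).astype(int))
        cols = {"outcome": groups.astype(float)}
        for v in params.variables:
            vals = np.empty(n, dtype=object)
            for g in (0, 1):
                m = groups == g
                if m.any():
                    vals[m] = _draw_variable(rng, v, g, int(m.sum()))
            if not isinstance(v, CategoricalVar):
                vals = vals.astype(float)
            cols[v.name] = vals
        if params.follow_up is not None:
            fu = np.empty(n, dtype=float)
            for g in (0, 1):
                m = groups == g
                if m.any():
                    mean, sd = (params.follow_up.case if g == 1
                                else params.follow_up.control)
                    lo, hi = params.follow_up.lo, params.follow_up.hi
                    if aux["died_within_2y"]:
                        lo, hi = 0.05, 2.0
                        mean, sd = 1.0, 0.6
                    fu[m] = _draw_truncnorm(rng, int(m.sum()), mean, sd, lo, hi)
            cols["follow_up_years"] = fu
        df = pd.DataFrame(cols)
        for k, flag in aux.items():
            df[k] = flag
        df["autopsy_available"] = rng.random(n) < 0.64
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(len(out))])
    out = inject_missing(out, params.missing_counts,
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
    if "apoe_genotype" in out.columns:
        out = add_apoe_columns(out)
    return out


def inject_missing(cohort: pd.DataFrame, missing_counts: dict,
                   seed: int) -> pd.DataFrame:
    """Blank exactly the requested number of cells per variable, uniformly
    without replacement; the outcome column is never masked."""
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    for var, count in missing_counts.items():
        if var == "outcome":
            raise ValueError("refusing to mask the outcome column")
        if var not in out.columns:
            raise ValueError(f"unknown variable {var!r} in missing counts")
        if count > n:
            raise ValueError(f"missing count {count} for {var!r} exceeds n={n}")
        if count == 0:
            continue
        rows = rng.choice(n, size=count, replace=False)
        if out[var].dtype == object:
            out.iloc[rows, out.columns.get_loc(var)] = None
        else:
            out.iloc[rows, out.columns.get_loc(var)] = np.nan
    return out


def _niaaa_cells_by_presence() -> dict:
    cells = {0: [], 1: []}
    for (b, c), lik in default_niaaa_matrix().items():
        cells[int(lik in ("intermediate", "high"))].append((b, c))
    return cells


def generate_pathology_panel(params: SyntheticParams, seed: int) -> pd.DataFrame:
    """Draw the autopsy cohort: baseline factors, raw pathology panel and
    dementia-at-death label.

    Amyloid, tangle and CAA presence, the NIA-AA AD-likelihood class and
    the dementia propensity all load on one latent severity factor, giving
    the planted amyloid-tangle-CAA co-occurrence and its association with
    dementia.  The dementia label is assigned to the top ``n_cases``
    propensities so class counts are exact.  Quantitative magnitudes are
    lognormal when the pathology is present and exactly 0 otherwise.
    """
    if params.pathology is None:
        raise ValueError("params lack a pathology section")
    params.validate()
    path = params.pathology
    prev = path.prevalence
    rng = np.random.default_rng(seed)
    n = params.n_included

    # solve the non-cortical, non-WM macroinfarct rate against the total
    pc = prev.get("cortical_macroinfarcts", 0.0)
    pw = prev.get("wm_macroinfarcts", 0.0)
    pt = prev.get("macroinfarcts", 0.0)
    base = (1 - pc) * (1 - pw)
    if base <= 0 or (1 - pt) > base + 1e-12:
        raise ValueError(
            f"inconsistent macroinfarct prevalences: total {pt} is below the "
            f"minimum {1 - base:.3f} implied by cortical {pc} and WM {pw}")
    p_other = 1 - (1 - pt) / base
    if p_other > 1:
        raise ValueError("inconsistent macroinfarct prevalences: residual "
                         "rate above 1")

    z = rng.standard_normal(n)
    rho = math.sqrt(path.ad_coupling)

    def latent_present(p, coupled):
        if p <= 0:
            return np.zeros(n, dtype=bool)
        if p >= 1:
            return np.ones(n, dtype=bool)
        u = rho * z + math.sqrt(1 - rho ** 2) * rng.standard_normal(n) \
            if coupled else rng.standard_normal(n)
        return u > stats.norm.ppf(1 - p)

    present = {
        "amyloid": latent_present(prev.get("amyloid", 0), True),
        "tangles": latent_present(prev.get("tangles", 0), True),
        "caa": latent_present(prev.get("caa", 0), True),
        "neuropath_ad": latent_present(prev.get("neuropath_ad", 0), True),
        "cortical_macroinfarcts": latent_present(pc, False),
        "wm_macroinfarcts": latent_present(pw, False),
        "other_macroinfarcts": latent_present(p_other, False),
        "microinfarcts": latent_present(prev.get("microinfarcts", 0), False),
        "alpha_synuclein": latent_present(prev.get("alpha_synuclein", 0), False),
        "hs": latent_present(prev.get("hs", 0), False),
        "tdp43": latent_present(prev.get("tdp43", 0), False),
    }

    # dementia: exact count via rank of the latent propensity
    rho_d = math.sqrt(path.dementia_coupling)
    v = rho_d * z + math.sqrt(1 - rho_d ** 2) * rng.standard_normal(n)
    dementia = np.zeros(n, dtype=float)
    dementia[np.argsort(v)[::-1][:params.n_cases]] = 1.0

    def magnitude(key, mask):
        mlog, slog = path.magnitudes[key]
        vals = np.zeros(n)
        vals[mask] = rng.lognormal(mlog, slog, int(mask.sum()))
        return vals

    panel = pd.DataFrame({
        "amyloid_load": magnitude("amyloid_load", present["amyloid"]),
        "tangle_count": magnitude("tangle_count", present["tangles"]),
        "caa_percent": np.minimum(magnitude("caa_percent", present["caa"]), 100.0),
    })
    counts = {}
    for key in ("cortical_macroinfarcts", "wm_macroinfarcts",
                "other_macroinfarcts"):
        c = np.zeros(n, dtype=float)
        m = present[key]
        c[m] = 1 + rng.poisson(0.6, int(m.sum()))
        counts[key] = c
    panel["macroinfarct_count"] = (counts["cortical_macroinfarcts"] +
                                   counts["wm_macroinfarcts"] +
                                   counts["other_macroinfarcts"])
    panel["cortical_macroinfarct_count"] = counts["cortical_macroinfarcts"]
    panel["wm_macroinfarct_count"] = counts["wm_macroinfarcts"]
    micro = np.zeros(n, dtype=float)
    micro[present["microinfarcts"]] = 1 + rng.poisson(
        0.5, int(present["microinfarcts"].sum()))
    panel["microinfarct_count"] = micro
    asyn = np.full(n, "absent", dtype=object)
    m = present["alpha_synuclein"]
    if m.any():
        asyn[m] = rng.choice(np.asarray(ALPHA_SYNUCLEIN_STAGES[1:], dtype=object),
                             size=int(m.sum()),
                             p=np.asarray(path.asyn_split) /
                             sum(path.asyn_split))
    panel["alpha_synuclein"] = asyn
    panel["hs_severity"] = np.where(present["hs"], "severe_marked_total",
                                    "no_minor").astype(object)
    panel["tdp43_positive"] = present["tdp43"].astype(float)
    cells = _niaaa_cells_by_presence()
    braak = np.empty(n, dtype=object)
    cerad = np.empty(n, dtype=object)
    for flag in (0, 1):
        m = present["neuropath_ad"] == bool(flag)
        opts = cells[flag]
        picks = rng.integers(0, len(opts), int(m.sum()))
        braak[m] = [opts[i][0] for i in picks]
        cerad[m] = [opts[i][1] for i in picks]
    panel["braak_stage"] = braak
    panel["cerad_score"] = cerad

    # baseline factors (outcome-independent pooled draws, APOE conditioned
    # on the AD-likelihood class)
    base_cols = {}
    for var in params.variables:
        if var.name == "apoe_genotype":
            geno = np.empty(n, dtype=object)
            for flag in (0, 1):
                m = present["neuropath_ad"] == bool(flag)
                probs = _norm(path.genotype_by_ad[flag])
                geno[m] = rng.choice(np.asarray(APOE_GENOTYPES, dtype=object),
                                     size=int(m.sum()),
                                     p=np.asarray(probs))
            base_cols[var.name] = geno
        else:
            base_cols[var.name] = _draw_variable(rng, var, 0, n)
    out = pd.DataFrame(base_cols)
    out["outcome"] = dementia
    if params.follow_up is not None:
        mean, sd = params.follow_up.control
        out["follow_up_years"] = _draw_truncnorm(
            rng, n, mean, sd, params.follow_up.lo, params.follow_up.hi)
    out["baseline_dementia"] = False
    out["died_within_2y"] = False
    out["autopsy_available"] = True
    out = pd.concat([out, panel], axis=1)
    out.insert(0, "subject_id", [f"P{i + 1:04d}" for i in range(n)])
    out = inject_missing(out, params.missing_counts,
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
    out = add_apoe_columns(out)
    return out
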