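"""Variable metadata and the concept-group hierarchy.

A prediction model is declared as a two-level tree: a root holding concept
groups (cognition, functioning, sociodemographics, ...), each group holding
the individual factors it combines.  Nesting deeper than two levels is
allowed and handled by the same recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import yaml

VARIABLE_KINDS = ("continuous", "ordinal", "binary", "categorical")

#: columns with special meaning in a cohort table; never treated as factors
RESERVED_COLUMNS = (
    "subject_id",
    "outcome",
    "follow_up_years",
    "died_within_2y",
    "autopsy_available",
    "baseline_dementia",
)


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one factor: its name, measurement kind and group.

    Parameters
    ----------
    name
        Column name in the cohort table.
    kind
        One of ``continuous``, ``ordinal``, ``binary``, ``categorical``.
    group
        Name of the concept group the factor belongs to.
    direction_hint
        Optional ``cases_high``/``cases_low`` hint; fitting ignores it and
        picks the orientation from the data, but it is kept for provenance.
    screen_with
        Name of another variable whose screening test governs this factor's
        selection (used for APOE carrier binaries, which inherit selection
        from the full-genotype test).
    """

    name: str
    kind: str
    group: str = ""
    direction_hint: Optional[str] = None
    screen_with: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(
                f"unknown variable kind {self.kind!r} for {self.name!r}; "
                f"expected one of {VARIABLE_KINDS}"
            )
        if not self.name:
            raise ValueError("variable name must be non-empty")


@dataclass
class Group:
    """A named node of the hierarchy holding factors and/or sub-groups."""

    name: str
    members: list = field(default_factory=list)

    def leaves(self) -> list[VariableSpec]:
        out: list[VariableSpec] = []
        for m in self.members:
            if isinstance(m, Group):
                out.extend(m.leaves())
            else:
                out.append(m)
        return out

    def walk(self, prefix: str = "") -> Iterator[tuple[str, Union["Group", VariableSpec]]]:
        """Yield ``(path, node)`` pairs depth-first, groups before leaves."""
        path = f"{prefix}{self.name}" if prefix == "" else f"{prefix}/{self.name}"
        yield path, self
        for m in self.members:
            if isinstance(m, Group):
                yield from m.walk(path)
            else:
                yield f"{path}/{m.name}", m

    def prune(self, keep: set[str]) -> Optional["Group"]:
        """Return a copy keeping only leaves named in ``keep``.

        Groups left without members are dropped; returns ``None`` if nothing
        survives.
        """
        members = []
        for m in self.members:
            if isinstance(m, Group):
                sub = m.prune(keep)
                if sub is not None:
                    members.append(sub)
            elif m.name in keep:
                members.append(m)
        if not members:
            return None
        return Group(self.name, members)

    def validate(self) -> None:
        names = [s.name for s in self.leaves()]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate variable names in hierarchy: {sorted(dupes)}")
        if not names:
            raise ValueError("hierarchy contains no variables")


def _group_to_dict(g: Group) -> dict:
    members = []
    for m in g.members:
        if isinstance(m, Group):
            members.append(_group_to_dict(m))
        else:
            d = {"name": m.name, "kind": m.kind}
            if m.direction_hint:
                d["direction_hint"] = m.direction_hint
            if m.screen_with:
                d["screen_with"] = m.screen_with
            members.append(d)
    return {"name": g.name, "members": members}


def _group_from_dict(d: dict, parent: str = "") -> Group:
    members = []
    for m in d.get("members", d.get("variables", [])):
        if "members" in m or "variables" in m:
            members.append(_group_from_dict(m, d["name"]))
        else:
            members.append(
                VariableSpec(
                    name=m["name"],
                    kind=m["kind"],
                    group=d["name"],
                    direction_hint=m.get("direction_hint"),
                    screen_with=m.get("screen_with"),
                )
            )
    return Group(d["name"], members)


def dump_hierarchy(root: Group, path: str) -> None:
    """Write a hierarchy to a YAML file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_group_to_dict(root), fh, sort_keys=False)


def load_hierarchy(path: str) -> Group:
    """Read a hierarchy from a YAML (or JSON, a YAML subset) file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if "groups" in doc:  # legacy flat layout: top-level list of groups
        root = Group(doc.get("name", "model"),
                     [_group_from_dict(g) for g in doc["groups"]])
    else:
        root = _group_from_dict(doc)
    root.validate()
    return root


def default_hierarchy(model_kind: str = "dementia") -> Group:
    """The initial factor-group tree used for both dementia and pathology
    models: sociodemographics, cognition, functioning, APOE genotype,
    comorbidities, cholesterol, blood pressure, lifestyle and depressive
    symptoms."""
    if model_kind not in ("dementia", "pathology"):
        raise ValueError(f"unknown model kind {model_kind!r}")

    def v(name, kind, group, **kw):
        return VariableSpec(name=name, kind=kind, group=group, **kw)

    g = "sociodemographics"
    socio = Group(g, [
        v("age", "continuous", g),
        v("male", "binary", g),
        v("education_years", "continuous", g),
        v("social_class", "ordinal", g),
    ])
    g = "cognition"
    cognition = Group(g, [
        v("mmse_total", "continuous", g),
        v("mmse_orientation", "ordinal", g),
        v("mmse_wordlist", "ordinal", g),
        v("mmse_calculation", "ordinal", g),
        v("mmse_other", "ordinal", g),
        v("spmsq_errors", "ordinal", g),
    ])
    g = "functioning"
    functioning = Group(g, [
        v("adl_sum", "continuous", g),
        v("competence_daily", "ordinal", g),
        v("memory_decline", "ordinal", g),
    ])
    g = "apoe"
    apoe = Group(g, [
        v("apoe_e2_carrier", "binary", g, screen_with="apoe_genotype"),
        v("apoe_e4_carrier", "binary", g, screen_with="apoe_genotype"),
        v("apoe_e3e3", "binary", g, screen_with="apoe_genotype"),
        v("apoe_genotype", "categorical", g),
    ])
    g = "comorbidity"
    comorbidity = Group(g, [
        v("cardiovascular", "binary", g),
        v("cerebrovascular", "binary", g),
        v("diabetes", "binary", g),
    ])
    g = "cholesterol"
    chol = Group(g, [
        v("total_cholesterol", "continuous", g),
        v("ldl_cholesterol", "continuous", g),
        v("hdl_cholesterol", "continuous", g),
    ])
    g = "blood_pressure"
    bp = Group(g, [
        v("systolic_bp", "continuous", g),
        v("diastolic_bp", "continuous", g),
    ])
    g = "lifestyle"
    lifestyle = Group(g, [
        v("bmi", "continuous", g),
        v("no_alcohol", "binary", g),
        v("nonsmoker", "binary", g),
    ])
    g = "depression"
    depression = Group(g, [v("zung_depression", "continuous", g)])

    root = Group("model", [socio, cognition, functioning, apoe, comorbidity,
                           chol, bp, lifestyle, depression])
    root.validate()
    return root


def default_variable_specs(model_kind: str = "dementia") -> list[VariableSpec]:
    """Flat list of the default hierarchy's variable declarations."""
    return default_hierarchy(model_kind).leaves()
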