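"""Property-range compliance scoring and screening-library filters.

The overall compliance score of a compound, ``#stars``, is the number of
descriptors in a configured 24-descriptor star set whose values fall outside
the recommended ranges spanned by 95% of known oral drugs; 0 stars means
fully compliant.  Descriptors missing from a compound's vector are listed as
unevaluable and never counted as violations.

Filters (drug-like, lead-like, fragment-like, the oral-availability rule of
three) are conjunctions of literal comparator clauses; the comparators are
applied exactly as published (MW = 500 fails drug-like, HBD = 5 passes).
Both the range registry and the filters are data (YAML), not code.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .chem_io import DescriptorTable
from .descriptors import DescriptorVector

_OPS = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
    "==": operator.eq,
}


@dataclass(frozen=True)
class DescriptorRange:
    """A recommended interval, possibly one-sided, with open/closed ends."""

    name: str
    low: float = -math.inf
    high: float = math.inf
    low_open: bool = False
    high_open: bool = False

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.name}: low {self.low} > high {self.high}")


def in_range(value: float, rng: DescriptorRange) -> bool:
    """True iff ``value`` lies within the range, honoring open/closed ends."""
    if not math.isfinite(value):
        raise ValueError(f"{rng.name}: value must be finite, got {value}")
    lo_ok = value > rng.low if rng.low_open else value >= rng.low
    hi_ok = value < rng.high if rng.high_open else value <= rng.high
    return lo_ok and hi_ok


@dataclass(frozen=True)
class FilterClause:
    descriptor: str
    comparator: str
    constant: float

    def holds(self, value: float) -> bool:
        return _OPS[self.comparator](value, self.constant)


@dataclass
class FilterRule:
    """A named screening filter: a conjunction (or at-least-k) of clauses."""

    name: str
    clauses: list[FilterClause]
    combine: str = "all"  # "all" or "at-least-k"
    k: int = 0

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError(f"filter {self.name}: clauses must be non-empty")
        if self.combine not in {"all", "at-least-k"}:
            raise ValueError(f"filter {self.name}: unknown combine {self.combine!r}")


@dataclass
class ComplianceReport:
    """Per-compound compliance: #stars, violated and unevaluable descriptors,
    and filter memberships (None = not classifiable for that filter)."""

    id: str
    stars: int
    out_of_range: list[str]
    missing: list[str]
    filters: dict[str, bool | None] = field(default_factory=dict)


class RangeRegistry:
    """Descriptor -> recommended range, plus the star set counted for #stars."""

    def __init__(self, ranges: Mapping[str, DescriptorRange], star_set: Sequence[str]):
        self.ranges = dict(ranges)
        unknown = [n for n in star_set if n not in self.ranges]
        if unknown:
            raise ValueError(f"star_set names without a registered range: {unknown}")
        self.star_set = list(star_set)

    def __contains__(self, name: str) -> bool:
        return name in self.ranges

    def __getitem__(self, name: str) -> DescriptorRange:
        return self.ranges[name]

    def with_range(self, rng: DescriptorRange) -> "RangeRegistry":
        ranges = dict(self.ranges)
        ranges[rng.name] = rng
        return RangeRegistry(ranges, self.star_set)

    @staticmethod
    def _parse_ranges(doc: Mapping) -> dict[str, DescriptorRange]:
        out = {}
        for name, spec in doc.items():
            out[name] = DescriptorRange(
                name=name,
                low=float(spec.get("low", -math.inf)),
                high=float(spec.get("high", math.inf)),
                low_open=bool(spec.get("low_open", False)),
                high_open=bool(spec.get("high_open", False)),
            )
        return out

    @classmethod
    def from_yaml(cls, path: str | Path, variant: str | None = None) -> "RangeRegistry":
        doc = yaml.safe_load(Path(path).read_text())
        return cls._from_doc(doc, variant)

    @classmethod
    def _from_doc(cls, doc: Mapping, variant: str | None) -> "RangeRegistry":
        ranges = cls._parse_ranges(doc["ranges"])
        if variant is not None:
            overrides = doc.get("variants", {}).get(variant)
            if overrides is None:
                raise ValueError(f"unknown range variant {variant!r}")
            ranges.update(cls._parse_ranges(overrides))
        return cls(ranges, doc.get("star_set", list(ranges)))

    @classmethod
    def default(cls, variant: str | None = None) -> "RangeRegistry":
        """The shipped registry (narrative ranges; ``variant='table'`` for the
        alternative logB/B and logK_HSA bounds)."""
        text = resources.files("admetprof.data").joinpath("ranges.yaml").read_text()
        return cls._from_doc(yaml.safe_load(text), variant)


def load_filters(path: str | Path | None = None) -> list[FilterRule]:
    """Load filter rules from YAML (the shipped defaults when path is None)."""
    if path is None:
        text = resources.files("admetprof.data").joinpath("ranges.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    rules = []
    for name, spec in doc.get("filters", {}).items():
        clauses = [FilterClause(d, cmp, float(c)) for d, cmp, c in spec["clauses"]]
        rules.append(
            FilterRule(
                name=name,
                clauses=clauses,
                combine=spec.get("combine", "all"),
                k=int(spec.get("k", 0)),
            )
        )
    return rules


def validate_filters(filters: Iterable[FilterRule], registry: RangeRegistry) -> None:
    """Raise if any filter clause names a descriptor unknown to the registry."""
    for rule in filters:
        for clause in rule.clauses:
            if clause.descriptor not in registry:
                raise ValueError(
                    f"filter {rule.name!r}: unknown descriptor {clause.descriptor!r}"
                )


def star_count(dv: DescriptorVector, registry: RangeRegistry) -> ComplianceReport:
    """#stars = number of star-set descriptors present and out of range.

    Descriptors absent from the vector are listed under ``missing`` and not
    counted as violations.
    """
    if not registry.star_set:
        raise ValueError("registry star_set is empty")
    out: list[str] = []
    missing: list[str] = []
    for name in registry.star_set:
        value = dv.get(name)
        if value is None:
            missing.append(name)
        elif not in_range(value, registry[name]):
            out.append(name)
    cid = getattr(dv, "id", "")
    return ComplianceReport(id=cid, stars=len(out), out_of_range=out, missing=missing)


def apply_filter(dv: DescriptorVector, rule: FilterRule) -> bool | None:
    """Evaluate one filter; None when any clause descriptor is missing
    (not classifiable — excluded from compliance denominators)."""
    verdicts = []
    for clause in rule.clauses:
        value = dv.get(clause.descriptor)
        if value is None:
            return None
        verdicts.append(clause.holds(value))
    if rule.combine == "all":
        return all(verdicts)
    return sum(verdicts) >= rule.k


@dataclass
class SubsetClassification:
    """Filter memberships per compound, with unclassifiable cases kept apart."""

    memberships: dict[str, set[str]]
    indeterminate: dict[str, set[str]]


def classify_subsets(table: DescriptorTable, filters: Sequence[FilterRule]) -> SubsetClassification:
    """Independent filter memberships for every compound in the table."""
    names = [f.name for f in filters]
    if len(set(names)) != len(names):
        raise ValueError(f"filters must be distinct by name: {names}")
    memberships: dict[str, set[str]] = {}
    indeterminate: dict[str, set[str]] = {}
    for cid, dv in table.rows():
        member: set[str] = set()
        unknown: set[str] = set()
        for rule in filters:
            verdict = apply_filter(dv, rule)
            if verdict is None:
                unknown.add(rule.name)
            elif verdict:
                member.add(rule.name)
        memberships[cid] = member
        if unknown:
            indeterminate[cid] = unknown
    return SubsetClassification(memberships, indeterminate)


def score_table(table: DescriptorTable, registry: RangeRegistry,
                filters: Sequence[FilterRule] = ()) -> list[ComplianceReport]:
    """Star-count every row and attach filter memberships."""
    reports = []
    for cid, dv in table.rows():
        rep = star_count(dv, registry)
        rep.id = cid
        for rule in filters:
            rep.filters[rule.name] = apply_filter(dv, rule)
        reports.append(rep)
    return reports
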