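"""Library-level aggregation of per-compound compliance.

Produces the kind of report a screening-library triage ends with: subset
sizes, #stars histograms, the headline "percent fully compliant" and
"percent with <= 2 violations" figures, per-descriptor mean values, percent
compliances per descriptor and per filter, and binned distributions for
plotting.  Compounds whose vector carries none of the scored descriptors
(e.g. records a descriptor engine failed on) are excluded from score
denominators and reported as unscored.

Percentages are reported to 2 decimals, half-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_io import DescriptorTable
from .compliance import (
    ComplianceReport,
    FilterRule,
    RangeRegistry,
    apply_filter,
    in_range,
    star_count,
)

#: descriptor -> (bin width, anchor) used for the default binned distributions
DEFAULT_BINS: dict[str, tuple[float, float]] = {
    "logB_B": (1.0, 0.0),
    "logS_wat": (1.0, 0.0),
    "logK_HSA": (1.0, 0.0),
    "logHERG": (1.0, 0.0),
    "logK_p": (1.0, 0.0),
    "metab": (1.0, 0.0),
}


def round_pct(x: float) -> float:
    """Percentage to 2 decimals, half-up (so 45.305 -> 45.31)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ComplianceStat:
    """One percent-compliance figure with its accounting."""

    pct: float | None  # None when no row was evaluable
    n_in: int
    n_evaluable: int
    n_excluded: int


def compliance_stat(
    table: DescriptorTable,
    name: str,
    registry: RangeRegistry,
    filters: Sequence[FilterRule] = (),
) -> ComplianceStat:
    """Percent of evaluable rows in range (descriptor) or passing (filter).

    Rows missing the descriptor (or any filter clause descriptor) are
    excluded from both numerator and denominator and counted as excluded.
    """
    rule = next((f for f in filters if f.name == name), None)
    n_total = len(table)
    if rule is not None:
        verdicts = [apply_filter(dv, rule) for _, dv in table.rows()]
        ok = sum(1 for v in verdicts if v is True)
        evaluable = sum(1 for v in verdicts if v is not None)
    elif name in registry:
        col = table.data[name] if name in table.data.columns else pd.Series(dtype=float)
        values = col.dropna()
        evaluable = len(values)
        rng = registry[name]
        ok = int(sum(in_range(float(v), rng) for v in values))
    else:
        raise KeyError(f"{name!r} is neither a registered descriptor nor a filter")
    if evaluable == 0:
        return ComplianceStat(None, 0, 0, n_total)
    return ComplianceStat(round_pct(100.0 * ok / evaluable), ok, evaluable, n_total - evaluable)


def percent_compliance(
    table: DescriptorTable,
    name: str,
    registry: RangeRegistry,
    filters: Sequence[FilterRule] = (),
) -> float | None:
    """Percent compliance for one descriptor or filter (None if unevaluable)."""
    return compliance_stat(table, name, registry, filters).pct


def summarize_means(table: DescriptorTable, subset_ids: Iterable[str] | None = None) -> dict[str, float]:
    """Arithmetic mean of every descriptor over evaluable rows."""
    data = table.data if subset_ids is None else table.subset(subset_ids).data
    means = data.mean(axis=0, skipna=True)
    return {k: float(v) for k, v in means.items() if not pd.isna(v)}


def star_distribution(reports: Sequence[ComplianceReport]) -> dict[int, int]:
    """Histogram of #stars over reports; counts sum to len(reports)."""
    hist: dict[int, int] = {}
    for rep in reports:
        hist[rep.stars] = hist.get(rep.stars, 0) + 1
    return dict(sorted(hist.items()))


def bin_distribution(
    table: DescriptorTable,
    name: str,
    width: float,
    anchor: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open bins [edge, edge + width) anchored at ``anchor``.

    A value exactly on an edge falls in the upper bin (the bin whose lower
    edge it is).  Returns (lower edges, counts); counts sum to the number of
    evaluable rows.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    values = table.data[name].dropna().to_numpy(dtype=float)
    if len(values) == 0:
        return np.array([]), np.array([], dtype=int)
    idx = np.floor((values - anchor) / width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = anchor + width * np.arange(lo, hi + 1)
    return edges, counts


@dataclass
class SubsetProfile:
    name: str
    n: int
    n_scored: int
    stars_hist: dict[int, int] = field(default_factory=dict)
    pct_stars0: float | None = None
    pct_stars_le2: float | None = None
    means: dict[str, float] = field(default_factory=dict)
    pct_compliance: dict[str, float | None] = field(default_factory=dict)
    n_excluded: dict[str, int] = field(default_factory=dict)
    bins: dict[str, dict] = field(default_factory=dict)


@dataclass
class LibraryProfile:
    """Aggregates for the whole library plus each filter-defined subset."""

    n_total: int
    n_unscored: int
    subsets: dict[str, SubsetProfile] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, dict):
                return {str(k): conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, np.ndarray):
                return [conv(v) for v in o.tolist()]
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            return o

        return conv(
            {
                "n_total": self.n_total,
                "n_unscored": self.n_unscored,
                "notes": self.notes,
                "subsets": {
                    name: {
                        "n": sp.n,
                        "n_scored": sp.n_scored,
                        "stars_hist": sp.stars_hist,
                        "pct_stars0": sp.pct_stars0,
                        "pct_stars_le2": sp.pct_stars_le2,
                        "means": sp.means,
                        "pct_compliance": sp.pct_compliance,
                        "n_excluded": sp.n_excluded,
                        "bins": sp.bins,
                    }
                    for name, sp in self.subsets.items()
                },
            }
        )

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _pct_stars_at_most(stars: pd.Series, k: int) -> float | None:
    if len(stars) == 0:
        return None
    return round_pct(100.0 * float((stars <= k).sum()) / len(stars))


def profile_library(
    table: DescriptorTable,
    registry: RangeRegistry,
    filters: Sequence[FilterRule] = (),
    *,
    subset_filters: Sequence[str] = ("druglike", "leadlike", "fragmentlike"),
    compliance_names: Sequence[str] | None = None,
    bins: Mapping[str, tuple[float, float]] | None = None,
    imported_stars_column: str | None = "stars",
) -> LibraryProfile:
    """Full library profile: the total library plus each filter subset.

    ``compliance_names`` defaults to every registered descriptor present in
    the table plus every filter.  If ``imported_stars_column`` names a table
    column (e.g. a star count embedded in the source SDF tags), those values
    take precedence over recomputed star counts for the rows that carry them;
    pass None to force recomputation throughout.

    A compound with none of the star-set descriptors present is unscored: it
    is excluded from the #stars denominators (and its exclusion reported) but
    still counted in ``n`` per subset membership.
    """
    if len(table) == 0:
        raise ValueError("cannot profile an empty table")
    if bins is None:
        bins = DEFAULT_BINS

    # per-row star counts (imported tag wins where present)
    stars_by_id: dict[str, int] = {}
    scored_ids: list[str] = []
    imported = {}
    if imported_stars_column and imported_stars_column in table.data.columns:
        imported = table.data[imported_stars_column].dropna().to_dict()
    for cid, dv in table.rows():
        if cid in imported:
            stars_by_id[cid] = int(imported[cid])
            scored_ids.append(cid)
            continue
        rep = star_count(dv, registry)
        if len(rep.missing) == len(registry.star_set):
            continue  # unscored: no star-set descriptor present at all
        stars_by_id[cid] = rep.stars
        scored_ids.append(cid)

    membership: dict[str, list[str]] = {"total": list(table.ids)}
    for fname in subset_filters:
        rule = next((f for f in filters if f.name == fname), None)
        if rule is None:
            continue
        ids = [cid for cid, dv in table.rows() if apply_filter(dv, rule) is True]
        membership[fname] = ids

    if compliance_names is None:
        compliance_names = [n for n in table.data.columns if n in registry]
        compliance_names += [f.name for f in filters]

    profile = LibraryProfile(
        n_total=len(table),
        n_unscored=len(table) - len(scored_ids),
        notes={
            "denominator": (
                f"{len(scored_ids)} of {len(table)} compounds carry scored "
                "descriptors; #stars percentages use the scored count"
            )
        },
    )

    for sname, ids in membership.items():
        sub = table.subset(ids)
        stars = pd.Series({i: stars_by_id[i] for i in ids if i in stars_by_id}, dtype=int)
        sp = SubsetProfile(name=sname, n=len(ids), n_scored=len(stars))
        sp.stars_hist = dict(sorted(stars.value_counts().items())) if len(stars) else {}
        sp.pct_stars0 = _pct_stars_at_most(stars, 0)
        sp.pct_stars_le2 = _pct_stars_at_most(stars, 2)
        sp.means = summarize_means(sub)
        for name in compliance_names:
            stat = compliance_stat(sub, name, registry, filters)
            sp.pct_compliance[name] = stat.pct
            sp.n_excluded[name] = stat.n_excluded
        for name, (width, anchor) in bins.items():
            if name in sub.data.columns:
                edges, counts = bin_distribution(sub, name, width, anchor)
                sp.bins[name] = {"edges": edges, "counts": counts, "width": width}
        profile.subsets[sname] = sp
    return profile


def plot_profile(profile: LibraryProfile, outdir) -> list[str]:
    """Convenience plots (stars histogram + binned distributions) as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    fig, ax = plt.subplots()
    for sname, sp in profile.subsets.items():
        if sp.stars_hist:
            ks = sorted(sp.stars_hist)
            ax.plot(ks, [sp.stars_hist[k] for k in ks], marker="o", label=sname)
    ax.set_xlabel("#stars")
    ax.set_ylabel("count")
    ax.legend()
    path = outdir / "stars_distribution.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))
    total = profile.subsets.get("total")
    if total is not None:
        for name, b in total.bins.items():
            fig, ax = plt.subplots()
            ax.bar(b["edges"], b["counts"], width=b["width"] * 0.9, align="edge")
            ax.set_xlabel(f"{name} (lower bin edge)")
            ax.set_ylabel("count")
            path = outdir / f"dist_{name}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(str(path))
    return written
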