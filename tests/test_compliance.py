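"""Range compliance, #stars scoring and the screening filters."""

import math
import random

import numpy as np
import pytest

import admetprof as ap
from admetprof.compliance import DescriptorRange, FilterClause, FilterRule


def make_dv(**values):
    return ap.DescriptorVector(values={k: float(v) for k, v in values.items()})


def get_filter(filters, name):
    return next(f for f in filters if f.name == name)


# --- in_range ----------------------------------------------------------------

def test_library_mean_solubility_inside_recommended_range(registry):
    assert ap.in_range(-5.16, registry["logS_wat"]) is True


def test_metab_below_lower_bound(registry):
    assert ap.in_range(0.0, registry["metab"]) is False


def test_herg_concern_is_one_sided_and_strict(registry):
    assert ap.in_range(-5.5, registry["logHERG"]) is False  # flagged as concern
    assert ap.in_range(-4.0, registry["logHERG"]) is True
    assert ap.in_range(-5.0, registry["logHERG"]) is False  # open lower end
    assert ap.in_range(100.0, registry["logHERG"]) is True  # unbounded above


def test_closed_interval_ends_included(registry):
    rng = registry["Glob"]
    assert ap.in_range(0.75, rng) and ap.in_range(0.95, rng)
    assert not ap.in_range(0.9501, rng)


def test_in_range_rejects_non_finite(registry):
    with pytest.raises(ValueError):
        ap.in_range(math.nan, registry["Glob"])


def test_invalid_range_rejected():
    with pytest.raises(ValueError):
        DescriptorRange("x", low=2.0, high=1.0)


# --- registry ----------------------------------------------------------------

def test_default_star_set_has_24_registered_descriptors(registry):
    assert len(registry.star_set) == 24
    assert all(name in registry for name in registry.star_set)


def test_registry_variant_overrides_disputed_bounds(registry):
    table = ap.RangeRegistry.default("table")
    assert registry["logB_B"].high == 1.2 and table["logB_B"].high == 1.0
    assert registry["logK_HSA"].high == 1.5 and table["logK_HSA"].high == 1.2
    with pytest.raises(ValueError):
        ap.RangeRegistry.default("nonsense")


def test_registry_star_set_must_be_registered():
    with pytest.raises(ValueError):
        ap.RangeRegistry({"MW": DescriptorRange("MW", 0, 1000)}, ["MW", "ghost"])


def test_registry_from_yaml_round_trip(tmp_path):
    p = tmp_path / "ranges.yaml"
    p.write_text("ranges:\n  MW: {low: 100, high: 600}\nstar_set: [MW]\n")
    reg = ap.RangeRegistry.from_yaml(p)
    assert reg.star_set == ["MW"]
    assert ap.in_range(600.0, reg["MW"])


# --- star_count --------------------------------------------------------------

def test_fully_compliant_vector_has_zero_stars(registry):
    dv = make_dv(logS_wat=-2.0, Glob=0.85, metab=4)
    rep = ap.star_count(dv, registry)
    assert rep.stars == 0
    assert rep.out_of_range == []
    # everything not supplied is reported missing, not violated
    assert len(rep.missing) == 21


def test_single_violation_named(registry):
    rep = ap.star_count(make_dv(logS_wat=-7.5, Glob=0.85), registry)
    assert rep.stars == 1
    assert rep.out_of_range == ["logS_wat"]


def test_star_count_equals_brute_force_recount(registry):
    """Random vectors over all registered descriptors vs an independent loop."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        dv = ap.DescriptorVector()
        for name in registry.star_set:
            r = registry[name]
            lo = r.low if math.isfinite(r.low) else r.high - 10
            hi = r.high if math.isfinite(r.high) else r.low + 10
            dv.set(name, rng.uniform(lo - 5, hi + 5))
        rep = ap.star_count(dv, registry)
        brute = 0
        for name in registry.star_set:
            r = registry[name]
            v = dv.values[name]
            lo_ok = v > r.low if r.low_open else v >= r.low
            hi_ok = v < r.high if r.high_open else v <= r.high
            brute += not (lo_ok and hi_ok)
        assert rep.stars == brute == len(rep.out_of_range)


def test_star_count_monotone_under_one_more_violation(registry):
    dv = make_dv(logS_wat=-2.0, Glob=0.85, metab=4)
    base = ap.star_count(dv, registry).stars
    dv.set("Glob", 0.2)  # push one descriptor out
    assert ap.star_count(dv, registry).stars == base + 1


def test_star_count_invariant_to_descriptor_order(registry):
    values = {"logS_wat": -7.5, "Glob": 0.2, "metab": 4.0, "MW": 400.0}
    items = list(values.items())
    random.Random(7).shuffle(items)
    a = ap.star_count(ap.DescriptorVector(values=dict(items)), registry)
    b = ap.star_count(ap.DescriptorVector(values=values), registry)
    assert a.stars == b.stars and set(a.out_of_range) == set(b.out_of_range)


def test_star_count_requires_star_set(registry):
    empty = ap.RangeRegistry(registry.ranges, [])
    with pytest.raises(ValueError):
        ap.star_count(make_dv(MW=300), empty)


# --- filters -----------------------------------------------------------------

def test_druglike_boundaries(filters):
    rule = get_filter(filters, "druglike")
    assert ap.apply_filter(make_dv(MW=400, logP=3.0, HBD=2, HBA=5), rule) is True
    assert ap.apply_filter(make_dv(MW=500, logP=3.0, HBD=2, HBA=5), rule) is False  # strict <
    assert ap.apply_filter(make_dv(MW=400, logP=3.0, HBD=5, HBA=10), rule) is True  # <= ends


def test_leadlike_boundaries(filters):
    rule = get_filter(filters, "leadlike")
    assert ap.apply_filter(make_dv(MW=350, logP=4.0, HBD=3, HBA=6), rule) is True
    assert ap.apply_filter(make_dv(MW=149.9, logP=2.0, HBD=1, HBA=2), rule) is False


def test_fragmentlike_boundaries(filters):
    rule = get_filter(filters, "fragmentlike")
    assert ap.apply_filter(make_dv(MW=200, logP=1.0, HBD=2, HBA=5, NRB=2), rule) is True
    assert ap.apply_filter(make_dv(MW=200, logP=1.0, HBD=3, HBA=5, NRB=2), rule) is False  # strict <
    assert ap.apply_filter(make_dv(MW=200, logP=1.0, HBD=2, HBA=5, NRB=3), rule) is False  # strict <


def test_ro3_boundaries(filters):
    rule = get_filter(filters, "ro3")
    assert ap.apply_filter(make_dv(logS_wat=-5.0, BIP_caco2=30, metab=5), rule) is True
    assert ap.apply_filter(make_dv(logS_wat=-5.0, BIP_caco2=22, metab=5), rule) is False  # strict >
    assert ap.apply_filter(make_dv(logS_wat=-5.7, BIP_caco2=30, metab=5), rule) is False


def test_missing_clause_descriptor_is_indeterminate(filters):
    rule = get_filter(filters, "druglike")
    assert ap.apply_filter(make_dv(MW=400, logP=3.0, HBD=2), rule) is None


def test_unknown_clause_descriptor_is_configuration_error(registry):
    rule = FilterRule("custom", [FilterClause("ghost", "<", 1.0)])
    with pytest.raises(ValueError, match="ghost"):
        ap.validate_filters([rule], registry)
    ap.validate_filters(ap.load_filters(), registry)  # shipped filters are clean


def test_filter_rule_validation():
    with pytest.raises(ValueError):
        FilterRule("empty", [])
    with pytest.raises(ValueError):
        FilterRule("bad", [FilterClause("MW", "<", 1.0)], combine="any")


def test_at_least_k_combine():
    rule = FilterRule(
        "loose_ro3",
        [FilterClause("logS_wat", ">", -5.7), FilterClause("BIP_caco2", ">", 22),
         FilterClause("metab", "<", 7)],
        combine="at-least-k", k=2,
    )
    assert ap.apply_filter(make_dv(logS_wat=-6.0, BIP_caco2=30, metab=5), rule) is True
    assert ap.apply_filter(make_dv(logS_wat=-6.0, BIP_caco2=10, metab=5), rule) is False


# --- classify_subsets --------------------------------------------------------

def test_fragment_clauses_imply_leadlike_hb_clauses(filters):
    """On an exhaustive grid, any vector passing fragment-like satisfies the
    lead-like HBD/HBA clauses (clause implication, brute force)."""
    frag = get_filter(filters, "fragmentlike")
    lead = get_filter(filters, "leadlike")
    for mw in (100, 250, 400):
        for logp in (-3, 0, 3, 4.5):
            for hbd in range(0, 7):
                for hba in range(0, 12):
                    for nrb in (0, 2, 3):
                        dv = make_dv(MW=mw, logP=logp, HBD=hbd, HBA=hba, NRB=nrb)
                        if ap.apply_filter(dv, frag):
                            assert hbd <= 3 and hba <= 6
                            assert ap.apply_filter(dv, lead) == (150 <= mw <= 350 and logp <= 4)


def test_classify_subsets_on_generated_truth(registry, filters):
    spec = ap.SyntheticSpec(
        n=300,
        marginals={
            "MW": {"mean": 350.0, "sigma": 150.0},
            "logP": {"mean": 2.5, "sigma": 2.0},
            "HBD": {"mean": 2.0, "sigma": 2.0, "min": 0.0},
            "HBA": {"mean": 5.0, "sigma": 3.0, "min": 0.0},
            "NRB": {"mean": 4.0, "sigma": 3.0, "min": 0.0},
        },
        seed=11,
    )
    table, truth = ap.generate_descriptor_table(spec, registry)
    result = ap.classify_subsets(table, filters)
    for cid in table.ids:
        for fname in ("druglike", "leadlike", "fragmentlike"):
            expected = truth.expected_filters.at[cid, fname]
            assert (fname in result.memberships[cid]) == bool(expected)
        # ro3 clauses absent from the table -> indeterminate, kept apart
        assert "ro3" in result.indeterminate[cid]
        assert "ro3" not in result.memberships[cid]


def test_classify_subsets_empty_table(filters):
    import pandas as pd

    empty = ap.DescriptorTable(pd.DataFrame(columns=["MW"], dtype=float))
    result = ap.classify_subsets(empty, filters)
    assert result.memberships == {} and result.indeterminate == {}


def test_classify_subsets_rejects_duplicate_filter_names(filters):
    with pytest.raises(ValueError):
        import pandas as pd

        table = ap.DescriptorTable(pd.DataFrame({"MW": [100.0]}, index=["a"]))
        ap.classify_subsets(table, [filters[0], filters[0]])
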