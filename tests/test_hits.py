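import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dynscreen.hits import (
    ThresholdRule,
    apply_rule,
    build_hit_table,
    call_cargo_hits,
    call_lethal,
    call_micronucleus_hits,
    categorize_mtoc,
    exclude_confounded,
    summarize_confirmation,
)

REF = np.array([-1.2, -0.5, 0.0, 0.4, 1.3, -0.3, 0.6, -0.9, 0.2, 0.4])


def test_threshold_is_closed_at_the_boundary():
    center, sd = REF.mean(), REF.std(ddof=1)
    rule = ThresholdRule("ep", k=2.5)
    boundary = pd.Series({"at": center - 2.5 * sd, "inside": center - 0.99 * 2.5 * sd})
    res = apply_rule(boundary, REF, rule)
    assert bool(res.loc["at", "hit"])
    assert not bool(res.loc["inside", "hit"])


def test_sidedness_restricts_direction():
    scores = pd.Series({"low": -100.0, "high": 100.0})
    low_only = apply_rule(scores, REF, ThresholdRule("ep", k=2.0, sidedness="low_only"))
    assert bool(low_only.loc["low", "hit"]) and not bool(low_only.loc["high", "hit"])
    high_only = apply_rule(scores, REF, ThresholdRule("ep", k=2.0, sidedness="high_only"))
    assert bool(high_only.loc["high", "hit"]) and not bool(high_only.loc["low", "hit"])


@given(bump=st.floats(min_value=0, max_value=50))
def test_hit_flags_monotone_in_score_magnitude(bump):
    rule = ThresholdRule("ep", k=2.0)
    base = pd.Series({"g": -2.0})
    stronger = pd.Series({"g": -2.0 - bump})
    if bool(apply_rule(base, REF, rule).loc["g", "hit"]):
        assert bool(apply_rule(stronger, REF, rule).loc["g", "hit"])


def test_exclusion_rules_and_reasons():
    refs = {
        "NTC": {"nucleus_area": REF, "nucleus_roundness": REF},
        "crLIS1": {"nucleus_area": REF + 0.1, "nucleus_roundness": REF - 0.1},
    }
    pooled_r = np.concatenate([REF, REF - 0.1])
    center, sd = pooled_r.mean(), pooled_r.std(ddof=1)
    genes = pd.DataFrame(
        {
            "nucleus_area": [0.0, 0.0, 30.0],
            "nucleus_roundness": [0.0, center - 3.6 * sd, 0.0],
        },
        index=["clean", "flat", "huge"],
    )
    flags = exclude_confounded(genes, refs)
    assert not flags.loc["clean", "excluded"]
    assert flags.loc["flat", "excluded_roundness"]
    assert "roundness" in flags.loc["flat", "exclusion_reason"]
    assert flags.loc["huge", "excluded_area"]


def test_cargo_hits_respect_rule_reference_groups():
    refs = {"NTC": {"ep": REF}, "crLIS1": {"ep": REF * 3}}
    genes = pd.DataFrame({"ep": [0.0, -10.0, 10.0]}, index=["null", "down", "up"])
    hits = call_cargo_hits(genes, refs, [ThresholdRule("ep", "NTC", 2.5)])
    assert not hits.loc["null", "any_cargo_hit"]
    assert hits.loc["down", "ep_direction"] == -1
    assert hits.loc["up", "ep_direction"] == 1


def test_lethal_and_micronucleus_trivial_calls():
    lis1 = np.array([30.0, 31.0, 29.0, 33.0, 28.0])
    scores = pd.Series({"at_lis1_median": 30.0, "plk1_like": 100.0})
    lethal = call_lethal(scores, lis1)
    assert not lethal["at_lis1_median"]
    assert lethal["plk1_like"]
    mn = call_micronucleus_hits(pd.Series({"null": 0.0, "strong": 50.0}), lis1)
    assert not mn["null"] and mn["strong"]


def _mtoc_frames():
    rng = np.random.default_rng(0)
    p1 = np.clip(rng.normal(0.80, 0.01, 30), 0, 1)
    p0 = np.clip(rng.normal(0.10, 0.01, 30), 0, 1)
    ntc = pd.DataFrame({"p0": p0, "p1": p1})
    ntc["pmulti"] = 1.0 - ntc["p0"] - ntc["p1"]
    genes = pd.DataFrame(
        {
            "p0": [0.10, 0.05, 0.50, 0.10],
            "p1": [0.80, 0.35, 0.42, 0.80],
            "pmulti": [0.10, 0.60, 0.08, 0.10],
        },
        index=["normal", "gain", "loss", "ntc_reference_exact"],
    )
    return genes, ntc


def test_mtoc_categorization():
    genes, ntc = _mtoc_frames()
    cats = categorize_mtoc(genes, ntc)
    assert cats.loc["normal", "category"] == "normal"
    assert cats.loc["gain", "category"] == "mtoc_gain"
    assert cats.loc["loss", "category"] == "mtoc_loss"
    assert cats.loc["ntc_reference_exact", "category"] == "normal"


def test_mtoc_proportions_must_sum_to_one():
    genes, ntc = _mtoc_frames()
    bad = genes.copy()
    bad.loc["normal", "p0"] = 0.5
    with pytest.raises(ValueError):
        categorize_mtoc(bad, ntc)


@pytest.mark.parametrize(
    "confirmed, total, decimals, expected",
    [
        (19, 22, 1, 86.4),
        (195, 296, 0, 66.0),
        (243, 377, 1, 64.5),
        (193, 377, 1, 51.2),
        (50, 377, 1, 13.3),
        (0, 5, 1, 0.0),
    ],
)
def test_confirmation_percentages_round_half_up(confirmed, total, decimals, expected):
    assert summarize_confirmation(confirmed, total, decimals) == expected


def test_confirmation_rejects_bad_counts():
    with pytest.raises(ValueError):
        summarize_confirmation(1, 0)
    with pytest.raises(ValueError):
        summarize_confirmation(5, 3)


def test_excluded_genes_never_carry_cargo_labels():
    refs = {
        "NTC": {"ep": REF, "nucleus_area": REF, "nucleus_roundness": REF},
        "crLIS1": {"ep": REF, "nucleus_area": REF, "nucleus_roundness": REF},
    }
    genes = pd.DataFrame(
        {"ep": [-50.0, -50.0], "nucleus_area": [0.0, 40.0], "nucleus_roundness": [0.0, 0.0]},
        index=["kept", "confounded"],
    )
    cargo = call_cargo_hits(genes, refs, [ThresholdRule("ep", "NTC", 2.5)])
    exclusions = exclude_confounded(genes, refs)
    table = build_hit_table(genes, exclusions, cargo)
    assert table.loc["kept", "any_cargo_hit"]
    assert table.loc["confounded", "excluded"]
    assert not table.loc["confounded", "any_cargo_hit"]
    assert table.index.is_unique
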