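import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dynscreen.plates import (
    CompositeEndpoint,
    EndpointError,
    NormalizationError,
    aggregate_crrna,
    aggregate_well,
    fit_lda_endpoint,
    replicate_concordance,
    robust_z_prime,
    rz_normalize,
    two_point_normalize,
)

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


# ------------------------------------------------------------- aggregation


def test_aggregate_well_mean_and_counts():
    cells = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
    prof = aggregate_well(cells, ["f"], min_cells=2)
    assert prof["f"] == 2.0
    assert prof["n_cells"] == 3 and prof["n_viable"] == 3
    assert not prof["low_count"] and not prof["excluded"]


def test_aggregate_well_all_gated_out_is_excluded():
    cells = pd.DataFrame({"f": [1.0, 2.0]})
    prof = aggregate_well(cells, ["f"], gate=pd.Series([False, False]))
    assert prof["excluded"]
    assert np.isnan(prof["f"])


def test_aggregate_well_matches_direct_summation():
    rng = np.random.default_rng(0)
    cells = pd.DataFrame({"f": rng.normal(size=1000)})
    prof = aggregate_well(cells, ["f"])
    oracle = float(np.sum(cells["f"].to_numpy()) / 1000)
    assert prof["f"] == pytest.approx(oracle, rel=1e-12)


# ---------------------------------------------------------------- rZ score


def test_rz_hand_computed_oracle():
    # NTC = {1..5}: median 3, MAD 1, robust SD 1.4826
    ntc = np.array([1, 2, 3, 4, 5], dtype=float)
    med, mad = np.median(ntc), np.median(np.abs(ntc - np.median(ntc)))
    assert rz_normalize(3.0, med, mad) == 0.0
    assert rz_normalize(3.0 + 1.4826, med, mad) == pytest.approx(1.0)


@given(x=finite)
def test_rz_antisymmetric_about_the_median(x):
    med, mad = 3.0, 1.0
    assert rz_normalize(x, med, mad) == pytest.approx(-rz_normalize(2 * med - x, med, mad))


def test_rz_zero_mad_raises_with_context():
    with pytest.raises(NormalizationError, match="featX.*plate9"):
        rz_normalize(1.0, 0.0, 0.0, feature="featX", plate="plate9")


@given(a=st.floats(min_value=-100, max_value=100), b=st.floats(min_value=0.1, max_value=100))
def test_rz_invariant_under_joint_affine_transform(a, b):
    ntc = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    x = 4.2
    med, mad = np.median(ntc), np.median(np.abs(ntc - np.median(ntc)))
    t = b * ntc + a
    tmed, tmad = np.median(t), np.median(np.abs(t - np.median(t)))
    assert rz_normalize(b * x + a, tmed, tmad) == pytest.approx(rz_normalize(x, med, mad))


# ----------------------------------------------------------- two-point score


@pytest.mark.parametrize(
    "x, expected", [(10.0, 0.0), (2.0, -100.0), (6.0, -50.0), (14.0, 50.0)]
)
def test_two_point_maps_control_medians(x, expected):
    assert two_point_normalize(x, med_ntc=10.0, med_pos=2.0, pos_target=-100.0) == expected


def test_two_point_equal_medians_raise():
    with pytest.raises(NormalizationError):
        two_point_normalize(1.0, 5.0, 5.0, -100.0)


# ------------------------------------------------------------------- rZ'


def test_rz_prime_perfect_window():
    assert robust_z_prime([10, 10, 10], [0, 0, 0]) == 1.0


def test_rz_prime_hand_computed_oracle():
    # {1..5} vs {11..15}: MAD 1 each, spread 2*1.4826, |dmed| = 10
    assert robust_z_prime([11, 12, 13, 14, 15], [1, 2, 3, 4, 5]) == pytest.approx(0.11044)


def test_rz_prime_symmetric_in_groups():
    pos, neg = [11, 12, 13, 15, 18], [1, 2, 3.5, 4, 5]
    assert robust_z_prime(pos, neg) == robust_z_prime(neg, pos)


def test_rz_prime_equal_medians_warns_and_returns_neg_inf():
    with pytest.warns(UserWarning):
        assert robust_z_prime([1, 2, 3], [3, 2, 1]) == -np.inf


def test_rz_prime_monotone_in_control_separation():
    neg = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    windows = [robust_z_prime(neg + shift, neg) for shift in (8.0, 16.0, 32.0)]
    assert windows[0] < windows[1] < windows[2]


@given(a=st.floats(min_value=-50, max_value=50), b=st.floats(min_value=0.1, max_value=50))
def test_rz_prime_invariant_under_joint_affine(a, b):
    pos = np.array([11.0, 12.5, 13.0, 14.0, 15.0])
    neg = np.array([1.0, 2.0, 3.0, 4.5, 5.0])
    assert robust_z_prime(b * pos + a, b * neg + a) == pytest.approx(
        robust_z_prime(pos, neg)
    )


# ------------------------------------------------------------------- LDA


def _profiles(n=200, seed=0):
    rng = np.random.default_rng(seed)
    ntc = pd.DataFrame(
        {"informative": rng.normal(0, 1, n), "noise": rng.normal(0, 1, n)}
    )
    pos = pd.DataFrame(
        {"informative": rng.normal(-5, 1, n), "noise": rng.normal(0, 1, n)}
    )
    profiles = pd.concat([ntc, pos], ignore_index=True)
    labels = pd.Series(["NTC"] * n + ["positive"] * n)
    return profiles, labels


def test_lda_suppresses_pure_noise_feature():
    profiles, labels = _profiles()
    ep = fit_lda_endpoint(profiles, labels, ["informative", "noise"], rz_prime_min=-np.inf)
    w = dict(zip(ep.features, ep.weights))
    assert abs(w["noise"]) / abs(w["informative"]) < 0.05


def test_lda_identical_features_share_weight():
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(0, 1, 100), rng.normal(-5, 1, 100)])
    profiles = pd.DataFrame({"a": x, "b": x.copy()})
    labels = pd.Series(["NTC"] * 100 + ["positive"] * 100)
    ep = fit_lda_endpoint(profiles, labels, ["a", "b"], rz_prime_min=-10.0)
    assert ep.weights[0] == pytest.approx(ep.weights[1], abs=1e-6)


def test_lda_projection_rescaled_to_control_medians():
    profiles, labels = _profiles()
    ep = fit_lda_endpoint(profiles, labels, ["informative", "noise"], rz_prime_min=-10.0)
    scores = ep.apply(profiles)
    assert np.median(scores[labels == "NTC"]) == pytest.approx(0.0, abs=1e-9)
    assert np.median(scores[labels == "positive"]) == pytest.approx(-100.0, abs=1e-9)


def test_lda_requires_an_informative_feature():
    profiles, labels = _profiles()
    with pytest.raises(EndpointError):
        fit_lda_endpoint(profiles, labels, ["noise"], rz_prime_min=0.1)


def test_lda_endpoint_round_trips_through_json():
    profiles, labels = _profiles()
    ep = fit_lda_endpoint(profiles, labels, ["informative", "noise"], rz_prime_min=-10.0)
    back = CompositeEndpoint.from_json(ep.to_json())
    pd.testing.assert_series_equal(back.apply(profiles), ep.apply(profiles))


# ----------------------------------------------------- replicates & pooling


def test_identical_replicates_have_unit_r_squared():
    s = pd.Series([1.0, 2.0, -3.0, 4.0], index=list("abcd"))
    r2, usable = replicate_concordance(s, s)
    assert r2 == pytest.approx(1.0)
    assert usable


def test_independent_noise_replicates_have_near_zero_r_squared():
    rng = np.random.default_rng(7)
    idx = [f"g{i}" for i in range(300)]
    r2, usable = replicate_concordance(
        pd.Series(rng.normal(size=300), index=idx),
        pd.Series(rng.normal(size=300), index=idx),
    )
    assert r2 < 0.05
    assert not usable


def test_weak_concordance_flagged_unusable():
    # R^2 around 0.15 stays under the 0.2 usability threshold
    rng = np.random.default_rng(3)
    x = rng.normal(size=500)
    y = 0.42 * x + rng.normal(size=500)
    r2, usable = replicate_concordance(
        pd.Series(x, index=range(500)), pd.Series(y, index=range(500))
    )
    assert 0.05 < r2 < 0.2
    assert not usable


def test_replicate_concordance_needs_three_pairs():
    with pytest.raises(ValueError):
        replicate_concordance(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))


def test_aggregate_crrna_median_examples():
    assert aggregate_crrna(pd.Series([-3.0, -2.0, -10.0])) == -3.0
    assert aggregate_crrna(pd.Series([4.5])) == 4.5


def test_aggregate_crrna_matches_sorting_oracle():
    rng = np.random.default_rng(11)
    scores = pd.Series(rng.normal(size=4000))
    pools = pd.Series(rng.integers(0, 1000, size=4000))
    pooled = aggregate_crrna(scores, pools)
    for pool in (0, 17, 999):
        vals = np.sort(scores[pools == pool].to_numpy())
        if len(vals) == 0:
            continue
        mid = len(vals) // 2
        oracle = vals[mid] if len(vals) % 2 else 0.5 * (vals[mid - 1] + vals[mid])
        assert pooled[pool] == pytest.approx(oracle)
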