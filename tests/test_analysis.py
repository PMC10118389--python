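"""Population statistics: immunity, shifts, turnover, clans, PCA, tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crisprcoevo as cc
from crisprcoevo.analysis import (
    AbundanceSeries,
    average_immunity,
    centre_of_mass,
    classify_large_clones,
    cluster_clans,
    empirical_establishment,
    marginal_immunity,
    morisita_horn,
    pca_trajectories,
    shift_asymmetry_test,
    speed_and_spread,
    time_shift_immunity,
    turnover,
)
from crisprcoevo.params import CrossReactivity


# ----------------------------------------------------------------------
# average and marginal immunity
# ----------------------------------------------------------------------

def test_average_immunity_hand_examples():
    # single shared type: immunity = e
    assert average_immunity({"A": 5}, {"A": 3}, e=0.4) == pytest.approx(0.4)
    # disjoint type sets, all-or-nothing kernel
    assert average_immunity({"A": 5}, {"B": 3}, e=1.0) == pytest.approx(0.0)
    # worked fraction: bacteria {A:2,B:1}, phage {A:1,C:3}, e = 1
    got = average_immunity({"A": 2, "B": 1}, {"A": 1, "C": 3}, e=1.0)
    assert got == pytest.approx(2 / 12)
    with pytest.raises(ValueError):
        average_immunity({}, {"A": 1})


def test_average_immunity_sequence_kernel():
    xr = CrossReactivity("step", 1.0)
    # clone one mutation from every phage, step kernel: full effectiveness
    got = marginal_immunity("01", "bacteria", {"00": 5, "11": 5}, e=0.95, xr=xr)
    assert got == pytest.approx(0.95)


def test_marginal_immunity_extremes():
    assert marginal_immunity("A", "bacteria", {"A": 10}, e=0.95) == pytest.approx(0.95)
    assert marginal_immunity("Z", "bacteria", {"A": 10}, e=0.95) == pytest.approx(0.0)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(1, 40), st.integers(0, 40)),
                min_size=1, max_size=6),
       st.floats(0.05, 1.0))
def test_delta_matching_equals_scaled_overlap(rows, e):
    """Average immunity with delta matching = e x matched-count overlap."""
    bact = {}
    phage = {}
    for t, nb, nv in rows:
        bact[f"T{t}"] = bact.get(f"T{t}", 0) + nb
        if nv:
            phage[f"T{t}"] = phage.get(f"T{t}", 0) + nv
    phage.setdefault("other", 3)
    NB = sum(bact.values())
    NV = sum(phage.values())
    overlap = sum(bact[k] * phage[k] for k in set(bact) & set(phage)) / (NB * NV)
    assert average_immunity(bact, phage, e=e) == pytest.approx(e * overlap, rel=1e-9)


def test_average_immunity_bounds_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(20):
        bact = {f"T{i}": rng.integers(1, 50) for i in range(rng.integers(1, 8))}
        phage = {f"T{i}": rng.integers(1, 50) for i in range(rng.integers(1, 8))}
        v = average_immunity(bact, phage, e=rng.uniform(0, 1))
        assert 0.0 <= v <= 1.0


# ----------------------------------------------------------------------
# time shift and turnover
# ----------------------------------------------------------------------

def _series(times, tables, population):
    types = sorted(set().union(*tables))
    counts = np.zeros((len(times), len(types)))
    for i, tab in enumerate(tables):
        for k, t in enumerate(types):
            counts[i, k] = tab.get(t, 0)
    return AbundanceSeries(np.asarray(times, float), types, counts, population)


def test_time_shift_zero_delay_matches_time_average():
    b = _series([0, 1, 2], [{"A": 2, "B": 1}, {"A": 1, "B": 2}, {"B": 3}], "bacteria")
    v = _series([0, 1, 2], [{"A": 1, "C": 3}, {"A": 2}, {"B": 1, "C": 1}], "phage")
    curve = time_shift_immunity(b, v, e=1.0)
    direct = np.mean([average_immunity(b.at(i), v.at(i), e=1.0) for i in range(3)])
    assert curve.at_zero() == pytest.approx(direct)
    assert curve.n[np.argmin(np.abs(curve.delays))] == 3


def test_time_shift_flat_for_stationary_series():
    tab = {"A": 2, "B": 1}
    b = _series(range(5), [dict(tab)] * 5, "bacteria")
    v = _series(range(5), [{"A": 1, "C": 1}] * 5, "phage")
    curve = time_shift_immunity(b, v, e=1.0)
    assert np.allclose(curve.mean, curve.mean[0])
    assert np.allclose(curve.sd, 0.0)


def test_time_shift_multiplier_applied():
    b = _series([0, 1], [{"A": 1}] * 2, "bacteria")
    v = _series([0, 1], [{"A": 1, "B": 3}] * 2, "phage")
    c1 = time_shift_immunity(b, v, e=1.0)
    c2 = time_shift_immunity(b, v, multiplier=696.0, e=1.0)
    assert c2.at_zero() == pytest.approx(696.0 * c1.at_zero())


def test_turnover_hand_example_and_monotone_decay():
    s = _series([0, 1], [{"a": 1, "b": 1, "c": 1}, {"a": 1, "c": 2, "d": 5}], "phage")
    c = turnover(s)
    assert c.mean[0] == pytest.approx(1.0)
    assert c.mean[1] == pytest.approx(2 / 3)
    # strictly nested disappearance: non-increasing curve
    tabs = [{"a": 1, "b": 1, "c": 1, "d": 1}, {"a": 1, "b": 1, "c": 1},
            {"a": 1, "b": 1}, {"a": 1}]
    c2 = turnover(_series(range(4), tabs, "phage"))
    assert np.all(np.diff(c2.mean) <= 1e-12)


# ----------------------------------------------------------------------
# establishment statistics
# ----------------------------------------------------------------------

def test_classify_large_clones_weights():
    out = classify_large_clones([1000.0], pest=2.09e-3, n_est=1e9)
    assert out["estimated_count"] == pytest.approx(1 - (1 - 0.00209) ** 1000, rel=1e-3)
    assert out["estimated_count"] == pytest.approx(0.877, rel=2e-3)
    assert classify_large_clones([5, 50, 500], pest=0.0, n_est=1e9)["estimated_count"] == 0
    # n -> infinity weight -> 1; at/above cutoff weight is exactly 1
    out2 = classify_large_clones([1e9, 10], pest=1e-3, n_est=100)
    assert out2["estimated_count"] == pytest.approx(1 + 1 - (1 - 1e-3) ** 10, rel=1e-6)


def _fake_clone(pop, max_size, birth=0.0, parent=0):
    from crisprcoevo.simulate import CloneRecord
    return CloneRecord(population=pop, sequence=1, parent=parent, birth=birth,
                       establishment=None, extinction=None, max_size=max_size)


def test_empirical_establishment_thresholds():
    clones = [_fake_clone("phage", s) for s in (1, 5, 50, 500)]
    assert empirical_establishment(clones, 0.0)["fraction_established"] == 1.0
    assert empirical_establishment(clones, np.inf)["fraction_established"] == 0.0
    assert empirical_establishment(clones, 10)["fraction_established"] == 0.5
    with pytest.raises(ValueError):
        empirical_establishment([], 1.0)


# ----------------------------------------------------------------------
# sequence-space geometry
# ----------------------------------------------------------------------

def test_centre_of_mass_worked_example():
    # 20 phages at [0,1] and 10 at [1,1]: centre of mass (1/3, 1)
    com = centre_of_mass(["01", "11"], [20, 10])
    assert com[0] == pytest.approx(1 / 3)
    assert com[1] == pytest.approx(1.0)
    out = speed_and_spread([(0.0, {"01": 20, "11": 10})], "00")
    assert out["distance"][0] == pytest.approx(4 / 3)


def test_spread_zero_for_monomorphic_population():
    out = speed_and_spread([(0.0, {"0101": 30})], "0000")
    assert out["spread"][0] == pytest.approx(0.0)
    assert out["distance"][0] == pytest.approx(2.0)


def test_speed_uses_max_distance_over_elapsed_time():
    snaps = [(0.0, {"00": 1}), (10.0, {"01": 1}), (20.0, {"11": 1}),
             (30.0, {"01": 1})]
    out = speed_and_spread(snaps, "00")
    assert out["max_distance"] == pytest.approx(2.0)
    assert out["speed"] == pytest.approx(2.0 / 30.0)


def test_cluster_clans_examples():
    assert cluster_clans(["0101"] * 4)["n_clans"] == 1
    res = cluster_clans(["000", "001", "011", "110"])
    assert res["n_clans"] == 2
    labels = res["labels"]
    assert labels[0] == labels[1] == labels[2]
    assert labels[3] != labels[0]
    # single-linkage chaining: a-b-c with d(a,b)=d(b,c)=1, d(a,c)=2
    assert cluster_clans(["000", "001", "011"])["n_clans"] == 1


def test_cluster_clans_order_and_abundance_invariance():
    seqs = ["0000", "0001", "0011", "1100", "1110"]
    base = cluster_clans(seqs)["n_clans"]
    perm = cluster_clans(seqs[::-1])["n_clans"]
    w = cluster_clans(seqs, [5, 1, 7, 2, 2])
    assert base == perm == w["n_clans"] == 2
    assert w["clan_sizes"].sum() == 17


def test_pca_trajectories_properties():
    times = np.arange(6.0)
    # two-type seesaw: rank-one variation
    counts = np.stack([np.linspace(1, 5, 6), np.linspace(5, 1, 6)], axis=1)
    v = AbundanceSeries(times, ["A", "B"], counts, "phage")
    b = AbundanceSeries(times, ["A", "B"], counts[::-1].copy(), "bacteria")
    out = pca_trajectories(v, b)
    evr = out["explained_variance_ratio"]
    assert evr[0] >= evr[1]
    assert np.allclose(out["phage"][:, 1], 0.0, atol=1e-9)
    # constant composition: all projected points coincide
    const = AbundanceSeries(times, ["A", "B"], np.tile([2.0, 1.0], (6, 1)), "phage")
    out2 = pca_trajectories(const, b)
    assert np.allclose(out2["phage"], out2["phage"][0], atol=1e-9)


# ----------------------------------------------------------------------
# similarity and the signed-rank test
# ----------------------------------------------------------------------

def test_morisita_horn_examples():
    assert morisita_horn({"A": 2, "B": 4}, {"A": 1, "B": 2}) == pytest.approx(1.0)
    assert morisita_horn({"A": 1}, {"B": 1}) == pytest.approx(0.0)
    # (5/9 + 10/16) * 3 * 4 = 170/12, so psi = 48/170 = 24/85
    got = morisita_horn({"A": 2, "B": 1}, {"A": 1, "C": 3})
    assert got == pytest.approx(24 / 85, rel=1e-12)
    with pytest.raises(ValueError):
        morisita_horn({}, {"A": 1})


def test_shift_asymmetry_degenerate_pairs():
    out = shift_asymmetry_test([0.3] * 8, [0.3] * 8)
    assert out["degenerate"] and out["p_value"] == pytest.approx(1.0)


def test_shift_asymmetry_minimal_p_n10():
    z = np.linspace(0.5, 0.6, 10)
    s = z - 0.1  # every shifted value strictly below its pair
    out = shift_asymmetry_test(z, s)
    assert out["p_value"] == pytest.approx(1 / 2 ** 10, rel=1e-9)


def test_shift_asymmetry_null_calibration():
    """Symmetric noise: one-sided p approximately uniform under the null."""
    rng = np.random.default_rng(3)
    ps = []
    for _ in range(300):
        z = rng.normal(size=12)
        s = z + rng.choice([-1, 1], size=12) * rng.exponential(1.0, size=12)
        ps.append(shift_asymmetry_test(z, s)["p_value"])
    from scipy.stats import kstest
    assert kstest(ps, "uniform").pvalue > 0.01


# ----------------------------------------------------------------------
# series container
# ----------------------------------------------------------------------

def test_series_validation_and_interpolation():
    with pytest.raises(ValueError):
        AbundanceSeries(np.array([0.0, 0.0]), ["A"], np.ones((2, 1)))
    with pytest.raises(ValueError):
        AbundanceSeries(np.array([0.0, 1.0]), ["A", "A"], np.ones((2, 2)))
    s = _series([0, 2, 4], [{"A": 2}, {"A": 4}, {"A": 0}], "phage")
    g = s.interpolate(np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
    assert np.allclose(g.counts[:, 0], [2, 3, 4, 2, 0])
    assert (g.counts >= 0).all()
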