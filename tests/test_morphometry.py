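import numpy as np
import pytest
from scipy import integrate, stats

from ploidyscale.morphometry import (
    classify_scaling,
    compartment_summary,
    frustum_lateral_area,
    frustum_volume,
    length_by_diameter,
    neurite_share_trend,
    population_folds,
    segment_metrics,
    sholl,
    weighted_ks,
)
from ploidyscale.simulate.neurons import NeuronSimParams, simulate_population
from ploidyscale.swc import NEURITE, SOMA

from conftest import make_tree


# ---------------------------------------------------------------------- edges

def test_cylinder_and_cone_closed_forms():
    assert frustum_volume(1.0, 1.0, 1.0) == pytest.approx(np.pi)
    assert frustum_lateral_area(1.0, 1.0, 1.0) == pytest.approx(2 * np.pi)
    assert frustum_volume(1.0, 0.0, 3.0) == pytest.approx(np.pi)
    assert frustum_lateral_area(1.0, 0.0, 3.0) == pytest.approx(np.pi * np.sqrt(10.0))


def test_frustum_matches_quadrature_on_random_edges():
    """Volume from pi*r(t)^2 and area from the surface-of-revolution integral."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        r1, r2 = rng.uniform(0.1, 3.0, 2)
        length = rng.uniform(0.5, 30.0)

        def radius(t):
            return r1 + (r2 - r1) * t / length

        v_num, _ = integrate.quad(lambda t: np.pi * radius(t) ** 2, 0, length)
        dr_dt = (r2 - r1) / length
        a_num, _ = integrate.quad(
            lambda t: 2 * np.pi * radius(t) * np.sqrt(1 + dr_dt**2), 0, length
        )
        assert frustum_volume(r1, r2, length) == pytest.approx(v_num, rel=1e-6)
        assert frustum_lateral_area(r1, r2, length) == pytest.approx(a_num, rel=1e-6)


# ------------------------------------------------------------------ summaries

def test_sphere_soma_only(soma_only_tree):
    rec = compartment_summary(soma_only_tree)
    assert rec.soma_volume == pytest.approx(4188.79, abs=0.01)
    assert rec.soma_surface == pytest.approx(1256.64, abs=0.01)
    assert rec.no_neurites
    assert rec.total_volume == rec.soma_volume


def test_unbranched_chain_summary(straight_chain_tree):
    rec = compartment_summary(straight_chain_tree)
    assert rec.total_neurite_length == pytest.approx(50.0)
    assert rec.n_terminal_points == 1
    assert rec.max_branch_level == 1
    # last node sits 52 um from the soma centre (soma radius 2 + 50)
    assert rec.max_radius == pytest.approx(52.0)
    assert rec.mean_neurite_diameter == pytest.approx(1.0)


def test_symmetric_binary_tree_counts(binary_tree_depth3):
    rec = compartment_summary(binary_tree_depth3)
    assert rec.n_terminal_points == 8
    assert rec.max_branch_level == 4  # stem level 1 + 3 bifurcations


def test_additivity_of_compartments(binary_tree_depth3):
    rec = compartment_summary(binary_tree_depth3)
    assert rec.total_volume == pytest.approx(rec.soma_volume + rec.neurite_volume, rel=1e-12)
    assert rec.total_surface == pytest.approx(rec.soma_surface + rec.neurite_surface, rel=1e-12)


def test_isometry_invariance():
    tree = simulate_population(NeuronSimParams(), 1, "diploid", seed=5)[0]
    rec = compartment_summary(tree)
    # rigid rotation + translation
    theta = 0.7
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0],
        [np.sin(theta), np.cos(theta), 0],
        [0, 0, 1],
    ])
    moved = make_tree([
        (int(tree.parent_id[i]), int(tree.node_type[i]),
         *(rot @ tree.xyz[i] + np.array([5.0, -3.0, 11.0])), float(tree.radius[i]))
        for i in range(tree.n_nodes)
    ])
    rec2 = compartment_summary(moved)
    for prop in ("soma_volume", "neurite_volume", "neurite_surface",
                 "total_neurite_length", "max_radius", "mean_neurite_diameter"):
        assert getattr(rec2, prop) == pytest.approx(getattr(rec, prop), rel=1e-9)


def test_rescaling_identity_volume_and_area():
    """Scaling lengths by a and radii by b: V x a*b^2, lateral A x a*b (cylinders)."""
    params = NeuronSimParams(taper_ratio=1.0)
    tree = simulate_population(params, 1, "diploid", seed=9)[0]
    a, b = 1.7, 0.8
    scaled = tree.rescaled(length_factor=a, neurite_radius_factor=b, soma_radius_factor=1.0)
    s0, s1 = segment_metrics(tree), segment_metrics(scaled)
    assert s1.volume.sum() == pytest.approx(a * b**2 * s0.volume.sum(), rel=1e-9)
    assert s1.lateral_area.sum() == pytest.approx(a * b * s0.lateral_area.sum(), rel=1e-9)
    assert s1.length.sum() == pytest.approx(a * s0.length.sum(), rel=1e-9)


# -------------------------------------------------- length-by-diameter and KS

def test_length_by_diameter_step_functions(straight_chain_tree):
    seg = segment_metrics(straight_chain_tree)
    grid = np.array([0.5, 0.99, 1.0, 2.0])
    frac = length_by_diameter([seg], grid)
    np.testing.assert_allclose(frac, [0, 0, 1, 1])


def test_length_by_diameter_two_diameters():
    t = make_tree([
        (-1, SOMA, 0, 0, 0, 1.0),
        (0, NEURITE, 11, 0, 0, 0.5),    # d=1, effective length 10
        (1, NEURITE, 21, 0, 0, 0.5),
        (0, NEURITE, 0, 11, 0, 1.0),    # d=2, effective length 10
        (3, NEURITE, 0, 21, 0, 1.0),
    ])
    seg = segment_metrics(t)
    frac = length_by_diameter([seg], np.array([1.0, 1.5, 2.0]))
    np.testing.assert_allclose(frac, [0.5, 0.5, 1.0])


def test_triploid_diameter_distribution_shifts_left():
    params = NeuronSimParams()
    for seed in range(1, 6):
        dip = [segment_metrics(t) for t in simulate_population(params, 5, "diploid", seed)]
        tri = [segment_metrics(t) for t in simulate_population(params, 5, "triploid", seed)]
        grid = np.linspace(0.1, 3.0, 50)
        fd = length_by_diameter(dip, grid)
        ft = length_by_diameter(tri, grid)
        assert np.all(ft >= fd - 1e-12)  # stochastic dominance toward smaller d
        assert ft.sum() > fd.sum()


def test_weighted_ks_identical_and_disjoint():
    a = [(np.array([1.0, 2.0]), np.array([1.0, 1.0]))]
    d, p = weighted_ks(a, list(a), n_perm=200, seed=0)
    assert d == 0.0 and p == 1.0
    b = [(np.array([10.0, 20.0]), np.array([1.0, 1.0]))]
    d, _ = weighted_ks(a, b, n_perm=200, seed=0)
    assert d == pytest.approx(1.0)


def test_weighted_ks_reduces_to_classical_under_equal_weights():
    rng = np.random.default_rng(3)
    xa = rng.normal(0, 1, 60)
    xb = rng.normal(0.4, 1.2, 45)
    ga = [(np.array([v]), np.array([1.0])) for v in xa]
    gb = [(np.array([v]), np.array([1.0])) for v in xb]
    d, _ = weighted_ks(ga, gb, n_perm=100, seed=0)
    assert d == pytest.approx(stats.ks_2samp(xa, xb).statistic, abs=1e-12)


# ---------------------------------------------------------------------- sholl

def test_sholl_straight_neurite():
    nodes = [(-1, SOMA, 0, 0, 0, 1.0)]
    for i in range(10):
        nodes.append((i, NEURITE, 10.0 * (i + 1), 0, 0, 0.5))
    radii, counts = sholl(make_tree(nodes), step=10.0)
    np.testing.assert_allclose(radii, np.arange(10, 101, 10))
    np.testing.assert_array_equal(counts, np.ones(10, dtype=int))


def test_sholl_bifurcation_at_15():
    t = make_tree([
        (-1, SOMA, 0, 0, 0, 1.0),
        (0, NEURITE, 15, 0, 0, 0.5),
        (1, NEURITE, 25, 7, 0, 0.5),
        (1, NEURITE, 25, -7, 0, 0.5),
    ])
    radii, counts = sholl(t, step=10.0)
    assert counts[0] == 1   # r=10 crosses only the stem
    assert counts[1] == 2   # r=20 crosses both daughters


def test_sholl_total_crossings_bound_and_bruteforce():
    tree = simulate_population(NeuronSimParams(), 1, "diploid", seed=11)[0]
    step = 2.0
    radii, counts = sholl(tree, step=step)
    rec = compartment_summary(tree)
    # every tip path crosses every sphere inside its extent
    assert counts.sum() >= rec.n_terminal_points
    # brute-force per-edge sphere crossing oracle
    centroid = tree.soma_centroid()
    soma = tree.soma_mask()
    dist = np.linalg.norm(tree.xyz - centroid, axis=1)
    for r, c in zip(radii, counts):
        brute = 0
        for i in range(tree.n_nodes):
            p = tree.parent_id[i]
            if p < 0 or soma[i]:
                continue
            d_par = 0.0 if soma[p] else dist[p]
            lo, hi = min(d_par, dist[i]), max(d_par, dist[i])
            if lo < r <= hi:
                brute += 1
        assert c == brute


# ------------------------------------------------ folds, scaling, share trend

def test_population_folds_identity():
    recs = [compartment_summary(t)
            for t in simulate_population(NeuronSimParams(), 5, "diploid", seed=2)]
    folds = population_folds(recs, list(recs), n_boot=50, seed=0)
    assert np.allclose(folds["fold"], 1.0)


def test_population_folds_deterministic_rescaling():
    """Seed-paired triploids are exact rescalings: compartment folds are analytic."""
    params = NeuronSimParams(taper_ratio=1.0)
    dip = [compartment_summary(t) for t in simulate_population(params, 10, "diploid", 4)]
    tri = [compartment_summary(t) for t in simulate_population(params, 10, "triploid", 4)]
    folds = population_folds(dip, tri, n_boot=50, seed=0).set_index("property")["fold"]
    assert folds["neurite_surface"] == pytest.approx(np.sqrt(1.5 * 1.95), rel=1e-6)
    assert folds["soma_surface"] == pytest.approx(1.5 ** (2 / 3), rel=1e-9)
    assert folds["soma_volume"] == pytest.approx(1.5, rel=1e-9)
    assert folds["neurite_volume"] == pytest.approx(1.5, rel=1e-6)
    assert folds["total_neurite_length"] == pytest.approx(1.95, rel=1e-9)


@pytest.mark.parametrize("fold, expected", [
    (1.5, "scaling"),
    (1.71, "superscaling"),
    (1.31, "subscaling"),
])
def test_classify_scaling_against_ploidy_reference(fold, expected):
    assert classify_scaling(fold, reference_fold=1.5, tolerance=0.1).scaling_class == expected


def test_classify_scaling_boundaries_inclusive():
    assert classify_scaling(1.6, 1.5, 0.1).scaling_class == "scaling"
    assert classify_scaling(1.4, 1.5, 0.1).scaling_class == "scaling"


def _records_with_shares(x, share):
    """Fabricate records with given total volumes and neurite surface shares."""
    recs = []
    for xv, s in zip(x, share):
        rec = compartment_summary(make_tree([(-1, SOMA, 0, 0, 0, 5.0)]))
        rec.total_volume = xv
        rec.total_surface = 100.0
        rec.neurite_surface = 100.0 * s
        recs.append(rec)
    return recs


def test_share_trend_constant_is_stable():
    x = np.linspace(1000, 5000, 30)
    res = neurite_share_trend(_records_with_shares(x, np.full(30, 0.8)))
    assert res["slope"] == pytest.approx(0.0, abs=1e-12)
    assert res["cusum_p"] > 0.05


def test_share_trend_detects_injected_break():
    rng = np.random.default_rng(0)
    n = 100
    x = np.linspace(1000, 9000, n)
    detections = 0
    reps = 25
    for _ in range(reps):
        share = np.where(x < 5000, 0.70, 0.85) + rng.normal(0, 0.02, n)
        res = neurite_share_trend(_records_with_shares(x, share))
        detections += res["cusum_p"] < 0.05
    assert detections / reps > 0.8


def test_share_trend_rises_with_neuron_size_in_generator():
    params = NeuronSimParams()
    for seed in range(1, 6):
        recs = [compartment_summary(t)
                for t in simulate_population(params, 30, "diploid", seed)]
        res = neurite_share_trend(recs)
        assert res["slope"] > 0
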