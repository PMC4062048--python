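"""Copy-number ratios, mixture binning and concordance."""

import itertools
import math

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from kirlink import (
    CNVEstimate,
    DegenerateFitError,
    NoReferenceError,
    QuadrantCounts,
    assign_copy_numbers,
    cnv_from_quadrants,
    cohen_kappa,
    fit_copy_number_mixture,
)
from kirlink.cnv import _map_components_to_integers, component_posteriors
from kirlink.simulate import simulate_cnv_well


def _independent_quadrants(lam_a, lam_b, n=200000):
    """Quadrant counts matching independent loading at the given occupancies
    as closely as integer rounding allows."""
    p_an, p_bn = math.exp(-lam_a), math.exp(-lam_b)
    n_nn = round(n * p_an * p_bn)
    n_np = round(n * p_an * (1 - p_bn))
    n_pn = round(n * (1 - p_an) * p_bn)
    return QuadrantCounts(n_nn=n_nn, n_pn=n_pn, n_np=n_np,
                          n_pp=n - n_nn - n_np - n_pn)


def test_reference_equal_target_is_diploid():
    q = QuadrantCounts(n_nn=4000, n_pn=4000, n_np=4000, n_pp=4000)
    est = cnv_from_quadrants(q)
    assert est.raw_cn == pytest.approx(2.0, abs=1e-12)
    assert est.ci_low < 2.0 < est.ci_high


def test_half_reference_ratio():
    q = _independent_quadrants(0.05, 0.10)
    est = cnv_from_quadrants(q)
    assert est.raw_cn == pytest.approx(1.0, abs=2e-3)


def test_zero_reference_raises():
    q = QuadrantCounts(n_nn=500, n_pn=500, n_np=0, n_pp=0)
    with pytest.raises(NoReferenceError):
        cnv_from_quadrants(q)


def test_ratio_scale_invariance():
    q1 = QuadrantCounts(n_nn=5000, n_pn=1500, n_np=3000, n_pp=500)
    q10 = QuadrantCounts(n_nn=50000, n_pn=15000, n_np=30000, n_pp=5000)
    assert cnv_from_quadrants(q1).raw_cn == pytest.approx(
        cnv_from_quadrants(q10).raw_cn, abs=1e-12)


def test_ratio_ci_brackets_truth_on_simulated_wells(rng):
    hits = 0
    for _ in range(50):
        q = simulate_cnv_well(2, 3000, 20000, rng)
        est = cnv_from_quadrants(q)
        hits += est.ci_low <= 2.0 <= est.ci_high
    assert hits >= 42  # ~95% nominal; binomial slack


# ---------------------------------------------------------------------------
# Mixture clustering


def _clustered_values(rng, means=(0.0, 1.0, 2.0), n_each=30, sd=0.05):
    """Raw copy-number values scattered around integer locations; the zero-
    copy cluster keeps its (small) signed measurement noise."""
    return np.concatenate([rng.normal(m, sd, n_each) for m in means])


def test_mixture_recovers_three_clusters(rng):
    vals = _clustered_values(rng)
    model = fit_copy_number_mixture(vals, seed=0)
    assert model.k == 3
    assert np.allclose(np.sort(model.means), model.means)
    assert list(model.component_to_integer) == [0, 1, 2]
    calls = assign_copy_numbers(model, vals)
    truth = [0] * 30 + [1] * 30 + [2] * 30
    assert [c.integer_cn for c in calls] == truth


def test_identical_values_collapse_to_one_component():
    model = fit_copy_number_mixture([1.5] * 20)
    assert model.k == 1
    assert model.means[0] == pytest.approx(1.5)


def test_too_few_values_raise():
    with pytest.raises(DegenerateFitError):
        fit_copy_number_mixture([1.0])
    with pytest.raises(DegenerateFitError):
        fit_copy_number_mixture([1.0, 2.0], k_candidates=[5])


def test_em_loglik_monotone(rng):
    """The EM ascent property, checked on every recorded trace."""
    for _ in range(5):
        vals = _clustered_values(rng, means=rng.uniform(0, 3, size=3), sd=0.1)
        model = fit_copy_number_mixture(vals, seed=0)
        diffs = np.diff(model.loglik_trace)
        assert np.all(diffs >= -1e-9)


def test_mixture_parameter_recovery(rng):
    """BIC selects the true component count and recovers locations for
    well-separated clusters (separation >= 6 sds)."""
    ok_k = 0
    reps = 30
    for _ in range(reps):
        k_true = int(rng.integers(2, 5))
        means = np.arange(k_true, dtype=float)
        sd = 0.08  # separation 1.0 > 6 * 0.08
        vals = _clustered_values(rng, means=means, n_each=30, sd=sd)
        model = fit_copy_number_mixture(vals, seed=0)
        if model.k == k_true:
            ok_k += 1
            se = sd / math.sqrt(30)
            assert np.allclose(model.means, means, atol=4 * se + 0.02)
    assert ok_k >= reps - 2


def test_against_sklearn_gaussian_mixture(rng):
    """Independent EM implementation agrees on a well-separated fit."""
    vals = _clustered_values(rng)
    model = fit_copy_number_mixture(vals, seed=0)
    gm = GaussianMixture(n_components=3, covariance_type="diag",
                         random_state=0, n_init=5).fit(vals.reshape(-1, 1))
    assert np.allclose(np.sort(gm.means_.ravel()), model.means, atol=0.02)


def test_systematic_underestimate_keeps_assignments(rng):
    """Clusters shifted to 85% of the integers (archival-DNA drift) must
    still map to the same integers."""
    base = _clustered_values(rng, means=(0.0, 1.0, 2.0, 3.0), n_each=25, sd=0.05)
    truth = [0] * 25 + [1] * 25 + [2] * 25 + [3] * 25
    shifted = base * 0.85
    model = fit_copy_number_mixture(shifted, seed=0)
    calls = assign_copy_numbers(model, shifted)
    assert [c.integer_cn for c in calls] == truth


def test_component_integer_mapping_handles_collisions():
    assert list(_map_components_to_integers(np.array([0.1, 1.9, 2.2]))) == [0, 2, 3]
    assert list(_map_components_to_integers(np.array([0.85, 1.7, 2.55]))) == [1, 2, 3]


def test_assignment_posteriors_and_flags(rng):
    vals = _clustered_values(rng)
    model = fit_copy_number_mixture(vals, seed=0)
    [call] = assign_copy_numbers(model, [2.01])
    assert call.integer_cn == 2
    assert call.posterior > 0.99
    assert not call.review_flag


def test_midpoint_tie_flags_and_breaks_low(rng):
    vals = np.concatenate([rng.normal(1.0, 0.05, 40), rng.normal(2.0, 0.05, 40)])
    model = fit_copy_number_mixture(vals, seed=0)
    midpoint = float(model.means.mean())
    post = component_posteriors(model, [midpoint])
    [call] = assign_copy_numbers(model, [midpoint])
    assert post[0, 0] == pytest.approx(post[0, 1], abs=0.02)
    assert call.review_flag
    assert call.integer_cn == model.component_to_integer[0]


def test_ci_excluding_assigned_integer_triggers_review(rng):
    """A sample binned at zero copies whose own interval excludes zero is the
    canonical case for manual correction toward one copy."""
    vals = _clustered_values(rng, means=(0.0, 1.0, 2.0), n_each=20, sd=0.03)
    model = fit_copy_number_mixture(vals, seed=0)
    est = CNVEstimate(sample_id="F-1268", gene="KIR2DL5", raw_cn=0.268,
                      ci_low=0.182, ci_high=0.353,
                      lambda_target=0.02, lambda_ref=0.15, n_droplets=15000)
    [call] = assign_copy_numbers(model, [est])
    assert call.integer_cn == 0
    assert call.review_flag


# ---------------------------------------------------------------------------
# Cohen's kappa


def test_kappa_hand_example():
    m1 = ["1"] * 4 + ["2"] * 5 + ["1"]
    m2 = ["1"] * 4 + ["2"] * 5 + ["2"]
    res = cohen_kappa(m1, m2)
    assert res.kappa == pytest.approx(0.8)
    assert res.n_pairs == 10
    assert res.ci_low <= 0.8 <= res.ci_high <= 1.0


def test_kappa_perfect_agreement():
    res = cohen_kappa([0, 1, 2, 1, 0], [0, 1, 2, 1, 0])
    assert res.kappa == pytest.approx(1.0)


def test_kappa_degenerate_single_category():
    res = cohen_kappa([1, 1, 1], [1, 1, 1])
    assert res.degenerate
    assert math.isnan(res.kappa)


def test_kappa_input_validation():
    with pytest.raises(ValueError):
        cohen_kappa([1, 2], [1])
    with pytest.raises(ValueError):
        cohen_kappa([1], [1])


def _kappa_by_enumeration(m1, m2):
    """Brute-force oracle: observed agreement by direct comparison; expected
    agreement by enumerating all n^2 cross-pairings of the two raters."""
    n = len(m1)
    p_o = sum(a == b for a, b in zip(m1, m2)) / n
    p_e = sum(a == b for a, b in itertools.product(m1, m2)) / n**2
    return (p_o - p_e) / (1 - p_e)


def test_kappa_matches_enumeration_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(2, 7))
        m1 = list(rng.integers(0, 3, size=n))
        m2 = list(rng.integers(0, 3, size=n))
        if len(set(m1) | set(m2)) < 2 or all(a == b for a, b in zip(m1, m2)):
            continue
        expected = _kappa_by_enumeration(m1, m2)
        assert cohen_kappa(m1, m2).kappa == pytest.approx(expected, abs=1e-12)
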