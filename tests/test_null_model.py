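"""Background model, exact/sampled null distributions and permutation p-values."""

import itertools
from math import comb

import numpy as np
import pytest

from varlap.io import ExpressionTable
import pandas as pd

from varlap.null_model import (
    clamp_alpha,
    enumerate_null_exact,
    estimate_gamma,
    mutation_burden,
    permutation_pvalue,
    sample_null_distribution,
    substream_rng,
)
from varlap.profiles import GeneStudyProfile

from conftest import random_profile


def _profile(case_counts, matched=(), L=600, gene="G", study="T"):
    return GeneStudyProfile(
        gene, study, L, dict(case_counts), matched_positions=set(matched)
    )


# -- burden and gamma ---------------------------------------------------------


def test_mutation_burden_closed_forms():
    p = _profile({i: 1 for i in range(1, 13)}, L=600)
    assert mutation_burden(p) == pytest.approx(0.02)
    sat = _profile({i: 1 for i in range(1, 6)}, L=5)
    assert mutation_burden(sat) == 1.0
    bad = _profile({i: 1 for i in range(1, 6)}, L=3)
    with pytest.raises(ValueError):
        mutation_burden(bad)


def test_estimate_gamma_is_mean_of_coefficients():
    # (alpha_obs, mu) = (0.2, 0.02) and (0.1, 0.005): coefficients 10 and 20
    g1 = _profile({i: 1 for i in range(1, 11)}, matched=(1, 2), L=500, gene="A")
    g2 = _profile({i: 1 for i in range(1, 11)}, matched=(1,), L=2000, gene="B")
    models = estimate_gamma([g1, g2])
    assert models["T"].gamma_hat == pytest.approx(15.0)
    tab = models["T"].table.set_index("gene")
    assert tab.loc["A", "alpha_bg"] == pytest.approx(15.0 * 0.02)
    assert tab.loc["B", "mu_hat"] == pytest.approx(0.005)


def test_gamma_zero_background_is_floored():
    g = _profile({1: 1, 2: 1}, matched=(), L=100)
    models = estimate_gamma([g])
    assert models["T"].gamma_hat == 0.0
    # the floor keeps the null sampler from declaring every S > 0 impossible
    assert models["T"].table["alpha_bg"].iloc[0] == pytest.approx(1e-6)


def test_gamma_requires_contributors():
    g = _profile({1: 1}, matched=(1,), L=100)
    expr = ExpressionTable.from_summary(
        pd.DataFrame({"gene": ["G"], "study_id": ["T"], "value": [0.0]}), cutoff=1.0
    )
    with pytest.raises(ValueError, match="contribute"):
        estimate_gamma([g], expression=expr, gene_set="expressed")


def test_clamp_alpha():
    assert clamp_alpha(1.7) == 1.0
    assert clamp_alpha(0.0) == 1e-6
    assert clamp_alpha(0.3) == 0.3


# -- exact enumeration vs brute force -----------------------------------------


def _brute_force_null(profile, alpha):
    """Literal oracle: enumerate every position subset."""
    counts = list(profile.case_counts.values())
    n, total = len(counts), sum(counts)
    mass = {}
    for k in range(n + 1):
        pk = comb(n, k) * alpha**k * (1 - alpha) ** (n - k)
        subsets = list(itertools.combinations(range(n), k))
        for sub in subsets:
            s = sum(counts[i] for i in sub) / total
            mass[s] = mass.get(s, 0.0) + pk / len(subsets)
    return mass


def test_exact_null_four_point_example(two_position_profile):
    exact = enumerate_null_exact(two_position_profile, 0.5)
    assert np.allclose(exact.values, [0.0, 0.25, 0.75, 1.0])
    assert np.allclose(exact.probs, [0.25, 0.25, 0.25, 0.25])
    assert exact.tail_prob(0.75) == pytest.approx(0.5)


def test_exact_null_degenerate_alphas(two_position_profile):
    zero = enumerate_null_exact(two_position_profile, 0.0)
    assert zero.values.tolist() == [0.0] and zero.probs.tolist() == [1.0]
    one = enumerate_null_exact(two_position_profile, 1.0)
    assert one.tail_prob(1.0) == pytest.approx(1.0)


def test_exact_null_uniform_counts_reduce_to_binomial():
    p = _profile({i: 2 for i in range(1, 6)})
    exact = enumerate_null_exact(p, 0.3)
    from scipy.stats import binom

    # with equal counts S = k/n, so P(S = k/n) = Bin(k; n, alpha)
    assert np.allclose(exact.probs, binom.pmf(np.arange(6), 5, 0.3))


def test_exact_null_matches_brute_force_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(10):
        prof = random_profile(rng, max_n=7)
        alpha = float(rng.uniform(0.05, 0.95))
        exact = enumerate_null_exact(prof, alpha)
        brute = _brute_force_null(prof, alpha)
        assert np.isclose(sum(brute.values()), 1.0)
        for v, p in zip(exact.values, exact.probs):
            assert p == pytest.approx(brute[round(v * prof.total_cases) / prof.total_cases], abs=1e-12)


def test_exact_null_size_guard():
    p = _profile({i: 1 for i in range(1, 30)}, L=100)
    with pytest.raises(ValueError, match="sample_null_distribution"):
        enumerate_null_exact(p, 0.1)


# -- sampling -----------------------------------------------------------------


def test_sampled_null_degenerate_alphas(two_position_profile):
    null0 = sample_null_distribution(two_position_profile, 0.0, n_min=500, n_max=500, seed=1)
    assert np.all(null0.draws == 0.0)
    null1 = sample_null_distribution(two_position_profile, 1.0, n_min=500, n_max=500, seed=1)
    assert np.all(null1.draws == 1.0)
    with pytest.raises(ValueError):
        sample_null_distribution(two_position_profile, 1.5)


def test_sampled_null_converges_to_exact_four_points(two_position_profile):
    null = sample_null_distribution(
        two_position_profile, 0.5, n_min=20_000, n_max=20_000, seed=2
    )
    for value in (0.0, 0.25, 0.75, 1.0):
        freq = np.mean(np.isclose(null.draws, value))
        assert freq == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / 20_000))


def test_sampled_null_mean_matches_exact_expectation():
    rng = np.random.default_rng(5)
    prof = random_profile(rng, max_n=8)
    alpha = 0.4
    exact = enumerate_null_exact(prof, alpha)
    null = sample_null_distribution(prof, alpha, n_min=20_000, n_max=20_000, seed=11)
    se = np.std(null.draws) / np.sqrt(null.n_draws)
    assert null.draws.mean() == pytest.approx(exact.mean(), abs=4 * se + 1e-9)


def test_adaptive_stopping_extends_draws_for_rare_tails():
    # all positions matched: observed S = 1 sits in a tiny tail, so sampling
    # must escalate beyond the minimum batch
    prof = _profile({i: 1 for i in range(1, 7)}, matched=tuple(range(1, 7)), L=1000)
    null = sample_null_distribution(prof, 0.05, n_min=10_000, n_max=60_000, seed=3)
    assert null.n_draws == 60_000  # exceedances never reach the target
    p = permutation_pvalue(1.0, null)
    assert p <= 2e-4


def test_permutation_pvalue_estimator_bounds(two_position_profile):
    null = sample_null_distribution(two_position_profile, 0.5, n_min=1000, n_max=1000, seed=4)
    assert permutation_pvalue(0.0, null) == 1.0  # every draw >= 0
    assert permutation_pvalue(2.0, null) == pytest.approx(1 / 1001)  # estimator floor
    p = permutation_pvalue(0.75, null)
    assert 0 < p <= 1


def test_substream_rng_is_deterministic_and_gene_specific():
    a1 = substream_rng(7, "KRAS", "LUAD").random(3)
    a2 = substream_rng(7, "KRAS", "LUAD").random(3)
    b = substream_rng(7, "TP53", "LUAD").random(3)
    assert np.array_equal(a1, a2)
    assert not np.array_equal(a1, b)
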