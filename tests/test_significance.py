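"""BH adjustment, expression-stratified cutoff, hit filter and eCDF report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varlap.significance import (
    OverlapResult,
    bh_adjust,
    ecdf_report,
    expression_cutoff,
    filter_hits,
    results_frame,
)


def _step_up_oracle(pvalues):
    """Independent brute-force BH: sort, scale by m/rank, enforce monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


def _result(p=0.5, p_adj=0.5, expressed=True, snr=10.0, cases=5, gene="G", study="T"):
    return OverlapResult(
        gene=gene,
        study_id=study,
        S=0.5,
        score_sd=0.1,
        snr=snr,
        m=1,
        n=2,
        total_cases=cases,
        matched_cases=max(1, cases // 2),
        L=500,
        mu_hat=0.004,
        alpha_obs=0.5,
        alpha_bg=0.04,
        n_draws=10_000,
        exceedances=int(p * 10_000),
        p=p,
        p_adj=p_adj,
        expressed=expressed,
    )


# -- BH -----------------------------------------------------------------------


def test_bh_closed_forms():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([0.05]), [0.05])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=120)
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_bh_matches_independent_step_up_oracle(pvalues):
    assert np.allclose(bh_adjust(pvalues), _step_up_oracle(pvalues), atol=1e-12)


def test_bh_monotone_in_sorted_order():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=100)
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# -- cutoff -------------------------------------------------------------------


def test_expression_cutoff_quartile():
    results = [_result(p_adj=0.2, expressed=False, gene=f"N{i}") for i in range(4)]
    assert expression_cutoff(results) == pytest.approx(0.2)
    varied = [
        _result(p_adj=x, expressed=False, gene=f"N{i}")
        for i, x in enumerate([0.1, 0.2, 0.3, 0.4])
    ]
    # type-7 linear interpolation quartile of [0.1, 0.2, 0.3, 0.4]
    assert expression_cutoff(varied) == pytest.approx(0.175)
    with pytest.raises(ValueError, match="explicit"):
        expression_cutoff([_result(expressed=True)])


# -- hit filter ---------------------------------------------------------------


def test_filter_hits_published_thresholds():
    hit = _result(p_adj=0.01, cases=2, snr=3.0, gene="HIT")
    too_few_cases = _result(p_adj=0.01, cases=1, snr=3.0, gene="FEW")
    nonexpressed = _result(p_adj=0.01, cases=5, snr=3.0, expressed=False, gene="OFF")
    weak_snr = _result(p_adj=0.01, cases=5, snr=1.5, gene="WEAK")
    results = [hit, too_few_cases, nonexpressed, weak_snr]
    hits = filter_hits(results, cutoff=0.062, snr_min=2.0, min_cases=2)
    assert [h.gene for h in hits] == ["HIT"]
    assert hit.is_hit and not too_few_cases.is_hit and not nonexpressed.is_hit


def test_filter_hits_strict_cutoff_and_matched_basis():
    tied = _result(p_adj=1.0, cases=5)
    assert filter_hits([tied], cutoff=1.0) == []  # ties never beat the cutoff
    assert filter_hits([tied], cutoff=1.0, inclusive=True) == [tied]
    few_matched = _result(p_adj=0.01, cases=5)
    few_matched.matched_cases = 1
    assert filter_hits([few_matched], cutoff=0.1, case_basis="matched", min_cases=2) == []


def test_filter_hits_monotone_in_thresholds():
    rng = np.random.default_rng(1)
    results = [
        _result(
            p_adj=float(rng.uniform()),
            cases=int(rng.integers(1, 8)),
            snr=float(rng.uniform(0, 6)),
            expressed=bool(rng.random() < 0.7),
            gene=f"G{i}",
        )
        for i in range(60)
    ]
    strict = {h.gene for h in filter_hits(results, cutoff=0.3, snr_min=3, min_cases=4)}
    loose = {h.gene for h in filter_hits(results, cutoff=0.5, snr_min=2, min_cases=2)}
    assert strict <= loose
    assert all(r.expressed for r in results if r.gene in loose)


# -- eCDF ---------------------------------------------------------------------


def test_ecdf_identical_strata_ks_zero():
    ps = [0.1, 0.4, 0.9]
    results = [_result(p=x, expressed=True, gene=f"E{i}") for i, x in enumerate(ps)]
    results += [_result(p=x, expressed=False, gene=f"N{i}") for i, x in enumerate(ps)]
    rep = ecdf_report(results)
    assert rep.ks_stat == pytest.approx(0.0)


def test_ecdf_single_point_strata_ks_one():
    results = [_result(p=0.1, expressed=True), _result(p=0.9, expressed=False, gene="N")]
    rep = ecdf_report(results)
    assert rep.ks_stat == pytest.approx(1.0)


def test_ecdf_empty_stratum_skipped():
    assert ecdf_report([_result(expressed=True)]) is None


def test_results_frame_columns(two_position_profile):
    frame = results_frame([_result()])
    assert {"gene", "p", "p_adj", "snr", "is_hit", "alpha_bg"} <= set(frame.columns)
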