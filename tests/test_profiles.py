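"""Match criteria, profile construction and the match score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varlap.io import PATHOGENIC, DiseaseVariant, ProteomeTable, SomaticVariant
from varlap.profiles import (
    GeneStudyProfile,
    MatchCriterion,
    build_profiles,
    compute_match_score,
    profiles_to_frame,
)


def _sv(gene, pos, alt, ref="G", sample="S1", study="T1", vclass="missense"):
    return SomaticVariant(gene, sample, study, pos, ref, alt, vclass)


def _dv(gene, pos, alt, ref="G"):
    return DiseaseVariant(gene, pos, ref, alt, category=PATHOGENIC)


PROTEOME = ProteomeTable({"KRAS": 189, "SOS1": 1333})


def test_exact_change_counts_cases():
    somatic = [_sv("KRAS", 12, "D", sample=f"S{i}") for i in range(3)]
    disease = [_dv("KRAS", 12, "D")]
    (prof,) = build_profiles(somatic, disease, PROTEOME, MatchCriterion("exact_change"))
    assert (prof.n, prof.m, prof.total_cases, prof.matched_cases) == (1, 1, 3, 3)
    assert compute_match_score(prof) == 1.0


def test_position_only_vs_exact_change():
    somatic = [_sv("KRAS", 12, "V")]
    disease = [_dv("KRAS", 12, "D")]
    (by_pos,) = build_profiles(somatic, disease, PROTEOME, MatchCriterion("position_only"))
    (by_exact,) = build_profiles(somatic, disease, PROTEOME, MatchCriterion("exact_change"))
    assert by_pos.m == 1 and by_exact.m == 0


def test_similar_change_uses_substitution_matrix():
    # somatic D10E vs disease D10Q: BLOSUM62(E, Q) = 2 > 0 -> similar
    somatic = [_sv("KRAS", 10, "E", ref="D")]
    disease = [_dv("KRAS", 10, "Q", ref="D")]
    (prof,) = build_profiles(somatic, disease, PROTEOME, MatchCriterion("similar_change"))
    assert prof.m == 1
    # D10W is not similar to Q (BLOSUM62(W, Q) = -2)
    somatic = [_sv("KRAS", 10, "W", ref="D")]
    (prof,) = build_profiles(somatic, disease, PROTEOME, MatchCriterion("similar_change"))
    assert prof.m == 0


def test_criterion_nesting_on_random_inputs():
    """Matched sets are nested: exact <= similar <= position-only."""
    rng = np.random.default_rng(7)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    somatic, disease = [], []
    for i in range(120):
        pos = int(rng.integers(1, 60))
        ref, alt = rng.choice(aas, 2, replace=False)
        somatic.append(_sv("SOS1", pos, str(alt), ref=str(ref), sample=f"S{i}"))
    for _ in range(60):
        pos = int(rng.integers(1, 60))
        ref, alt = rng.choice(aas, 2, replace=False)
        disease.append(_dv("SOS1", pos, str(alt), ref=str(ref)))
    profs = {
        mode: build_profiles(somatic, disease, PROTEOME, MatchCriterion(mode))[0]
        for mode in ("exact_change", "similar_change", "position_only")
    }
    assert profs["exact_change"].matched_positions <= profs["similar_change"].matched_positions
    assert profs["similar_change"].matched_positions <= profs["position_only"].matched_positions


def test_non_missense_excluded_and_missing_length_skipped(caplog):
    somatic = [
        _sv("KRAS", 12, "D"),
        _sv("KRAS", 13, "G", ref="G", vclass="silent"),  # silent: excluded
        _sv("UNKNOWNGENE", 5, "D"),  # no protein length: profile skipped
    ]
    profs = build_profiles(somatic, [], PROTEOME, MatchCriterion())
    assert len(profs) == 1 and profs[0].gene == "KRAS" and profs[0].n == 1


def test_match_score_examples(two_position_profile):
    assert compute_match_score(two_position_profile) == 0.75
    no_match = GeneStudyProfile("G", "T", 100, {1: 2, 2: 2})
    assert compute_match_score(no_match) == 0.0
    all_match = GeneStudyProfile(
        "G", "T", 100, {1: 2, 2: 2}, matched_positions={1, 2}
    )
    assert compute_match_score(all_match) == 1.0


@given(
    matched_extra=st.integers(min_value=1, max_value=50),
    unmatched_extra=st.integers(min_value=1, max_value=50),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_score_monotonicity(matched_extra, unmatched_extra):
    """More cases at a matched position never lower S; at an unmatched position
    never raise S."""
    base = GeneStudyProfile("G", "T", 100, {1: 3, 2: 1}, matched_positions={1})
    s0 = compute_match_score(base)
    more_matched = GeneStudyProfile(
        "G", "T", 100, {1: 3 + matched_extra, 2: 1}, matched_positions={1}
    )
    more_unmatched = GeneStudyProfile(
        "G", "T", 100, {1: 3, 2: 1 + unmatched_extra}, matched_positions={1}
    )
    assert compute_match_score(more_matched) >= s0
    assert compute_match_score(more_unmatched) <= s0


def test_profile_invariants_enforced():
    with pytest.raises(ValueError):
        GeneStudyProfile("G", "T", 100, {})  # no cases
    with pytest.raises(ValueError):
        GeneStudyProfile("G", "T", 100, {1: 1}, matched_positions={2})  # unmutated match


def test_profiles_export_frame(two_position_profile):
    frame = profiles_to_frame([two_position_profile])
    row = frame.iloc[0]
    assert row["n"] == 2 and row["m"] == 1 and row["matched_positions"] == "10"
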