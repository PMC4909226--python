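"""Per-gene, per-study mutation profiles and the match score.

A :class:`GeneStudyProfile` collapses the harmonized somatic table for one gene
in one tumor study into per-position case counts, overlays the disease-variant
positions under a chosen match criterion, and exposes the counts the statistics
are built from: ``n`` unique mutated positions, ``m`` matched positions, total
and matched case counts.

The match score S is the fraction of reported somatic cases that fall at
residue positions matched to inherited-disease variants:

    S = matched_cases / total_cases,   0 <= S <= 1.

Three match criteria are supported (nested from strict to loose):
``exact_change`` (same position, same alternate residue) is a subset of
``similar_change`` (same position, alternate residue scored similar under a
substitution matrix, BLOSUM62 by default) which is a subset of
``position_only`` (any disease variant at the position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import substitution_matrices

from varlap.io import DiseaseVariant, ProteomeTable, SomaticVariant

logger = logging.getLogger(__name__)

MODES = ("position_only", "exact_change", "similar_change")


@dataclass(frozen=True)
class MatchCriterion:
    """Rule deciding whether a somatic case at a disease-variant position counts
    as a match.

    ``similar_change`` declares two alternate residues similar when their score
    in ``matrix`` (a substitution matrix name understood by Biopython) is
    strictly positive; identical residues always score positive, so exact
    changes are always similar.
    """

    mode: str = "exact_change"
    matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def _matrix(self):
        return substitution_matrices.load(self.matrix)

    def alt_matches(self, somatic_alt: str, disease_alts: Iterable[str]) -> bool:
        """Does a somatic alternate residue match any disease alternate?"""
        disease_alts = set(disease_alts)
        if not disease_alts:
            return False
        if self.mode == "position_only":
            return True
        if self.mode == "exact_change":
            return somatic_alt in disease_alts
        mat = self._matrix()
        alphabet = set(mat.alphabet)
        for d in disease_alts:
            if d == somatic_alt:
                return True
            if somatic_alt in alphabet and d in alphabet and mat[somatic_alt, d] > 0:
                return True
        return False


@dataclass
class GeneStudyProfile:
    """Mutation profile of one gene in one tumor study.

    ``case_counts`` maps each 1-based mutated position to its number of
    reported cases (rows); ``disease_positions`` maps positions carrying
    disease variants to the set of disease alternate residues observed there;
    ``matched_positions`` is the subset of mutated positions satisfying the
    match criterion.
    """

    gene: str
    study_id: str
    L: int
    case_counts: dict[int, int]
    disease_positions: dict[int, set[str]] = field(default_factory=dict)
    matched_positions: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("protein length must be >= 1")
        if not self.case_counts:
            raise ValueError("profile requires at least one somatic case")
        if any(c < 1 for c in self.case_counts.values()):
            raise ValueError("per-position case counts must be >= 1")
        if not self.matched_positions <= set(self.case_counts):
            raise ValueError("matched positions must be mutated positions")

    @property
    def n(self) -> int:
        """Number of unique mutated positions."""
        return len(self.case_counts)

    @property
    def m(self) -> int:
        """Number of matched unique positions."""
        return len(self.matched_positions)

    @property
    def total_cases(self) -> int:
        return sum(self.case_counts.values())

    @property
    def matched_cases(self) -> int:
        return sum(self.case_counts[p] for p in self.matched_positions)


def build_profiles(
    somatic: Sequence[SomaticVariant],
    disease: Sequence[DiseaseVariant],
    proteome: ProteomeTable,
    criterion: MatchCriterion | None = None,
) -> list[GeneStudyProfile]:
    """Assemble one profile per (gene, study) with at least one somatic case.

    Only missense somatic records enter the profiles (the statistic is defined
    on residue substitutions); a gene without a known protein length is skipped
    with a logged warning.  A somatic case at position p is matched when p
    carries a disease variant whose alternate residues satisfy the criterion
    for the somatic alternate.
    """
    criterion = criterion or MatchCriterion()
    disease_map: dict[str, dict[int, set[str]]] = {}
    for dv in disease:
        disease_map.setdefault(dv.gene, {}).setdefault(dv.position, set()).add(dv.alt_aa)

    grouped: dict[tuple[str, str], dict[int, dict[str, int]]] = {}
    for sv in somatic:
        if sv.variant_class != "missense":
            continue
        key = (sv.gene, sv.study_id)
        # per position, count cases per somatic alternate residue
        grouped.setdefault(key, {}).setdefault(sv.position, {})
        grouped[key][sv.position][sv.alt_aa] = (
            grouped[key][sv.position].get(sv.alt_aa, 0) + 1
        )

    profiles: list[GeneStudyProfile] = []
    skipped_no_length: set[str] = set()
    for (gene, study), positions in sorted(grouped.items()):
        L = proteome.get(gene)
        if L is None:
            skipped_no_length.add(gene)
            continue
        case_counts = {p: sum(alts.values()) for p, alts in positions.items()}
        gene_disease = disease_map.get(gene, {})
        disease_positions = {p: set(gene_disease[p]) for p in case_counts if p in gene_disease}
        matched = {
            p
            for p, alts in positions.items()
            if p in gene_disease
            and any(criterion.alt_matches(a, gene_disease[p]) for a in alts)
        }
        profiles.append(
            GeneStudyProfile(
                gene=gene,
                study_id=study,
                L=L,
                case_counts=case_counts,
                disease_positions=disease_positions,
                matched_positions=matched,
            )
        )
    if skipped_no_length:
        logger.warning(
            "build_profiles: %d genes skipped for missing protein length",
            len(skipped_no_length),
        )
    return profiles


def compute_match_score(profile: GeneStudyProfile) -> float:
    """Match score S = matched cases / total cases, in [0, 1]."""
    total = profile.total_cases
    if total < 1:
        raise ValueError("profile has no cases")
    return profile.matched_cases / total


def profiles_to_frame(profiles: Sequence[GeneStudyProfile]) -> pd.DataFrame:
    """Export profiles as a TSV-ready table."""
    rows = []
    for p in profiles:
        rows.append(
            (
                p.gene,
                p.study_id,
                p.L,
                p.n,
                p.m,
                p.total_cases,
                p.matched_cases,
                ";".join(str(x) for x in sorted(p.matched_positions)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "study_id", "L", "n", "m", "total_cases", "matched_cases", "matched_positions"],
    )
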