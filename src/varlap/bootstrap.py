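"""Bootstrap confidence in the match score: the signal-to-noise ratio.

The observed cases of a gene-study pair are resampled with replacement
(N = 1000 replicates by default) and the match score recomputed on each
replicate.  The signal-to-noise ratio relates the observed score to the
bootstrap spread:

    SNR = S / sd(S*)^2        ("variance" form, the default)
    SNR = S / sd(S*)          ("sd" form, for sensitivity analyses)

When every case is matched (or none is) the replicates are constant, the
standard deviation is zero and the result is flagged degenerate: the SNR is
reported as +inf for a positive score (it passes any finite threshold) and 0
for a zero score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from varlap.profiles import GeneStudyProfile, compute_match_score

SNR_FORMS = ("variance", "sd")


@dataclass
class BootstrapResult:
    gene: str
    study_id: str
    n_reps: int
    score_sd: float
    snr: float
    degenerate: bool
    form: str = "variance"


def bootstrap_scores(
    profile: GeneStudyProfile,
    n_reps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap replicate match scores.

    Each replicate resamples total_cases cases with replacement from the case
    list, where each case carries its position's matched/unmatched label, and
    recomputes S.  Because the labels are exchangeable, the matched count of a
    replicate is exactly Binomial(total_cases, S); the replicate scores are
    drawn from that distribution directly rather than materializing case lists.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    total = profile.total_cases
    s = compute_match_score(profile)
    return rng.binomial(total, s, size=n_reps) / total


def snr(observed_s: float, replicate_scores: np.ndarray, form: str = "variance") -> tuple[float, float, bool]:
    """Signal-to-noise ratio from bootstrap replicates.

    Returns ``(snr, score_sd, degenerate)``.  The spread is the sample (n-1)
    standard deviation of the replicates.  With zero spread the result is
    degenerate: +inf when the observed score is positive, 0 when it is zero.
    """
    if form not in SNR_FORMS:
        raise ValueError(f"form must be one of {SNR_FORMS}")
    replicate_scores = np.asarray(replicate_scores, dtype=float)
    if replicate_scores.size == 0:
        raise ValueError("replicate_scores must be nonempty")
    sd = float(np.std(replicate_scores, ddof=1)) if replicate_scores.size > 1 else 0.0
    if sd == 0.0:
        return (float("inf") if observed_s > 0 else 0.0), 0.0, True
    denom = sd * sd if form == "variance" else sd
    return observed_s / denom, sd, False


def bootstrap_result(
    profile: GeneStudyProfile,
    n_reps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    form: str = "variance",
) -> BootstrapResult:
    """Convenience wrapper: bootstrap a profile and package the SNR."""
    scores = bootstrap_scores(profile, n_reps=n_reps, seed=seed, rng=rng)
    value, sd, degenerate = snr(compute_match_score(profile), scores, form=form)
    return BootstrapResult(
        gene=profile.gene,
        study_id=profile.study_id,
        n_reps=n_reps,
        score_sd=sd,
        snr=value,
        degenerate=degenerate,
        form=form,
    )
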