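"""Burden-proportional background model and the empirical null of the match score.

The background model assumes that, absent any biological relationship between
the two databases, the probability that a mutated position coincides with a
disease variant ("background match rate" alpha) grows linearly with the gene's
mutation burden:

    mu_hat   = n / L                (unique mutated positions over protein length)
    alpha    = gamma_t * mu_hat     (linear model, clamped to [0, 1])
    alpha_hat= m / n                (observed per-gene match rate)
    gamma_t  = mean over genes of alpha_hat / mu_hat   (tumor-study-specific slope)

The null distribution of the match score S for a gene is the convolution over
the number of matches k of the score distribution given k, with
k ~ Binomial(n, alpha): each unique mutated position is a Bernoulli trial, and
the k matched positions are placed uniformly at random (without replacement)
among the n mutated positions.  The null is evaluated either exactly, by
enumerating position subsets (small n), or by Monte Carlo permutation with an
adaptive draw count.  P-values are upper-tail with the add-one estimator
p = (1 + #{draws >= observed}) / (1 + #draws), which can never return zero.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from varlap.io import ExpressionTable
from varlap.profiles import GeneStudyProfile, compute_match_score

logger = logging.getLogger(__name__)

#: Floor applied to the background match rate so a degenerate estimate of
#: gamma = 0 cannot make every positive score infinitely significant.
ALPHA_FLOOR = 1e-6

_TIE_TOL = 1e-12  # scores are ratios of small integers; ties are exact in float


def mutation_burden(profile: GeneStudyProfile) -> float:
    """Mutation burden mu = n / L (unique mutated positions over length)."""
    if profile.n > profile.L:
        raise ValueError(
            f"{profile.gene}/{profile.study_id}: n={profile.n} exceeds protein length L={profile.L}"
        )
    return profile.n / profile.L


def clamp_alpha(alpha: float, floor: float = ALPHA_FLOOR) -> float:
    """Clamp a background match rate into [floor, 1]."""
    if alpha > 1.0:
        logger.debug("alpha_bg %.3g clamped to 1", alpha)
    elif alpha < floor:
        logger.debug("alpha_bg %.3g floored to %g", alpha, floor)
    return float(min(1.0, max(floor, alpha)))


@dataclass
class BackgroundModel:
    """Per-study background: proportionality coefficient and per-gene rates."""

    study_id: str
    gamma_hat: float
    table: pd.DataFrame  # gene, n, m, L, mu_hat, alpha_obs, alpha_bg
    n_contributing: int

    def alpha_bg(self, gene: str) -> float:
        row = self.table.loc[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(gene)
        return float(row["alpha_bg"].iloc[0])


def estimate_gamma(
    profiles: Sequence[GeneStudyProfile],
    expression: ExpressionTable | None = None,
    expr_cutoff: float | None = None,
    gene_set: str = "all",
    include_unmatched: bool = True,
    alpha_floor: float = ALPHA_FLOOR,
) -> dict[str, BackgroundModel]:
    """Estimate the study-specific proportionality coefficient gamma.

    For each study, gamma_hat is the mean over contributing genes of the
    per-gene coefficient alpha_hat / mu_hat = (m/n) / (n/L).  Genes with no
    matched position contribute a coefficient of zero unless
    ``include_unmatched`` is False.  ``gene_set`` selects which genes
    contribute: ``"all"`` or ``"expressed"`` (requires ``expression``; a gene
    absent from the expression table counts as nonexpressed).  Background
    rates alpha_bg = gamma_hat * mu_hat are clamped into [alpha_floor, 1].
    """
    if gene_set not in ("all", "expressed"):
        raise ValueError("gene_set must be 'all' or 'expressed'")
    if gene_set == "expressed" and expression is None:
        raise ValueError("gene_set='expressed' requires an expression table")
    if expr_cutoff is not None and expression is not None:
        expression = expression.with_cutoff(expr_cutoff)

    by_study: dict[str, list[GeneStudyProfile]] = {}
    for p in profiles:
        by_study.setdefault(p.study_id, []).append(p)

    models: dict[str, BackgroundModel] = {}
    for study, plist in sorted(by_study.items()):
        coefficients = []
        rows = []
        for p in plist:
            mu = mutation_burden(p)
            alpha_obs = p.m / p.n
            contributes = True
            if gene_set == "expressed" and not expression.is_expressed(p.gene, study):
                contributes = False
            if p.m == 0 and not include_unmatched:
                contributes = False
            if contributes:
                coefficients.append(alpha_obs / mu)
            rows.append((p.gene, p.n, p.m, p.L, mu, alpha_obs))
        if not coefficients:
            raise ValueError(f"no genes contribute to gamma estimation in study {study}")
        gamma_hat = float(np.mean(coefficients))
        table = pd.DataFrame(
            rows, columns=["gene", "n", "m", "L", "mu_hat", "alpha_obs"]
        )
        table["alpha_bg"] = [
            clamp_alpha(gamma_hat * mu, alpha_floor) for mu in table["mu_hat"]
        ]
        models[study] = BackgroundModel(
            study_id=study,
            gamma_hat=gamma_hat,
            table=table,
            n_contributing=len(coefficients),
        )
    return models


# -- null distribution: sampling ----------------------------------------------


@dataclass
class NullDistribution:
    """Empirical null of the match score for one gene-study pair."""

    gene: str
    study_id: str
    alpha_bg: float
    observed_s: float
    draws: np.ndarray
    exceedances: int

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)


def _null_scores(
    rng: np.random.Generator,
    counts: np.ndarray,
    total: int,
    alpha: float,
    size: int,
    max_chunk: int = 4_000_000,
) -> np.ndarray:
    """Vectorized draws of the null score.

    For each draw, k ~ Binomial(n, alpha) positions are chosen uniformly
    without replacement and the score is the case-count sum over the chosen
    positions divided by the total.  Draws are grouped by k; each group selects
    uniform random k-subsets via argpartition of iid uniforms.
    """
    n = counts.size
    k = rng.binomial(n, alpha, size=size)
    out = np.zeros(size, dtype=np.float64)
    out[k == n] = 1.0
    for kk in np.unique(k):
        if kk == 0 or kk == n:
            continue
        idx = np.flatnonzero(k == kk)
        # keep the uniform matrix below ~max_chunk elements per slice
        step = max(1, max_chunk // n)
        for start in range(0, idx.size, step):
            sl = idx[start : start + step]
            u = rng.random((sl.size, n))
            sel = np.argpartition(u, kk - 1, axis=1)[:, :kk]
            out[sl] = counts[sel].sum(axis=1) / total
    return out


def sample_null_distribution(
    profile: GeneStudyProfile,
    alpha_bg: float,
    n_min: int = 10_000,
    n_max: int = 1_000_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    batch_size: int = 10_000,
    target_exceedances: int = 50,
) -> NullDistribution:
    """Sample the empirical null of S for one profile.

    Draws arrive in batches of ``batch_size`` until at least ``n_min`` draws
    have been taken; sampling then stops early once the number of draws at or
    above the observed score reaches ``target_exceedances`` (the p-value's
    relative error is then controlled), and in any case at ``n_max`` draws.
    """
    if not 0.0 <= alpha_bg <= 1.0:
        raise ValueError(f"alpha_bg must be in [0, 1], got {alpha_bg}")
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    if n_max < n_min:
        raise ValueError("n_max must be >= n_min")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.asarray(sorted(profile.case_counts.values()), dtype=np.int64)
    total = int(counts.sum())
    observed = compute_match_score(profile)

    chunks: list[np.ndarray] = []
    n_done = 0
    exceed = 0
    while n_done < n_max:
        want = min(batch_size, n_max - n_done)
        draws = _null_scores(rng, counts, total, alpha_bg, want)
        chunks.append(draws)
        n_done += want
        exceed += int(np.count_nonzero(draws >= observed - _TIE_TOL))
        if n_done >= n_min and exceed >= target_exceedances:
            break
    return NullDistribution(
        gene=profile.gene,
        study_id=profile.study_id,
        alpha_bg=alpha_bg,
        observed_s=observed,
        draws=np.concatenate(chunks),
        exceedances=exceed,
    )


def permutation_pvalue(observed_s: float, null: NullDistribution) -> float:
    """Upper-tail permutation p-value with the add-one estimator.

    p = (1 + #{null draws >= observed}) / (1 + n_draws); draws equal to the
    observed score count as exceedances, and p is never zero.
    """
    if null.n_draws == 0:
        raise ValueError("null distribution is empty")
    exceed = int(np.count_nonzero(null.draws >= observed_s - _TIE_TOL))
    return (1 + exceed) / (1 + null.n_draws)


# -- null distribution: exact enumeration -------------------------------------


@dataclass
class ExactNullDistribution:
    """Exact null of S: achievable score values with their probabilities."""

    gene: str
    study_id: str
    alpha_bg: float
    values: np.ndarray  # ascending achievable scores
    probs: np.ndarray

    def tail_prob(self, s: float) -> float:
        """P(S >= s) under the exact null."""
        return float(self.probs[self.values >= s - _TIE_TOL].sum())

    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))


def enumerate_null_exact(
    profile: GeneStudyProfile, alpha_bg: float, max_n: int = 20
) -> ExactNullDistribution:
    """Exact null distribution of S by dynamic programming over positions.

    The probability of each achievable score s is

        P(S = s) = sum_k Binomial(k; n, alpha) * #{k-subsets with case sum s*T} / C(n, k)

    where T is the total case count.  Subset counts per (k, sum) are computed
    with a knapsack-style dynamic program, equivalent to enumerating all
    2^n position subsets.  Guarded at n <= ``max_n``; larger profiles should be
    sampled instead.
    """
    if not 0.0 <= alpha_bg <= 1.0:
        raise ValueError(f"alpha_bg must be in [0, 1], got {alpha_bg}")
    n = profile.n
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds enumeration limit {max_n}; use sample_null_distribution"
        )
    counts = sorted(profile.case_counts.values())
    total = sum(counts)
    # dp[(k, s)] = number of k-subsets with case-count sum s
    dp: dict[tuple[int, int], int] = {(0, 0): 1}
    for c in counts:
        new = dict(dp)
        for (k, s), cnt in dp.items():
            key = (k + 1, s + c)
            new[key] = new.get(key, 0) + cnt
        dp = new

    binom_k = {k: sps.binom.pmf(k, n, alpha_bg) for k in range(n + 1)}
    mass: dict[int, float] = {}
    for (k, s), cnt in dp.items():
        mass[s] = mass.get(s, 0.0) + binom_k[k] * cnt / comb(n, k)
    sums = np.array(sorted(mass), dtype=np.int64)
    values = sums / total
    probs = np.array([mass[s] for s in sums])
    keep = probs > 0  # degenerate alpha puts exact zeros on unreachable scores
    values, probs = values[keep], probs[keep]
    return ExactNullDistribution(
        gene=profile.gene,
        study_id=profile.study_id,
        alpha_bg=alpha_bg,
        values=values,
        probs=probs,
    )


def substream_rng(seed: int, gene: str, study_id: str) -> np.random.Generator:
    """Deterministic per-(gene, study) random generator.

    Derived from the run seed and a CRC32 of the gene/study labels, so each
    gene's null is reproducible independently of evaluation order.
    """
    tag = zlib.crc32(f"{gene}|{study_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def null_summary_frame(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble exported null summaries (gene, study, alpha_bg, draws, p)."""
    return pd.DataFrame(
        rows, columns=["gene", "study_id", "alpha_bg", "n_draws", "exceedances", "p"]
    )
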