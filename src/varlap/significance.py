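"""Multiple-testing correction, expression-stratified cutoff and hit filtering.

Nominal permutation p-values are corrected with the Benjamini-Hochberg step-up
procedure, pooled across all gene-study pairs analyzed together.  The adjusted
p-value cutoff is derived from the data themselves: nonexpressed genes cannot
be cancer drivers, so their adjusted p-values form an empirical false-positive
distribution, and the cutoff is its first quartile.  A gene-study pair is a hit
when it is expressed, has at least ``min_cases`` reported cases, a
signal-to-noise ratio above ``snr_min`` and an adjusted p-value strictly below
the cutoff (a hit must be *more* significant than the nonexpressed stratum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """All statistics for one gene-study pair."""

    gene: str
    study_id: str
    S: float
    score_sd: float
    snr: float
    m: int
    n: int
    total_cases: int
    matched_cases: int
    L: int
    mu_hat: float
    alpha_obs: float
    alpha_bg: float
    n_draws: int
    exceedances: int
    p: float
    p_adj: float = float("nan")
    expressed: bool = True
    is_hit: bool = False
    degenerate_snr: bool = False


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def expression_cutoff(
    results: Sequence[OverlapResult] | pd.DataFrame,
    quantile: float = 0.25,
    method: str = "linear",
) -> float:
    """Adjusted-p cutoff: first quartile of the nonexpressed stratum.

    Pooled across studies; the quantile rule defaults to linear interpolation
    (numpy's "linear", the type-7 rule).  Raises when there is no nonexpressed
    result, in which case an explicit cutoff must be supplied by the caller.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_frame(results)
    nonexpr = frame.loc[~frame["expressed"].astype(bool), "p_adj"].to_numpy(float)
    if nonexpr.size == 0:
        raise ValueError(
            "no nonexpressed gene-study pairs: supply an explicit adjusted-p cutoff"
        )
    return float(np.quantile(nonexpr, quantile, method=method))


def filter_hits(
    results: Sequence[OverlapResult],
    cutoff: float,
    snr_min: float = 2.0,
    min_cases: int = 2,
    case_basis: str = "total",
    inclusive: bool = False,
) -> list[OverlapResult]:
    """Apply the final hit filter and set ``is_hit`` in place.

    A hit is expressed, has at least ``min_cases`` reported cases (``case_basis``
    selects total or matched cases), an SNR strictly above ``snr_min``, and an
    adjusted p-value below the cutoff.  The cutoff comparison is strict by
    default — a hit must beat the nonexpressed false-positive stratum, and on
    tie-heavy null data a non-strict comparison would pass every gene —
    ``inclusive=True`` switches to ``<=``.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    if case_basis not in ("total", "matched"):
        raise ValueError("case_basis must be 'total' or 'matched'")
    hits = []
    for r in results:
        cases = r.total_cases if case_basis == "total" else r.matched_cases
        below = r.p_adj <= cutoff if inclusive else r.p_adj < cutoff
        r.is_hit = bool(
            r.expressed and cases >= min_cases and r.snr > snr_min and below
        )
        if r.is_hit:
            hits.append(r)
    return hits


@dataclass
class EcdfReport:
    """Paired empirical CDFs of nominal p for expressed vs nonexpressed genes."""

    expressed_x: np.ndarray
    expressed_y: np.ndarray
    nonexpressed_x: np.ndarray
    nonexpressed_y: np.ndarray
    ks_stat: float
    ks_pvalue: float
    n_expressed: int
    n_nonexpressed: int

    def to_frame(self) -> pd.DataFrame:
        a = pd.DataFrame(
            {"stratum": "expressed", "p": self.expressed_x, "ecdf": self.expressed_y}
        )
        b = pd.DataFrame(
            {
                "stratum": "nonexpressed",
                "p": self.nonexpressed_x,
                "ecdf": self.nonexpressed_y,
            }
        )
        return pd.concat([a, b], ignore_index=True)


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(x)
    return xs, np.arange(1, xs.size + 1) / xs.size


def ecdf_report(results: Sequence[OverlapResult] | pd.DataFrame) -> EcdfReport | None:
    """Empirical CDFs of nominal p by expression stratum, with a one-sided KS test.

    The KS statistic is D+ = sup_x (F_expressed(x) - F_nonexpressed(x)); a large
    value means the expressed stratum has the heavier small-p tail, the
    signature of genuine signal.  Returns None (with a warning) when either
    stratum is empty.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_frame(results)
    expr = frame.loc[frame["expressed"].astype(bool), "p"].to_numpy(float)
    nonexpr = frame.loc[~frame["expressed"].astype(bool), "p"].to_numpy(float)
    if expr.size == 0 or nonexpr.size == 0:
        logger.warning("ecdf_report: empty stratum, report skipped")
        return None
    ks = sps.ks_2samp(expr, nonexpr, alternative="greater", method="asymp")
    ex, ey = _ecdf(expr)
    nx, ny = _ecdf(nonexpr)
    return EcdfReport(
        expressed_x=ex,
        expressed_y=ey,
        nonexpressed_x=nx,
        nonexpressed_y=ny,
        ks_stat=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        n_expressed=expr.size,
        n_nonexpressed=nonexpr.size,
    )


def results_frame(results: Sequence[OverlapResult]) -> pd.DataFrame:
    """One row per gene-study pair with every OverlapResult field."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "study_id": r.study_id,
                "S": r.S,
                "score_sd": r.score_sd,
                "snr": r.snr,
                "m": r.m,
                "n": r.n,
                "total_cases": r.total_cases,
                "matched_cases": r.matched_cases,
                "L": r.L,
                "mu_hat": r.mu_hat,
                "alpha_obs": r.alpha_obs,
                "alpha_bg": r.alpha_bg,
                "n_draws": r.n_draws,
                "exceedances": r.exceedances,
                "p": r.p,
                "p_adj": r.p_adj,
                "expressed": r.expressed,
                "is_hit": r.is_hit,
                "degenerate_snr": r.degenerate_snr,
            }
            for r in results
        ]
    )
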