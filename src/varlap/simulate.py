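"""Synthetic-data generation for calibration, power and robustness studies.

Two generators are provided.

``generate_null_dataset`` emulates a pooled tumor-sequencing study in which the
overlap between somatic mutations and a disease-variant catalogue arises purely
by chance, exactly as the background model assumes: each gene receives a
protein length and a per-residue somatic rate, unique mutated positions follow
from the rate, and each mutated position is independently "matched" (a disease
variant is planted there with the somatic alternate residue) with probability
clamp(gamma_true * n / L, 0, 1).  Optional planted-enrichment genes and
long/heavily mutated decoys support power and false-positive studies.

``generate_simulation_panel`` reproduces a parameter-sweep panel of simulated
genes: protein length, number of matched positions, target match score,
background (unmatched) mutated positions and a case-count scale factor are
drawn independently, and the smallest case configuration satisfying the target
match score ("unit measurement") is constructed and then scaled.

Both generators emit the same record types the readers produce, so synthetic
data can exercise the entire pipeline including the TSV dialects.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from varlap.io import (
    PATHOGENIC,
    DiseaseVariant,
    ExpressionTable,
    ProteomeTable,
    SomaticVariant,
    somatic_to_frame,
    disease_to_frame,
)

logger = logging.getLogger(__name__)

_AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulatedGene:
    """Ground truth for one simulated gene."""

    gene: str
    L: int
    n_positions: int
    m_planted: int
    true_alpha: float
    alpha_bg_true: float
    enriched: bool
    long_null: bool
    expressed: bool
    target_score: float | None = None
    achieved_score: float | None = None
    scale: int | None = None


@dataclass
class SyntheticDataset:
    """A bundle of generated inputs plus the truth table."""

    somatic: list[SomaticVariant]
    disease: list[DiseaseVariant]
    proteome: ProteomeTable
    expression: ExpressionTable
    truth: pd.DataFrame
    gamma_true: float | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle in the dialects the readers consume.

        The somatic table is written as a MAF-style TSV, disease variants in
        the HUMSAVAR flat dialect (three-letter codes), protein lengths as a
        two-column TSV, expression as a per-(gene, study) summary TSV, and the
        truth table as TSV.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        maf = somatic_to_frame(self.somatic)
        three = {v: k.capitalize() for k, v in _aa3_map().items()}
        maf_df = pd.DataFrame(
            {
                "Hugo_Symbol": maf["gene"],
                "Tumor_Sample_Barcode": maf["sample_id"],
                "Variant_Classification": [
                    "Missense_Mutation" if c == "missense" else c.capitalize()
                    for c in maf["variant_class"]
                ],
                "Protein_Change": [
                    f"p.{r}{p}{a}"
                    for r, p, a in zip(maf["ref_aa"], maf["position"], maf["alt_aa"])
                ],
            }
        )
        paths["somatic"] = outdir / "somatic.maf.tsv"
        maf_df.to_csv(paths["somatic"], sep="\t", index=False)

        paths["disease"] = outdir / "disease.humsavar.txt"
        with open(paths["disease"], "w") as fh:
            fh.write("gene_name  accession  FTId  change  category  dbSNP  disease_name\n")
            for v in self.disease:
                ref3 = three[v.ref_aa]
                alt3 = three[v.alt_aa]
                cat = "Disease" if v.category == PATHOGENIC else v.category.capitalize()
                label = v.disease_label.replace(" ", "_") or "-"
                fh.write(
                    f"{v.gene}  SIM{v.position:06d}  VAR_{v.position:06d}  "
                    f"p.{ref3}{v.position}{alt3}  {cat}  -  {label}\n"
                )

        paths["proteome"] = outdir / "protein_lengths.tsv"
        self.proteome.to_frame().to_csv(paths["proteome"], sep="\t", index=False)

        paths["expression"] = outdir / "expression_summary.tsv"
        self.expression.frame.to_csv(paths["expression"], sep="\t", index=False)

        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _aa3_map() -> dict[str, str]:
    from Bio.SeqUtils import IUPACData

    return {k.upper(): v for k, v in IUPACData.protein_letters_3to1.items()}


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(_log_uniform(rng, lo, hi + 0.49)))


def _expression_value(rng: np.random.Generator, expressed: bool) -> float:
    """RSEM-like bimodal expression: silent genes near zero, active genes
    log-normal around ~50 with a wide spread, so a realistic minority of
    active genes sits in the 1-10 window probed by the cutoff sweep."""
    if expressed:
        return float(np.exp(rng.normal(np.log(50.0), 1.8)))
    return float(rng.uniform(0.0, 0.5))


def _random_substitution(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(_AAS, size=2, replace=False)
    return str(ref), str(alt)


def _emit_gene_records(
    rng: np.random.Generator,
    gene: str,
    study_id: str,
    positions: np.ndarray,
    counts: np.ndarray,
    matched_mask: np.ndarray,
    somatic: list[SomaticVariant],
    disease: list[DiseaseVariant],
    n_samples: int = 400,
) -> None:
    """Emit per-case somatic rows and disease variants for one gene."""
    sample_pool = rng.integers(0, n_samples, size=int(counts.sum()))
    i = 0
    for pos, cnt, matched in zip(positions, counts, matched_mask):
        ref, alt = _random_substitution(rng)
        for _ in range(int(cnt)):
            somatic.append(
                SomaticVariant(
                    gene=gene,
                    sample_id=f"{study_id}-{sample_pool[i]:04d}",
                    study_id=study_id,
                    position=int(pos),
                    ref_aa=ref,
                    alt_aa=alt,
                    variant_class="missense",
                )
            )
            i += 1
        if matched:
            # the planted disease variant copies the somatic alternate residue,
            # so position/exact/similar criteria coincide on synthetic data
            disease.append(
                DiseaseVariant(
                    gene=gene,
                    position=int(pos),
                    ref_aa=ref,
                    alt_aa=alt,
                    disease_label="SimulatedDisease",
                    category=PATHOGENIC,
                    source_dialect="humsavar",
                )
            )


def generate_null_dataset(
    n_genes: int,
    gamma_true: float = 10.0,
    seed: int = 0,
    study_id: str = "SIM",
    length_range: tuple[int, int] = (100, 2000),
    rate_range: tuple[float, float] = (0.0008, 0.006),
    extra_case_rate: float = 0.5,
    expressed_fraction: float = 0.7,
    expression_cutoff: float = 1.0,
    n_enriched: int = 0,
    enrichment: float = 10.0,
    min_enriched_cases: int = 5,
    enriched_rate_range: tuple[float, float] = (0.004, 0.012),
    enriched_min_positions: int = 3,
    n_long_null: int = 0,
    long_null_length: int = 5000,
    long_null_rate: float = 0.12,
) -> SyntheticDataset:
    """Generate a study in which matches occur at exactly the background rate.

    Per gene: protein length L is log-uniform over ``length_range``; a
    per-residue somatic rate r is log-uniform over ``rate_range``; the number
    of unique mutated positions is n = max(1, Binomial(L, r)); each position
    receives 1 + Poisson(``extra_case_rate``) reported cases; and each position
    is matched (a pathogenic disease variant planted there) independently with
    probability alpha = clamp(gamma_true * n / L, 0, 1).  Expression is
    assigned independently of the mutation process.

    ``n_enriched`` genes (always expressed) are planted with a match
    probability ``enrichment`` times the background rate and with recurrent
    cases at matched positions so that at least ``min_enriched_cases`` matched
    cases are reported — the hotspot signature of genuine overlap.  Enriched
    genes draw their somatic rate from ``enriched_rate_range`` and carry at
    least ``enriched_min_positions`` mutated positions: detectable drivers are
    recurrently mutated at several residues, and overlap at a single position
    can never beat a null that places one match uniformly among few positions.
    ``n_long_null`` genes emulate very long, heavily but randomly mutated
    false-positive decoys (length ``long_null_length``, rate
    ``long_null_rate``) with no enrichment beyond background.
    """
    if gamma_true < 0:
        raise ValueError("gamma_true must be >= 0")
    rng = np.random.default_rng(seed)
    somatic: list[SomaticVariant] = []
    disease: list[DiseaseVariant] = []
    lengths: dict[str, int] = {}
    expr_rows = []
    truth_rows = []

    kinds = ["null"] * n_genes + ["enriched"] * n_enriched + ["long_null"] * n_long_null
    for gi, kind in enumerate(kinds):
        gene = f"G{gi:05d}"
        if kind == "long_null":
            L = int(long_null_length)
            rate = float(long_null_rate)
        elif kind == "enriched":
            L = _log_uniform_int(rng, *length_range)
            rate = float(_log_uniform(rng, *enriched_rate_range))
        else:
            L = _log_uniform_int(rng, *length_range)
            rate = float(_log_uniform(rng, *rate_range))
        n_floor = enriched_min_positions if kind == "enriched" else 1
        n = max(n_floor, int(rng.binomial(L, min(rate, 1.0))))
        n = min(n, L)
        positions = rng.choice(L, size=n, replace=False) + 1
        counts = 1 + rng.poisson(extra_case_rate, size=n)
        alpha_bg_true = min(1.0, gamma_true * n / L)
        if kind == "enriched":
            true_alpha = min(1.0, enrichment * alpha_bg_true)
        else:
            true_alpha = alpha_bg_true
        matched = rng.random(n) < true_alpha
        if kind == "enriched":
            if not matched.any():
                matched[rng.integers(0, n)] = True
            # hotspot recurrence: top up matched cases to the planted minimum
            deficit = min_enriched_cases - int(counts[matched].sum())
            if deficit > 0:
                hot = np.flatnonzero(matched)[0]
                counts[hot] += deficit
            expressed = True
        else:
            expressed = bool(rng.random() < expressed_fraction)
        _emit_gene_records(
            rng, gene, study_id, positions, counts, matched, somatic, disease
        )
        lengths[gene] = L
        expr_rows.append((gene, study_id, _expression_value(rng, expressed)))
        truth_rows.append(
            SimulatedGene(
                gene=gene,
                L=L,
                n_positions=n,
                m_planted=int(matched.sum()),
                true_alpha=float(true_alpha),
                alpha_bg_true=float(alpha_bg_true),
                enriched=kind == "enriched",
                long_null=kind == "long_null",
                expressed=expressed,
            )
        )

    expression = ExpressionTable.from_summary(
        pd.DataFrame(expr_rows, columns=["gene", "study_id", "value"]),
        cutoff=expression_cutoff,
    )
    truth = pd.DataFrame([vars(t) for t in truth_rows])
    return SyntheticDataset(
        somatic=somatic,
        disease=disease,
        proteome=ProteomeTable(lengths),
        expression=expression,
        truth=truth,
        gamma_true=gamma_true,
    )


def _unit_configuration(score: float, n_matched: int, max_denominator: int = 100) -> tuple[int, int]:
    """Smallest (matched, total) case counts realizing a target match score.

    The score is approximated by the closest fraction with denominator at most
    ``max_denominator`` and the configuration is scaled minimally so that each
    of the ``n_matched`` matched positions can carry at least one case.
    """
    frac = Fraction(score).limit_denominator(max_denominator)
    c0, t0 = max(1, frac.numerator), frac.denominator
    if c0 >= t0:  # scores at the open upper end still need >= 1 unmatched case
        c0, t0 = t0 - 1, t0
    unit = max(1, ceil(n_matched / c0))
    return c0 * unit, t0 * unit


def generate_simulation_panel(
    n_genes: int = 1000,
    seed: int = 0,
    study_id: str = "SIMPANEL",
    length_range: tuple[int, int] = (10, 8000),
    match_range: tuple[int, int] = (1, 100),
    score_range: tuple[float, float] = (0.01, 0.99),
    scale_range: tuple[int, int] = (1, 50),
    max_denominator: int = 100,
    expression_cutoff: float = 1.0,
) -> SyntheticDataset:
    """Parameter-sweep panel of simulated genes with planted match scores.

    Per gene, drawn independently: protein length (log-uniform over
    ``length_range``), number of matched positions (uniform over
    ``match_range``), target match score (uniform over ``score_range``), and a
    case-count scale factor (uniform integer over ``scale_range``).  The unit
    configuration — the smallest matched/unmatched case counts realizing the
    target score — fixes the number of unmatched mutated positions available
    (each needs at least one unit case); the background position count is drawn
    uniformly from 1 to that maximum (capped by L minus the matched positions),
    then all case counts are multiplied by the scale factor.  Infeasible
    parameter combinations (more matched positions than residues) are resampled
    and counted in the log.
    """
    rng = np.random.default_rng(seed)
    somatic: list[SomaticVariant] = []
    disease: list[DiseaseVariant] = []
    lengths: dict[str, int] = {}
    expr_rows = []
    truth_rows = []
    resampled = 0

    gi = 0
    while gi < n_genes:
        L = _log_uniform_int(rng, *length_range)
        M = int(rng.integers(match_range[0], match_range[1] + 1))
        if M + 1 > L:  # need at least one unmatched position too
            resampled += 1
            continue
        target = float(rng.uniform(*score_range))
        scale = int(rng.integers(scale_range[0], scale_range[1] + 1))
        c_unit, t_unit = _unit_configuration(target, M, max_denominator)
        u_unit = t_unit - c_unit  # unmatched unit cases, >= 1
        B = int(rng.integers(1, min(L - M, u_unit) + 1))
        achieved = c_unit / t_unit

        matched_cases = c_unit * scale
        unmatched_cases = u_unit * scale

        gene = f"P{gi:05d}"
        positions = rng.choice(L, size=M + B, replace=False) + 1
        counts = np.zeros(M + B, dtype=np.int64)
        # distribute cases as evenly as possible within each group
        counts[:M] = matched_cases // M
        counts[: matched_cases % M] += 1
        counts[M:] = unmatched_cases // B
        counts[M : M + (unmatched_cases % B)] += 1
        matched_mask = np.zeros(M + B, dtype=bool)
        matched_mask[:M] = True

        _emit_gene_records(
            rng, gene, study_id, positions, counts, matched_mask, somatic, disease,
            n_samples=2000,
        )
        lengths[gene] = L
        expr_rows.append((gene, study_id, _expression_value(rng, True)))
        truth_rows.append(
            SimulatedGene(
                gene=gene,
                L=L,
                n_positions=M + B,
                m_planted=M,
                true_alpha=M / (M + B),
                alpha_bg_true=float("nan"),
                enriched=True,
                long_null=False,
                expressed=True,
                target_score=target,
                achieved_score=achieved,
                scale=scale,
            )
        )
        gi += 1

    if resampled:
        logger.info("generate_simulation_panel: %d infeasible draws resampled", resampled)
    expression = ExpressionTable.from_summary(
        pd.DataFrame(expr_rows, columns=["gene", "study_id", "value"]),
        cutoff=expression_cutoff,
    )
    truth = pd.DataFrame([vars(t) for t in truth_rows])
    return SyntheticDataset(
        somatic=somatic,
        disease=disease,
        proteome=ProteomeTable(lengths),
        expression=expression,
        truth=truth,
        gamma_true=None,
    )


@dataclass
class RobustnessReport:
    """Rank correlations of nominal p against protein length and burden."""

    rho_length: float
    rho_length_ci: tuple[float, float]
    rho_length_p: float
    rho_burden: float
    rho_burden_ci: tuple[float, float]
    rho_burden_p: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": ["protein_length", "mutation_burden"],
                "spearman_rho": [self.rho_length, self.rho_burden],
                "ci_low": [self.rho_length_ci[0], self.rho_burden_ci[0]],
                "ci_high": [self.rho_length_ci[1], self.rho_burden_ci[1]],
                "p_value": [self.rho_length_p, self.rho_burden_p],
                "n": [self.n, self.n],
            }
        )


def _spearman_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Spearman correlation."""
    if n < 4 or not np.isfinite(rho) or abs(rho) >= 1:
        return (float("nan"), float("nan"))
    z = np.arctanh(rho)
    se = 1.06 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def robustness_report(results: pd.DataFrame) -> RobustnessReport:
    """Diagnose residual covariate bias in the nominal p-values.

    Takes a results table (columns p, L, mu_hat) and reports Spearman rank
    correlations of nominal p against protein length and against mutation
    burden, with Fisher-z confidence intervals.  Degenerate covariates
    (constant length) yield NaN correlations, reported as not applicable.
    """
    p = results["p"].to_numpy(float)
    L = results["L"].to_numpy(float)
    mu = results["mu_hat"].to_numpy(float)
    n = p.size
    if np.unique(L).size < 2:
        rho_l, p_l = float("nan"), float("nan")
    else:
        rho_l, p_l = sps.spearmanr(p, L)
    if np.unique(mu).size < 2:
        rho_b, p_b = float("nan"), float("nan")
    else:
        rho_b, p_b = sps.spearmanr(p, mu)
    return RobustnessReport(
        rho_length=float(rho_l),
        rho_length_ci=_spearman_ci(rho_l, n),
        rho_length_p=float(p_l),
        rho_burden=float(rho_b),
        rho_burden_ci=_spearman_ci(rho_b, n),
        rho_burden_p=float(p_b),
        n=n,
    )
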