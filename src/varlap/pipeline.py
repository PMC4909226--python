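"""End-to-end orchestration: inputs -> profiles -> null model -> hits.

:func:`analyze` is the in-memory pipeline working on variant records;
:func:`run_overlap` wraps it with file readers, TSV writers and a run manifest.
Results are deterministic given the seed: each gene-study pair draws its null
from an independent substream derived from (seed, gene, study).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from varlap.bootstrap import bootstrap_result
from varlap.io import (
    DiseaseVariant,
    ExpressionTable,
    ProteomeTable,
    SomaticVariant,
    filter_pathogenic,
    load_expression,
    read_disease_variants,
    read_somatic_maf,
    reconcile_reference_residues,
)
from varlap.null_model import (
    estimate_gamma,
    permutation_pvalue,
    sample_null_distribution,
    substream_rng,
)
from varlap.profiles import (
    GeneStudyProfile,
    MatchCriterion,
    build_profiles,
    compute_match_score,
)
from varlap.significance import (
    OverlapResult,
    bh_adjust,
    ecdf_report,
    expression_cutoff,
    filter_hits,
    results_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one overlap run; defaults mirror the published analysis
    settings (1000 bootstrap replicates, 10^4-10^6 permutations, SNR > 2, at
    least two reported cases, expression cutoff 1)."""

    somatic_paths: dict[str, str] = field(default_factory=dict)  # study_id -> MAF path
    disease_path: str = ""
    disease_dialect: str = "humsavar"
    proteome_path: str = ""
    expression_path: str | None = None
    sample_to_study: dict[str, str] | None = None
    outdir: str = "varlap_out"

    criterion: str = "exact_change"
    similarity_matrix: str = "BLOSUM62"
    expression_cutoff: float = 1.0
    n_boot: int = 1000
    n_min: int = 10_000
    n_max: int = 1_000_000
    snr_form: str = "variance"
    snr_min: float = 2.0
    min_cases: int = 2
    case_basis: str = "total"
    quantile_rule: str = "linear"
    bh_scope: str = "pooled"  # pooled | per-study
    gamma_gene_set: str = "all"
    explicit_cutoff: float | None = None
    seed: int = 0


@dataclass
class AnalysisResult:
    """Everything one run produces, in memory."""

    results: list[OverlapResult]
    frame: pd.DataFrame
    cutoff: float
    hits: list[OverlapResult]
    ecdf: object
    background: dict
    criterion: MatchCriterion


def score_profiles(
    profiles: Sequence[GeneStudyProfile],
    background: Mapping,
    seed: int = 0,
    n_boot: int = 1000,
    n_min: int = 10_000,
    n_max: int = 1_000_000,
    snr_form: str = "variance",
    expression: ExpressionTable | None = None,
) -> list[OverlapResult]:
    """Null sampling, p-value and bootstrap SNR for every profile."""
    results: list[OverlapResult] = []
    for prof in profiles:
        model = background[prof.study_id]
        alpha_bg = model.alpha_bg(prof.gene)
        rng = substream_rng(seed, prof.gene, prof.study_id)
        null = sample_null_distribution(
            prof, alpha_bg, n_min=n_min, n_max=n_max, rng=rng
        )
        s = null.observed_s
        p = permutation_pvalue(s, null)
        boot = bootstrap_result(prof, n_reps=n_boot, rng=rng, form=snr_form)
        expressed = (
            expression.is_expressed(prof.gene, prof.study_id)
            if expression is not None
            else True
        )
        results.append(
            OverlapResult(
                gene=prof.gene,
                study_id=prof.study_id,
                S=s,
                score_sd=boot.score_sd,
                snr=boot.snr,
                m=prof.m,
                n=prof.n,
                total_cases=prof.total_cases,
                matched_cases=prof.matched_cases,
                L=prof.L,
                mu_hat=prof.n / prof.L,
                alpha_obs=prof.m / prof.n,
                alpha_bg=alpha_bg,
                n_draws=null.n_draws,
                exceedances=null.exceedances,
                p=p,
                expressed=expressed,
                degenerate_snr=boot.degenerate,
            )
        )
    return results


def analyze(
    somatic: Sequence[SomaticVariant],
    disease: Sequence[DiseaseVariant],
    proteome: ProteomeTable,
    expression: ExpressionTable | None = None,
    criterion: str | MatchCriterion = "exact_change",
    similarity_matrix: str = "BLOSUM62",
    seed: int = 0,
    n_boot: int = 1000,
    n_min: int = 10_000,
    n_max: int = 1_000_000,
    snr_form: str = "variance",
    snr_min: float = 2.0,
    min_cases: int = 2,
    case_basis: str = "total",
    quantile_rule: str = "linear",
    bh_scope: str = "pooled",
    gamma_gene_set: str = "all",
    explicit_cutoff: float | None = None,
    pathogenic_only: bool = True,
    reconcile: bool = True,
) -> AnalysisResult:
    """Run the full overlap analysis on in-memory records.

    Filters the disease table to pathogenic records, reconciles reference
    residues, builds profiles, estimates the per-study background, computes
    permutation p-values and bootstrap SNRs, adjusts p-values (pooled across
    all pairs by default), derives the expression-stratified cutoff (unless an
    explicit one is supplied) and applies the hit filter.
    """
    if isinstance(criterion, str):
        criterion = MatchCriterion(mode=criterion, matrix=similarity_matrix)
    if pathogenic_only:
        disease = filter_pathogenic(disease)
    if reconcile:
        somatic, disease, _ = reconcile_reference_residues(somatic, disease)
    profiles = build_profiles(somatic, disease, proteome, criterion)
    if not profiles:
        raise ValueError("no gene-study profiles could be built from the inputs")
    background = estimate_gamma(
        profiles,
        expression=expression,
        gene_set=gamma_gene_set,
    )
    results = score_profiles(
        profiles,
        background,
        seed=seed,
        n_boot=n_boot,
        n_min=n_min,
        n_max=n_max,
        snr_form=snr_form,
        expression=expression,
    )
    if bh_scope == "per-study":
        for study in {r.study_id for r in results}:
            idx = [i for i, r in enumerate(results) if r.study_id == study]
            adj = bh_adjust([results[i].p for i in idx])
            for i, a in zip(idx, adj):
                results[i].p_adj = float(a)
    else:
        adj = bh_adjust([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_adj = float(a)

    if explicit_cutoff is not None:
        cutoff = float(explicit_cutoff)
    else:
        cutoff = expression_cutoff(results, method=quantile_rule)
    hits = filter_hits(
        results, cutoff, snr_min=snr_min, min_cases=min_cases, case_basis=case_basis
    )
    report = ecdf_report(results)
    return AnalysisResult(
        results=results,
        frame=results_frame(results),
        cutoff=cutoff,
        hits=hits,
        ecdf=report,
        background=background,
        criterion=criterion,
    )


def _checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_overlap(config: RunConfig) -> AnalysisResult:
    """File-based pipeline: read inputs, analyze, write outputs and a manifest.

    Writes ``results.tsv`` (one row per gene-study pair), ``hits.tsv``,
    ``ecdf.tsv`` and ``manifest.json`` (config, input checksums, version) into
    ``config.outdir``.
    """
    somatic: list[SomaticVariant] = []
    read_stats: dict[str, dict] = {}
    for study, path in sorted(config.somatic_paths.items()):
        stats: dict = {}
        somatic.extend(read_somatic_maf(path, study, stats=stats))
        read_stats[f"somatic:{study}"] = stats
    dstats: dict = {}
    disease = read_disease_variants(
        config.disease_path, config.disease_dialect, stats=dstats
    )
    read_stats["disease"] = dstats
    proteome = ProteomeTable.from_file(config.proteome_path)
    expression = None
    if config.expression_path:
        expression = load_expression(
            config.expression_path,
            cutoff=config.expression_cutoff,
            sample_to_study=config.sample_to_study,
        )

    out = analyze(
        somatic,
        disease,
        proteome,
        expression,
        criterion=config.criterion,
        similarity_matrix=config.similarity_matrix,
        seed=config.seed,
        n_boot=config.n_boot,
        n_min=config.n_min,
        n_max=config.n_max,
        snr_form=config.snr_form,
        snr_min=config.snr_min,
        min_cases=config.min_cases,
        case_basis=config.case_basis,
        quantile_rule=config.quantile_rule,
        bh_scope=config.bh_scope,
        gamma_gene_set=config.gamma_gene_set,
        explicit_cutoff=config.explicit_cutoff,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out.frame.to_csv(outdir / "results.tsv", sep="\t", index=False)
    results_frame(out.hits).to_csv(outdir / "hits.tsv", sep="\t", index=False)
    if out.ecdf is not None:
        out.ecdf.to_frame().to_csv(outdir / "ecdf.tsv", sep="\t", index=False)
    inputs = {"disease": config.disease_path, "proteome": config.proteome_path}
    inputs.update({f"somatic:{k}": v for k, v in config.somatic_paths.items()})
    if config.expression_path:
        inputs["expression"] = config.expression_path
    from varlap import __version__

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "input_checksums": {k: _checksum(v) for k, v in inputs.items()},
        "read_stats": read_stats,
        "cutoff": out.cutoff,
        "n_results": len(out.results),
        "n_hits": len(out.hits),
        "gamma_hat": {s: m.gamma_hat for s, m in out.background.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info(
        "run_overlap: %d pairs, cutoff %.4g, %d hits",
        len(out.results),
        out.cutoff,
        len(out.hits),
    )
    return out
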