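"""Readers, filters and reconciliation for the four input tables.

Four kinds of input feed the overlap statistic:

* somatic mutation calls in MAF-style TSV (one reported case per row, with an
  HGVS ``p.`` short protein change such as ``p.G12D``);
* inherited-disease variants, either in the UniProt HUMSAVAR flat-file dialect
  (three-letter codes, ``p.Gly12Asp``) or the ClinVar ``variant_summary`` TSV
  dialect (``p.`` token embedded in the ``Name`` field);
* canonical protein lengths (two-column TSV or protein FASTA);
* per-gene expression summaries (RSEM-like), used only to stratify genes into
  expressed versus nonexpressed.

All protein coordinates are 1-based (HGVS convention).  Only single-residue
substitutions are retained for matching; rows that do not encode one are
skipped and counted.  Gene identity is by symbol, uppercased and stripped;
an optional synonym table may be supplied for simple remapping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, MutableMapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import IUPACData

logger = logging.getLogger(__name__)

# -- amino-acid code tables ---------------------------------------------------

AA1 = set("ACDEFGHIKLMNPQRSTVWY")
_AA3TO1 = {k.upper(): v for k, v in IUPACData.protein_letters_3to1.items()}
_AA3TO1["TER"] = "*"

_HGVS_SHORT = re.compile(r"p\.\(?([A-Z])(\d+)([A-Z*])\)?$")
_HGVS_LONG = re.compile(r"p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|Ter|\*)\)?")

PATHOGENIC = "disease-pathogenic"
POLYMORPHISM = "polymorphism"
UNCLASSIFIED = "unclassified"

# MAF Variant_Classification vocabulary -> controlled vocabulary
_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "silent": "silent",
    "synonymous": "silent",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "splice_site": "splice",
    "splice_region": "splice",
}


def normalize_symbol(symbol: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Uppercase/strip a gene symbol and apply an optional synonym table."""
    s = str(symbol).strip().upper()
    if synonyms:
        s = synonyms.get(s, s)
    return s


def parse_hgvs_short(token: str) -> tuple[str, int, str] | None:
    """Parse a one-letter HGVS protein change like ``p.G12D``.

    Returns ``(ref, position, alt)`` or None when the token is not a
    single-residue substitution (indels, frameshifts, ``p.M1?`` and friends).
    """
    m = _HGVS_SHORT.match(str(token).strip())
    if not m:
        return None
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if ref not in AA1 or (alt not in AA1 and alt != "*") or pos < 1:
        return None
    return ref, pos, alt


def parse_hgvs_long(token: str) -> tuple[str, int, str] | None:
    """Parse a three-letter HGVS protein change like ``p.Gly12Asp``."""
    m = _HGVS_LONG.search(str(token).strip())
    if not m:
        return None
    ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
    ref = _AA3TO1.get(ref3.upper())
    alt = "*" if alt3 == "*" else _AA3TO1.get(alt3.upper())
    if ref is None or alt is None or ref == "*" or pos < 1:
        return None
    return ref, pos, alt


# -- domain types -------------------------------------------------------------


@dataclass(frozen=True)
class SomaticVariant:
    """One reported somatic substitution (one case = one MAF row)."""

    gene: str
    sample_id: str
    study_id: str
    position: int
    ref_aa: str
    alt_aa: str
    variant_class: str  # missense | silent | nonsense | splice | other

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.study_id:
            raise ValueError("study_id must be nonempty")
        if self.variant_class == "missense" and self.ref_aa == self.alt_aa:
            raise ValueError("missense variant with identical ref/alt residues")


@dataclass(frozen=True)
class DiseaseVariant:
    """One inherited-disease substitution record."""

    gene: str
    position: int
    ref_aa: str
    alt_aa: str
    disease_label: str = ""
    category: str = UNCLASSIFIED  # disease-pathogenic | polymorphism | unclassified
    source_dialect: str = "humsavar"  # humsavar | clinvar
    splice_affecting: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


class ProteomeTable:
    """Canonical protein length per gene symbol."""

    def __init__(self, lengths: Mapping[str, int]):
        clean: dict[str, int] = {}
        for gene, length in lengths.items():
            length = int(length)
            if length < 1:
                raise ValueError(f"protein length must be >= 1 for {gene}")
            clean[normalize_symbol(gene)] = length
        self._lengths = clean

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def get(self, gene: str) -> int | None:
        return self._lengths.get(normalize_symbol(gene))

    def __getitem__(self, gene: str) -> int:
        length = self.get(gene)
        if length is None:
            raise KeyError(gene)
        return length

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self._lengths.items()), columns=["gene", "length"]
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ProteomeTable":
        """Read lengths from a two-column TSV or a protein FASTA.

        FASTA input is detected by a leading ``>``; sequence length is used as
        the protein length and the first whitespace-delimited token of the
        record id as the gene symbol.
        """
        path = Path(path)
        with open(path) as fh:
            first = fh.read(1)
        if first == ">":
            lengths = {
                rec.id.split("|")[-1]: len(rec.seq)
                for rec in SeqIO.parse(str(path), "fasta")
            }
            return cls(lengths)
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError("protein length table needs two columns: gene, length")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


@dataclass
class ExpressionTable:
    """Per (gene, study) expression summaries with an expressed/nonexpressed flag.

    The summary statistic is the median across available samples of a study;
    entirely missing (gene, study) pairs are imputed with the median of the
    gene's available values (first within the study, then across studies).
    A gene-study pair is flagged expressed when its summary is >= ``cutoff``.
    """

    frame: pd.DataFrame  # columns: gene, study_id, value, expressed
    cutoff: float

    def __post_init__(self) -> None:
        if (self.frame["value"] < 0).any():
            raise ValueError("expression values must be nonnegative")
        self._flags = {
            (g, s): bool(e)
            for g, s, e in zip(
                self.frame["gene"], self.frame["study_id"], self.frame["expressed"]
            )
        }
        self._values = {
            (g, s): float(v)
            for g, s, v in zip(
                self.frame["gene"], self.frame["study_id"], self.frame["value"]
            )
        }

    @classmethod
    def from_summary(
        cls, frame: pd.DataFrame, cutoff: float = 1.0
    ) -> "ExpressionTable":
        """Build from a long table with columns gene, study_id, value."""
        df = frame.copy()
        df["gene"] = [normalize_symbol(g) for g in df["gene"]]
        if (df["value"] < 0).any():
            raise ValueError("expression values must be nonnegative")
        df["expressed"] = df["value"] >= cutoff
        return cls(df[["gene", "study_id", "value", "expressed"]], cutoff)

    def with_cutoff(self, cutoff: float) -> "ExpressionTable":
        """Re-flag the same summaries at a different expression cutoff."""
        df = self.frame.copy()
        df["expressed"] = df["value"] >= cutoff
        return ExpressionTable(df, cutoff)

    def value(self, gene: str, study_id: str) -> float | None:
        return self._values.get((normalize_symbol(gene), study_id))

    def is_expressed(self, gene: str, study_id: str, default: bool = False) -> bool:
        return self._flags.get((normalize_symbol(gene), study_id), default)


# -- readers ------------------------------------------------------------------

DEFAULT_MAF_COLUMNS = {
    "gene": "Hugo_Symbol",
    "sample": "Tumor_Sample_Barcode",
    "variant_class": "Variant_Classification",
    "protein_change": "Protein_Change",
}


def read_somatic_maf(
    path: str | Path,
    study_id: str,
    columns: Mapping[str, str] | None = None,
    synonyms: Mapping[str, str] | None = None,
    stats: MutableMapping[str, int] | None = None,
) -> list[SomaticVariant]:
    """Read a MAF-style TSV into somatic variant records.

    One record is produced per row carrying a parseable single-residue
    substitution; other rows (indels, frameshifts, unparseable tokens) are
    skipped and counted.  Cases are per row and never deduplicated.

    Parameters
    ----------
    columns:
        Mapping of logical names (gene, sample, variant_class, protein_change)
        to header names; defaults to the cBioPortal MAF headers.
    stats:
        Optional dict filled with ``rows``, ``kept`` and ``skipped`` counts.
    """
    cols = dict(DEFAULT_MAF_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for logical, name in cols.items():
        if name not in df.columns:
            raise ValueError(f"required MAF column missing: {name} ({logical})")
    records: list[SomaticVariant] = []
    skipped = 0
    for gene, sample, vclass, change in zip(
        df[cols["gene"]], df[cols["sample"]], df[cols["variant_class"]], df[cols["protein_change"]]
    ):
        parsed = parse_hgvs_short(change) if pd.notna(change) else None
        if parsed is None:
            skipped += 1
            continue
        ref, pos, alt = parsed
        vc = _CLASS_MAP.get(str(vclass).strip().lower(), "other")
        # Classification column may disagree with the token; trust the token
        # for the silent/nonsense distinction since matching keys off residues.
        if ref == alt:
            vc = "silent" if vc not in ("splice",) else vc
        elif alt == "*":
            vc = "nonsense"
        try:
            records.append(
                SomaticVariant(
                    gene=normalize_symbol(gene, synonyms),
                    sample_id=str(sample),
                    study_id=study_id,
                    position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    variant_class=vc,
                )
            )
        except ValueError:
            skipped += 1
    if stats is not None:
        stats.update(rows=len(df), kept=len(records), skipped=skipped)
    if skipped:
        logger.info("read_somatic_maf(%s): skipped %d/%d rows", path, skipped, len(df))
    return records


def _humsavar_category(token: str) -> str:
    t = token.strip().lower()
    # release 2014-era vocabulary and the newer LP/P style both appear in the wild
    if t in ("disease", "lp/p", "pathogenic", "likely_pathogenic"):
        return PATHOGENIC
    if t in ("polymorphism", "lb/b", "benign", "likely_benign"):
        return POLYMORPHISM
    return UNCLASSIFIED


def _clinvar_category(significance: str) -> str:
    s = str(significance).lower()
    if "conflicting" in s:
        return UNCLASSIFIED
    if "pathogenic" in s:
        return PATHOGENIC
    if "benign" in s:
        return POLYMORPHISM
    return UNCLASSIFIED


def read_disease_variants(
    path: str | Path,
    dialect: str,
    synonyms: Mapping[str, str] | None = None,
    stats: MutableMapping[str, int] | None = None,
) -> list[DiseaseVariant]:
    """Read inherited-disease variants from a HUMSAVAR flat file or a ClinVar
    variant_summary TSV.

    Three-letter substitution codes are converted to one-letter; rows without a
    parseable single-residue substitution or with unknown amino-acid codes are
    skipped and counted.  Categories are assigned from the file's
    significance/type column; filtering to pathogenic records is a separate,
    explicit step (:func:`filter_pathogenic`).
    """
    if dialect == "humsavar":
        return _read_humsavar(path, synonyms, stats)
    if dialect == "clinvar":
        return _read_clinvar(path, synonyms, stats)
    raise ValueError(f"unknown disease-variant dialect: {dialect!r}")


def _read_humsavar(path, synonyms, stats) -> list[DiseaseVariant]:
    records: list[DiseaseVariant] = []
    rows = 0
    skipped = 0
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if len(tokens) < 4 or not any(t.startswith("p.") for t in tokens):
                continue  # header / prose lines
            rows += 1
            change_idx, change = next(
                (i, t) for i, t in enumerate(tokens) if t.startswith("p.")
            )
            parsed = parse_hgvs_long(change)
            if parsed is None:
                skipped += 1
                continue
            ref, pos, alt = parsed
            category = UNCLASSIFIED
            if change_idx + 1 < len(tokens):
                category = _humsavar_category(tokens[change_idx + 1])
            label = " ".join(tokens[change_idx + 2 :]).strip()
            records.append(
                DiseaseVariant(
                    gene=normalize_symbol(tokens[0], synonyms),
                    position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    disease_label=label,
                    category=category,
                    source_dialect="humsavar",
                    splice_affecting="splic" in label.lower(),
                )
            )
    if stats is not None:
        stats.update(rows=rows, kept=len(records), skipped=skipped)
    return records


def _read_clinvar(path, synonyms, stats) -> list[DiseaseVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("Name", "ClinicalSignificance", "GeneSymbol"):
        if col not in df.columns:
            raise ValueError(f"required ClinVar column missing: {col}")
    label_col = "PhenotypeList" if "PhenotypeList" in df.columns else None
    records: list[DiseaseVariant] = []
    skipped = 0
    for _, row in df.iterrows():
        parsed = parse_hgvs_long(str(row["Name"]))
        if parsed is None:
            skipped += 1
            continue
        ref, pos, alt = parsed
        label = str(row[label_col]) if label_col else ""
        records.append(
            DiseaseVariant(
                gene=normalize_symbol(row["GeneSymbol"], synonyms),
                position=pos,
                ref_aa=ref,
                alt_aa=alt,
                disease_label=label,
                category=_clinvar_category(row["ClinicalSignificance"]),
                source_dialect="clinvar",
                splice_affecting="splic" in label.lower(),
            )
        )
    if stats is not None:
        stats.update(rows=len(df), kept=len(records), skipped=skipped)
    return records


# -- filters and reconciliation ----------------------------------------------


def filter_pathogenic(variants: Iterable[DiseaseVariant]) -> list[DiseaseVariant]:
    """Keep only disease-pathogenic records.

    Polymorphisms and unclassified alleles are dropped.  Silent substitutions
    (ref == alt) are dropped as well unless annotated as splice-affecting.
    """
    kept = []
    for v in variants:
        if v.category != PATHOGENIC:
            continue
        if v.ref_aa == v.alt_aa and not v.splice_affecting:
            continue
        kept.append(v)
    return kept


@dataclass
class DiscrepancyReport:
    """Accounting of reference-residue conflicts between the two sources."""

    keys: list[tuple[str, int]] = field(default_factory=list)
    n_somatic_removed: int = 0
    n_disease_removed: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_somatic_removed + self.n_disease_removed


def reconcile_reference_residues(
    somatic: Sequence[SomaticVariant], disease: Sequence[DiseaseVariant]
) -> tuple[list[SomaticVariant], list[DiseaseVariant], DiscrepancyReport]:
    """Remove every record at a (gene, position) key where the two sources
    disagree on the reference residue.

    A key present in only one source is untouched.  The operation is symmetric
    in the two sources and idempotent.
    """
    refs: dict[tuple[str, int], set[str]] = {}
    for v in somatic:
        refs.setdefault((v.gene, v.position), set()).add(v.ref_aa)
    disease_keys: dict[tuple[str, int], set[str]] = {}
    for v in disease:
        disease_keys.setdefault((v.gene, v.position), set()).add(v.ref_aa)

    bad: set[tuple[str, int]] = set()
    for key, d_refs in disease_keys.items():
        if key in refs and len(refs[key] | d_refs) > 1:
            bad.add(key)

    report = DiscrepancyReport(keys=sorted(bad))
    somatic_out = []
    for v in somatic:
        if (v.gene, v.position) in bad:
            report.n_somatic_removed += 1
        else:
            somatic_out.append(v)
    disease_out = []
    for v in disease:
        if (v.gene, v.position) in bad:
            report.n_disease_removed += 1
        else:
            disease_out.append(v)
    if bad:
        logger.info(
            "reconcile_reference_residues: removed %d records at %d keys",
            report.n_removed,
            len(bad),
        )
    return somatic_out, disease_out, report


def load_expression(
    path: str | Path,
    cutoff: float = 1.0,
    sample_to_study: Mapping[str, str] | None = None,
) -> ExpressionTable:
    """Load a gene x sample expression TSV and summarize per (gene, study).

    The first column is the gene symbol; remaining columns are samples.
    ``sample_to_study`` assigns samples to tumor studies (all samples fall in a
    single study ``"ALL"`` when omitted).  The per (gene, study) summary is the
    median over available (non-missing) samples; a (gene, study) pair with no
    available samples is imputed with the median of the gene's available values
    across the other studies.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    df[gene_col] = [normalize_symbol(g) for g in df[gene_col]]
    values = df.set_index(gene_col)
    if (values < 0).any().any():
        raise ValueError("expression values must be nonnegative")
    if sample_to_study is None:
        sample_to_study = {c: "ALL" for c in values.columns}
    studies = sorted(set(sample_to_study.values()))
    rows = []
    gene_overall = values.median(axis=1, skipna=True)
    for study in studies:
        samples = [c for c in values.columns if sample_to_study.get(c) == study]
        med = values[samples].median(axis=1, skipna=True)
        med = med.fillna(gene_overall)
        for gene, v in med.items():
            if pd.isna(v):
                continue
            rows.append((gene, study, float(v)))
    frame = pd.DataFrame(rows, columns=["gene", "study_id", "value"])
    return ExpressionTable.from_summary(frame, cutoff)


# -- harmonized round-trip tables ---------------------------------------------


def somatic_to_frame(variants: Sequence[SomaticVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (v.gene, v.sample_id, v.study_id, v.position, v.ref_aa, v.alt_aa, v.variant_class)
            for v in variants
        ],
        columns=["gene", "sample_id", "study_id", "position", "ref_aa", "alt_aa", "variant_class"],
    )


def frame_to_somatic(frame: pd.DataFrame) -> list[SomaticVariant]:
    return [
        SomaticVariant(
            gene=r.gene,
            sample_id=str(r.sample_id),
            study_id=str(r.study_id),
            position=int(r.position),
            ref_aa=r.ref_aa,
            alt_aa=r.alt_aa,
            variant_class=r.variant_class,
        )
        for r in frame.itertuples(index=False)
    ]


def disease_to_frame(variants: Sequence[DiseaseVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                v.gene,
                v.position,
                v.ref_aa,
                v.alt_aa,
                v.disease_label,
                v.category,
                v.source_dialect,
                v.splice_affecting,
            )
            for v in variants
        ],
        columns=[
            "gene",
            "position",
            "ref_aa",
            "alt_aa",
            "disease_label",
            "category",
            "source_dialect",
            "splice_affecting",
        ],
    )


def frame_to_disease(frame: pd.DataFrame) -> list[DiseaseVariant]:
    return [
        DiseaseVariant(
            gene=r.gene,
            position=int(r.position),
            ref_aa=r.ref_aa,
            alt_aa=r.alt_aa,
            disease_label="" if pd.isna(r.disease_label) else str(r.disease_label),
            category=r.category,
            source_dialect=r.source_dialect,
            splice_affecting=bool(r.splice_affecting),
        )
        for r in frame.itertuples(index=False)
    ]
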