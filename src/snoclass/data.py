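"""Containers and I/O for tissue abundance matrices and gene annotation tables.

The pipeline consumes two tab-separated inputs: a gene x sample abundance
matrix in TPM together with a sample sheet mapping each sample to a tissue,
and a per-gene annotation table carrying the Ensembl biotype, genomic
context, host-gene attributes, snoRNA box type and target class, NMD and
promoter flags and phastCons conservation scores.  This module also houses
the preprocessing rules applied before any analysis: collapsing raw Ensembl
biotypes into generic groups, the 1-TPM expression filter, replicate
averaging into per-tissue means, and per-gene averaging of per-nucleotide
conservation scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

#: Sentinel returned by :func:`group_biotype` for biotypes that are removed
#: from every analysis (the provisional "TEC" class).
EXCLUDE = "exclude"

BIOTYPE_GROUPS = (
    "protein-coding",
    "pseudogene",
    "lncRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "miRNA",
    "other",
)

_PROTEIN_CODING_RAW = (
    "IG_C_gene", "IG_D_gene", "IG_J_gene", "IG_V_gene",
    "TR_C_gene", "TR_D_gene", "TR_J_gene", "TR_V_gene",
    "polymorphic_pseudogene", "protein_coding",
)
_PSEUDOGENE_RAW = (
    "unitary_pseudogene", "unprocessed_pseudogene", "processed_pseudogene",
    "transcribed_unprocessed_pseudogene", "transcribed_unitary_pseudogene",
    "transcribed_processed_pseudogene", "IG_pseudogene", "IG_C_pseudogene",
    "IG_J_pseudogene", "IG_V_pseudogene", "TR_J_pseudogene",
    "TR_V_pseudogene", "pseudogene",
)
_LNCRNA_RAW = (
    "3prime_overlapping_ncRNA", "antisense", "lincRNA", "macro_lncRNA",
    "bidirectional_promoter_lncRNA", "processed_transcript",
    "sense_intronic", "sense_overlapping", "non_coding", "lncRNA",
)
_TRNA_RAW = ("Mt_tRNA", "tRNA")
_OTHER_RAW = ("rRNA", "Mt_rRNA", "ribozyme", "scRNA", "vaultRNA", "sRNA")

_BIOTYPE_MAP: dict[str, str] = {}
_BIOTYPE_MAP.update({b: "protein-coding" for b in _PROTEIN_CODING_RAW})
_BIOTYPE_MAP.update({b: "pseudogene" for b in _PSEUDOGENE_RAW})
_BIOTYPE_MAP.update({b: "lncRNA" for b in _LNCRNA_RAW})
_BIOTYPE_MAP.update({b: "tRNA" for b in _TRNA_RAW})
_BIOTYPE_MAP.update({b: "other" for b in _OTHER_RAW})
_BIOTYPE_MAP.update({"snoRNA": "snoRNA", "snRNA": "snRNA", "miRNA": "miRNA"})

#: Columns expected (or derivable) in an annotation table.
ANNOTATION_COLUMNS = (
    "gene_name", "biotype_raw", "biotype_group", "genomic_context",
    "host_gene_id", "host_biotype_group", "host_function_group",
    "box_type", "target_class", "nmd_substrate", "promoter_type",
    "conservation_vertebrates", "conservation_primates",
)


def group_biotype(biotype_raw: str) -> str:
    """Collapse a raw Ensembl biotype string into a generic group.

    Returns one of :data:`BIOTYPE_GROUPS`, or the :data:`EXCLUDE` sentinel
    for the provisional "TEC" biotype, which is removed from all analyses.
    Unrecognised strings fall back to ``"other"`` with a logged warning.
    Total function: never raises.
    """
    if biotype_raw == "TEC":
        return EXCLUDE
    try:
        return _BIOTYPE_MAP[biotype_raw]
    except KeyError:
        log.warning("stage=biotype action=unknown_biotype value=%r -> other",
                    biotype_raw)
        return "other"


def group_host_biotype(host_biotype_raw: str | None) -> str:
    """Collapse a host-gene biotype into protein-coding / non-coding / intergenic.

    An empty or missing value means the gene has no host (it is an
    independently transcribed, intergenic gene).
    """
    if host_biotype_raw is None or (isinstance(host_biotype_raw, float)
                                    and np.isnan(host_biotype_raw)):
        return "intergenic"
    if host_biotype_raw == "":
        return "intergenic"
    if group_biotype(host_biotype_raw) == "protein-coding":
        return "protein-coding"
    return "non-coding"


@dataclass(eq=False)
class AbundanceMatrix:
    """Gene x sample abundance matrix in TPM with a sample-to-tissue map.

    ``values`` is indexed by gene id with one column per sample;
    ``sample_to_tissue`` maps every sample id to exactly one tissue.
    Invariants (checked on construction): values are finite and
    non-negative, ids are unique, every sample is mapped, and every tissue
    has at least one sample.
    """

    values: pd.DataFrame
    sample_to_tissue: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise DataError("duplicate gene ids in abundance matrix")
        if v.columns.duplicated().any():
            raise DataError("duplicate sample ids in abundance matrix")
        if v.isna().any().any():
            raise DataError("missing values in abundance matrix")
        if (v.values < 0).any():
            raise DataError("negative abundance values")
        unmapped = set(v.columns) - set(self.sample_to_tissue.index)
        if unmapped:
            raise DataError(f"samples absent from sample sheet: {sorted(unmapped)}")
        self.sample_to_tissue = self.sample_to_tissue.loc[list(v.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for t in self.sample_to_tissue:
            if t not in seen:
                seen.append(t)
        return seen

    def subset(self, gene_ids: Iterable[str]) -> "AbundanceMatrix":
        keep = [g for g in self.values.index if g in set(gene_ids)]
        return AbundanceMatrix(self.values.loc[keep], self.sample_to_tissue)


@dataclass(eq=False)
class TissueProfile:
    """Per-gene mean abundance per tissue (replicates averaged)."""

    values: pd.DataFrame  # genes x tissues

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


def read_sample_sheet(path) -> pd.Series:
    """Read a two-column (sample, tissue) TSV into a sample->tissue Series."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if sheet.shape[1] < 2:
        raise DataError("sample sheet must have at least two columns (sample, tissue)")
    sample, tissue = sheet.columns[:2]
    if sheet[sample].duplicated().any():
        raise DataError("duplicate sample ids in sample sheet")
    return pd.Series(sheet[tissue].values, index=sheet[sample].values, name="tissue")


def read_abundance_table(path, sample_sheet) -> AbundanceMatrix:
    """Load a TPM matrix (first column gene id, one column per sample).

    Genes with any missing abundance value are dropped with a logged count;
    duplicate ids or samples absent from the sheet are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene ids: {dups[:5]}")
    if df.columns.duplicated().any():
        raise DataError("duplicate sample columns")
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        log.warning("stage=load action=drop_missing_values count=%d", n_missing)
        df = df.dropna(axis=0)
    mapping = read_sample_sheet(sample_sheet)
    return AbundanceMatrix(df.astype(float), mapping)


def tissue_means(matrix: AbundanceMatrix) -> TissueProfile:
    """Average replicate samples within each tissue."""
    groups = matrix.sample_to_tissue
    means = matrix.values.T.groupby(groups, sort=False).mean().T
    return TissueProfile(means[matrix.tissues])


def mean_conservation(per_base_scores: Sequence[float]) -> float:
    """Per-gene conservation: arithmetic mean of per-nucleotide scores in [0, 1]."""
    scores = np.asarray(per_base_scores, dtype=float)
    if scores.size == 0:
        raise DataError("empty conservation score sequence")
    if np.isnan(scores).any() or scores.min() < 0 or scores.max() > 1:
        raise DataError("conservation scores must lie in [0, 1]")
    return float(scores.mean())


def read_annotation(path) -> pd.DataFrame:
    """Load a per-gene annotation TSV, deriving grouped columns when absent.

    ``biotype_group`` is derived from ``biotype_raw`` and
    ``host_biotype_group`` from ``host_biotype_raw`` (or ``host_gene_id``
    emptiness) when not supplied explicitly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" not in df.columns:
        raise DataError("annotation table must have a gene_id column")
    if df["gene_id"].duplicated().any():
        raise DataError("duplicate gene ids in annotation")
    df = df.set_index("gene_id")
    if "biotype_group" not in df.columns:
        if "biotype_raw" not in df.columns:
            raise DataError("annotation needs biotype_raw or biotype_group")
        df["biotype_group"] = df["biotype_raw"].map(group_biotype)
    if "host_biotype_group" not in df.columns:
        src = df.get("host_biotype_raw", pd.Series("", index=df.index))
        df["host_biotype_group"] = src.map(group_host_biotype)
    for col in ("conservation_vertebrates", "conservation_primates"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
    if "nmd_substrate" in df.columns:
        df["nmd_substrate"] = df["nmd_substrate"].map(
            {"True": True, "true": True, "1": True,
             "False": False, "false": False, "0": False}).astype("boolean")
    validate_annotation(df)
    return df


def validate_annotation(annotation: pd.DataFrame) -> None:
    """Check cross-field consistency of an annotation table."""
    if "genomic_context" in annotation.columns and "host_gene_id" in annotation.columns:
        intergenic = annotation["genomic_context"] == "intergenic"
        hostless = annotation["host_gene_id"].fillna("") == ""
        if not (intergenic == hostless).all():
            bad = annotation.index[intergenic != hostless].tolist()
            raise DataError(f"genomic_context and host_gene_id disagree for {bad[:5]}")
    for col in ("conservation_vertebrates", "conservation_primates"):
        if col in annotation.columns:
            s = annotation[col].dropna()
            if ((s < 0) | (s > 1)).any():
                raise DataError(f"{col} outside [0, 1]")


def filter_expressed(
    matrix: AbundanceMatrix,
    annotation: pd.DataFrame | None = None,
    threshold_tpm: float = 1.0,
    exclude_name_prefixes: Sequence[str] = ("SCARNA",),
) -> tuple[AbundanceMatrix, dict[str, int]]:
    """Apply the expression filter and the fixed exclusion rules.

    Retains genes whose abundance strictly exceeds ``threshold_tpm`` in at
    least one individual sample; removes genes whose biotype collapses to
    the exclusion sentinel; removes snoRNA-biotype genes whose gene name
    starts with one of ``exclude_name_prefixes`` (by default the
    scaRNA-named genes misannotated as snoRNAs).  Returns the filtered
    matrix together with per-rule removal counts.  Idempotent.
    """
    if threshold_tpm <= 0:
        raise ConfigError("expression threshold must be positive")
    v = matrix.values
    counts = {"input": int(len(v))}

    drop_biotype = pd.Series(False, index=v.index)
    drop_prefix = pd.Series(False, index=v.index)
    unannotated = 0
    if annotation is not None:
        present = v.index.intersection(annotation.index)
        unannotated = int(len(v) - len(present))
        groups = annotation.loc[present, "biotype_group"]
        drop_biotype.loc[present] = (groups == EXCLUDE).values
        if "gene_name" in annotation.columns and exclude_name_prefixes:
            names = annotation.loc[present, "gene_name"].fillna("")
            is_sno = groups == "snoRNA"
            pref = names.str.startswith(tuple(exclude_name_prefixes))
            drop_prefix.loc[present] = (is_sno & pref).values
    below = v.max(axis=1) <= threshold_tpm

    keep = ~(drop_biotype | drop_prefix | below)
    counts.update(
        excluded_biotype=int(drop_biotype.sum()),
        excluded_name_prefix=int((drop_prefix & ~drop_biotype).sum()),
        below_threshold=int((below & ~drop_biotype & ~drop_prefix).sum()),
        unannotated=unannotated,
        kept=int(keep.sum()),
    )
    for rule in ("excluded_biotype", "excluded_name_prefix", "below_threshold"):
        log.info("stage=filter action=%s count=%d", rule, counts[rule])
    return AbundanceMatrix(v.loc[keep], matrix.sample_to_tissue), counts


def biotype_abundance_breakdown(
    matrix: AbundanceMatrix, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-tissue total abundance and share per biotype group.

    For each tissue, sums the tissue-mean TPM of every gene in each biotype
    group and expresses it as a fraction of the tissue total; fractions sum
    to one per tissue.  Genes absent from the annotation count as "other".
    """
    profile = tissue_means(matrix)
    groups = annotation["biotype_group"].reindex(profile.values.index).fillna("other")
    sums = profile.values.groupby(groups.values, sort=True).sum()
    rows = []
    for tissue in profile.tissues:
        total = sums[tissue].sum()
        for biotype, tpm in sums[tissue].items():
            rows.append({
                "tissue": tissue,
                "biotype_group": biotype,
                "total_tpm": float(tpm),
                "fraction": float(tpm / total) if total > 0 else np.nan,
            })
    return pd.DataFrame(rows)
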