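"""Tabular input/output and the internal data model.

The pipeline consumes MaxQuant-style ``proteinGroups.txt`` / ``peptides.txt``
tables, SDRF-like sample annotation tables and plain expression-matrix TSVs,
and represents quantification data as an :class:`IntensityMatrix` — a
proteins × assays matrix with explicit missingness (NaN) and a processing
*stage* tag that records where in the normalization pipeline the values sit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "LINEAGES",
    "SAMPLE_TYPES",
    "ENZYMES",
    "FormatError",
    "IntensityMatrix",
    "AssayAnnotation",
    "PeptideEvidenceTable",
    "GeneMap",
    "AnchorAbundances",
    "read_protein_groups",
    "read_peptides",
    "read_sdrf",
    "write_sdrf",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_anchors",
    "write_anchors",
    "restrict_to_enzyme",
]

#: Pipeline stages in the only order transitions may occur.
STAGES = ("raw_ibaq", "ppb", "log2_ppb", "imputed", "batch_corrected")

#: Controlled vocabulary of tissue lineages.
LINEAGES = frozenset(
    {
        "blood", "bone", "brain", "breast", "cervix", "colorectal", "kidney",
        "liver", "lung", "lymph_node", "ovarian", "prostate", "skin",
    }
)

SAMPLE_TYPES = frozenset({"cell_line", "tumour", "normal"})
ENZYMES = frozenset({"trypsin", "lysc", "chymotrypsin", "gluc"})

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


class FormatError(ValueError):
    """Raised when an input table does not match the expected dialect."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Proteins × assays quantification matrix with explicit missingness.

    ``values`` is a DataFrame indexed by protein-group id with one column per
    assay; missing entries are NaN.  ``stage`` tags how far through the
    normalization pipeline the values have progressed and is enforced by the
    stage-transition checks in :mod:`protscape.normalization`.
    """

    values: pd.DataFrame
    stage: str = "raw_ibaq"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate assay ids")
        if self.stage in ("raw_ibaq", "ppb"):
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ValueError(f"negative values at stage {self.stage!r}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the entry is missing."""
        return self.values.isna()

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, stage: str | None = None) -> "IntensityMatrix":
        return IntensityMatrix(values=values, stage=stage or self.stage)

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise ValueError(
                f"operation requires stage in {stages}, got {self.stage!r}"
            )


@dataclass
class AssayAnnotation:
    """Per-assay metadata; ``study_id`` is the batch covariate."""

    table: pd.DataFrame  # index: assay_id

    REQUIRED = ("study_id", "sample_id", "sample_type", "lineage", "replicate_group", "enzyme")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise FormatError("duplicate assay ids in annotation")
        bad_type = set(self.table["sample_type"]) - SAMPLE_TYPES
        if bad_type:
            raise FormatError(f"sample_type values outside vocabulary: {sorted(bad_type)}")
        bad_enzyme = set(self.table["enzyme"]) - ENZYMES
        if bad_enzyme:
            raise FormatError(f"enzyme values outside vocabulary: {sorted(bad_enzyme)}")
        if (self.table["study_id"].astype(str).str.len() == 0).any():
            raise FormatError("empty study_id")
        # Unknown lineages are preserved but flagged, not rejected.
        self.table = self.table.copy()
        self.table["lineage_known"] = self.table["lineage"].isin(LINEAGES)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.table.index)

    def for_assays(self, assay_ids: Iterable[str]) -> "AssayAnnotation":
        """Subset to the given assays, erroring on orphans."""
        assay_ids = list(assay_ids)
        orphans = [a for a in assay_ids if a not in self.table.index]
        if orphans:
            raise FormatError(f"assays without annotation: {orphans}")
        return AssayAnnotation(self.table.loc[assay_ids, list(self.REQUIRED)].copy())

    def column(self, name: str, assay_ids: Iterable[str] | None = None) -> pd.Series:
        t = self.table if assay_ids is None else self.table.loc[list(assay_ids)]
        return t[name]


@dataclass
class PeptideEvidenceTable:
    """Long-format peptide evidence: one row per (peptide, assay) detection.

    ``mapping`` gives each peptide's mapped protein-group set; ``detections``
    holds (peptide_sequence, assay_id) pairs with a detection flag.
    """

    mapping: dict[str, frozenset[str]]
    detections: pd.DataFrame  # columns: peptide_sequence, assay_id, detected

    def __post_init__(self) -> None:
        for pep, prots in self.mapping.items():
            if not pep or not _AA_RE.match(pep):
                raise FormatError(f"invalid peptide sequence {pep!r}")
            if not prots:
                raise FormatError(f"peptide {pep} maps to no protein")
        need = {"peptide_sequence", "assay_id", "detected"}
        if not need <= set(self.detections.columns):
            raise FormatError(f"detections table needs columns {sorted(need)}")
        unknown = set(self.detections["peptide_sequence"]) - set(self.mapping)
        if unknown:
            raise FormatError(f"detections reference unmapped peptides: {sorted(unknown)[:5]}")

    @property
    def peptides(self) -> list[str]:
        return list(self.mapping)

    def detected_assays(self, peptide: str) -> set[str]:
        d = self.detections
        sel = d[(d["peptide_sequence"] == peptide) & d["detected"].astype(bool)]
        return set(sel["assay_id"])


@dataclass
class GeneMap:
    """protein_group_id ↔ leading razor protein ↔ gene id."""

    table: pd.DataFrame  # columns: protein_group_id, leading_razor_protein, gene_id

    def __post_init__(self) -> None:
        need = {"protein_group_id", "leading_razor_protein", "gene_id"}
        if not need <= set(self.table.columns):
            raise FormatError(f"gene map needs columns {sorted(need)}")
        if self.table["protein_group_id"].duplicated().any():
            raise FormatError("duplicate protein_group_id in gene map")

    def razor_of(self, protein_group_id: str) -> str:
        row = self.table[self.table["protein_group_id"] == protein_group_id]
        if row.empty:
            raise KeyError(protein_group_id)
        return str(row["leading_razor_protein"].iloc[0])

    def gene_of(self, protein_group_id: str) -> str | None:
        row = self.table[self.table["protein_group_id"] == protein_group_id]
        if row.empty:
            raise KeyError(protein_group_id)
        g = row["gene_id"].iloc[0]
        return None if pd.isna(g) or g == "" else str(g)


@dataclass
class AnchorAbundances:
    """Absolute abundances (copies per cell) of anchor proteins per sample."""

    table: pd.DataFrame  # index: protein_id, columns: sample/assay ids

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if (vals[~np.isnan(vals)] <= 0).any():
                raise ValueError("anchor copies-per-cell must be positive")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

@dataclass
class ProteinGroupsOptions:
    """Column-name conventions of the proteinGroups dialect."""

    id_column: str = "Protein group id"
    razor_column: str = "Leading razor protein"
    gene_column: str = "Gene name"
    ibaq_prefix: str = "iBAQ "
    reverse_column: str = "Reverse"
    contaminant_column: str = "Potential contaminant"
    flag_marker: str = "+"


def read_protein_groups(
    path, options: ProteinGroupsOptions | None = None
) -> tuple[IntensityMatrix, GeneMap]:
    """Load a proteinGroups-style TSV into a raw-iBAQ matrix and gene map.

    Rows flagged (with a ``+`` marker) as reverse/decoy or contaminant are
    dropped; zero iBAQ intensities become missing (the upstream tool reports
    undetected proteins as 0, not as measured zeros).
    """
    opt = options or ProteinGroupsOptions()
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (opt.id_column, opt.razor_column):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    ibaq_cols = [c for c in df.columns if c.startswith(opt.ibaq_prefix) and c != opt.ibaq_prefix.strip()]
    if not ibaq_cols:
        raise FormatError(f"no iBAQ columns (prefix {opt.ibaq_prefix!r}) found")
    keep = pd.Series(True, index=df.index)
    for flag_col in (opt.reverse_column, opt.contaminant_column):
        if flag_col in df.columns:
            keep &= df[flag_col].fillna("") != opt.flag_marker
    df = df[keep]
    ids = df[opt.id_column]
    if ids.duplicated().any():
        raise FormatError(f"duplicate protein-group ids: {ids[ids.duplicated()].tolist()}")
    values = df[ibaq_cols].apply(pd.to_numeric, errors="coerce").astype(float)
    values.index = ids.tolist()
    values.columns = [c[len(opt.ibaq_prefix):] for c in ibaq_cols]
    values = values.where(values != 0.0)  # zero iBAQ -> missing
    gene_map = GeneMap(
        pd.DataFrame(
            {
                "protein_group_id": ids.tolist(),
                "leading_razor_protein": df[opt.razor_column].tolist(),
                "gene_id": (
                    df[opt.gene_column].tolist() if opt.gene_column in df.columns
                    else [""] * len(df)
                ),
            }
        )
    )
    return IntensityMatrix(values=values, stage="raw_ibaq"), gene_map


def read_peptides(path) -> PeptideEvidenceTable:
    """Load a peptides-style TSV (Sequence, Proteins, per-assay detection columns).

    Detection columns are named ``Detected <assay>`` and hold 0/1 flags; the
    Proteins column is a ``;``-joined accession list.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "Sequence" not in df.columns or "Proteins" not in df.columns:
        raise FormatError("peptides table needs 'Sequence' and 'Proteins' columns")
    det_cols = [c for c in df.columns if c.startswith("Detected ")]
    mapping: dict[str, frozenset[str]] = {}
    rows = []
    for _, row in df.iterrows():
        pep = row["Sequence"]
        mapping[pep] = frozenset(p for p in str(row["Proteins"]).split(";") if p)
        for c in det_cols:
            assay = c[len("Detected "):]
            rows.append((pep, assay, str(row[c]) in ("1", "True", "true", "+")))
    detections = pd.DataFrame(rows, columns=["peptide_sequence", "assay_id", "detected"])
    return PeptideEvidenceTable(mapping=mapping, detections=detections)


def write_peptides(table: PeptideEvidenceTable, path) -> None:
    assays = sorted(set(table.detections["assay_id"]))
    rows = []
    det = table.detections.set_index(["peptide_sequence", "assay_id"])["detected"]
    for pep, prots in table.mapping.items():
        row: dict[str, object] = {"Sequence": pep, "Proteins": ";".join(sorted(prots))}
        for a in assays:
            row[f"Detected {a}"] = int(bool(det.get((pep, a), False)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_SDRF_COLS = ["assay_id", "study_id", "sample_id", "sample_type", "lineage", "replicate_group", "enzyme"]


def read_sdrf(path) -> AssayAnnotation:
    """Read an SDRF-like TSV of per-assay sample annotations."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SDRF_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"SDRF missing columns: {missing}")
    return AssayAnnotation(df.set_index("assay_id")[_SDRF_COLS[1:]])


def write_sdrf(annotation: AssayAnnotation, path) -> None:
    out = annotation.table[list(AssayAnnotation.REQUIRED)].copy()
    out.index.name = "assay_id"
    out.to_csv(path, sep="\t")


def read_matrix_tsv(path, stage: str) -> IntensityMatrix:
    """Read an expression matrix TSV (first column = protein id)."""
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    df.index.name = None
    return IntensityMatrix(values=df, stage=stage)


def write_matrix_tsv(matrix: IntensityMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def read_anchors(path) -> AnchorAbundances:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    df.index.name = None
    return AnchorAbundances(df)


def write_anchors(anchors: AnchorAbundances, path) -> None:
    out = anchors.table.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Assay restriction
# ---------------------------------------------------------------------------

def restrict_to_enzyme(
    matrix: IntensityMatrix, annotation: AssayAnnotation, enzyme: str = "trypsin"
) -> IntensityMatrix:
    """Keep only assays digested with the requested enzyme.

    iBAQ divides by the count of theoretically observable peptides, which
    depends on the protease; mixing enzymes would make values incomparable,
    so quantitative analysis is restricted to a single enzyme (trypsin by
    default).
    """
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    ann = annotation.for_assays(matrix.assay_ids)
    keep = [a for a in matrix.assay_ids if ann.table.loc[a, "enzyme"] == enzyme]
    if not keep:
        raise ValueError(f"no assays digested with {enzyme!r}")
    return matrix.with_values(matrix.values[keep])
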