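"""Tumour-specific peptides and proteins, majority detection, intersections.

Works on presence/absence peptide evidence only.  A peptide is tumour-only
if it was detected in at least one tumour assay and in no cell-line assay;
only peptides mapping to a single protein are used for protein calls; a
protein is tumour-specific if it carries tumour-only unique evidence and has
no peptide evidence of any kind in cell lines.  Per-group majority detection
uses an inclusive 50% boundary, and group intersections follow exclusive
(UpSet-style) semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import AssayAnnotation, IntensityMatrix, PeptideEvidenceTable

__all__ = [
    "TumourSpecificResult",
    "tumour_only_peptides",
    "unique_mapping_filter",
    "tumour_specific_proteins",
    "majority_detection",
    "intersection_counts",
    "tumour_specific_analysis",
]


@dataclass
class TumourSpecificResult:
    tumour_only_peptides: frozenset[str]
    tumour_only_unique_peptides: frozenset[str]
    tumour_specific_proteins: frozenset[str]
    per_lineage_majority: dict[str, frozenset[str]]
    intersection_counts: dict[frozenset[str], int]


def _detections_by_type(
    table: PeptideEvidenceTable, annotation: AssayAnnotation
) -> pd.DataFrame:
    det = table.detections[table.detections["detected"].astype(bool)].copy()
    ann = annotation.for_assays(sorted(set(det["assay_id"])))
    det["sample_type"] = det["assay_id"].map(ann.table["sample_type"])
    return det


def tumour_only_peptides(
    table: PeptideEvidenceTable, annotation: AssayAnnotation
) -> frozenset[str]:
    """Peptides detected in ≥1 tumour assay and in zero cell-line assays."""
    det = _detections_by_type(table, annotation)
    in_tumour = set(det.loc[det["sample_type"] == "tumour", "peptide_sequence"])
    in_cell = set(det.loc[det["sample_type"] == "cell_line", "peptide_sequence"])
    return frozenset(in_tumour - in_cell)


def unique_mapping_filter(
    peptides: Iterable[str], table: PeptideEvidenceTable
) -> frozenset[str]:
    """Retain peptides whose mapped protein set has exactly one member."""
    return frozenset(p for p in peptides if len(table.mapping[p]) == 1)


def tumour_specific_proteins(
    unique_peptides: Iterable[str],
    table: PeptideEvidenceTable,
    annotation: AssayAnnotation,
) -> frozenset[str]:
    """Proteins evidenced only in tumours, via unique tumour-only peptides.

    A candidate protein carries ≥1 tumour-only unique peptide; it is then
    excluded if *any* peptide mapping to it (unique or shared) was detected
    in a cell-line assay.
    """
    det = _detections_by_type(table, annotation)
    cell_peptides = set(det.loc[det["sample_type"] == "cell_line", "peptide_sequence"])
    proteins_with_cell_evidence: set[str] = set()
    for pep in cell_peptides:
        proteins_with_cell_evidence |= table.mapping[pep]
    candidates: set[str] = set()
    for pep in unique_peptides:
        (prot,) = table.mapping[pep]
        candidates.add(prot)
    return frozenset(candidates - proteins_with_cell_evidence)


def majority_detection(
    data: IntensityMatrix | PeptideEvidenceTable,
    annotation: AssayAnnotation,
    group_by: str = "lineage",
) -> dict[str, frozenset[str]]:
    """Per group: proteins detected in ≥50% of the group's samples (inclusive).

    In matrix mode detection means ≥1 observed value; in evidence-table mode
    it means ≥1 detected peptide mapping (uniquely or not) to the protein.
    """
    if isinstance(data, IntensityMatrix):
        detected = data.values.notna()
        ann = annotation.for_assays(data.assay_ids)
        groups = ann.table[group_by]
    else:
        det = data.detections[data.detections["detected"].astype(bool)]
        assays = sorted(set(det["assay_id"]))
        ann = annotation.for_assays(assays)
        groups = ann.table[group_by]
        proteins = sorted({p for prots in data.mapping.values() for p in prots})
        detected = pd.DataFrame(False, index=proteins, columns=assays)
        for _, row in det.iterrows():
            for prot in data.mapping[row["peptide_sequence"]]:
                detected.loc[prot, row["assay_id"]] = True
    result: dict[str, frozenset[str]] = {}
    for group in groups.unique():
        cols = groups.index[groups == group]
        if len(cols) == 0:
            raise ValueError(f"empty group {group!r}")
        frac = detected[list(cols)].mean(axis=1)
        result[str(group)] = frozenset(frac.index[frac >= 0.5])
    return result


def intersection_counts(
    per_group_sets: Mapping[str, Iterable[str]],
) -> dict[frozenset[str], int]:
    """Exclusive (UpSet-style) intersection counts.

    Each element is counted once, under exactly the combination of all the
    groups that contain it; the counts therefore sum to the size of the
    union of the input sets.
    """
    sets = {g: frozenset(v) for g, v in per_group_sets.items()}
    if not sets:
        raise ValueError("need at least one group")
    universe = frozenset().union(*sets.values())
    counts: dict[frozenset[str], int] = {}
    for element in universe:
        combo = frozenset(g for g, s in sets.items() if element in s)
        counts[combo] = counts.get(combo, 0) + 1
    return counts


def tumour_specific_analysis(
    table: PeptideEvidenceTable, annotation: AssayAnnotation
) -> TumourSpecificResult:
    """End-to-end tumour-specific analysis on one evidence table."""
    t_only = tumour_only_peptides(table, annotation)
    unique = unique_mapping_filter(t_only, table)
    proteins = tumour_specific_proteins(unique, table, annotation)
    det = _detections_by_type(table, annotation)
    tumour_assays = det.loc[det["sample_type"] == "tumour", "assay_id"].unique()
    if len(tumour_assays):
        ann_t = annotation.for_assays(sorted(tumour_assays))
        # restrict majority detection to the tumour side, per lineage
        sub = PeptideEvidenceTable(
            mapping=table.mapping,
            detections=table.detections[
                table.detections["assay_id"].isin(tumour_assays)
            ].reset_index(drop=True),
        )
        majority = majority_detection(sub, ann_t, group_by="lineage")
        majority = {
            lin: frozenset(s & proteins) for lin, s in majority.items()
        }
        inter = intersection_counts(majority) if any(majority.values()) else {}
    else:
        majority, inter = {}, {}
    return TumourSpecificResult(
        tumour_only_peptides=t_only,
        tumour_only_unique_peptides=unique,
        tumour_specific_proteins=proteins,
        per_lineage_majority=majority,
        intersection_counts=inter,
    )
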