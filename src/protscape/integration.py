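"""Merging the cell-line and tumour landscapes and coverage reporting.

The two sides of the dataset are normalized separately (batch correction is
only identifiable within each side) and merged afterwards by
cross-referencing leading razor protein accessions.  Matching is two-pass:
exact accession first, then with isoform suffixes (``-N``) stripped.  The
merged matrix carries missing values where a protein was quantified on only
one side; cross-side scale differences are deliberately not re-corrected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AssayAnnotation, GeneMap, IntensityMatrix

__all__ = ["MergedLandscape", "merge_by_razor", "coverage_report"]

logger = logging.getLogger("protscape")

_ISOFORM_RE = re.compile(r"-\d+$")


def strip_isoform(accession: str) -> str:
    """Drop a trailing ``-N`` isoform suffix from a UniProt-style accession."""
    return _ISOFORM_RE.sub("", accession)


@dataclass
class MergedLandscape:
    """Union matrix over both sides with per-protein provenance."""

    union_matrix: IntensityMatrix
    intersection_ids: list[str]
    provenance: pd.DataFrame  # columns: protein_id, side, razor_id, match_pass

    @property
    def union_ids(self) -> list[str]:
        return self.union_matrix.protein_ids

    @property
    def n_union(self) -> int:
        return len(self.union_ids)

    @property
    def n_intersection(self) -> int:
        return len(self.intersection_ids)


def _razor_index(matrix: IntensityMatrix, gene_map: GeneMap) -> pd.Series:
    """protein_group_id -> razor accession, de-duplicated after isoform
    stripping by keeping the protein group with the larger total intensity."""
    gm = gene_map.table.set_index("protein_group_id")["leading_razor_protein"]
    razors = gm.reindex(matrix.protein_ids)
    if razors.isna().any():
        missing = razors.index[razors.isna()].tolist()
        raise ValueError(f"protein groups absent from gene map: {missing[:5]}")
    stripped = razors.map(strip_isoform)
    if stripped.duplicated().any():
        totals = matrix.values.sum(axis=1, skipna=True)
        keep = (
            pd.DataFrame({"razor": stripped, "total": totals})
            .sort_values("total", ascending=False)
            .drop_duplicates("razor")
            .index
        )
        dropped = sorted(set(razors.index) - set(keep))
        logger.info("dropped %d duplicate-razor protein groups: %s",
                    len(dropped), dropped[:5])
        razors = razors.loc[razors.index.isin(keep)]
    return razors


def merge_by_razor(
    cell_matrix: IntensityMatrix,
    tumour_matrix: IntensityMatrix,
    cell_gene_map: GeneMap,
    tumour_gene_map: GeneMap,
) -> MergedLandscape:
    """Merge two batch-corrected matrices on leading razor accessions.

    Pass one matches exact accessions; pass two strips isoform suffixes from
    the still-unmatched accessions.  Unmatched proteins are kept with
    missing values on the absent side.  Quantification values are never
    altered.
    """
    cell_matrix.require_stage("batch_corrected")
    tumour_matrix.require_stage("batch_corrected")
    if cell_matrix.n_proteins == 0 and tumour_matrix.n_proteins == 0:
        raise ValueError("both input matrices are empty")
    overlap = set(cell_matrix.assay_ids) & set(tumour_matrix.assay_ids)
    if overlap:
        raise ValueError(f"assays present on both sides: {sorted(overlap)[:5]}")

    cr = _razor_index(cell_matrix, cell_gene_map)
    tr = _razor_index(tumour_matrix, tumour_gene_map)
    c_by_razor = {r: pid for pid, r in cr.items()}
    t_by_razor = {r: pid for pid, r in tr.items()}

    # pass one: exact accession
    matched: dict[str, tuple[str, str, int]] = {}  # razor -> (cell pid, tum pid, pass)
    for r, cpid in c_by_razor.items():
        if r in t_by_razor:
            matched[r] = (cpid, t_by_razor[r], 1)
    # pass two: isoform-stripped on the leftovers
    c_left = {strip_isoform(r): (r, pid) for r, pid in c_by_razor.items() if r not in matched}
    t_left = {strip_isoform(r): (r, pid) for r, pid in t_by_razor.items()
              if pid not in {t for _, t, _ in matched.values()}}
    for key, (r_c, cpid) in c_left.items():
        if key in t_left:
            matched[key] = (cpid, t_left[key][1], 2)

    matched_c = {c for c, _, _ in matched.values()}
    matched_t = {t for _, t, _ in matched.values()}
    cvals = cell_matrix.values.loc[list(cr.index)]
    tvals = tumour_matrix.values.loc[list(tr.index)]

    rows, prov = [], []
    index = []
    for razor in sorted(matched):
        cpid, tpid, p = matched[razor]
        rows.append(np.concatenate([cvals.loc[cpid].to_numpy(),
                                    tvals.loc[tpid].to_numpy()]))
        index.append(razor)
        prov.append((razor, "both", f"{cr[cpid]}|{tr[tpid]}", p))
    for pid in cvals.index:
        if pid not in matched_c:
            rows.append(np.concatenate([cvals.loc[pid].to_numpy(),
                                        np.full(tvals.shape[1], np.nan)]))
            index.append(cr[pid])
            prov.append((cr[pid], "cell_line", cr[pid], 0))
    for pid in tvals.index:
        if pid not in matched_t:
            rows.append(np.concatenate([np.full(cvals.shape[1], np.nan),
                                        tvals.loc[pid].to_numpy()]))
            index.append(tr[pid])
            prov.append((tr[pid], "tumour", tr[pid], 0))

    union = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, cvals.shape[1] + tvals.shape[1])),
        index=index,
        columns=list(cvals.columns) + list(tvals.columns),
    )
    provenance = pd.DataFrame(prov, columns=["protein_id", "side", "razor_id", "match_pass"])
    return MergedLandscape(
        union_matrix=IntensityMatrix(values=union, stage="batch_corrected"),
        intersection_ids=sorted(matched),
        provenance=provenance,
    )


def coverage_report(
    landscape: MergedLandscape | IntensityMatrix,
    annotation: AssayAnnotation,
    group_by: str = "sample_type",
) -> tuple[pd.Series, pd.Series]:
    """Detected-protein counts per sample and group averages.

    A protein counts as detected in a sample when it has at least one
    observed value in that sample's assays.  Returns ``(per_assay_counts,
    per_group_mean_counts)``.
    """
    matrix = landscape.union_matrix if isinstance(landscape, MergedLandscape) else landscape
    ann = annotation.for_assays(matrix.assay_ids)
    if group_by not in ann.table.columns:
        raise ValueError(f"unknown group {group_by!r}")
    per_assay = matrix.values.notna().sum(axis=0)
    groups = ann.table[group_by]
    per_group = per_assay.groupby(groups).mean()
    return per_assay, per_group
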