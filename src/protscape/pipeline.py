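"""End-to-end orchestration: simulate → normalize per side → merge →
peptide landscape → concordance → enrichment → validation.

The default topology mirrors the two-batch processing of the source data:
cell-line and tumour assays are normalized separately (batch correction is
only identifiable within a side) and merged last.  A manifest records the
configuration, seeds and per-stage shapes; identical config + seed yields
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance, enrichment_gsea, integration, peptide_landscape, validation
from .io_formats import (
    AssayAnnotation,
    GeneMap,
    IntensityMatrix,
    write_anchors,
    write_matrix_tsv,
    write_peptides,
    write_sdrf,
)
from .normalization import NormalizationConfig, log2_transform, ppb_normalize, presence_filter, run_normalization
from .synthetic_data import GeneratorConfig, generate_multistudy, generate_paired_rna, generate_peptide_fixture

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("protscape")


@dataclass
class PipelineConfig:
    """Configuration of a simulate-mode pipeline run."""

    out_dir: str | Path = "protscape_run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    n_gene_sets: int = 10
    gene_set_size: int = 15
    gsea_permutations: int = 200
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "generator": {k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
                              for k, v in asdict(self.generator).items()},
                "normalization": asdict(self.normalization),
                "n_gene_sets": self.n_gene_sets,
                "gene_set_size": self.gene_set_size,
                "gsea_permutations": self.gsea_permutations,
                "seed": self.seed,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _identity_gene_map(matrix: IntensityMatrix) -> GeneMap:
    ids = matrix.protein_ids
    return GeneMap(pd.DataFrame({
        "protein_group_id": ids, "leading_razor_protein": ids, "gene_id": ids,
    }))


def _split_by_type(matrix: IntensityMatrix, annotation: AssayAnnotation, stype: str) -> IntensityMatrix:
    ann = annotation.for_assays(matrix.assay_ids)
    keep = [a for a in matrix.assay_ids if ann.table.loc[a, "sample_type"] == stype]
    return matrix.with_values(matrix.values[keep])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on synthetic data; returns the manifest dict.

    All result tables are written as TSV under ``config.out_dir``; failures
    abort with the stage name and leave a ``FAILED`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    stage = "simulate"
    try:
        gen = config.generator
        gen.seed = config.seed
        raw, annotation, truth = generate_multistudy(gen)
        emit("raw_ibaq.tsv", lambda p: write_matrix_tsv(raw, p))
        emit("sdrf.tsv", lambda p: write_sdrf(annotation, p))
        emit("truth_log2.tsv", lambda p: truth.true_log2_abundance.to_csv(p, sep="\t"))
        emit("truth_batch_offsets.tsv", lambda p: truth.batch_offsets.to_csv(p, sep="\t"))
        emit("truth_anchors.tsv", lambda p: write_anchors(truth.anchor_abundance, p))
        emit("truth_config.txt", lambda p: Path(p).write_text(
            "".join(f"{k}: {v}\n" for k, v in asdict(gen).items())))
        manifest["stages"][stage] = {"proteins": raw.n_proteins, "assays": raw.n_assays}

        stage = "normalize"
        log_lines: list[str] = []
        sides: dict[str, IntensityMatrix] = {}
        for stype in ("cell_line", "tumour"):
            sub = _split_by_type(raw, annotation, stype)
            if sub.n_assays == 0:
                continue
            norm = run_normalization(sub, annotation, config.normalization, log=log_lines)
            sides[stype] = norm
            emit(f"normalized_{stype}.tsv", lambda p, m=norm: write_matrix_tsv(m, p))
        emit("processing_log.txt", lambda p: Path(p).write_text("\n".join(log_lines) + "\n"))
        manifest["stages"][stage] = {
            s: {"proteins": m.n_proteins, "assays": m.n_assays} for s, m in sides.items()
        }

        stage = "merge"
        if len(sides) == 2:
            landscape = integration.merge_by_razor(
                sides["cell_line"], sides["tumour"],
                _identity_gene_map(sides["cell_line"]), _identity_gene_map(sides["tumour"]),
            )
            emit("merged_landscape.tsv", lambda p: write_matrix_tsv(landscape.union_matrix, p))
            emit("merge_provenance.tsv", lambda p: landscape.provenance.to_csv(p, sep="\t", index=False))
            per_assay, per_group = integration.coverage_report(landscape, annotation)
            emit("coverage_per_assay.tsv", lambda p: per_assay.rename("n_proteins").to_csv(p, sep="\t"))
            emit("coverage_per_group.tsv", lambda p: per_group.rename("mean_n_proteins").to_csv(p, sep="\t"))
            merged = landscape.union_matrix
            manifest["stages"][stage] = {
                "union": landscape.n_union, "intersection": landscape.n_intersection,
            }
        else:
            merged = next(iter(sides.values()))
            manifest["stages"][stage] = {"skipped": "single side"}

        stage = "peptides"
        table, pep_truth = generate_peptide_fixture(gen)
        emit("peptide_evidence.tsv", lambda p: write_peptides(table, p))
        result = peptide_landscape.tumour_specific_analysis(table, annotation)
        emit("tumour_specific_proteins.tsv", lambda p: pd.Series(
            sorted(result.tumour_specific_proteins), name="protein_id").to_csv(p, sep="\t", index=False))
        emit("intersection_counts.tsv", lambda p: pd.DataFrame(
            [{"combination": "&".join(sorted(c)), "count": n}
             for c, n in sorted(result.intersection_counts.items(), key=lambda kv: sorted(kv[0]))]
        ).to_csv(p, sep="\t", index=False))
        manifest["stages"][stage] = {
            "tumour_only_peptides": len(result.tumour_only_peptides),
            "tumour_specific_proteins": len(result.tumour_specific_proteins),
            "planted": len(pep_truth.tumour_specific_proteins),
        }

        stage = "concordance"
        corr = concordance.pairwise_correlation(merged, method="pearson")
        emit("sample_correlations.tsv", lambda p: corr.to_csv(p, sep="\t"))
        cv = concordance.cv_by_group(merged, annotation, group_by="lineage")
        emit("cv_by_lineage.tsv", lambda p: cv.to_csv(p, sep="\t", index=False))
        rna = generate_paired_rna(truth, gen)
        # cell-line assays, columns renamed assay -> sample for gene alignment
        cell_ann = annotation.for_assays(sides["cell_line"].assay_ids) if "cell_line" in sides else None
        prot = sides.get("cell_line", merged)
        pv = prot.values.copy()
        if cell_ann is not None:
            pv.columns = [cell_ann.table.loc[a, "sample_id"] for a in pv.columns]
        paired = concordance.PairedOmics(protein=pv, rna=rna)
        within = concordance.within_sample_rna_protein(paired)
        emit("rna_within_sample.tsv", lambda p: within.to_csv(p, sep="\t"))
        across = concordance.across_sample_rna_protein(paired)
        emit("rna_across_sample.tsv", lambda p: across.to_csv(p, sep="\t"))
        manifest["stages"][stage] = {
            "median_within_rs": float(within["rs"].median()),
            "median_across_rs": float(across["rs"].median()),
            "n_significant_genes": int(across["significant"].sum()),
        }

        stage = "gsea"
        ranked = enrichment_gsea.RankedGeneList.from_series(across["rs"])
        rng = np.random.default_rng(config.seed + 17)
        gene_sets = {
            f"random_set_{i:02d}": set(rng.choice(ranked.genes, size=min(config.gene_set_size, len(ranked) - 1),
                                                  replace=False))
            for i in range(config.n_gene_sets)
        }
        gsea = enrichment_gsea.gsea_preranked(
            ranked, gene_sets, n_permutations=config.gsea_permutations, seed=config.seed,
        )
        emit("gsea_results.tsv", lambda p: gsea.to_csv(p, sep="\t"))
        manifest["stages"][stage] = {"n_sets": len(gsea)}

        stage = "validate"
        if "cell_line" in sides:
            sub_raw = _split_by_type(raw, annotation, "cell_line")
            log2m = log2_transform(ppb_normalize(sub_raw))
            dens_before = validation.density_profiles(log2m, annotation)
            dens_after = validation.density_profiles(sides["cell_line"], annotation)
            emit("density_before.tsv", lambda p: dens_before.to_csv(p, sep="\t"))
            emit("density_after.tsv", lambda p: dens_after.to_csv(p, sep="\t"))
            filtered = presence_filter(log2m, config.normalization.presence_threshold)
            from .normalization import impute
            imputed = impute(filtered, config.normalization)
            assess = validation.pca_batch_assessment(
                imputed, sides["cell_line"], annotation, seed=config.seed,
            )
            manifest["stages"][stage] = {
                "ari_study_before": assess.ari_study_before,
                "ari_lineage_before": assess.ari_lineage_before,
                "ari_study_after": assess.ari_study_after,
                "ari_lineage_after": assess.ari_lineage_after,
                "location_spread_before": dens_before.attrs["location_spread"],
                "location_spread_after": dens_after.attrs["location_spread"],
            }
            ann_cell = annotation.for_assays(sub_raw.assay_ids)
            a2s = ann_cell.table["sample_id"]
            anchor = validation.anchor_validation(
                {"raw_ibaq": sub_raw, "corrected": sides["cell_line"]},
                truth.anchor_abundance, assay_to_sample=a2s,
            )
            emit("anchor_validation.tsv", lambda p: anchor.per_assay.to_csv(p, sep="\t"))
            manifest["stages"][stage]["anchor_medians"] = {
                k: float(v) for k, v in anchor.medians.items()
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for name in manifest["outputs"]:
        p = out / name
        if not p.exists() or p.stat().st_size == 0:
            raise RuntimeError(f"declared output missing or empty: {name}")
    return manifest
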