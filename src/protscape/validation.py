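"""Diagnostics establishing that the normalization worked.

Density/location summaries per study (global batch shifts), a PCA + k-means
batch assessment quantifying whether assays cluster by study or by lineage
(adjusted Rand index), anchor-protein validation against absolute
copies-per-cell abundances, and a benchmark of the three imputation methods
against synthetic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .io_formats import AnchorAbundances, AssayAnnotation, IntensityMatrix
from .normalization import impute_lls, impute_lod, impute_svd
from .synthetic_data import SyntheticTruth

__all__ = [
    "BatchAssessment",
    "AnchorValidation",
    "density_profiles",
    "pca_batch_assessment",
    "anchor_validation",
    "imputation_benchmark",
]


def density_profiles(
    matrix: IntensityMatrix | pd.DataFrame, annotation: AssayAnnotation
) -> pd.DataFrame:
    """Per-study location/scale summaries of a log-scale matrix.

    Returns one row per study (median, mean, sd, IQR of the pooled observed
    values) with a ``location_spread`` attribute — the maximum absolute
    difference between study medians — attached via ``DataFrame.attrs``.
    """
    vals = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    ann = annotation.for_assays(list(vals.columns))
    studies = ann.table["study_id"]
    rows = []
    for study in studies.unique():
        cols = list(studies.index[studies == study])
        pooled = vals[cols].to_numpy().ravel()
        pooled = pooled[~np.isnan(pooled)]
        rows.append(
            {
                "study_id": study,
                "n_values": len(pooled),
                "median": np.median(pooled),
                "mean": pooled.mean(),
                "sd": pooled.std(ddof=1) if len(pooled) > 1 else 0.0,
                "iqr": float(np.subtract(*np.percentile(pooled, [75, 25]))),
            }
        )
    out = pd.DataFrame(rows).set_index("study_id")
    med = out["median"].to_numpy()
    out.attrs["location_spread"] = float(np.max(np.abs(med[:, None] - med[None, :]))) if len(med) else 0.0
    return out


@dataclass
class BatchAssessment:
    """PCA coordinates and clustering-agreement scores before/after correction."""

    coordinates_before: pd.DataFrame
    coordinates_after: pd.DataFrame
    variance_explained_before: np.ndarray
    variance_explained_after: np.ndarray
    ari_study_before: float
    ari_lineage_before: float
    ari_study_after: float
    ari_lineage_after: float


def _pca_coords(vals: pd.DataFrame, n_components: int, scale: bool) -> tuple[pd.DataFrame, np.ndarray]:
    X = vals.to_numpy(dtype=float).T  # assays × proteins
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete (imputed) matrix")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    return (
        pd.DataFrame(coords, index=vals.columns,
                     columns=[f"PC{i+1}" for i in range(coords.shape[1])]),
        pca.explained_variance_ratio_,
    )


def _kmeans_ari(coords: pd.DataFrame, labels: pd.Series, seed: int) -> float:
    k = labels.nunique()
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    pred = km.fit_predict(coords.iloc[:, :2].to_numpy())
    return float(adjusted_rand_score(labels.to_numpy(), pred))


def pca_batch_assessment(
    matrix_before: IntensityMatrix,
    matrix_after: IntensityMatrix,
    annotation: AssayAnnotation,
    n_components: int = 2,
    scale: bool = False,
    seed: int = 0,
) -> BatchAssessment:
    """Quantify study- vs lineage-driven clustering before and after correction.

    PCA on centered assay profiles (proteins as features; unit-variance
    scaling optional), k-means with k = number of label levels in the top-2
    component space, and adjusted Rand index against study and lineage
    labels.  Effective batch removal shows ARI(study) falling below
    ARI(lineage) after correction.
    """
    if list(matrix_before.assay_ids) != list(matrix_after.assay_ids):
        raise ValueError("before/after matrices must cover the same assays")
    ann = annotation.for_assays(matrix_before.assay_ids)
    study = ann.table["study_id"]
    lineage = ann.table["lineage"]
    if matrix_before.n_assays < max(study.nunique(), lineage.nunique()):
        raise ValueError("fewer assays than label groups")
    cb, vb = _pca_coords(matrix_before.values, n_components, scale)
    ca, va = _pca_coords(matrix_after.values, n_components, scale)
    return BatchAssessment(
        coordinates_before=cb,
        coordinates_after=ca,
        variance_explained_before=vb,
        variance_explained_after=va,
        ari_study_before=_kmeans_ari(cb, study, seed),
        ari_lineage_before=_kmeans_ari(cb, lineage, seed),
        ari_study_after=_kmeans_ari(ca, study, seed),
        ari_lineage_after=_kmeans_ari(ca, lineage, seed),
    )


@dataclass
class AnchorValidation:
    """Per-variant, per-assay anchor Spearman coefficients and medians."""

    per_assay: pd.DataFrame  # rows: assay, columns: variant
    medians: pd.Series       # per-variant median across assays


def anchor_validation(
    variants: dict[str, IntensityMatrix],
    anchors: AnchorAbundances,
    assay_to_sample: pd.Series | None = None,
    min_anchors: int = 3,
) -> AnchorValidation:
    """Spearman between quantification variants and absolute abundances.

    For every variant and assay, the Spearman correlation between the
    variant's values and copies-per-cell over the anchor proteins shared by
    both; assays with fewer than ``min_anchors`` shared anchors are NaN.
    ``assay_to_sample`` maps matrix assay ids onto the anchor table's sample
    columns (identity if omitted).
    """
    results: dict[str, dict[str, float]] = {}
    for name, matrix in variants.items():
        vals = matrix.values
        shared = [p for p in anchors.protein_ids if p in vals.index]
        col: dict[str, float] = {}
        for assay in vals.columns:
            sample = assay_to_sample[assay] if assay_to_sample is not None else assay
            if sample not in anchors.table.columns:
                col[assay] = np.nan
                continue
            x = vals.loc[shared, assay].to_numpy(dtype=float)
            y = anchors.table.loc[shared, sample].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < min_anchors:
                col[assay] = np.nan
                continue
            col[assay] = float(stats.spearmanr(x[ok], y[ok]).statistic)
        results[name] = col
    per_assay = pd.DataFrame(results)
    return AnchorValidation(per_assay=per_assay, medians=per_assay.median(axis=0, skipna=True))


def imputation_benchmark(
    matrix: IntensityMatrix,
    truth_log2: pd.DataFrame,
    methods: tuple[str, ...] = ("svd", "lod", "lls"),
    svd_rank: int | None = None,
    svd_tol: float = 1e-6,
    lls_k: int = 5,
) -> pd.Series:
    """RMSE of each imputation method on the masked entries only.

    ``matrix`` is a log2-stage matrix with missing values whose true values
    are known (``truth_log2``, aligned on proteins × assays).
    """
    matrix.require_stage("log2_ppb")
    mask = matrix.values.isna().to_numpy()
    if not mask.any():
        raise ValueError("no masked entries to benchmark")
    truth = truth_log2.loc[matrix.values.index, matrix.values.columns].to_numpy(dtype=float)
    rmse = {}
    for method in methods:
        if method == "svd":
            imp = impute_svd(matrix, rank=svd_rank, tol=svd_tol)
        elif method == "lod":
            imp = impute_lod(matrix)
        elif method == "lls":
            imp = impute_lls(matrix, k=lls_k)
        else:
            raise ValueError(f"unknown method {method!r}")
        err = imp.values.to_numpy()[mask] - truth[mask]
        rmse[method] = float(np.sqrt(np.mean(err**2)))
    return pd.Series(rmse)
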