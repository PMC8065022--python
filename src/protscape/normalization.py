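"""Two-step normalization: ppb scaling, imputation, and batch removal.

The pipeline takes a raw iBAQ matrix to a batch-corrected log2 matrix in a
fixed stage order::

    raw_ibaq -> ppb -> log2_ppb -> (presence filter) -> imputed -> batch_corrected

ppb scaling makes assays compositionally comparable (each assay's observed
values sum to 1e8); the presence filter keeps proteins quantified in at
least half of the assays; missing values are imputed (iterative SVD by
default, with limit-of-detection and local-least-squares alternatives for
benchmarking); and study-of-origin batch effects are removed per protein by
an ordinary-least-squares linear model on the batch covariate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AssayAnnotation, IntensityMatrix

__all__ = [
    "NormalizationConfig",
    "ppb_normalize",
    "log2_transform",
    "presence_filter",
    "impute_svd",
    "impute_lod",
    "impute_lls",
    "remove_batch_effects",
    "run_normalization",
    "PPB_TOTAL",
]

logger = logging.getLogger("protscape")

#: Total observed signal per assay after ppb scaling (1e8 — the scaling is
#: named "parts per billion" by convention in the source data although the
#: constant is 10^8).
PPB_TOTAL = 100_000_000.0


@dataclass
class NormalizationConfig:
    """Parameters of the normalization pipeline."""

    presence_threshold: float = 0.5
    impute_method: str = "svd"          # svd | lod | lls
    svd_rank: int | None = None          # default min(5, min(dim) - 1)
    svd_tol: float = 1e-4
    svd_max_iter: int = 500
    lls_k: int = 5
    batch_covariate: str = "study_id"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.presence_threshold <= 1.0:
            raise ValueError("presence_threshold must lie in (0, 1]")
        if self.impute_method not in ("svd", "lod", "lls"):
            raise ValueError(f"unknown impute_method {self.impute_method!r}")
        if self.svd_tol <= 0:
            raise ValueError("svd_tol must be positive")
        if self.svd_rank is not None and self.svd_rank < 1:
            raise ValueError("svd_rank must be >= 1")


def ppb_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Scale each assay so its observed intensities sum to 1e8.

    Each observed value is divided by the assay's total observed signal and
    multiplied by 100,000,000; the denominator sums observed values only
    (missing entries carry no signal).  Missing entries stay missing.
    """
    matrix.require_stage("raw_ibaq")
    vals = matrix.values
    totals = vals.sum(axis=0, skipna=True)
    dead = totals.index[(totals == 0) | vals.notna().sum(axis=0).eq(0)]
    if len(dead):
        raise ValueError(f"assays with no observed signal: {list(dead)}")
    return matrix.with_values(vals / totals * PPB_TOTAL, stage="ppb")


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2 of observed ppb values; missing preserved."""
    matrix.require_stage("ppb")
    vals = matrix.values
    if (vals.to_numpy()[~np.isnan(vals.to_numpy())] <= 0).any():
        raise ValueError("log2 requires strictly positive observed values")
    return matrix.with_values(np.log2(vals), stage="log2_ppb")


def presence_filter(matrix: IntensityMatrix, threshold: float = 0.5) -> IntensityMatrix:
    """Keep proteins observed in at least ``threshold`` of the assays.

    The boundary is inclusive: with four assays and the default threshold a
    protein observed in exactly two is retained.  Row order is preserved.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    frac = matrix.values.notna().mean(axis=1)
    keep = frac[frac >= threshold].index
    if len(keep) == 0:
        warnings.warn("presence filter removed every protein", stacklevel=2)
    return matrix.with_values(matrix.values.loc[keep])


def _check_imputable(matrix: IntensityMatrix) -> None:
    matrix.require_stage("log2_ppb")
    vals = matrix.values
    empty_rows = vals.index[vals.notna().sum(axis=1) == 0].tolist()
    if empty_rows:
        raise ValueError(f"proteins with no observed value: {empty_rows[:5]}")
    empty_cols = vals.columns[vals.notna().sum(axis=0) == 0].tolist()
    if empty_cols:
        raise ValueError(f"assays with no observed value: {empty_cols}")


def impute_svd(
    matrix: IntensityMatrix,
    rank: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> IntensityMatrix:
    """Iterative rank-``rank`` SVD imputation of missing entries.

    Missing entries are initialized with per-protein means, then repeatedly
    overwritten with the rank-k SVD reconstruction of the current complete
    matrix until the relative Frobenius change of the imputed entries drops
    below ``tol`` or ``max_iter`` is reached.  Observed entries are never
    modified.
    """
    _check_imputable(matrix)
    X = matrix.values.to_numpy(dtype=float).copy()
    mask = np.isnan(X)
    if not mask.any():
        return matrix.with_values(matrix.values.copy(), stage="imputed")
    k = rank if rank is not None else min(5, min(X.shape) - 1)
    if k >= min(X.shape):
        raise ValueError(f"rank {k} must be < min(dim) = {min(X.shape)}")
    row_means = np.nanmean(X, axis=1)
    X[mask] = np.broadcast_to(row_means[:, None], X.shape)[mask]
    prev = X[mask].copy()
    converged = False
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k, :]
        X[mask] = recon[mask]
        cur = X[mask]
        denom = np.linalg.norm(cur)
        change = np.linalg.norm(cur - prev) / denom if denom > 0 else 0.0
        prev = cur.copy()
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SVD imputation did not converge in {max_iter} iterations", stacklevel=2
        )
    out = pd.DataFrame(X, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(out, stage="imputed")


def impute_lod(matrix: IntensityMatrix) -> IntensityMatrix:
    """Limit-of-detection imputation: per-assay minimum observed value."""
    matrix.require_stage("log2_ppb")
    vals = matrix.values.copy()
    empty_cols = vals.columns[vals.notna().sum(axis=0) == 0].tolist()
    if empty_cols:
        raise ValueError(f"assays with no observed value: {empty_cols}")
    mins = vals.min(axis=0, skipna=True)
    out = vals.fillna(mins)
    return matrix.with_values(out, stage="imputed")


def impute_lls(matrix: IntensityMatrix, k: int = 5) -> IntensityMatrix:
    """Local-least-squares imputation.

    Each incomplete protein is regressed (OLS with intercept) on its ``k``
    most correlated complete proteins over the target's observed assays;
    missing entries are predicted from the fit.
    """
    _check_imputable(matrix)
    vals = matrix.values
    X = vals.to_numpy(dtype=float)
    mask = np.isnan(X)
    if not mask.any():
        return matrix.with_values(vals.copy(), stage="imputed")
    complete = ~mask.any(axis=1)
    if complete.sum() < k:
        raise ValueError(
            f"LLS needs at least k={k} complete proteins, found {int(complete.sum())}"
        )
    comp_idx = np.where(complete)[0]
    C = X[comp_idx, :]
    out = X.copy()
    for i in np.where(mask.any(axis=1))[0]:
        obs = ~mask[i, :]
        y = X[i, obs]
        if y.std() == 0:
            out[i, ~obs] = y[0]
            continue
        # correlation of the target with each complete protein over the
        # target's observed columns
        co = C[:, obs]
        with np.errstate(invalid="ignore"):
            cc = np.array([
                np.corrcoef(y, co[j, :])[0, 1] if co[j, :].std() > 0 else 0.0
                for j in range(co.shape[0])
            ])
        cc = np.nan_to_num(cc)
        nb = np.argsort(-np.abs(cc))[:k]
        A = np.column_stack([np.ones(obs.sum()), co[nb, :].T])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        A_miss = np.column_stack([np.ones((~obs).sum()), C[nb, :][:, ~obs].T])
        out[i, ~obs] = A_miss @ beta
    res = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return matrix.with_values(res, stage="imputed")


def impute(matrix: IntensityMatrix, config: NormalizationConfig) -> IntensityMatrix:
    """Dispatch to the configured imputation method."""
    if config.impute_method == "svd":
        return impute_svd(matrix, rank=config.svd_rank, tol=config.svd_tol,
                          max_iter=config.svd_max_iter)
    if config.impute_method == "lod":
        return impute_lod(matrix)
    return impute_lls(matrix, k=config.lls_k)


def remove_batch_effects(
    matrix: IntensityMatrix,
    annotation: AssayAnnotation,
    batch_covariate: str = "study_id",
) -> IntensityMatrix:
    """Subtract per-protein batch effects estimated by a linear model.

    For each protein an OLS model of abundance on batch membership is fitted
    and the fitted batch component is subtracted, constrained so that the
    protein's grand mean is preserved (equivalently: within-batch deviations
    from batch means are kept and the batch means are collapsed onto the
    grand mean).  Requires a complete (imputed) matrix.
    """
    matrix.require_stage("imputed", "batch_corrected")
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("batch removal requires a complete (imputed) matrix")
    ann = annotation.for_assays(matrix.assay_ids)
    if batch_covariate not in ann.table.columns:
        raise ValueError(f"unknown batch covariate {batch_covariate!r}")
    batches = ann.table[batch_covariate]
    levels = batches.unique()
    if len(levels) < 2:
        warnings.warn("single batch: batch removal is the identity", stacklevel=2)
        return matrix.with_values(vals.copy(), stage="batch_corrected")
    # guard against confounding with biological structure we must keep
    for bio in ("lineage", "sample_type"):
        if bio in ann.table.columns:
            bio_vals = ann.table[bio]
            if bio_vals.nunique() > 1 and (
                batches.groupby(bio_vals).nunique().eq(1).all()
                and bio_vals.groupby(batches).nunique().eq(1).all()
            ):
                raise ValueError(
                    f"batch covariate {batch_covariate!r} is confounded with {bio!r}"
                )
    X = vals.to_numpy(dtype=float)
    grand = X.mean(axis=1, keepdims=True)
    corrected = np.empty_like(X)
    for level in levels:
        cols = np.asarray(batches == level)
        bmean = X[:, cols].mean(axis=1, keepdims=True)
        corrected[:, cols] = X[:, cols] - bmean + grand
    out = pd.DataFrame(corrected, index=vals.index, columns=vals.columns)
    return matrix.with_values(out, stage="batch_corrected")


def batch_offset_estimates(
    matrix: IntensityMatrix,
    annotation: AssayAnnotation,
    batch_covariate: str = "study_id",
) -> pd.DataFrame:
    """Per-protein fitted batch coefficients (batch mean − grand mean)."""
    vals = matrix.values
    ann = annotation.for_assays(matrix.assay_ids)
    batches = ann.table[batch_covariate]
    est = {}
    grand = vals.mean(axis=1)
    for level in batches.unique():
        cols = vals.columns[np.asarray(batches == level)]
        est[level] = vals[cols].mean(axis=1) - grand
    return pd.DataFrame(est)


def run_normalization(
    matrix: IntensityMatrix,
    annotation: AssayAnnotation,
    config: NormalizationConfig | None = None,
    log: list[str] | None = None,
) -> IntensityMatrix:
    """Full pipeline: ppb → log2 → presence filter → impute → batch removal.

    ``log`` (if given) collects one line per stage with its parameters and
    the matrix shape after the stage.
    """
    cfg = config or NormalizationConfig()
    cfg.validate()

    def note(msg: str, m: IntensityMatrix) -> None:
        line = f"{msg} -> {m.n_proteins} proteins x {m.n_assays} assays [{m.stage}]"
        logger.info(line)
        if log is not None:
            log.append(line)

    m = ppb_normalize(matrix)
    note("ppb_normalize(total=1e8)", m)
    m = log2_transform(m)
    note("log2_transform", m)
    m = presence_filter(m, cfg.presence_threshold)
    note(f"presence_filter(threshold={cfg.presence_threshold})", m)
    m = impute(m, cfg)
    note(f"impute(method={cfg.impute_method})", m)
    m = remove_batch_effects(m, annotation, cfg.batch_covariate)
    note(f"remove_batch_effects(covariate={cfg.batch_covariate})", m)
    return m
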