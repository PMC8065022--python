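"""Correlation and variability statistics.

Sample–sample correlations on pairwise-complete observations, hierarchical
clustering of the correlation matrix, within/between sample-type summaries,
per-protein coefficients of variation, within-sample (across genes) and
across-sample (per gene, BH-adjusted) mRNA–protein Spearman correlations,
and a two-way lineage × study ANOVA with Tukey HSD post-hoc contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .io_formats import AssayAnnotation, IntensityMatrix

__all__ = [
    "PairedOmics",
    "pairwise_correlation",
    "hierarchical_cluster",
    "within_between_summary",
    "cv_by_group",
    "within_sample_rna_protein",
    "across_sample_rna_protein",
    "lineage_anova",
]

DEFAULT_MIN_OVERLAP = 10


@dataclass
class PairedOmics:
    """Gene-aligned protein (log2) and mRNA matrices over shared samples.

    mRNA values are stored as given (FPKM-like); rank statistics are
    unaffected, and Pearson-type uses go through ``log2(FPKM + 1)``.
    """

    protein: pd.DataFrame  # genes × samples, log2 scale
    rna: pd.DataFrame      # genes × samples, FPKM-like

    def __post_init__(self) -> None:
        genes = self.protein.index.intersection(self.rna.index)
        samples = self.protein.columns.intersection(self.rna.columns)
        if self.protein.index.duplicated().any() or self.rna.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if len(genes) == 0 or len(samples) == 0:
            raise ValueError("no shared genes or samples between the two layers")
        self.protein = self.protein.loc[genes, samples]
        self.rna = self.rna.loc[genes, samples]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.protein.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.protein.columns)

    @property
    def rna_log2(self) -> pd.DataFrame:
        return np.log2(self.rna + 1.0)


def _corr_complete(x: np.ndarray, y: np.ndarray, method: str) -> float:
    """Correlation on the jointly observed entries; NaN when degenerate."""
    ok = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[ok], y[ok]
    if len(xs) < 2 or xs.std() == 0 or ys.std() == 0:
        return np.nan
    if method == "pearson":
        return float(stats.pearsonr(xs, ys).statistic)
    return float(stats.spearmanr(xs, ys).statistic)


def pairwise_correlation(
    matrix: IntensityMatrix | pd.DataFrame,
    method: str = "pearson",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Assay × assay correlation matrix on pairwise-complete observations.

    Pairs with fewer than ``min_overlap`` jointly observed proteins (or a
    constant vector within the complete subset) are reported as NaN.  The
    result is symmetric with a unit diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    vals = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    assays = list(vals.columns)
    if len(assays) < 2:
        raise ValueError("need at least two assays")
    X = vals.to_numpy(dtype=float)
    n = len(assays)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
            if ok.sum() < min_overlap:
                continue
            out[i, j] = out[j, i] = _corr_complete(X[:, i], X[:, j], method)
    return pd.DataFrame(out, index=assays, columns=assays)


def hierarchical_cluster(
    correlation_table: pd.DataFrame, linkage_method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of correlation-matrix rows (Euclidean).

    Returns the scipy linkage matrix and the dendrogram leaf order.
    Undefined correlations must be resolved (imputed or excluded) first.
    """
    if correlation_table.isna().any().any():
        raise ValueError(
            "correlation matrix contains undefined entries; impute or exclude first"
        )
    if correlation_table.shape[0] == 1:
        return np.empty((0, 4)), list(correlation_table.index)
    d = pdist(correlation_table.to_numpy(), metric="euclidean")
    Z = hierarchy.linkage(d, method=linkage_method)
    order = hierarchy.leaves_list(Z)
    return Z, [correlation_table.index[i] for i in order]


def within_between_summary(
    correlation_table: pd.DataFrame, annotation: AssayAnnotation
) -> dict[str, pd.Series]:
    """Distributions of coefficients within and between sample types.

    Returns three off-diagonal coefficient collections keyed
    ``within_cell_line``, ``within_tumour`` and ``between`` (cell line ×
    tumour pairs).
    """
    ann = annotation.for_assays(list(correlation_table.index))
    stype = ann.table["sample_type"]
    cats: dict[str, list[float]] = {"within_cell_line": [], "within_tumour": [], "between": []}
    assays = list(correlation_table.index)
    for i, a in enumerate(assays):
        for b in assays[i + 1:]:
            r = correlation_table.loc[a, b]
            ta, tb = stype[a], stype[b]
            if ta == tb == "cell_line":
                cats["within_cell_line"].append(r)
            elif ta == tb == "tumour":
                cats["within_tumour"].append(r)
            elif {ta, tb} == {"cell_line", "tumour"}:
                cats["between"].append(r)
    out = {}
    for k, v in cats.items():
        if not v:
            warnings.warn(f"no pairs in category {k}", stacklevel=2)
        out[k] = pd.Series(v, dtype=float)
    return out


def cv_by_group(
    matrix: IntensityMatrix | pd.DataFrame,
    annotation: AssayAnnotation,
    group_by: str = "lineage",
    linear_scale: bool = False,
) -> pd.DataFrame:
    """Per-protein, per-group coefficient of variation (percent).

    CV is computed on the linear intensity scale; if the input is a log2
    matrix (``linear_scale=False``, the default for the pipeline's final
    matrices) values are back-transformed with ``2**x`` first.  Groups with
    fewer than two observed values for a protein are excluded, as are
    zero-mean rows.
    """
    vals = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    if not linear_scale:
        vals = np.exp2(vals)
    ann = annotation.for_assays(list(vals.columns))
    groups = ann.table[group_by]
    rows = []
    for group in groups.unique():
        cols = list(groups.index[groups == group])
        sub = vals[cols]
        n_obs = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        keep = (n_obs >= 2) & (mean > 0)
        for pid in sub.index[keep]:
            rows.append(
                {
                    "protein_id": pid,
                    "group": group,
                    "mean": mean[pid],
                    "sd": sd[pid],
                    "cv_percent": 100.0 * sd[pid] / mean[pid],
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "group", "mean", "sd", "cv_percent"])


def within_sample_rna_protein(
    paired: PairedOmics, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> pd.DataFrame:
    """Per-sample Spearman between mRNA and protein across genes.

    Returns one row per sample with the coefficient, the number of complete
    mRNA–protein pairs and the large-sample p-value; samples with fewer than
    ``min_overlap`` complete pairs are NaN-flagged.
    """
    rows = []
    P, R = paired.protein, paired.rna
    for s in paired.sample_ids:
        x, y = P[s].to_numpy(float), R[s].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < min_overlap:
            rows.append({"sample_id": s, "rs": np.nan, "n_complete": n, "p_value": np.nan})
            continue
        res = stats.spearmanr(x[ok], y[ok])
        rows.append({"sample_id": s, "rs": float(res.statistic),
                     "n_complete": n, "p_value": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("sample_id")


def across_sample_rna_protein(
    paired: PairedOmics,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-gene Spearman across samples with Benjamini–Hochberg adjustment.

    Genes constant in either layer (or with fewer than ``min_overlap``
    complete samples) are reported NaN and excluded from the adjustment.
    Adds a boolean ``significant`` column at ``adjusted_p < alpha``.
    """
    P, R = paired.protein.to_numpy(float), paired.rna.to_numpy(float)
    rs = np.full(len(paired.gene_ids), np.nan)
    pv = np.full(len(paired.gene_ids), np.nan)
    nc = np.zeros(len(paired.gene_ids), dtype=int)
    for g in range(P.shape[0]):
        x, y = P[g], R[g]
        ok = ~(np.isnan(x) | np.isnan(y))
        nc[g] = ok.sum()
        if nc[g] < min_overlap or x[ok].std() == 0 or y[ok].std() == 0:
            continue
        res = stats.spearmanr(x[ok], y[ok])
        rs[g], pv[g] = res.statistic, res.pvalue
    out = pd.DataFrame(
        {"rs": rs, "n_complete": nc, "p_value": pv},
        index=paired.gene_ids,
    )
    defined = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if defined.any():
        adj[defined.to_numpy()] = multipletests(
            out.loc[defined, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["adjusted_p"] = adj
    out["significant"] = out["adjusted_p"] < alpha
    return out


def lineage_anova(
    per_assay_rs: pd.Series,
    annotation: AssayAnnotation,
    min_group_size: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way fixed-effects ANOVA of r_s on lineage and study, plus Tukey HSD.

    Main effects only (no interaction); lineages with fewer than
    ``min_group_size`` assays are excluded before fitting.  Returns the
    ANOVA table and the Tukey pairwise-comparison table over lineages.
    """
    ann = annotation.for_assays(list(per_assay_rs.index))
    df = pd.DataFrame(
        {
            "rs": per_assay_rs.to_numpy(float),
            "lineage": ann.table["lineage"].to_numpy(),
            "study": ann.table["study_id"].to_numpy(),
        }
    ).dropna()
    sizes = df["lineage"].value_counts()
    df = df[df["lineage"].isin(sizes.index[sizes >= min_group_size])]
    if df["lineage"].nunique() < 2:
        raise ValueError("need at least two lineages after size filtering")
    if df["study"].nunique() < 1:
        raise ValueError("need at least one study")
    formula = "rs ~ C(lineage) + C(study)" if df["study"].nunique() > 1 else "rs ~ C(lineage)"
    model = ols(formula, data=df).fit()
    table = anova_lm(model, typ=2)
    tukey = pairwise_tukeyhsd(df["rs"].to_numpy(), df["lineage"].to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return table, tukey_df
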