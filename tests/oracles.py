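"""Independent brute-force oracles used by the test suite.

These deliberately reimplement the checked operations in the most direct
textbook way, sharing no code with the package internals.
"""

import numpy as np


def svd_impute_oracle(X, rank, tol=1e-6, max_iter=500):
    """Straightforward iterative-SVD imputation (row-mean init)."""
    X = np.array(X, dtype=float)
    mask = np.isnan(X)
    if not mask.any():
        return X
    for i in range(X.shape[0]):
        X[i, mask[i]] = np.nanmean(X[i])
    prev = X[mask].copy()
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        recon = U[:, :rank] @ np.diag(s[:rank]) @ Vt[:rank]
        X[mask] = recon[mask]
        if np.linalg.norm(X[mask] - prev) / max(np.linalg.norm(X[mask]), 1e-300) < tol:
            break
        prev = X[mask].copy()
    return X


def batch_removal_oracle(X, batches):
    """Per-protein OLS on batch indicators; residual plus grand mean."""
    X = np.asarray(X, dtype=float)
    batches = np.asarray(batches)
    out = np.empty_like(X)
    levels = np.unique(batches)
    for i in range(X.shape[0]):
        y = X[i]
        D = np.column_stack([(batches == b).astype(float) for b in levels])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        out[i] = resid + y.mean()
    return out


def pairwise_complete_corr_oracle(X, method):
    """Per-pair complete-subset textbook correlation."""
    n = X.shape[1]
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
            x, y = X[ok, i], X[ok, j]
            if len(x) < 2 or x.std() == 0 or y.std() == 0:
                continue
            if method == "spearman":
                x = _ranks(x)
                y = _ranks(y)
            xm, ym = x - x.mean(), y - y.mean()
            out[i, j] = out[j, i] = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
    return out


def _ranks(v):
    """Average ranks, computed directly."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def enrichment_score_oracle(genes_in_order, scores, gene_set, weight):
    """Literal running-sum ES: walk the list, track the extremum."""
    n = len(genes_in_order)
    hits = [g in gene_set for g in genes_in_order]
    m = sum(hits)
    denom_hit = sum(abs(s) ** weight for g, s, h in zip(genes_in_order, scores, hits) if h)
    running = 0.0
    profile = []
    for g, s, h in zip(genes_in_order, scores, hits):
        if h:
            running += (abs(s) ** weight) / denom_hit if denom_hit > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        profile.append(running)
    hi, lo = max(profile), min(profile)
    best = hi if hi >= -lo - 1e-12 else lo  # positive preferred on exact tie
    return best, profile


def bh_adjust_oracle(pvals):
    """Hand-executed Benjamini–Hochberg step-up."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        adj[idx] = running_min
    return adj
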