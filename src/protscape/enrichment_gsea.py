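"""Preranked gene-set enrichment (weighted Kolmogorov–Smirnov statistic).

Given a gene list ranked by a score (here typically the per-gene
mRNA–protein Spearman correlation) and a collection of gene sets, the
enrichment score (ES) is the extremum of a running sum that increments at
set members proportionally to ``|score|**weight`` and decrements by
``1/(N - m)`` elsewhere.  Significance comes from gene-set-label
permutations (random sets of matched size): NES is the ES divided by the
mean |null ES| of matching sign, the nominal p-value is the matched-sign
permutation tail, and FDR q uses the standard NES-ratio estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "enrichment_score",
    "gsea_preranked",
    "read_gmt",
    "write_gmt",
]


@dataclass
class RankedGeneList:
    """Gene ids ordered by descending ranking score."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if (np.diff(self.scores) > 0).any():
            order = np.argsort(-self.scores, kind="stable")
            self.genes = [self.genes[i] for i in order]
            self.scores = self.scores[order]

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedGeneList":
        s = s.dropna().sort_values(ascending=False)
        return cls(genes=list(s.index), scores=s.to_numpy())

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str]
    set_size: int


def enrichment_score(
    ranked: RankedGeneList, gene_set: set[str] | frozenset[str], weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of one gene set, plus the full running-sum profile.

    Raises if the set does not intersect the list or swallows it whole.
    """
    n = len(ranked)
    hits = np.array([g in gene_set for g in ranked.genes])
    m = int(hits.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if m == n:
        raise ValueError("gene set equals the whole ranked list")
    w_all = np.abs(ranked.scores) ** weight_exponent
    w_hit = np.where(hits, w_all, 0.0)
    W = w_hit.sum()
    if W == 0:
        w_hit = hits.astype(float)
        W = float(m)
    steps = np.where(hits, w_hit / W, -1.0 / (n - m))
    running = np.cumsum(steps)
    i_pos, i_neg = int(np.argmax(running)), int(np.argmin(running))
    # positive extremum preferred on (float-tolerant) exact ties
    if running[i_pos] >= -running[i_neg] - 1e-12:
        return float(running[i_pos]), running
    return float(running[i_neg]), running


def _leading_edge(
    ranked: RankedGeneList, gene_set: set[str], running: np.ndarray, es: float
) -> list[str]:
    if es >= 0:
        peak = int(np.argmax(running))
        return [g for g in ranked.genes[: peak + 1] if g in gene_set]
    trough = int(np.argmin(running))
    return [g for g in ranked.genes[trough:] if g in gene_set]


def _null_es(
    n: int, m: int, weights_all: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution from random same-size gene sets (vectorized)."""
    # random m-subsets of range(n), sorted per row
    keys = rng.random((n_permutations, n))
    Q = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
    w = weights_all[Q]
    W = w.sum(axis=1, keepdims=True)
    zero = (W[:, 0] == 0)
    if zero.any():
        w[zero] = 1.0
        W[zero] = float(m)
    d = 1.0 / (n - m)
    cw = np.cumsum(w, axis=1) / W
    j = np.arange(1, m + 1)
    after = cw - (Q + 1 - j) * d
    before = np.concatenate([np.zeros((n_permutations, 1)), cw[:, :-1]], axis=1) - (Q - (j - 1)) * d
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    return np.where(es_pos >= -es_neg - 1e-12, es_pos, es_neg)


def gsea_preranked(
    ranked: RankedGeneList,
    gene_sets: dict[str, set[str] | frozenset[str]],
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    min_size: int = 2,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    Returns a DataFrame indexed by set name with columns ``es``, ``nes``,
    ``nominal_p``, ``fdr_q``, ``set_size`` and ``leading_edge``
    (comma-joined).  Deterministic given ``seed``.  Sets whose overlap with
    the list falls outside ``[min_size, max_size]`` are skipped.
    """
    if not gene_sets:
        raise ValueError("need at least one gene set")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    n = len(ranked)
    max_size = max_size if max_size is not None else n - 1
    rng = np.random.default_rng(seed)
    w_all = np.abs(ranked.scores) ** weight_exponent
    in_list = set(ranked.genes)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    null_cache: dict[int, np.ndarray] = {}
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & in_list
        m = len(members)
        if m < min_size or m > max_size:
            continue
        es, running = enrichment_score(ranked, members, weight_exponent)
        if m not in null_cache:
            null_cache[m] = _null_es(n, m, w_all, n_permutations, rng)
        null = null_cache[m]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same) == 0:
            nominal_p, nes = 0.0, np.nan
            null_nes = np.array([])
        else:
            # classical convention: matched-sign tail fraction; 0 means the
            # observed ES exceeded every permutation (below resolution)
            nominal_p = float((np.abs(same) >= abs(es)).sum()) / len(same)
            mean_same = np.abs(same).mean()
            nes = es / mean_same
            pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
            neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
            null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
            null_nes = null_nes[np.isfinite(null_nes)]
        null_nes_pool.append(null_nes)
        rows.append(
            {
                "gene_set": name,
                "es": es,
                "nes": nes,
                "nominal_p": nominal_p,
                "set_size": m,
                "leading_edge": ",".join(_leading_edge(ranked, members, running, es)),
            }
        )
    if not rows:
        raise ValueError("no gene set passed the size bounds")
    out = pd.DataFrame(rows).set_index("gene_set")

    # FDR q: ratio of null-NES to observed-NES tail fractions, matched sign.
    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs = out["nes"].to_numpy()
    q = np.full(len(out), np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac_den = (pooled >= 0).sum()
            null_frac = (pooled >= nes).sum() / max(null_frac_den, 1)
            obs_den = (obs >= 0).sum()
            obs_frac = (obs >= nes).sum() / max(obs_den, 1)
        else:
            null_frac_den = (pooled < 0).sum()
            null_frac = (pooled <= nes).sum() / max(null_frac_den, 1)
            obs_den = (obs < 0).sum()
            obs_frac = (obs <= nes).sum() / max(obs_den, 1)
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    out["fdr_q"] = q
    return out[["es", "nes", "nominal_p", "fdr_q", "set_size", "leading_edge"]]


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members…)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            fh.write("\t".join([name, description, *sorted(gene_sets[name])]) + "\n")
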