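"""Ranked-list enrichment (GSEA) and hypergeometric over-representation.

Two engines:

* Preranked GSEA with the weighted Kolmogorov-Smirnov-like running sum:
  genes are ordered by score (regression coefficient), hits advance the sum
  by ``|score|^w / sum_hits |score|^w`` and misses retreat by
  ``1 / (N - N_hits)``; the enrichment score is the extreme deviation. The
  null is a permutation of gene-set membership (the only null available from
  a coefficient vector alone), nominal p is the same-sign tail fraction, and
  NES divides ES by the mean magnitude of same-sign permuted scores.
* Over-representation with the upper-tail hypergeometric test.

Both apply Benjamini-Hochberg FDR across evaluated terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "RankedList",
    "rank_genes",
    "enrichment_score",
    "gsea_preranked",
    "ora_hypergeometric",
    "bh_adjust",
]

RESULT_COLUMNS = [
    "term",
    "library",
    "statistic",
    "es",
    "nes",
    "odds",
    "k",
    "K",
    "p",
    "padj",
    "direction",
    "genes",
]


@dataclass(frozen=True)
class RankedList:
    """Genes strictly ordered by descending score.

    Ties are broken by gene identifier (ascending), recorded in
    ``tie_break`` so the ordering is reproducible.
    """

    genes: tuple[str, ...]
    scores: np.ndarray
    tie_break: str = "gene identifier (ascending)"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked list contains duplicate genes")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("ranked list contains non-finite scores")
        if np.any(np.diff(self.scores) > 0):
            raise ValidationError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(scores: pd.Series) -> RankedList:
    """Build a RankedList from a gene -> score Series (e.g. a beta vector)."""
    s = scores.dropna()
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return RankedList(genes=tuple(order), scores=s.loc[order].to_numpy(dtype=float))


def _steps(scores: np.ndarray, member: np.ndarray, weight: float) -> np.ndarray:
    """Per-position running-sum increments for one membership vector."""
    n = len(scores)
    n_hit = int(member.sum())
    if n_hit == 0 or n_hit == n:
        raise ValidationError("gene set must be a proper non-empty subset of the universe")
    w = np.abs(scores) ** weight
    hit_total = w[member].sum()
    steps = np.full(n, -1.0 / (n - n_hit))
    if hit_total > 0:
        steps[member] = w[member] / hit_total
    else:  # all hit scores are zero: fall back to unweighted hits
        steps[member] = 1.0 / n_hit
    return steps


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight_exponent: float = 1.0
) -> tuple[float, int]:
    """ES and the index of its extreme deviation along the ranked list."""
    member = np.fromiter((g in set(gene_set) for g in ranked.genes), bool, len(ranked))
    run = np.cumsum(_steps(ranked.scores, member, weight_exponent))
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def _permuted_es(
    scores: np.ndarray,
    n_hit: int,
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """ES values for random gene-set memberships of fixed size."""
    n = len(scores)
    w = np.abs(scores) ** weight
    miss = -1.0 / (n - n_hit)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, n_hit - 1, axis=1)[:, :n_hit]
        steps = np.full((m, n), miss)
        hit_w = w[idx]
        denom = hit_w.sum(axis=1)
        rows = np.repeat(np.arange(m), n_hit)
        vals = np.where(
            denom[:, None] > 0, hit_w / np.where(denom[:, None] > 0, denom[:, None], 1.0), 1.0 / n_hit
        )
        steps[rows, idx.ravel()] = vals.ravel()
        run = np.cumsum(steps, axis=1)
        ext = np.argmax(np.abs(run), axis=1)
        out[done : done + m] = run[np.arange(m), ext]
        done += m
    return out


def gsea_preranked(
    ranked: RankedList | pd.Series,
    gene_sets: Mapping[str, Iterable[str]],
    weight_exponent: float = 1.0,
    n_perm: int = 10_000,
    min_size: int = 10,
    max_size: int = 500,
    seed: int | None = None,
    library: str = "custom",
) -> pd.DataFrame:
    """Preranked GSEA over a term library with a membership-permutation null.

    Terms whose overlap with the ranked universe falls outside
    ``[min_size, max_size]`` are skipped. Nominal p is the one-sided tail of
    same-sign permuted ES values (with the +1 continuity correction); BH-FDR
    is applied across evaluated terms.
    """
    if isinstance(ranked, pd.Series):
        ranked = rank_genes(ranked)
    if not gene_sets:
        raise ValidationError("empty term library")
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes)
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}

    perm_cache: dict[int, np.ndarray] = {}
    rows = []
    for term, members in gene_sets.items():
        overlap = sorted(set(members) & universe)
        k = len(overlap)
        if k == len(universe):
            raise ValidationError(f"term {term!r} equals the full ranked universe")
        if not (min_size <= k <= max_size):
            continue
        es, ext = enrichment_score(ranked, overlap, weight_exponent)
        if k not in perm_cache:
            perm_cache[k] = _permuted_es(ranked.scores, k, weight_exponent, n_perm, rng)
        perm = perm_cache[k]
        if es >= 0:
            side = perm[perm >= 0]
            tail = int((side >= es).sum())
        else:
            side = perm[perm < 0]
            tail = int((side <= es).sum())
        p = (tail + 1) / (len(side) + 1)
        nes = es / np.mean(np.abs(side)) if len(side) else np.nan
        if es >= 0:
            leading = [g for g in overlap if gene_pos[g] <= ext]
        else:
            leading = [g for g in overlap if gene_pos[g] >= ext]
        rows.append(
            {
                "term": term,
                "library": library,
                "statistic": "gsea",
                "es": es,
                "nes": nes,
                "odds": np.nan,
                "k": k,
                "K": len(set(members)),
                "p": p,
                "padj": np.nan,
                "direction": "up" if es >= 0 else "down",
                "genes": ";".join(sorted(leading, key=lambda g: gene_pos[g])),
            }
        )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def ora_hypergeometric(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    library: str = "custom",
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a gene list.

    For a term with K members in the universe (size N) and a query of size
    n overlapping in k genes, ``p = P(X >= k)`` with X hypergeometric.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query gene list")
    stray = query - universe
    if stray:
        raise ValidationError(f"query genes outside the universe: {sorted(stray)[:5]}")
    if not gene_sets:
        raise ValidationError("empty term library")

    N, n = len(universe), len(query)
    rows = []
    for term, members in gene_sets.items():
        term_set = set(members) & universe
        K = len(term_set)
        overlap = sorted(term_set & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        denom = (K - k) * (n - k)
        odds = (k * (N - K - n + k)) / denom if denom > 0 else np.inf if k else np.nan
        rows.append(
            {
                "term": term,
                "library": library,
                "statistic": "ora",
                "es": np.nan,
                "nes": np.nan,
                "odds": odds,
                "k": k,
                "K": K,
                "p": min(p, 1.0),
                "padj": np.nan,
                "direction": "over",
                "genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    ``q_i = min_{j >= i} p_(j) * m / j`` over the ascending order, capped at
    1. NA p-values yield NA q-values and are excluded from m.
    """
    p = np.asarray(list(pvalues), dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q
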