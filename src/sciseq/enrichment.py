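"""Gene-set enrichment: Fisher over-representation and rank-based
weighted-KS enrichment with a permutation null.

Two engines:

* :func:`fisher_enrichment` — one-sided hypergeometric over-representation
  of a query gene list against each set of a collection, BH-corrected.
* :func:`enrichment_score` / :func:`permutation_null` — the weighted
  Kolmogorov–Smirnov running-sum statistic over a fold-change-ranked gene
  list.  Walking down the list, hits increment the running sum by
  |metric|^p normalized over the in-set |metric|^p total and misses
  decrement by 1/(N − N_set); the enrichment score (ES) is the signed
  maximum deviation, zero in expectation when the set falls at random.

The null is built by permuting gene labels (random same-size sets), not
phenotypes: with 2–3 replicates per stage, phenotype permutation is
degenerate.  NES divides ES by the mean |null ES| of the same sign; the
nominal p is the fraction of same-sign null ES at least as extreme,
reported with the (r+1)/(n+1) floor so it is never zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, ValidationError
from .de import bh_adjust


def fisher_enrichment(
    query, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """One-sided over-representation of ``query`` in each gene set.

    Sets are intersected with the universe; p is the hypergeometric upper
    tail P(X ≥ overlap); q is BH across sets.
    """
    universe = set(map(str, universe))
    query = set(map(str, query))
    if not universe or not query:
        raise ValidationError("query and universe must be non-empty")
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    n_u, n_q = len(universe), len(query)
    rows = []
    for name, members in sorted(collection.items()):
        in_universe = members & universe
        k = len(in_universe & query)
        m = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, n_u, m, n_q)) if m else 1.0
        # odds ratio of the 2×2 table, 0.5 continuity only when degenerate
        a, b = k, n_q - k
        c, d = m - k, n_u - m - (n_q - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": m,
                "query_size": n_q,
                "universe_size": n_u,
                "odds_ratio": odds,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows).set_index("set")
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table


def rank_by_fold_change(de_table: pd.DataFrame) -> pd.Series:
    """Genes ranked by descending log2 fold change (ties by gene id)."""
    metric = de_table["log2_fc"]
    order = pd.DataFrame(
        {"metric": metric.to_numpy(), "gene": list(metric.index)}
    ).sort_values(["metric", "gene"], ascending=[False, True], kind="mergesort")
    ranked = pd.Series(
        order["metric"].to_numpy(),
        index=pd.Index(order["gene"], name="gene"),
        name="log2_fc",
    )
    return ranked


def _hit_mask(ranked: pd.Series, gene_set) -> np.ndarray:
    members = set(map(str, gene_set))
    return np.fromiter((g in members for g in ranked.index), dtype=bool,
                       count=len(ranked))


def _es_from_mask(
    metric: np.ndarray, hits: np.ndarray, weight: float
) -> tuple[float, np.ndarray]:
    n = len(metric)
    n_set = int(hits.sum())
    if n_set == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if n_set == n:
        raise ValidationError("gene set covers the entire ranked list")
    w = np.abs(metric) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all in-set metrics zero: fall back to unweighted hits
        hit_w = hits.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hits) / (n - n_set)
    curve = np.cumsum(steps)
    es = curve[np.argmax(np.abs(curve))]
    return float(es), curve


def enrichment_score(
    ranked: pd.Series, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the running-sum curve.

    ``ranked`` is the fold-change-ordered metric series from
    :func:`rank_by_fold_change`; ``weight`` is the hit-weight exponent p
    (p = 1 is the standard weighted statistic, p = 0 the classic KS).
    """
    hits = _hit_mask(ranked, gene_set)
    return _es_from_mask(ranked.to_numpy(dtype=float), hits, weight)


def leading_edge(ranked: pd.Series, gene_set, weight: float = 1.0) -> list[str]:
    """Set members before (after) the running-sum extremum for ES > 0 (< 0)."""
    hits = _hit_mask(ranked, gene_set)
    es, curve = _es_from_mask(ranked.to_numpy(dtype=float), hits, weight)
    peak = int(np.argmax(np.abs(curve)))
    genes = np.asarray(ranked.index)
    if es >= 0:
        mask = hits & (np.arange(len(hits)) <= peak)
    else:
        mask = hits & (np.arange(len(hits)) >= peak)
    return list(genes[mask])


def _null_es(
    metric: np.ndarray, n_set: int, n_perm: int, weight: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(metric)
    out = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=n_set, replace=False)
        hits = np.zeros(n, dtype=bool)
        hits[idx] = True
        out[i], _ = _es_from_mask(metric, hits, weight)
    return out


def permutation_null(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Gene-label permutation null for every set: ES, NES, nominal p, FDR q.

    Nominal p = (r + 1)/(n_perm + 1) where r counts same-sign null ES at
    least as extreme as the observed ES; NES = ES / mean |same-sign null ES|.
    FDR q is BH across the queried sets.
    """
    if n_perm < 100:
        raise ValidationError("use at least 100 permutations")
    metric = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sorted(collection.items()):
        hits = _hit_mask(ranked, members)
        es, _ = _es_from_mask(metric, hits, weight)
        null = _null_es(metric, int(hits.sum()), n_perm, weight, rng)
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            denom = float(np.abs(same_sign).mean())
            nes = es / denom if denom > 0 else np.nan
            r = int((np.abs(same_sign) >= abs(es)).sum())
            p = (r + 1) / (len(same_sign) + 1)
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "p_value": p,
                "n_perm": n_perm,
                "leading_edge": ",".join(leading_edge(ranked, members, weight)),
            }
        )
    table = pd.DataFrame(rows).set_index("set")
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table
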