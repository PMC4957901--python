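"""Hypergeometric singular enrichment with FDR control and hallmark roll-ups.

Per-term over-representation of a query gene set against a fixed
background universe, the GeneCodis-style contract: every count (query
size, term size, hits) is taken after intersecting with the supplied
background and with the annotated genes.  The upper-tail probability is
computed from log-factorials for numerical stability.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k, K, n, N):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), vectorized.

    ``N`` is the background size, ``K`` the number of annotated background
    genes, ``n`` the query size and ``k`` the observed hits.  Computed by
    summing log-factorial terms of the tail, so it is stable for large
    backgrounds.  Scalars or broadcastable arrays accepted.
    """
    k, K, n, N = np.broadcast_arrays(
        np.asarray(k, dtype=int),
        np.asarray(K, dtype=int),
        np.asarray(n, dtype=int),
        np.asarray(N, dtype=int),
    )
    if np.any(K > N) or np.any(n > N) or np.any(k > np.minimum(n, K)) or np.any(
        (k < 0) | (K < 0) | (n < 0) | (N < 0)
    ):
        raise ValueError("arguments must satisfy 0 <= k <= min(n, K), K <= N, n <= N")
    hi = np.minimum(n, K)
    width = int((hi - k).max()) + 1 if k.size else 1
    # j-grid over the tail; rows past hi are masked out
    j = k[..., None] + np.arange(width)
    valid = j <= hi[..., None]
    j = np.where(valid, j, 0)
    logp = (
        _log_comb(K[..., None], j)
        + _log_comb((N - K)[..., None], n[..., None] - j)
        - _log_comb(N[..., None], n[..., None])
    )
    logp = np.where(valid, logp, -np.inf)
    m = logp.max(axis=-1)
    with np.errstate(divide="ignore"):
        out = np.exp(m) * np.exp(logp - m[..., None]).sum(axis=-1)
    out = np.minimum(out, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def singular_enrichment(
    query_genes: Iterable[str],
    annotations: Mapping[str, set],
    background_genes: Iterable[str],
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of ``query_genes``.

    Query genes outside the background are logged and dropped.  Only terms
    with at least one annotated background gene and at least one query hit
    are tested; BH-FDR is computed across the tested terms.  Returns a
    DataFrame sorted by p-value with columns term, k, n, K, N, p_value, fdr.
    """
    background = set(background_genes)
    query = set(query_genes)
    outside = query - background
    if outside:
        logger.warning("%d query genes outside background dropped", len(outside))
        query &= background
    if not query:
        logger.warning("empty query after background restriction")
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "p_value", "fdr"])
    N = len(background)
    n = len(query)
    rows = []
    for term, genes in annotations.items():
        term_bg = set(genes) & background
        if not term_bg:
            continue
        k = len(term_bg & query)
        if k == 0:
            continue
        rows.append((term, k, n, len(term_bg), N))
    if not rows:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "p_value", "fdr"])
    res = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N"])
    res["p_value"] = hypergeom_upper_tail(res["k"], res["K"], res["n"], res["N"])
    res["fdr"] = bh_fdr(res["p_value"])
    return res.sort_values("p_value", kind="mergesort", ignore_index=True)


def hallmark_rollup(
    enriched_by_timepoint: Mapping[str, pd.DataFrame],
    term_to_hallmark: Mapping[str, str],
    network_genes_by_timepoint: Mapping[str, set],
    annotations: Mapping[str, set],
) -> tuple[pd.DataFrame, list[str]]:
    """Hallmark x time-point matrix of miRNA-regulated gene counts.

    A cell (hallmark h, time point t) counts the union of genes that are in
    the time-t network and annotated to any enriched term mapped to h.
    Enriched terms without a hallmark mapping are excluded and returned as
    the unmapped report.
    """
    unmapped: set[str] = set()
    hallmarks = sorted(set(term_to_hallmark.values()))
    timepoints = list(enriched_by_timepoint.keys())
    matrix = pd.DataFrame(0, index=hallmarks, columns=timepoints, dtype=int)
    for tp, table in enriched_by_timepoint.items():
        net_genes = set(network_genes_by_timepoint.get(tp, ()))
        per_hallmark: dict[str, set] = {h: set() for h in hallmarks}
        for term in table["term"]:
            hallmark = term_to_hallmark.get(term)
            if hallmark is None:
                unmapped.add(term)
                continue
            per_hallmark[hallmark] |= set(annotations.get(term, ())) & net_genes
        for h in hallmarks:
            matrix.loc[h, tp] = len(per_hallmark[h])
    if unmapped:
        logger.warning("%d enriched terms had no hallmark mapping", len(unmapped))
    return matrix, sorted(unmapped)
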