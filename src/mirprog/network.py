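"""Correlation-filtered stage-specific and trend-matched regulatory networks.

Candidate miRNA->mRNA interactions (sequence-based predictions) are first
screened by Spearman correlation across all samples: miRNAs repress their
targets, so only strictly negative correlations survive.  Surviving pairs
are then admitted into a stage network at a time point when both ends are
differentially expressed with opposite signs there, or into a trend
network when the target's transition pattern is the exact character-wise
mirror of a trending miRNA's pattern.  Edges carry an ``admitted_by`` tag
so stage- and trend-admitted edges never mix silently.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dynamics import opposite_pattern

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["mirna", "gene", "rho", "admitted_by"]


def filter_by_correlation(
    candidates: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
) -> pd.DataFrame:
    """Keep candidate pairs with strictly negative Spearman correlation.

    ``candidates`` needs columns ``mirna`` and ``gene``; expression
    matrices are features x samples over the same sample columns.  Pairs
    whose correlation is non-negative or not computable (a constant
    vector) are dropped; candidates referencing unknown features are
    logged, skipped and counted in ``result.attrs["n_unknown"]``.
    """
    if list(mirna_expr.columns) != list(mrna_expr.columns):
        mrna_expr = mrna_expr[mirna_expr.columns]
    known = candidates["mirna"].isin(mirna_expr.index) & candidates["gene"].isin(
        mrna_expr.index
    )
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("%d candidate pairs reference unknown features; skipped", n_unknown)
    cand = candidates.loc[known].drop_duplicates(subset=["mirna", "gene"]).copy()

    # rank once per feature, then correlate ranks (Spearman = Pearson on mid-ranks)
    mi_ranks = mirna_expr.rank(axis=1)
    mr_ranks = mrna_expr.rank(axis=1)
    mi = _standardize_ranks(mi_ranks.loc[cand["mirna"]].to_numpy())
    mr = _standardize_ranks(mr_ranks.loc[cand["gene"]].to_numpy())
    n = mi_ranks.shape[1]
    rho = np.einsum("ij,ij->i", mi, mr) / n
    cand["rho"] = rho
    kept = cand[np.isfinite(cand["rho"]) & (cand["rho"] < 0)].reset_index(drop=True)
    kept.attrs["n_unknown"] = n_unknown
    kept.attrs["n_dropped_nonnegative"] = len(cand) - len(kept)
    return kept


def _standardize_ranks(ranks: np.ndarray) -> np.ndarray:
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = centered / sd
    out[~np.isfinite(out)] = np.nan
    return out


def stage_network(
    filtered: pd.DataFrame,
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    timepoint: str,
) -> pd.DataFrame:
    """Edges whose ends are oppositely differentially expressed at a stage.

    Both the miRNA and the gene must be significant (direction != "ns") at
    ``timepoint`` and their directions must differ (one up, one down).
    """
    mi = de_mirna[de_mirna["timepoint"] == timepoint].set_index("feature")["direction"]
    mr = de_mrna[de_mrna["timepoint"] == timepoint].set_index("feature")["direction"]
    if mi.empty or mr.empty:
        raise ValueError(f"DE tables do not cover time point {timepoint!r}")
    d_mi = filtered["mirna"].map(mi)
    d_mr = filtered["gene"].map(mr)
    keep = (
        d_mi.isin(["up", "down"]) & d_mr.isin(["up", "down"]) & (d_mi != d_mr)
    )
    edges = filtered.loc[keep, ["mirna", "gene", "rho"]].copy()
    edges["admitted_by"] = f"stage:{timepoint}"
    return edges.reset_index(drop=True)


def trend_network(
    filtered: pd.DataFrame,
    mirna_profiles: pd.DataFrame,
    mrna_profiles: pd.DataFrame,
    hamming_tolerance: int = 0,
) -> pd.DataFrame:
    """Edges where the gene pattern mirrors a trending miRNA's pattern.

    Only miRNAs in a monotone trend group (non_decrease or non_increase)
    seed edges; a gene matches when its pattern equals the character-wise
    opposite of the miRNA's pattern (exactly by default; a Hamming
    tolerance can relax the match).
    """
    trending = mirna_profiles[
        mirna_profiles["trend_group"].isin(["non_decrease", "non_increase"])
    ]
    mi_pattern = trending["pattern"]
    mr_pattern = mrna_profiles["pattern"]
    d_mi = filtered["mirna"].map(mi_pattern)
    d_mr = filtered["gene"].map(mr_pattern)
    ok = d_mi.notna() & d_mr.notna()
    if hamming_tolerance == 0:
        match = ok & (d_mi.map(lambda p: opposite_pattern(p) if isinstance(p, str) else p) == d_mr)
    else:
        def _close(pair):
            p, q = pair
            if not isinstance(p, str) or not isinstance(q, str):
                return False
            return sum(a != b for a, b in zip(opposite_pattern(p), q)) <= hamming_tolerance

        match = ok & pd.Series(map(_close, zip(d_mi, d_mr)), index=filtered.index)
    edges = filtered.loc[match, ["mirna", "gene", "rho"]].copy()
    edges["admitted_by"] = "trend"
    return edges.reset_index(drop=True)


def degree_stats(edges: pd.DataFrame) -> dict:
    """Node/edge counts and mean degrees over nodes with degree >= 1."""
    if edges.empty:
        logger.warning("empty network")
        return {
            "n_mirnas": 0,
            "n_genes": 0,
            "n_edges": 0,
            "mean_targets_per_mirna": float("nan"),
            "mean_regulators_per_gene": float("nan"),
        }
    dedup = edges.drop_duplicates(subset=["mirna", "gene"])
    return {
        "n_mirnas": int(dedup["mirna"].nunique()),
        "n_genes": int(dedup["gene"].nunique()),
        "n_edges": int(len(dedup)),
        "mean_targets_per_mirna": float(len(dedup) / dedup["mirna"].nunique()),
        "mean_regulators_per_gene": float(len(dedup) / dedup["gene"].nunique()),
    }


def signed_concordance(calls_a: dict, calls_b: dict) -> float:
    """Percentage of shared ids with the same up/down direction.

    Returns ``nan`` when the two call sets share no ids (reported as NA
    downstream).
    """
    shared = set(calls_a) & set(calls_b)
    if not shared:
        return float("nan")
    agree = sum(1 for i in shared if calls_a[i] == calls_b[i])
    return 100.0 * agree / len(shared)
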