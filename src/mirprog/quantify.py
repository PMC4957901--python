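"""Expression quantification, normalization and per-stage differential expression.

This module turns small-RNA read alignments or raw count matrices into
normalized expression values and per-time-point differential-expression
summaries (tumor vs. normal), the inputs every downstream network stage
consumes.  The differential test is a deliberately simple, pluggable
stand-in: a Welch t-test on log2(normalized counts + 1) with
Benjamini-Hochberg FDR control.  Externally computed DE tables in the same
schema (feature, timepoint, logFC, p, fdr, direction) are accepted anywhere
a DE table is expected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrichment import bh_fdr

logger = logging.getLogger(__name__)

TIMEPOINTS = ("w6", "w8", "w10", "w12")
CONDITIONS = ("tumor", "normal")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix with sample metadata.

    ``values`` is a features-by-samples DataFrame of non-negative integers.
    ``samples`` is indexed by sample id with columns ``timepoint``,
    ``condition`` and ``replicate``.  ``feature_lengths`` (bases) is only
    required for RPKM.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample_subset(self, timepoint: str | None = None, condition: str | None = None) -> list[str]:
        meta = self.samples.loc[self.values.columns]
        mask = pd.Series(True, index=meta.index)
        if timepoint is not None:
            mask &= meta["timepoint"] == timepoint
        if condition is not None:
            mask &= meta["condition"] == condition
        return list(meta.index[mask])


def count_mirna_reads(
    read_alignments: Iterable[GenomicInterval],
    mirna_loci: Mapping[str, GenomicInterval],
    check_strand: str = "auto",
) -> pd.Series:
    """Count reads per miRNA locus under the >50%-overlap rule.

    A read increments miRNA ``m`` iff its overlap with the locus of ``m``
    is strictly greater than half the locus length (and the chromosome, and
    optionally strand, match).  A read clearing the threshold for several
    loci increments each of them.

    Parameters
    ----------
    check_strand:
        ``"auto"`` requires matching strands only when both records carry
        one (neither is ``"."``); ``"always"`` additionally treats ``"."``
        as a mismatch against explicit strands; ``"never"`` ignores strand.
    """
    if check_strand not in ("auto", "always", "never"):
        raise ValueError(f"unknown check_strand mode {check_strand!r}")
    counts = pd.Series(0, index=list(mirna_loci.keys()), dtype=int)
    loci_by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for mid, locus in mirna_loci.items():
        loci_by_chrom.setdefault(locus.chrom, []).append((mid, locus))
    for read in read_alignments:
        for mid, locus in loci_by_chrom.get(read.chrom, ()):
            if check_strand == "always" and read.strand != locus.strand:
                continue
            if (
                check_strand == "auto"
                and "." not in (read.strand, locus.strand)
                and read.strand != locus.strand
            ):
                continue
            if read.overlap(locus) > 0.5 * len(locus):
                counts[mid] += 1
    return counts


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column is replaced by the cross-sample mean of the order
    statistics at its within-column ranks; tied values receive the mean of
    the reference values over their tied rank block.
    """
    if values.size == 0:
        raise ValueError("empty matrix")
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # average reference values across tied ranks
        mapped = pd.Series(mapped).groupby(pd.Series(col)).transform("mean").to_numpy()
        out[:, j] = mapped
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads."""
    if counts.feature_lengths is None:
        raise ValueError("feature_lengths required for RPKM")
    lengths = counts.feature_lengths.reindex(counts.values.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    libsizes = counts.values.sum(axis=0)
    if (libsizes <= 0).any():
        raise ValueError("zero library size")
    kb = lengths.to_numpy(dtype=float) / 1e3
    millions = libsizes.to_numpy(dtype=float) / 1e6
    return pd.DataFrame(
        counts.values.to_numpy(dtype=float) / np.outer(kb, millions),
        index=counts.values.index,
        columns=counts.values.columns,
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties).

    Returns ``nan`` when either vector is constant; downstream filters
    treat a non-computable correlation as a dropped pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _fit_f_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-fit of a scaled-F prior to observed variances.

    Per-feature variances s2 with d residual df are modelled as
    s2 ~ s0^2 * F(d, d0); d0 and s0 are recovered from the mean and
    variance of log s2 via the digamma/trigamma moment equations.
    Returns (d0, s0_squared); d0 = inf when the observed spread is no
    wider than the chi-square sampling spread (no extra variability).
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    ev = z.var(ddof=1) - special.polygamma(1, d / 2)
    if ev <= 0:
        return np.inf, float(np.exp(e.mean()))
    # invert trigamma(d0/2) = ev by Newton iteration
    x = 0.5 + 1.0 / ev
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1 - tri / ev) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2 * x
    s0_sq = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s0_sq)


def _moderated_ttest(t_arr: np.ndarray, n_arr: np.ndarray) -> np.ndarray:
    """Two-group moderated t-test p-values (empirical-Bayes variance).

    Pooled two-group variances are shrunk toward a scaled-F prior fitted
    across features; the t statistic then has d + d0 degrees of freedom.
    Constant features (zero pooled variance everywhere relevant) get p=1.
    """
    n1, n2 = t_arr.shape[1], n_arr.shape[1]
    d = n1 + n2 - 2
    v1 = t_arr.var(axis=1, ddof=1)
    v2 = n_arr.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    d0, s0_sq = _fit_f_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df = d0 + d
    diff = t_arr.mean(axis=1) - n_arr.mean(axis=1)
    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    if np.isinf(df):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df)
    return np.where(np.isfinite(p), p, 1.0)


def _direction(logfc: float, fdr: float, cutoff: float) -> str:
    if fdr < cutoff and logfc > 0:
        return "up"
    if fdr < cutoff and logfc < 0:
        return "down"
    return "ns"


def differential_expression(
    counts: CountMatrix,
    timepoint: str,
    normalized: pd.DataFrame | None = None,
    pseudocount: float = 1.0,
    fdr_cutoff: float = 0.05,
    method: str = "moderated",
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression at one time point.

    logFC is log2 of the (pseudocounted) mean normalized tumor expression
    over the mean normalized normal expression; the p-value comes from a
    two-sample location test on log2(normalized + 1) — by default a
    moderated t-test whose per-feature variances are shrunk toward an
    empirical-Bayes prior (the variance sharing that makes small-n
    RNA-seq testing workable, in the spirit of limma/edgeR), or a plain
    Welch t-test with ``method="welch"``.  FDR is Benjamini-Hochberg
    across features.  Returns a DataFrame with columns feature,
    timepoint, logFC, p_value, fdr, direction.
    """
    if normalized is None:
        normalized = quantile_normalize(counts.values)
    tumor = counts.sample_subset(timepoint=timepoint, condition="tumor")
    normal = counts.sample_subset(timepoint=timepoint, condition="normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >=2 tumor and >=2 normal samples at {timepoint} "
            f"(got {len(tumor)} tumor, {len(normal)} normal)"
        )
    t_arr = normalized[tumor].to_numpy(dtype=float)
    n_arr = normalized[normal].to_numpy(dtype=float)
    logfc = np.log2(t_arr.mean(axis=1) + pseudocount) - np.log2(
        n_arr.mean(axis=1) + pseudocount
    )
    log_t, log_n = np.log2(t_arr + 1), np.log2(n_arr + 1)
    if method == "moderated":
        p = _moderated_ttest(log_t, log_n)
    elif method == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(log_t, log_n, axis=1, equal_var=False)
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    else:
        raise ValueError(f"unknown DE method {method!r}")
    fdr = bh_fdr(p)
    records = pd.DataFrame(
        {
            "feature": counts.feature_ids,
            "timepoint": timepoint,
            "logFC": logfc,
            "p_value": p,
            "fdr": fdr,
        }
    )
    records["direction"] = [
        _direction(lf, q, fdr_cutoff) for lf, q in zip(records["logFC"], records["fdr"])
    ]
    return records


def differential_expression_all(
    counts: CountMatrix,
    timepoints: Sequence[str] = TIMEPOINTS,
    **kwargs,
) -> pd.DataFrame:
    """Concatenate :func:`differential_expression` over time points."""
    normalized = kwargs.pop("normalized", None)
    if normalized is None:
        normalized = quantile_normalize(counts.values)
    tables = [
        differential_expression(counts, tp, normalized=normalized, **kwargs)
        for tp in timepoints
    ]
    return pd.concat(tables, ignore_index=True)
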