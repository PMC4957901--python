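"""Pseudo fold-changes, stage transitions and the 27-pattern alphabet.

Each feature's per-time-point log2 fold-change (tumor over normal) is
mapped to a signed pseudo fold-change phiFC, which is 2^logFC for
logFC >= 0 and -2^(-logFC) otherwise.  The transform is symmetric around
+/-1: a 2-fold induction gives +2 and a 2-fold repression gives -2, so
differences between consecutive time points (transitions) weigh up- and
down-regulation equally.  Transitions are discretized into '+', '0', '-'
by a mu +/- k*sigma band (k = 0.4 by default), yielding 3^3 = 27 possible
transition patterns over four time points, which are grouped into
monotone trends (non-decrease / non-increase), flat ("000") and mixed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASSES = ("+", "0", "-")
#: all 3^3 = 27 transition patterns over four time points
ALL_PATTERNS = tuple("".join(p) for p in itertools.product(CLASSES, repeat=3))

_trend_label_warned = False


@dataclass(frozen=True)
class DiscretizationParams:
    """Band parameters for transition discretization."""

    mu: float | np.ndarray
    sigma: float | np.ndarray
    k: float = 0.4
    scope: Literal["pooled", "per-transition"] = "pooled"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if np.any(np.asarray(self.sigma) < 0):
            raise ValueError("sigma must be non-negative")


def phi_fc(logfc):
    """Signed pseudo fold-change: 2^logFC if logFC >= 0, else -2^(-logFC).

    Note the jump at 0: phi_fc -> 1 as logFC -> 0+ and -> -1 as
    logFC -> 0-; values in (-1, 1) are never produced.
    """
    arr = np.asarray(logfc, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logFC must be finite")
    out = np.where(arr >= 0, 2.0**arr, -(2.0 ** (-arr)))
    if out.ndim == 0:
        return float(out)
    return out


def transitions(phifc: Sequence[float]) -> np.ndarray:
    """Differences of phiFC between consecutive time points."""
    arr = np.asarray(phifc, dtype=float)
    if arr.ndim == 1 and arr.size < 2 or arr.ndim == 2 and arr.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    return np.diff(arr, axis=-1)


def discretize(
    all_transitions,
    k: float = 0.4,
    scope: Literal["pooled", "per-transition"] = "pooled",
    ddof: int = 0,
) -> tuple[DiscretizationParams, np.ndarray]:
    """Discretize transitions into '+', '0', '-' by a mu +/- k*sigma band.

    '+' iff T > mu + k*sigma, '-' iff T < mu - k*sigma, '0' otherwise
    (the inequalities are strict, so boundary values and a degenerate
    sigma = 0 both map to '0').  With ``scope="pooled"`` (default) one mu
    and sigma are computed over the whole collection; with
    ``"per-transition"`` each transition index (column) gets its own band.
    ``ddof=0`` uses the population standard deviation.

    Returns the fitted band and the class array (same shape as the input).
    """
    arr = np.asarray(all_transitions, dtype=float)
    if arr.size == 0:
        raise ValueError("empty transition collection")
    if scope == "pooled":
        mu = float(arr.mean())
        sigma = float(arr.std(ddof=ddof))
    elif scope == "per-transition":
        if arr.ndim != 2:
            raise ValueError("per-transition scope needs a 2-D features x transitions array")
        mu = arr.mean(axis=0)
        sigma = arr.std(axis=0, ddof=ddof)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    params = DiscretizationParams(mu=mu, sigma=sigma, k=k, scope=scope)
    classes = classify(arr, params)
    return params, classes


def classify(values, params: DiscretizationParams) -> np.ndarray:
    """Apply a fitted discretization band to transition values."""
    arr = np.asarray(values, dtype=float)
    upper = params.mu + params.k * params.sigma
    lower = params.mu - params.k * params.sigma
    out = np.full(arr.shape, "0", dtype="<U1")
    out[arr > upper] = "+"
    out[arr < lower] = "-"
    return out


def classify_pattern(classes: Sequence[str]) -> str:
    """Concatenate three transition classes into one of the 27 patterns."""
    if len(classes) != 3:
        raise ValueError(f"expected 3 transition classes, got {len(classes)}")
    for c in classes:
        if c not in CLASSES:
            raise ValueError(f"invalid class {c!r}")
    return "".join(classes)


def _check_pattern(pattern: str) -> None:
    if any(c not in CLASSES for c in pattern):
        raise ValueError(f"invalid pattern {pattern!r}")


def trend_group(pattern: str) -> str:
    """Classify a pattern as non_decrease, non_increase, flat or mixed.

    non_decrease patterns use only {'0', '+'} and non_increase only
    {'0', '-'}; the all-zero pattern is its own "flat" group (a flat
    profile is neither trend), everything else is "mixed".
    """
    global _trend_label_warned
    _check_pattern(pattern)
    if not _trend_label_warned:
        logger.warning(
            "trend labels are bound to the math: non_decrease = only {0,+}, "
            "non_increase = only {0,-}"
        )
        _trend_label_warned = True
    chars = set(pattern)
    if chars == {"0"}:
        return "flat"
    if chars <= {"0", "+"}:
        return "non_decrease"
    if chars <= {"0", "-"}:
        return "non_increase"
    return "mixed"


def opposite_pattern(pattern: str) -> str:
    """Character-wise mirror of a pattern ('+' <-> '-', '0' fixed)."""
    _check_pattern(pattern)
    return pattern.translate(str.maketrans("+-", "-+"))


def build_profiles(
    logfc: pd.DataFrame,
    k: float = 0.4,
    scope: Literal["pooled", "per-transition"] = "pooled",
    ddof: int = 0,
) -> pd.DataFrame:
    """Build transition profiles from a features x time-points logFC table.

    The discretization band is fitted on this table's own transition
    population (so e.g. miRNAs and mRNAs each use their own mu, sigma).
    Returns a DataFrame indexed by feature with phiFC and transition
    columns, the pattern string and its trend group.
    """
    if logfc.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    phi = phi_fc(logfc.to_numpy())
    trans = transitions(phi)
    _, classes = discretize(trans, k=k, scope=scope, ddof=ddof)
    patterns = ["".join(row) for row in classes]
    out = pd.DataFrame(index=logfc.index)
    for i, tp in enumerate(logfc.columns):
        out[f"phifc_{tp}"] = phi[:, i]
    for i in range(trans.shape[1]):
        out[f"T{i + 1}"] = trans[:, i]
    out["pattern"] = patterns
    out["trend_group"] = [trend_group(p) for p in patterns]
    return out


def pattern_summary(profiles: pd.DataFrame, phifc_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-pattern feature counts and median phiFC trajectory."""
    if phifc_columns is None:
        phifc_columns = [c for c in profiles.columns if c.startswith("phifc_")]
    grouped = profiles.groupby("pattern")
    summary = grouped.size().to_frame("n_features")
    for col in phifc_columns:
        summary[f"median_{col}"] = grouped[col].median()
    return summary.reset_index()
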