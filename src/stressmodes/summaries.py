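"""Descriptive statistics downstream of mode classification.

Mode frequency tables, mode x log2FC-bin contingency analysis with standard
Pearson residuals, subset gene frequencies (omega), percent-increase
arithmetic, and silhouette scoring of labelled groupings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from stressmodes.pattern_classifier import ALL_LABELS, MODES, ModeAssignment

#: symmetric default log2FC bins for the contingency analysis
DEFAULT_BIN_EDGES = (-math.inf, -2.0, -1.0, 0.0, 1.0, 2.0, math.inf)


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, matching printed percentage style."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ModeFrequencyTable:
    """Counts and percentages of features per pattern mode."""

    counts: Dict[str, int]
    percentages: Dict[str, float]
    total: int
    denominator: str = "classified"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percentages[m] for m in self.counts],
            }
        )


def mode_frequencies(
    assignments: Iterable[ModeAssignment],
    include_na: bool = False,
) -> ModeFrequencyTable:
    """Tabulate mode counts and percentages.

    With ``include_na`` the non_assigned class joins both the table and the
    percentage denominator; otherwise percentages are of assigned (mode-
    classified) features only.  The denominator is reported alongside so a
    percentage is never quoted without its base.
    """
    labels = ALL_LABELS if include_na else MODES
    counts = {label: 0 for label in labels}
    for a in assignments:
        if a.mode in counts:
            counts[a.mode] += 1
    total = sum(counts.values())
    if total > 0:
        percentages = {m: 100.0 * c / total for m, c in counts.items()}
    else:
        percentages = {m: 0.0 for m in counts}
    return ModeFrequencyTable(
        counts=counts,
        percentages=percentages,
        total=total,
        denominator="classified+na" if include_na else "classified",
    )


@dataclass
class ContingencyResult:
    """Observed/expected matrices, standard Pearson residuals, chi2 and dof."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame
    chi2: float
    dof: int


def pearson_residuals(observed: pd.DataFrame | np.ndarray) -> ContingencyResult:
    """Independence analysis of a two-way count table.

    Expected counts are row_total x col_total / grand_total; residuals are
    the standard Pearson residuals (O - E)/sqrt(E).  Cells with E = 0 carry
    residual 0 and do not contribute to chi2; degrees of freedom count only
    rows and columns with a nonzero margin.
    """
    obs = pd.DataFrame(observed).astype(float)
    if (obs.to_numpy() < 0).any():
        raise ValueError("observed counts must be non-negative")
    o = obs.to_numpy()
    grand = o.sum()
    if grand == 0:
        exp = np.zeros_like(o)
    else:
        exp = np.outer(o.sum(axis=1), o.sum(axis=0)) / grand
    with np.errstate(divide="ignore", invalid="ignore"):
        res = np.where(exp > 0, (o - exp) / np.sqrt(np.where(exp > 0, exp, 1.0)), 0.0)
    chi2 = float(np.sum(res[exp > 0] ** 2))
    nonzero_rows = int(np.sum(o.sum(axis=1) > 0))
    nonzero_cols = int(np.sum(o.sum(axis=0) > 0))
    dof = max(nonzero_rows - 1, 0) * max(nonzero_cols - 1, 0)
    if dof == 0:
        chi2 = 0.0
    expected = pd.DataFrame(exp, index=obs.index, columns=obs.columns)
    residuals = pd.DataFrame(res, index=obs.index, columns=obs.columns)
    return ContingencyResult(obs, expected, residuals, chi2, dof)


def contingency_analysis(
    assignments: Sequence[ModeAssignment],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    include_na: bool = False,
) -> ContingencyResult:
    """Mode x log2FC-bin contingency table of the combined-stress response.

    Features are binned by their SWL log2FC into half-open intervals
    [e_i, e_{i+1}); values outside the outermost edges are excluded.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be >= 2 strictly increasing values")
    labels = ALL_LABELS if include_na else MODES
    bin_names = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    counts = np.zeros((len(labels), len(edges) - 1), dtype=float)
    row_of = {m: i for i, m in enumerate(labels)}
    for a in assignments:
        if a.mode not in row_of:
            continue
        j = int(np.searchsorted(edges, a.f_swl, side="right")) - 1
        if 0 <= j < len(edges) - 1:
            counts[row_of[a.mode], j] += 1
    observed = pd.DataFrame(counts, index=list(labels), columns=bin_names)
    return pearson_residuals(observed)


def pct_increase(n_combined: int, n_single: int, ndigits: int | None = 1) -> float:
    """Percent increase of a combined-stress count over a single-stress count.

    Returns (n_combined - n_single)/n_single x 100, half-up rounded to
    ``ndigits`` decimals (pass ``None`` for the raw value).
    """
    if n_single <= 0:
        raise ValueError("n_single must be positive")
    pct = (n_combined - n_single) / n_single * 100.0
    return pct if ndigits is None else round_half_up(pct, ndigits)


def subset_frequency(
    annotations: Mapping[str, str],
    subset: Iterable[str],
    symbol: str,
    ndigits: int | None = 2,
) -> float:
    """Frequency omega of a gene symbol within a feature subset, in percent."""
    subset = set(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    hits = sum(1 for fid in subset if annotations.get(fid) == symbol)
    omega = 100.0 * hits / len(subset)
    return omega if ndigits is None else round_half_up(omega, ndigits)


def silhouette_scores(
    points: np.ndarray | pd.DataFrame,
    labels: Sequence,
) -> tuple[np.ndarray, pd.Series]:
    """Euclidean silhouette coefficients per observation and per-group means.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean intra-group
    distance and b(i) the smallest mean distance to another group; scores
    lie in [-1, 1] and singleton groups score 0 by convention.  A score near
    +1 marks a group well separated from all others; near 0, a group sitting
    next to a neighbouring one.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise ValueError("points must be a 2-D observation x variable matrix")
    if np.isnan(x).any():
        raise ValueError("points contain missing values")
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels length must match number of observations")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups for silhouette scoring")
    scores = silhouette_samples(x, labels, metric="euclidean")
    means = pd.Series(scores).groupby(labels).mean()
    return scores, means
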