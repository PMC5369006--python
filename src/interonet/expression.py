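"""Age-resolved expression analysis: co-expression and trend enrichment.

Works on a genes x age-points abundance matrix (seven age points in the
default study design).  Provides pairwise Pearson co-expression at a
|r| >= 0.9 threshold, per-gene age trends (correlation with age, last/first
abundance ratio, and an up/down/none classification), and two one-sided
Fisher's exact tests: enrichment of co-expressed pairs within a pathway
gene set, and enrichment of up-regulated transcripts within a network
gene set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import FisherResult

__all__ = [
    "ExpressionMatrix",
    "pearson_correlation",
    "coexpressed_pairs",
    "coexpression_enrichment",
    "age_trend_table",
    "upregulation_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x age-points abundance table.

    ``values`` has one row per gene (unique index) and one column per age
    point; all abundances must be strictly positive.  ``age_points``
    defaults to the ordinal indices 1..T.
    """

    values: pd.DataFrame
    age_points: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated gene rows: {list(dups)[:5]}")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("abundances must be strictly positive")
        if self.age_points is None:
            self.age_points = np.arange(1, self.values.shape[1] + 1,
                                        dtype=float)
        else:
            self.age_points = np.asarray(self.age_points, dtype=float)
            if len(self.age_points) != self.values.shape[1]:
                raise ValueError("age_points length does not match the "
                                 "number of columns")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_age_points(self) -> int:
        return self.values.shape[1]

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def constant_genes(self) -> FrozenSet[str]:
        """Genes with zero variance (Pearson correlation undefined)."""
        v = self.values.to_numpy(dtype=float)
        const = v.std(axis=1) == 0.0
        return frozenset(self.values.index[const])


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Standard product-moment correlation of two equal-length profiles.

    Raises ``ValueError("undefined")`` for a constant profile; the caller
    decides whether to exclude the gene or propagate the error.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("profiles must have equal length")
    if xa.size < 3:
        raise ValueError("profiles must have length >= 3")
    if xa.std() == 0.0 or ya.std() == 0.0:
        raise ValueError("undefined: constant profile")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return max(-1.0, min(1.0, r))


def _standardised(values: np.ndarray) -> np.ndarray:
    """Rows scaled so that z_i . z_j equals the Pearson correlation."""
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    return centred / norms


def coexpressed_pairs(
    expr: ExpressionMatrix,
    genes: Optional[Iterable[str]] = None,
    tau: float = 0.9,
) -> Tuple[Set[Tuple[str, str]], Set[Tuple[str, str]]]:
    """All unordered gene pairs with Pearson r >= tau (positive set) or
    r <= -tau (opposite set).

    Restricted to ``genes`` when given.  Genes with constant profiles have
    an undefined correlation; they are excluded and logged.
    """
    if genes is None:
        subset = list(expr.genes)
    else:
        genes = set(genes)
        missing = genes - set(expr.genes)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        subset = [g for g in expr.genes if g in genes]
    const = expr.constant_genes()
    usable = [g for g in subset if g not in const]
    dropped = len(subset) - len(usable)
    if dropped:
        logger.info("excluded %d constant-profile genes from the pair "
                    "universe", dropped)
    if len(usable) < 2:
        warnings.warn("fewer than 2 usable genes: empty pair sets")
        return set(), set()
    v = expr.values.loc[usable].to_numpy(dtype=float)
    z = _standardised(v)
    corr = z @ z.T
    pos: Set[Tuple[str, str]] = set()
    neg: Set[Tuple[str, str]] = set()
    iu, ju = np.triu_indices(len(usable), k=1)
    rvals = corr[iu, ju]
    for i, j in zip(iu[rvals >= tau], ju[rvals >= tau]):
        pos.add((usable[i], usable[j]) if usable[i] <= usable[j]
                else (usable[j], usable[i]))
    for i, j in zip(iu[rvals <= -tau], ju[rvals <= -tau]):
        neg.add((usable[i], usable[j]) if usable[i] <= usable[j]
                else (usable[j], usable[i]))
    return pos, neg


def _pair_counts(
    z: np.ndarray, tau: float, direction: str, chunk: int = 512
) -> int:
    """Count unordered row pairs with r >= tau (or <= -tau), chunked."""
    n = z.shape[0]
    total = 0
    for start in range(0, n, chunk):
        block = z[start:start + chunk]
        corr = block @ z.T  # (chunk, n)
        if direction == "positive":
            mask = corr >= tau
        else:
            mask = corr <= -tau
        # keep strictly-upper-triangle entries only
        rows = np.arange(start, start + block.shape[0])[:, None]
        cols = np.arange(n)[None, :]
        mask &= cols > rows
        total += int(mask.sum())
    return total


def coexpression_enrichment(
    expr: ExpressionMatrix,
    pathway_genes: Iterable[str],
    tau: float = 0.9,
    direction: str = "positive",
) -> FisherResult:
    """Is co-expression enriched among pathway gene pairs?

    The universe is the set of all unordered pairs of usable
    (non-constant) genes in the matrix.  The 2x2 table crosses
    {pair within pathway} x {co-expressed in the given direction at tau};
    the one-sided (enrichment) Fisher p and the hypergeometric
    expectation for the pathway/co-expressed cell are reported.
    """
    if direction not in ("positive", "opposite"):
        raise ValueError(f"direction must be 'positive' or 'opposite', "
                         f"got {direction!r}")
    pathway = set(pathway_genes)
    missing = pathway - set(expr.genes)
    if missing:
        raise KeyError(f"pathway genes not in matrix: {sorted(missing)[:5]}")
    const = expr.constant_genes()
    usable = [g for g in expr.genes if g not in const]
    pathway_usable = [g for g in usable if g in pathway]
    if len(pathway_usable) < 2:
        raise ValueError("pathway must contain at least 2 usable genes")

    n_total = len(usable)
    total_pairs = n_total * (n_total - 1) // 2
    pathway_pairs = len(pathway_usable) * (len(pathway_usable) - 1) // 2

    z = _standardised(expr.values.loc[usable].to_numpy(dtype=float))
    coexpr_total = _pair_counts(z, tau, direction)
    pos_of = {g: i for i, g in enumerate(usable)}
    idx = [pos_of[g] for g in pathway_usable]
    coexpr_in_pathway = _pair_counts(z[idx], tau, direction)

    a = coexpr_in_pathway
    b = pathway_pairs - a
    c = coexpr_total - a
    d = total_pairs - pathway_pairs - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    expected = pathway_pairs * coexpr_total / total_pairs
    return FisherResult(table=((a, b), (c, d)), odds_ratio=float(odds),
                        p_value=float(p), expected=expected)


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along axis 1, partial windows at the edges."""
    if window <= 1:
        return v.copy()
    n_cols = v.shape[1]
    half = (window - 1) // 2
    out = np.empty_like(v, dtype=float)
    for j in range(n_cols):
        lo = max(0, j - half)
        hi = min(n_cols, j + window - half)
        out[:, j] = v[:, lo:hi].mean(axis=1)
    return out


@dataclass
class TrendClassifier:
    """Configurable stand-in for a "continuously up/down-regulated" call.

    A gene is classified *up* when its correlation with age is at least
    ``tau_trend`` and every consecutive step of its smoothed profile
    (centred moving average, ``smooth_window`` points) is non-decreasing;
    *down* symmetrically; otherwise *none*.  Constant genes are *none*.
    Externally derived up/down gene lists can be supplied to the
    enrichment test directly, bypassing this classifier.
    """

    tau_trend: float = 0.7
    smooth_window: int = 3
    tol: float = field(default=1e-12)

    def classify(self, expr: ExpressionMatrix) -> pd.DataFrame:
        v = expr.values.to_numpy(dtype=float)
        age = expr.age_points
        sd = v.std(axis=1)
        const = sd == 0.0

        vc = v - v.mean(axis=1, keepdims=True)
        ac = age - age.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            pcc = (vc @ ac) / (np.linalg.norm(vc, axis=1)
                               * np.linalg.norm(ac))
        pcc[const] = np.nan

        smoothed = _moving_average(v, self.smooth_window)
        steps = np.diff(smoothed, axis=1)
        mono_up = (steps >= -self.tol).all(axis=1)
        mono_down = (steps <= self.tol).all(axis=1)

        trend = np.full(v.shape[0], "none", dtype=object)
        up = ~const & (pcc >= self.tau_trend) & mono_up
        down = ~const & (pcc <= -self.tau_trend) & mono_down
        trend[up] = "up"
        trend[down] = "down"

        ratio = v[:, -1] / v[:, 0]
        return pd.DataFrame(
            {"age_pcc": pcc, "ratio": ratio, "trend": trend},
            index=expr.genes,
        )


def age_trend_table(
    expr: ExpressionMatrix,
    classifier: Optional[TrendClassifier] = None,
) -> pd.DataFrame:
    """Per-gene age trend statistics.

    Columns: ``age_pcc`` (Pearson correlation of the profile with the age
    vector; NaN for constant genes), ``ratio`` (last-day abundance divided
    by first-day abundance), and ``trend`` in {up, down, none}.
    """
    classifier = classifier or TrendClassifier()
    return classifier.classify(expr)


def upregulation_enrichment(
    expr: ExpressionMatrix,
    network_genes: Iterable[str],
    trend_table: Optional[pd.DataFrame] = None,
    up_genes: Optional[Iterable[str]] = None,
    classifier: Optional[TrendClassifier] = None,
) -> FisherResult:
    """Are up-regulated transcripts enriched among network genes?

    The universe is all profiles of the matrix.  The 2x2 table crosses
    {gene in network} x {classified up-regulated}; a one-sided
    (enrichment) Fisher p and the expected up-count within the network
    are reported.  Up-calls come from ``up_genes`` when supplied,
    otherwise from ``trend_table`` or the default :class:`TrendClassifier`.
    """
    network = set(network_genes)
    missing = network - set(expr.genes)
    if missing:
        raise KeyError(f"network genes not in matrix: {sorted(missing)[:5]}")
    if up_genes is not None:
        up = set(up_genes)
    else:
        if trend_table is None:
            trend_table = age_trend_table(expr, classifier)
        up = set(trend_table.index[trend_table["trend"] == "up"])

    n_total = expr.n_genes
    n_net = len(network)
    k_up = len(up)
    a = len(network & up)
    b = n_net - a
    c = k_up - a
    d = n_total - n_net - c
    expected = n_net * k_up / n_total
    if k_up == 0:
        warnings.warn("no up-regulated genes in the matrix: degenerate "
                      "contingency table")
        return FisherResult(table=((a, b), (c, d)), odds_ratio=float("nan"),
                            p_value=1.0, expected=expected, degenerate=True)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return FisherResult(table=((a, b), (c, d)), odds_ratio=float(odds),
                        p_value=float(p), expected=expected)
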