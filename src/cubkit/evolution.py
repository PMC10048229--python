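"""Inferential layer: ENC-GC3s expected curve, neutrality regression,
group summaries and RSCU clustering.

The ENC-GC3s plot compares observed ENC values to Wright's null expectation
under mutation-only codon usage,

    ENC_expected(s) = 2 + s + 29 / (s^2 + (1 - s)^2),

with s the synonymous third-position GC fraction. Points on or near the
curve are consistent with mutation-driven usage; points far below indicate
selection. The neutrality plot regresses GC12 on GC3 across genes: a slope
near 1 means all positions track the same (mutational) pressure, a slope
near 0 means first/second positions are constrained while third positions
drift, i.e. selection dominates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from skbio import TreeNode

logger = logging.getLogger(__name__)


def expected_enc_curve(s):
    """Wright's expected ENC under mutation-only usage at GC3s == s.

    Accepts a scalar or array in [0, 1]; vectorized.
    """
    arr = np.asarray(s, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("GC3s must lie in [0, 1]")
    out = 2.0 + arr + 29.0 / (arr ** 2 + (1.0 - arr) ** 2)
    return float(out) if np.isscalar(s) or arr.ndim == 0 else out


def enc_gc3s_points(indices: pd.DataFrame) -> pd.DataFrame:
    """Attach the expected ENC and the deviation (expected - observed).

    ``indices`` needs columns ``gc3s`` and ``enc``; label columns pass
    through. Empty input yields an empty frame with the new columns.
    """
    out = indices.copy()
    if out.empty:
        out["enc_expected"] = pd.Series(dtype=float)
        out["deviation"] = pd.Series(dtype=float)
        return out
    out["enc_expected"] = expected_enc_curve(out["gc3s"].to_numpy())
    out["deviation"] = out["enc_expected"] - out["enc"]
    return out


def near_curve_fraction(points: pd.DataFrame, band: float = 2.0,
                        by: Optional[Sequence[str]] = None):
    """Fraction of points with |deviation| <= band, overall or per group."""
    near = points["deviation"].abs() <= band
    if by is None:
        return float(near.mean())
    return near.groupby([points[c] for c in by]).mean()


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n_points: int
    group: Union[str, None] = None


def neutrality_fit(gc3, gc12, group=None) -> NeutralityFit:
    """OLS fit of GC12 on GC3 with Pearson r and its two-sided p-value."""
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if x.shape != y.shape:
        raise ValueError("gc3 and gc12 must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"neutrality fit needs >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("neutrality fit undefined: GC3 is constant")
    if np.ptp(y) == 0:
        # flat response: slope and correlation are exactly zero
        return NeutralityFit(slope=0.0, intercept=float(y[0]), r=0.0,
                             p_value=1.0, n_points=n, group=group)
    fit = stats.linregress(x, y)
    return NeutralityFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r=float(fit.rvalue), p_value=float(fit.pvalue),
                         n_points=n, group=group)


def neutrality_table(fits: Sequence[NeutralityFit]) -> pd.DataFrame:
    """Tabulate fits; adds a Benjamini-Hochberg column next to the raw p."""
    df = pd.DataFrame([{"group": f.group, "slope": f.slope,
                        "intercept": f.intercept, "r": f.r,
                        "p_value": f.p_value, "n": f.n_points}
                       for f in fits])
    if not df.empty:
        df["p_bh"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df


def group_summary(values: pd.DataFrame, statistic: str,
                  by: Sequence[str] = ("gene", "family")) -> pd.DataFrame:
    """Mean +- sample SD (n-1 denominator) of one column per group.

    Single-observation cells get sd = 0 and are flagged.
    """
    if values.empty:
        raise ValueError("group_summary needs a non-empty table")
    grouped = values.groupby(list(by))[statistic]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    out["sd"] = out["sd"].fillna(0.0)
    out["single_observation"] = out["n"] == 1
    return out.reset_index()


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    matrix: pd.DataFrame

    def row_newick(self) -> str:
        return _linkage_to_newick(self.row_linkage, self.matrix.index.tolist())

    def col_newick(self) -> str:
        return _linkage_to_newick(self.col_linkage, self.matrix.columns.tolist())


def _linkage_to_newick(linkage: np.ndarray, labels) -> str:
    # the matrix was canonicalized before linkage, so the original
    # observation order skbio expects is the sorted label order
    original = sorted(labels)
    tree = TreeNode.from_linkage_matrix(np.asarray(linkage),
                                        [str(x) for x in original])
    return str(tree).strip()


def rscu_cluster(matrix: pd.DataFrame, metric: str = "euclidean",
                 method: str = "average") -> ClusterResult:
    """Agglomerative clustering of an RSCU matrix on rows and columns.

    Rows and columns are first canonicalized by sorted label so that the
    result is invariant to input ordering (scipy breaks distance ties by
    observation index). Undefined entries are imputed as 0 with a logged
    note. Returns the linkage trees, leaf orders and the reordered matrix.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    m = matrix.sort_index(axis=0).sort_index(axis=1)
    n_missing = int(m.isna().sum().sum())
    if n_missing:
        logger.info("imputing %d undefined RSCU entries as 0 for clustering",
                    n_missing)
        m = m.fillna(0.0)
    row_linkage = hierarchy.linkage(m.to_numpy(), method=method, metric=metric)
    col_linkage = hierarchy.linkage(m.to_numpy().T, method=method, metric=metric)
    row_order = [m.index[i] for i in hierarchy.leaves_list(row_linkage)]
    col_order = [m.columns[i] for i in hierarchy.leaves_list(col_linkage)]
    reordered = m.loc[row_order, col_order]
    return ClusterResult(row_linkage=row_linkage, col_linkage=col_linkage,
                         row_order=row_order, col_order=col_order,
                         matrix=reordered)
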