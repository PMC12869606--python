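"""Transcription-normalized occupancy and factor-similarity statistics.

Raw ChIP-nexus binding at a promoter scales with its transcriptional
activity; dividing the binding signal by the promoter's CAGE expression score
yields an occupancy per transcript that can be compared between promoter
types (Wilcoxon rank-sum).  Factor similarity is measured as pairwise Pearson
correlation of log2(signal+1) binding levels across promoters, converted to
1-r distances and clustered with Ward's linkage.  A condition contrast
(control vs triptolide) on the correlation between a factor and TBP signal in
an upstream vs downstream window exposes which factors track the TFIID
loading state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "FactorSimilarity",
    "normalize_by_cage",
    "compare_types",
    "factor_similarity",
    "correlation_delta",
]


def normalize_by_cage(
    binding: pd.Series, cage_score: pd.Series
) -> pd.Series:
    """Binding per promoter divided by its CAGE expression score.

    Promoters with non-positive or missing CAGE score are excluded (with a
    warning), never returned as NaN/inf.
    """
    common = binding.index.intersection(cage_score.index)
    b = binding.loc[common]
    c = cage_score.loc[common]
    ok = c > 0
    n_dropped = int((~ok).sum()) + (len(binding) - len(common))
    if n_dropped:
        warnings.warn(
            f"normalize_by_cage: excluded {n_dropped} promoters with no "
            "positive CAGE score",
            stacklevel=2,
        )
    return (b[ok] / c[ok]).rename("normalized")


def compare_types(
    values_a: np.ndarray | pd.Series, values_b: np.ndarray | pd.Series
) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two promoter groups.

    Returns (U statistic, p-value, median difference a-b).  Degenerate input
    where every value is tied yields p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_types needs >= 2 values per group")
    med_diff = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("compare_types: all values tied; p = 1", stacklevel=2)
        return float(len(a) * len(b) / 2), 1.0, med_diff
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue), med_diff


@dataclass
class FactorSimilarity:
    correlation: pd.DataFrame  # factor x factor Pearson r on log2(x+1)
    distance: pd.DataFrame  # 1 - r
    linkage: np.ndarray  # scipy linkage matrix, Ward's D heights
    dropped: list[str]


def _ward_d_linkage(condensed: np.ndarray) -> np.ndarray:
    """Ward linkage applied to the given dissimilarities directly.

    scipy's "ward" treats its input as Euclidean distances (squaring them
    internally, the ward.D2 convention); feeding it sqrt(d) and squaring the
    merge heights recovers the classic Ward update on d itself (the hclust
    ward.D convention).
    """
    Z = linkage(np.sqrt(condensed), method="ward")
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2
    return Z


def factor_similarity(
    totals: pd.DataFrame, promoter_ids: list[str] | None = None
) -> FactorSimilarity:
    """Pairwise factor similarity from per-promoter binding totals.

    ``totals`` is a promoters x factors frame of binding signal (e.g. summed
    over [-50, +50]).  Signals are log2(x+1) transformed, correlated across
    promoters (Pearson), converted to 1-r distances and Ward-linked.  Factors
    with constant signal have undefined correlation and are dropped with a
    warning.  Requires >= 2 surviving factors and >= 3 promoters.
    """
    df = totals.loc[promoter_ids] if promoter_ids is not None else totals
    if len(df) < 3:
        raise ValueError("factor_similarity requires >= 3 promoters")
    logged = np.log2(df.astype(float) + 1.0)
    dropped = [c for c in logged.columns if logged[c].nunique() <= 1]
    if dropped:
        warnings.warn(
            f"factor_similarity: dropped constant factors {dropped}", stacklevel=2
        )
        logged = logged.drop(columns=dropped)
    if logged.shape[1] < 2:
        raise ValueError("factor_similarity requires >= 2 non-constant factors")
    corr = logged.corr(method="pearson")
    dist = 1.0 - corr
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = _ward_d_linkage(condensed)
    return FactorSimilarity(correlation=corr, distance=dist, linkage=Z, dropped=dropped)


def correlation_delta(
    tbp_windows: dict[str, dict[str, pd.Series]],
    taf_totals: dict[str, pd.DataFrame],
    control: str = "control",
    treated: str = "triptolide",
) -> pd.DataFrame:
    """Condition contrast of factor-vs-TBP window correlations.

    ``tbp_windows[condition][window]`` holds per-promoter TBP signal summed in
    the "upstream" or "downstream" window for each condition;
    ``taf_totals[condition]`` is a promoters x factors frame of binding
    totals.  For each factor and window, the Pearson correlation with TBP is
    computed per condition and the delta ``PCC(control) - PCC(treated)`` is
    reported.  Promoter sets must match across conditions.
    """
    for cond in (control, treated):
        if cond not in tbp_windows or cond not in taf_totals:
            raise ValueError(f"missing condition {cond!r}")
    idx = taf_totals[control].index
    if not idx.equals(taf_totals[treated].index):
        raise ValueError("promoter sets differ between conditions")
    rows = []
    for window in tbp_windows[control]:
        tbp_c = tbp_windows[control][window].loc[idx]
        tbp_t = tbp_windows[treated][window].loc[idx]
        for fac in taf_totals[control].columns:
            r_c = float(np.corrcoef(tbp_c, taf_totals[control][fac])[0, 1])
            r_t = float(np.corrcoef(tbp_t, taf_totals[treated][fac])[0, 1])
            rows.append(
                {
                    "factor": fac,
                    "window": window,
                    "pcc_control": r_c,
                    "pcc_treated": r_t,
                    "delta": r_c - r_t,
                }
            )
    return pd.DataFrame(rows)
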