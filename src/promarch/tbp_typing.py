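"""De novo promoter typing from per-promoter TBP profile shape.

TBP's strand-specific binding profile differs by promoter class (sharp -18
footprint at TATA promoters, downstream +32-dominant signal at DPR promoters,
diffuse or low signal at TCT/housekeeping promoters).  Promoters are typed de
novo by (1) keeping the top 90% of narrow promoters by total TBP signal in an
81 bp TSS-centered window, (2) rank-transforming each promoter's profile so
only its shape matters, (3) k-means clustering (k=4, 100 restarts, 30
iterations) and (4) naming clusters by their core-element enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .signal_io import ProfileMatrix, window_signal

__all__ = [
    "ClusterModel",
    "select_top_signal",
    "profile_feature_matrix",
    "rank_transform",
    "kmeans_profiles",
    "label_clusters",
]

ELEMENT_FAMILY = {
    "TATA": "TATA",
    "MTE": "DPR",
    "DPE": "DPR",
    "PB": "DPR",
    "TCT": "TCT/HK",
    "DRE": "TCT/HK",
    "Ohler1": "TCT/HK",
    "Ohler6": "TCT/HK",
    "Ohler7": "TCT/HK",
}


@dataclass
class ClusterModel:
    k: int
    restarts: int
    max_iter: int
    seed: int
    labels: pd.Series = field(default=None)  # promoter -> cluster (1..k)
    centroids: np.ndarray = field(default=None)
    inertia: float = 0.0  # best total within-cluster sum of squares


def select_top_signal(
    profile: ProfileMatrix,
    window: tuple[int, int] = (-40, 40),
    keep_frac: float = 0.9,
) -> list[str]:
    """Promoter ids in the top ``keep_frac`` by total signal in ``window``.

    Both strands are summed.  The signal threshold is the value held by the
    last promoter inside the kept fraction; ties at the threshold are all
    kept, so an all-equal input is returned whole.
    """
    if not profile.promoter_ids:
        raise ValueError("select_top_signal requires at least one promoter")
    if not 0 < keep_frac <= 1:
        raise ValueError("keep_frac must be in (0, 1]")
    totals = window_signal(profile, window, mode="sum", strands="both")
    n_keep = int(np.ceil(keep_frac * len(totals)))
    order = np.argsort(-totals, kind="stable")
    threshold = totals[order[n_keep - 1]]
    keep = totals >= threshold
    return [pid for pid, k in zip(profile.promoter_ids, keep) if k]


def profile_feature_matrix(
    profile: ProfileMatrix,
    window: tuple[int, int] = (-40, 40),
    promoter_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Promoters x (positions over both strands) feature matrix for clustering.

    Columns are sense positions followed by antisense positions over the
    inclusive window.
    """
    i0, i1 = profile.offset_index(window[0]), profile.offset_index(window[1])
    cols = [f"sense_{o}" for o in profile.offsets[i0 : i1 + 1]] + [
        f"anti_{o}" for o in profile.offsets[i0 : i1 + 1]
    ]
    X = np.hstack([profile.sense[:, i0 : i1 + 1], profile.antisense[:, i0 : i1 + 1]])
    df = pd.DataFrame(X, index=profile.promoter_ids, columns=cols)
    if promoter_ids is not None:
        df = df.loc[promoter_ids]
    return df


def rank_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise rank transform onto (0, 1].

    Values in each row are ranked smallest-to-largest (average ranks for
    ties) and divided by the number of columns, so each row becomes a shape
    descriptor invariant to any strictly monotone rescaling of its signal.
    """
    ranks = np.apply_along_axis(rankdata, 1, matrix.to_numpy(dtype=float))
    return pd.DataFrame(
        ranks / matrix.shape[1], index=matrix.index, columns=matrix.columns
    )


def kmeans_profiles(
    matrix: pd.DataFrame,
    k: int = 4,
    restarts: int = 100,
    max_iter: int = 30,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-restarts Lloyd k-means on the rank-transformed profiles.

    ``restarts`` random initializations are run for at most ``max_iter``
    Lloyd iterations each and the solution with the smallest total
    within-cluster sum of squares is kept.  Cluster labels are 1-based.
    """
    if k > len(matrix):
        raise ValueError("k exceeds the number of promoters")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=seed,
    ).fit(matrix.to_numpy(dtype=float))
    return ClusterModel(
        k=k,
        restarts=restarts,
        max_iter=max_iter,
        seed=seed,
        labels=pd.Series(km.labels_ + 1, index=matrix.index, name="cluster"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def label_clusters(
    model: ClusterModel,
    enrichment: pd.DataFrame,
    mean_amplitude: pd.Series | None = None,
    q_max: float = 0.05,
) -> dict[int, str]:
    """Name each cluster by its most significantly enriched element family.

    ``enrichment`` is the table from
    :func:`promarch.elements.element_enrichment` computed on the cluster
    assignment.  A cluster takes the family (TATA, DPR or TCT/HK) of its
    lowest-q enriched element with ratio > 1 and q < ``q_max``; clusters with
    no significant enrichment are "unresolved".  When two or more clusters
    resolve to TCT/HK they are told apart by ``mean_amplitude`` (mean raw TBP
    signal per cluster): the stronger is "TCT/HK-diffuse", the weaker
    "TCT/HK-low".
    """
    names: dict[int, str] = {}
    for cl in sorted(model.labels.unique()):
        sub = enrichment[
            (enrichment["cluster"] == cl)
            & (enrichment["ratio"] > 1)
            & (enrichment["q"] < q_max)
            & enrichment["element"].isin(ELEMENT_FAMILY)
        ]
        if sub.empty:
            names[cl] = "unresolved"
        else:
            best = sub.sort_values(["q", "element"]).iloc[0]
            names[cl] = ELEMENT_FAMILY[best["element"]]
    tct_hk = [cl for cl, n in names.items() if n == "TCT/HK"]
    if len(tct_hk) >= 2 and mean_amplitude is not None:
        ordered = sorted(tct_hk, key=lambda cl: -mean_amplitude.loc[cl])
        names[ordered[0]] = "TCT/HK-diffuse"
        for cl in ordered[1:]:
            names[cl] = "TCT/HK-low"
    return names
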