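"""Footprint-midpoint geometry and factor-module grouping.

A ChIP-nexus footprint is a pair of stop-base peaks: one on the sense strand
just upstream of the protein-DNA crosslink and one on the antisense strand
just downstream.  The crosslink point is localized by the midpoint between the
sense-strand peak and its nearest downstream antisense-strand peak.  At
promoters, midpoints of the general machinery fall into six canonical regions
(-150/-50 diffuse, -30, -18/-14, +10, +19, +32 relative to the TSS), and PCA
over the normalized average profiles groups factors into structural modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "FootprintCall",
    "RegionTable",
    "ModulePca",
    "find_peaks",
    "pair_and_midpoint",
    "assign_region",
    "minmax_normalize",
    "pca_modules",
]


@dataclass
class FootprintCall:
    factor: str
    sense_peak_offset: int
    antisense_peak_offset: int
    midpoint: int
    height: float
    region_label: str = ""

    def __post_init__(self) -> None:
        if self.antisense_peak_offset <= self.sense_peak_offset:
            raise ValueError("antisense peak must lie downstream of sense peak")
        if not self.sense_peak_offset <= self.midpoint <= self.antisense_peak_offset:
            raise ValueError("midpoint must lie between the paired peaks")


@dataclass
class RegionTable:
    """The six canonical promoter footprint regions (TSS-relative bp).

    Interval regions match midpoints by containment; point regions by distance
    up to ``tol``; among multiple matches the nearest region wins.
    """

    regions: tuple[tuple[str, tuple[int, int] | int], ...] = (
        ("R1", (-150, -50)),
        ("R2", -30),
        ("R3", (-18, -14)),
        ("R4", 10),
        ("R5", 19),
        ("R6", 32),
    )
    tol: int = 5


def _boxcar(x: np.ndarray, halfwidth: int) -> np.ndarray:
    if halfwidth <= 0:
        return x.astype(float)
    w = 2 * halfwidth + 1
    kernel = np.ones(w) / w
    padded = np.pad(x.astype(float), halfwidth, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def find_peaks(
    profile: np.ndarray,
    offsets: np.ndarray,
    min_height_frac: float = 0.2,
    smooth_halfwidth: int = 1,
) -> list[tuple[int, float]]:
    """Local maxima of a smoothed average strand profile.

    The profile is boxcar-smoothed, candidate plateaus are maximal runs of
    equal smoothed values strictly greater than both flanking values (edges
    count as lower), and the reported position is the raw-profile argmax
    inside the plateau extended by the smoothing halfwidth (leftmost on raw
    ties), so the position of a sharp spike survives smoothing.  Peaks below
    ``min_height_frac`` times the smoothed window maximum are discarded, and
    candidates resolving to the same position are merged.  Returns
    (offset, raw_height) pairs; an all-zero profile yields an empty list.
    """
    x = np.asarray(profile, dtype=float)
    if len(x) != len(offsets):
        raise ValueError("profile and offsets lengths differ")
    if not np.any(x > 0):
        return []
    s = _boxcar(x, smooth_halfwidth)
    threshold = min_height_frac * s.max()
    peaks: list[tuple[int, float]] = []
    n = len(s)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        left_lower = i == 0 or s[i - 1] < s[i]
        right_lower = j == n - 1 or s[j + 1] < s[i]
        # whole-array plateau is no peak
        if left_lower and right_lower and not (i == 0 and j == n - 1):
            if s[i] >= threshold and s[i] > 0:
                lo = max(0, i - smooth_halfwidth)
                hi = min(n - 1, j + smooth_halfwidth)
                seg = x[lo : hi + 1]
                k = lo + int(np.argmax(seg))
                peaks.append((int(offsets[k]), float(x[k])))
        i = j + 1
    seen: dict[int, float] = {}
    for off, h in peaks:
        seen[off] = max(h, seen.get(off, 0.0))
    return sorted(seen.items())


def pair_and_midpoint(
    sense_peaks: list[tuple[int, float]],
    antisense_peaks: list[tuple[int, float]],
    max_pair_dist: int = 25,
    factor: str = "",
) -> list[FootprintCall]:
    """Pair each sense peak with its nearest strictly-downstream antisense peak.

    Pairs farther apart than ``max_pair_dist`` bp are not formed; unpaired
    peaks are dropped.  The midpoint is the integer part of the arithmetic
    mean of the two peak offsets (rounded toward zero, so mirrored profiles
    give exactly negated midpoints); the footprint height is the smaller of
    the two peak heights.
    """
    calls = []
    for s_off, s_h in sense_peaks:
        candidates = [
            (a_off, a_h)
            for a_off, a_h in antisense_peaks
            if a_off > s_off and a_off - s_off <= max_pair_dist
        ]
        if not candidates:
            continue
        a_off, a_h = min(candidates, key=lambda t: t[0] - s_off)
        mid = int((s_off + a_off) / 2)  # truncation toward zero
        calls.append(
            FootprintCall(
                factor=factor,
                sense_peak_offset=s_off,
                antisense_peak_offset=a_off,
                midpoint=mid,
                height=min(s_h, a_h),
            )
        )
    return calls


def assign_region(midpoint: int, regions: RegionTable | None = None) -> str:
    """Assign a footprint midpoint to one of the canonical regions.

    Returns the region name or "unassigned".  Interval regions match by
    containment (distance 0 inside); point regions within ``tol`` bp; the
    nearest matching region wins, ties going to the earlier (more upstream)
    region.
    """
    regions = regions or RegionTable()
    best_name, best_dist = "unassigned", None
    for name, ref in regions.regions:
        if isinstance(ref, tuple):
            lo, hi = ref
            if lo <= midpoint <= hi:
                dist = 0
            else:
                continue
        else:
            dist = abs(midpoint - ref)
            if dist > regions.tol:
                continue
        if best_dist is None or dist < best_dist:
            best_name, best_dist = name, dist
    return best_name


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Affine map of a vector onto [0, 1]; constant vectors are an error."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant vector")
    return (x - lo) / (hi - lo)


@dataclass
class ModulePca:
    coordinates: pd.DataFrame  # factors x PCs
    explained_variance_ratio: np.ndarray
    modules: pd.Series = field(default=None)  # factor -> module id


def pca_modules(
    factor_profiles: dict[str, np.ndarray],
    n_modules: int = 4,
    n_components: int = 2,
    seed: int = 0,
) -> ModulePca:
    """Group factors into modules by PCA of their average profiles.

    Each factor's concatenated sense+antisense average profile is min-max
    normalized, the profile matrix is centered (not scaled) and decomposed by
    PCA, and k-means (k = ``n_modules``) on the first ``n_components``
    principal coordinates assigns module membership.
    """
    factors = list(factor_profiles)
    if len(factors) < 2:
        raise ValueError("pca_modules requires at least 2 factors")
    X = np.vstack([minmax_normalize(factor_profiles[f]) for f in factors])
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        raise ValueError("more components requested than factors support")
    pca = PCA(n_components=max_comp)
    coords = pca.fit_transform(X)  # sklearn centers, does not scale
    coord_df = pd.DataFrame(
        coords, index=factors,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    km = KMeans(
        n_clusters=n_modules, n_init=50, random_state=seed, algorithm="lloyd"
    ).fit(coords[:, :n_components])
    return ModulePca(
        coordinates=coord_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        modules=pd.Series(km.labels_, index=factors, name="module"),
    )
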