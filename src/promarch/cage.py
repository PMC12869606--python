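"""CAGE tag normalization and TSS clustering.

CAGE (cap analysis of gene expression) counts capped 5' ends per genomic
position (CTSS records: contig, 1-based position, strand, tag count).  The
analysis here mirrors the standard tag-cluster workflow: power-law
normalization of tag counts onto a common reference distribution (tags per
million, TPM), per-sample distance clustering of CTSSs, interquantile boundary
calling, cross-sample consensus aggregation, dominant-TSS calling, and
selection of active promoters with narrow initiation windows.

The power-law normalization maps each sample's reverse-cumulative count
distribution onto a reference law ``r(x) = k * x**(-alpha)`` with alpha = 1.19
and total tag count T = 1e6, fitted by ordinary least squares on log-log
scale over counts in [3, 40000].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import zeta

from .signal_io import PromoterRecord

__all__ = [
    "PowerLawParams",
    "TssCluster",
    "read_ctss",
    "write_ctss",
    "powerlaw_normalize",
    "cluster_ctss",
    "interquantile_bounds",
    "aggregate_clusters",
    "dominant_tss",
    "select_promoters",
]

CTSS_COLUMNS = ["contig", "pos", "strand", "count"]


@dataclass
class PowerLawParams:
    """Reference power law for tag-count normalization."""

    alpha_ref: float = 1.19
    t_ref: float = 1e6
    fit_min: int = 3
    fit_max: int = 40_000

    def __post_init__(self) -> None:
        if self.alpha_ref <= 0:
            raise ValueError("alpha_ref must be positive")
        if self.fit_min >= self.fit_max:
            raise ValueError("fit_min must be < fit_max")


@dataclass
class TssCluster:
    """A TSS tag cluster with interquantile geometry.

    Genomic positions are 1-based (CTSS convention); ``start``/``end`` are the
    inclusive cluster bounds, ``positions``/``signal`` the per-base tag signal
    inside it.  ``q_low``/``q_up`` hold the genomic positions of the 10th and
    90th cumulative-signal percentiles and ``iq_width = q_up - q_low + 1``.
    """

    contig: str
    strand: str
    start: int
    end: int
    positions: np.ndarray
    signal: np.ndarray
    tpm: float = 0.0
    q_low: int = 0
    q_up: int = 0
    iq_width: int = 0
    dominant: int = 0
    tpm_max_sample: float = 0.0
    single_tss: bool = False
    meta: dict = field(default_factory=dict)


def read_ctss(path) -> pd.DataFrame:
    """Read a 4-column CTSS TSV (contig, 1-based pos, strand, count)."""
    df = pd.read_csv(path, sep="\t", header=None, names=CTSS_COLUMNS,
                     dtype={"contig": str, "pos": int, "strand": str})
    return df


def write_ctss(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=CTSS_COLUMNS)


def _reverse_cumulative(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct count values and number of positions with count >= value."""
    values, mult = np.unique(counts, return_counts=True)
    ranks = mult[::-1].cumsum()[::-1]
    return values.astype(float), ranks.astype(float)


def fit_powerlaw_slope(counts: np.ndarray, fit_min: float, fit_max: float) -> tuple[float, float]:
    """OLS fit of log10(reverse cumulative rank) vs log10(count).

    Returns (intercept, slope) of the log-log line fitted over count values in
    [fit_min, fit_max].  The slope estimates -alpha of the sample.
    """
    values, ranks = _reverse_cumulative(counts)
    mask = (values >= fit_min) & (values <= fit_max)
    if np.count_nonzero(mask) < 2:
        raise ValueError("fewer than 2 distinct count values in fit range")
    x = np.log10(values[mask])
    y = np.log10(ranks[mask])
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def powerlaw_normalize(
    ctss: pd.DataFrame, params: PowerLawParams | None = None
) -> pd.DataFrame:
    """Normalize raw CTSS counts onto the reference power law (TPM scale).

    Each raw count x is mapped through its fitted reverse-cumulative rank
    ``r(x) = 10**a * x**b`` onto the value x' solving
    ``r(x) = k_ref * x'**(-alpha_ref)`` with ``k_ref = T_ref / zeta(alpha_ref)``
    (the constant that gives the reference law a total of T_ref tags).  The map
    is strictly monotone, so ranks are preserved.
    """
    params = params or PowerLawParams()
    counts = ctss["count"].to_numpy()
    if np.any(counts <= 0):
        raise ValueError("CTSS counts must be positive integers")
    intercept, slope = fit_powerlaw_slope(counts, params.fit_min, params.fit_max)
    # total tags of the reference law: sum_{x>=1} k*x^-alpha = k*zeta(alpha)
    k_ref = params.t_ref / zeta(params.alpha_ref)
    # r_fit(x) on log10 scale, then invert reference law
    log_r = intercept + slope * np.log10(counts.astype(float))
    log_norm = (np.log10(k_ref) - log_r) / params.alpha_ref
    out = ctss.copy()
    out["count"] = 10.0 ** log_norm
    return out


def cluster_ctss(ctss: pd.DataFrame, max_dist: int = 30) -> list[TssCluster]:
    """Distance-cluster CTSS positions per contig and strand.

    Consecutive positions on the same strand whose genomic distance is at most
    ``max_dist`` bp merge into one cluster; opposite strands never merge.
    """
    clusters: list[TssCluster] = []
    for (contig, strand), grp in ctss.groupby(["contig", "strand"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        sig = grp["count"].to_numpy(dtype=float)
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_dist)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [len(pos)]))
        for s, e in zip(starts, ends):
            c = TssCluster(
                contig=contig,
                strand=strand,
                start=int(pos[s]),
                end=int(pos[e - 1]),
                positions=pos[s:e].copy(),
                signal=sig[s:e].copy(),
                tpm=float(sig[s:e].sum()),
                single_tss=(e - s == 1),
            )
            interquantile_bounds(c)
            c.dominant = dominant_tss(c.positions, c.signal, strand)
            clusters.append(c)
    return clusters


def interquantile_bounds(
    cluster: TssCluster, q_low: float = 0.1, q_up: float = 0.9
) -> tuple[int, int, int]:
    """Set/return the interquantile boundaries of a cluster.

    The boundary positions are the first genomic positions (ascending) at which
    the cumulative signal reaches ``q * total``; the interquantile width is
    ``q_up_pos - q_low_pos + 1`` bp and spans >= (q_up - q_low) of the signal
    by construction.
    """
    total = cluster.signal.sum()
    if total <= 0:
        raise ValueError("zero-signal cluster has no interquantile bounds")
    cum = np.cumsum(cluster.signal)
    lo_idx = int(np.searchsorted(cum, q_low * total))
    up_idx = int(np.searchsorted(cum, q_up * total))
    cluster.q_low = int(cluster.positions[lo_idx])
    cluster.q_up = int(cluster.positions[up_idx])
    cluster.iq_width = cluster.q_up - cluster.q_low + 1
    return cluster.q_low, cluster.q_up, cluster.iq_width


def dominant_tss(positions: np.ndarray, summed_signal: np.ndarray, strand: str) -> int:
    """Position with the highest summed signal; ties go to the 5'-most position.

    5'-most means smallest coordinate on '+', largest on '-'.
    """
    best = summed_signal.max()
    at_best = positions[summed_signal == best]
    return int(at_best.min() if strand == "+" else at_best.max())


def aggregate_clusters(
    per_sample: list[list[TssCluster]],
    ctss_tables: list[pd.DataFrame],
    max_dist: int = 100,
    tpm_min: float = 0.5,
) -> list[TssCluster]:
    """Aggregate per-sample tag clusters into consensus clusters.

    Clusters with TPM >= ``tpm_min`` in at least one sample are pooled and
    merged across samples when their interquantile (central) regions are on the
    same strand and within ``max_dist`` bp of each other.  Consensus
    coordinates are the union of the constituent central regions; cumulative
    quantiles and the dominant TSS are recomputed on the per-position signal
    summed across samples.  The consensus ``tpm`` is the mean total TPM across
    samples; ``tpm_max_sample`` keeps the largest constituent cluster TPM.
    """
    if not per_sample:
        raise ValueError("aggregate_clusters requires at least one sample")
    n_samples = len(per_sample)
    kept = [c for sample in per_sample for c in sample if c.tpm >= tpm_min]
    consensus: list[TssCluster] = []
    # group by contig/strand, sweep by central-region start
    keyed: dict[tuple[str, str], list[TssCluster]] = {}
    for c in kept:
        keyed.setdefault((c.contig, c.strand), []).append(c)
    # summed per-position signal across samples, looked up lazily per contig/strand
    signal_maps: dict[tuple[str, str], pd.Series] = {}
    for df in ctss_tables:
        for (contig, strand), grp in df.groupby(["contig", "strand"]):
            key = (contig, strand)
            s = grp.set_index("pos")["count"].astype(float)
            if key in signal_maps:
                signal_maps[key] = signal_maps[key].add(s, fill_value=0.0)
            else:
                signal_maps[key] = s
    for (contig, strand) in sorted(keyed):
        members = sorted(keyed[(contig, strand)], key=lambda c: (c.q_low, c.q_up))
        groups: list[list[TssCluster]] = []
        cur = [members[0]]
        cur_end = members[0].q_up
        for c in members[1:]:
            if c.q_low - cur_end <= max_dist:
                cur.append(c)
                cur_end = max(cur_end, c.q_up)
            else:
                groups.append(cur)
                cur = [c]
                cur_end = c.q_up
        groups.append(cur)
        summed = signal_maps[(contig, strand)].sort_index()
        for grp in groups:
            lo = min(c.q_low for c in grp)
            hi = max(c.q_up for c in grp)
            window = summed.loc[lo:hi]
            positions = window.index.to_numpy()
            signal = window.to_numpy()
            cons = TssCluster(
                contig=contig,
                strand=strand,
                start=lo,
                end=hi,
                positions=positions,
                signal=signal,
                tpm=float(signal.sum()) / n_samples,
                tpm_max_sample=max(c.tpm for c in grp),
                single_tss=len(positions) == 1,
            )
            interquantile_bounds(cons)
            cons.dominant = dominant_tss(positions, signal, strand)
            consensus.append(cons)
    return consensus


def select_promoters(
    clusters: list[TssCluster],
    single_tss_tpm_min: float = 3.0,
    narrow_width_max: int = 11,
    gene_of: dict[int, str] | None = None,
) -> list[PromoterRecord]:
    """Select active promoters and flag narrow initiation windows.

    Single-TSS clusters require TPM >= ``single_tss_tpm_min``; clusters with
    ``iq_width < narrow_width_max`` are flagged narrow.  When ``gene_of`` maps
    cluster indices to gene ids, only the highest-TPM cluster per gene is kept.
    Promoter TSS = the cluster's dominant TSS, converted to a 0-based
    coordinate.
    """
    keep: list[tuple[int, TssCluster]] = []
    for i, c in enumerate(clusters):
        if c.single_tss and c.tpm < single_tss_tpm_min:
            continue
        keep.append((i, c))
    if gene_of:
        best: dict[str, tuple[int, TssCluster]] = {}
        ungenic: list[tuple[int, TssCluster]] = []
        for i, c in keep:
            gene = gene_of.get(i)
            if gene is None:
                ungenic.append((i, c))
            elif gene not in best or c.tpm > best[gene][1].tpm:
                best[gene] = (i, c)
        keep = sorted(best.values(), key=lambda t: t[0]) + ungenic
        keep.sort(key=lambda t: t[0])
    out = []
    for i, c in keep:
        out.append(
            PromoterRecord(
                promoter_id=f"p{i:05d}",
                contig=c.contig,
                tss=c.dominant - 1,  # CTSS 1-based -> genomic 0-based
                strand=c.strand,
                tpm=c.tpm,
                iq_width=c.iq_width,
                narrow=c.iq_width < narrow_width_max,
                gene=gene_of.get(i) if gene_of else None,
            )
        )
    return out
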