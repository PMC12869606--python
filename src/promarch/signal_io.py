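"""Strand-specific coverage I/O and TSS-centered profile extraction.

ChIP-nexus coverage is stored as per-base "stop" counts (the 5' exonuclease
barrier position of each read) on the plus and minus strand separately.  This
module reads/writes that coverage as paired bedGraph files, normalizes it to
reads per million (RPM), pools replicates, and extracts orientation-corrected
TSS-centered profile matrices for downstream footprint and occupancy analysis.

Coordinate conventions
----------------------
Genomic coordinates are 0-based half-open internally; bedGraph/BED records are
native 0-based half-open; CAGE CTSS positions are 1-based (converted at the
boundary in :mod:`promarch.cage`).  TSS-relative offsets place the TSS at 0 and
windows are inclusive at both ends, so "100 bp centered on the TSS" means the
101-position interval [-50, +50].
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StrandedTrack",
    "ProfileMatrix",
    "PromoterRecord",
    "WindowConfig",
    "read_stranded_bedgraph",
    "write_stranded_bedgraph",
    "read_promoter_bed",
    "write_promoter_bed",
    "rpm_normalize",
    "pool_replicates",
    "extract_profiles",
    "window_signal",
]


@dataclass
class WindowConfig:
    """Inclusive TSS-relative analysis windows (TSS = offset 0)."""

    binding_window: tuple[int, int] = (-50, 50)
    cage_window: tuple[int, int] = (-150, 150)
    pca_window: tuple[int, int] = (-50, 50)  # 101 bp centered on TSS
    tbp_cluster_window: tuple[int, int] = (-40, 40)  # 81 bp centered on TSS
    heatmap_sort_window: tuple[int, int] = (-50, 50)

    def __post_init__(self) -> None:
        for name in (
            "binding_window",
            "cage_window",
            "pca_window",
            "tbp_cluster_window",
            "heatmap_sort_window",
        ):
            lo, hi = getattr(self, name)
            if not (lo <= 0 <= hi):
                raise ValueError(f"{name}=({lo},{hi}) must contain offset 0")


@dataclass
class PromoterRecord:
    """A promoter anchored at its dominant TSS.

    ``tss`` is a 0-based genomic coordinate of the dominant CAGE TSS; ``strand``
    is '+' or '-'.  ``tpm`` is the power-law normalized CAGE expression of the
    consensus cluster and ``iq_width`` its 10-90% interquantile width in bp.
    """

    promoter_id: str
    contig: str
    tss: int
    strand: str
    tpm: float = 0.0
    iq_width: int = 0
    narrow: bool = False
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class StrandedTrack:
    """Per-base stop counts on both strands over named contigs."""

    contig_lengths: dict[str, int]
    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.plus) != set(self.minus) or set(self.plus) != set(
            self.contig_lengths
        ):
            raise ValueError("plus/minus/contig_lengths must cover identical contigs")
        for contig, length in self.contig_lengths.items():
            for strand in (self.plus, self.minus):
                arr = strand[contig]
                if len(arr) != length:
                    raise ValueError(
                        f"coverage length {len(arr)} != contig length {length} "
                        f"for {contig}"
                    )
                if np.any(arr < 0):
                    raise ValueError(f"negative coverage on {contig}")

    @classmethod
    def zeros(cls, contig_lengths: dict[str, int], **meta) -> "StrandedTrack":
        return cls(
            contig_lengths=dict(contig_lengths),
            plus={c: np.zeros(n) for c, n in contig_lengths.items()},
            minus={c: np.zeros(n) for c, n in contig_lengths.items()},
            meta=meta,
        )

    def total(self) -> float:
        return float(
            sum(a.sum() for a in self.plus.values())
            + sum(a.sum() for a in self.minus.values())
        )


@dataclass
class ProfileMatrix:
    """Promoters x TSS-relative offsets signal, orientation corrected.

    ``sense`` is the transcribed strand of each promoter: for minus-strand
    promoters the offset axis has been reversed and the plus/minus tracks
    swapped, so row orientation is always 5'->3' of the promoter.
    """

    promoter_ids: list[str]
    offsets: np.ndarray  # inclusive range [-flank, +flank]
    sense: np.ndarray  # (n_promoters, n_offsets)
    antisense: np.ndarray

    def __post_init__(self) -> None:
        if self.sense.shape != self.antisense.shape:
            raise ValueError("sense/antisense shapes differ")
        if self.sense.shape != (len(self.promoter_ids), len(self.offsets)):
            raise ValueError("profile shape inconsistent with ids/offsets")

    def offset_index(self, offset: int) -> int:
        i = int(offset - self.offsets[0])
        if i < 0 or i >= len(self.offsets):
            raise IndexError(f"offset {offset} outside [{self.offsets[0]}, {self.offsets[-1]}]")
        return i

    def metaprofile(self) -> tuple[np.ndarray, np.ndarray]:
        """Average over promoters -> (sense, antisense) mean profiles."""
        return self.sense.mean(axis=0), self.antisense.mean(axis=0)


def _read_bedgraph_dense(path, contig_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    arrays = {c: np.zeros(n) for c, n in contig_lengths.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            contig, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if contig not in contig_lengths:
                raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
            if start < 0 or end > contig_lengths[contig] or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside contig "
                    f"{contig} (length {contig_lengths[contig]})"
                )
            if covered[contig][start:end].any():
                raise ValueError(f"{path}:{lineno}: overlapping bedGraph intervals")
            covered[contig][start:end] = True
            arrays[contig][start:end] = value
    return arrays


def read_stranded_bedgraph(
    path_plus, path_minus, contig_lengths: dict[str, int], **meta
) -> StrandedTrack:
    """Read one bedGraph per strand into a dense :class:`StrandedTrack`.

    Positions not covered by any record are 0.  Overlapping intervals on one
    strand and records outside the declared contigs are errors.
    """
    return StrandedTrack(
        contig_lengths=dict(contig_lengths),
        plus=_read_bedgraph_dense(path_plus, contig_lengths),
        minus=_read_bedgraph_dense(path_minus, contig_lengths),
        meta=dict(meta),
    )


def _write_bedgraph_dense(path, arrays: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for contig in sorted(arrays):
            arr = arrays[contig]
            # run-length encode consecutive equal nonzero values
            nz = np.flatnonzero(arr)
            if len(nz) == 0:
                continue
            breaks = np.flatnonzero(
                (np.diff(nz) != 1) | (np.diff(arr[nz]) != 0)
            )
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(nz) - 1]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{contig}\t{nz[s]}\t{nz[e] + 1}\t{arr[nz[s]]:.10g}\n"
                )


def write_stranded_bedgraph(track: StrandedTrack, path_plus, path_minus) -> None:
    """Write a track as one bedGraph per strand (zero runs omitted)."""
    _write_bedgraph_dense(path_plus, track.plus)
    _write_bedgraph_dense(path_minus, track.minus)


def read_promoter_bed(path) -> list[PromoterRecord]:
    """Read promoters from BED6 (name=promoter id, score=TPM, strand).

    The record's thickStart-like single-base anchor is taken as the interval
    start for '+' and end-1 for '-'; pipeline-written BEDs are 1 bp wide at the
    dominant TSS so this is exact.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            contig, start, end, name, score, strand = f[:6]
            start, end = int(start), int(end)
            tss = start if strand == "+" else end - 1
            out.append(
                PromoterRecord(
                    promoter_id=name, contig=contig, tss=tss, strand=strand,
                    tpm=float(score),
                )
            )
    return out


def write_promoter_bed(promoters: list[PromoterRecord], path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f"{p.contig}\t{p.tss}\t{p.tss + 1}\t{p.promoter_id}\t"
                f"{p.tpm:.6g}\t{p.strand}\n"
            )


def rpm_normalize(track: StrandedTrack) -> StrandedTrack:
    """Scale coverage to reads per million of the replicate's aligned reads.

    Every per-base value is multiplied by ``1e6 / total_aligned_reads`` where
    ``total_aligned_reads`` comes from ``track.meta``.
    """
    total = track.meta.get("total_aligned_reads")
    if not total or total <= 0:
        raise ValueError("rpm_normalize requires meta['total_aligned_reads'] > 0")
    scale = 1e6 / total
    meta = dict(track.meta)
    meta["normalized"] = True
    return StrandedTrack(
        contig_lengths=dict(track.contig_lengths),
        plus={c: a * scale for c, a in track.plus.items()},
        minus={c: a * scale for c, a in track.minus.items()},
        meta=meta,
    )


def pool_replicates(tracks: list[StrandedTrack]) -> StrandedTrack:
    """Average RPM-normalized replicate tracks base-by-base."""
    if not tracks:
        raise ValueError("pool_replicates requires at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.meta.get("factor") != first.meta.get("factor") or t.meta.get(
            "condition"
        ) != first.meta.get("condition"):
            raise ValueError("cannot pool tracks from different factors/conditions")
        if t.contig_lengths != first.contig_lengths:
            raise ValueError("cannot pool tracks over different contigs")
    for t in tracks:
        if not t.meta.get("normalized"):
            raise ValueError("pool_replicates expects RPM-normalized tracks")
    n = len(tracks)
    meta = {
        "factor": first.meta.get("factor"),
        "condition": first.meta.get("condition"),
        "normalized": True,
        "n_replicates": n,
    }
    return StrandedTrack(
        contig_lengths=dict(first.contig_lengths),
        plus={
            c: sum(t.plus[c] for t in tracks) / n for c in first.contig_lengths
        },
        minus={
            c: sum(t.minus[c] for t in tracks) / n for c in first.contig_lengths
        },
        meta=meta,
    )


def extract_profiles(
    track: StrandedTrack, promoters: list[PromoterRecord], flank: int
) -> ProfileMatrix:
    """Extract TSS-centered per-base profiles, oriented 5'->3' per promoter.

    For a plus-strand promoter sense = plus strand; for a minus-strand promoter
    the offsets are reversed and plus/minus swapped so that sense is always the
    transcribed strand.  Promoters whose ±flank window leaves the contig are
    dropped (and logged), not errors.
    """
    offsets = np.arange(-flank, flank + 1)
    kept_ids: list[str] = []
    sense_rows: list[np.ndarray] = []
    anti_rows: list[np.ndarray] = []
    for p in promoters:
        length = track.contig_lengths.get(p.contig)
        if length is None:
            logger.warning("promoter %s on unknown contig %s dropped", p.promoter_id, p.contig)
            continue
        lo, hi = p.tss - flank, p.tss + flank
        if lo < 0 or hi >= length:
            logger.info("promoter %s window outside contig; dropped", p.promoter_id)
            continue
        plus = track.plus[p.contig][lo : hi + 1]
        minus = track.minus[p.contig][lo : hi + 1]
        if p.strand == "+":
            sense_rows.append(plus.copy())
            anti_rows.append(minus.copy())
        else:
            sense_rows.append(minus[::-1].copy())
            anti_rows.append(plus[::-1].copy())
        kept_ids.append(p.promoter_id)
    n = len(kept_ids)
    shape = (n, len(offsets))
    return ProfileMatrix(
        promoter_ids=kept_ids,
        offsets=offsets,
        sense=np.vstack(sense_rows) if n else np.zeros(shape),
        antisense=np.vstack(anti_rows) if n else np.zeros(shape),
    )


def window_signal(
    profile: ProfileMatrix,
    window: tuple[int, int],
    mode: str = "sum",
    strands: str = "both",
) -> np.ndarray:
    """Per-promoter scalar signal over an inclusive TSS-relative window.

    ``strands`` is "both" (default), "sense" or "antisense"; ``mode`` is "sum"
    or "mean" (mean is taken over all positions x strands included).
    """
    lo, hi = window
    if lo < profile.offsets[0] or hi > profile.offsets[-1]:
        raise ValueError(f"window ({lo},{hi}) outside profile flank")
    i0, i1 = profile.offset_index(lo), profile.offset_index(hi)
    parts = []
    if strands in ("both", "sense"):
        parts.append(profile.sense[:, i0 : i1 + 1])
    if strands in ("both", "antisense"):
        parts.append(profile.antisense[:, i0 : i1 + 1])
    if not parts:
        raise ValueError(f"unknown strands mode {strands!r}")
    block = np.hstack(parts)
    if mode == "sum":
        return block.sum(axis=1)
    if mode == "mean":
        return block.mean(axis=1)
    raise ValueError(f"unknown mode {mode!r}")
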