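"""Core promoter element scanning, promoter typing, enrichment, and PWMs.

Drosophila core promoters carry short, strictly positioned sequence elements:
the TATA box, the initiator (Inr), the downstream promoter region elements
(MTE, DPE, PB — the DPR class), housekeeping elements (DRE, Ohler 1/6/7) and
the TCT initiator of ribosomal protein genes.  Each element is an IUPAC
consensus scanned in a fixed TSS-relative window; the TATA box tolerates one
mismatch, all others none.  Promoter types are then called by combinatorial
presence/absence rules, and per-cluster element enrichment is scored with
Fisher's exact test under Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MotifSpec",
    "PromoterTypeCall",
    "DEFAULT_MOTIFS",
    "IUPAC",
    "iupac_mismatches",
    "scan_window",
    "element_presence",
    "classify_promoters",
    "element_enrichment",
    "build_pwm",
    "write_meme",
    "read_motif_table",
    "write_motif_table",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC consensus constrained to a TSS-relative window.

    ``window_start``/``window_end`` are inclusive TSS-relative offsets (TSS=0)
    within which the *entire* motif must lie.
    """

    name: str
    consensus: str
    window_start: int
    window_end: int
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes in {self.name}: {bad}")
        if self.window_end - self.window_start + 1 < len(self.consensus):
            raise ValueError(f"window of {self.name} shorter than its consensus")


# Default element table: name, consensus, window, mismatch allowance.
# One mismatch is tolerated for the TATA box only.
DEFAULT_MOTIFS: tuple[MotifSpec, ...] = (
    MotifSpec("TATA", "STATAWAWR", -40, -20, 1),
    MotifSpec("INR", "TCAKTY", -5, 5, 0),
    MotifSpec("DPE", "GGWYV", 25, 35, 0),
    MotifSpec("MTE", "CSARCSSA", 10, 30, 0),
    MotifSpec("PB", "KCGRWCG", 20, 50, 0),
    MotifSpec("DRE", "WATCGATW", -70, -10, 0),
    MotifSpec("Ohler1", "GGTCACACTR", -10, 10, 0),
    MotifSpec("Ohler6", "RGTATWTT", -50, -10, 0),
    MotifSpec("Ohler7", "CAKCNCTR", -70, 10, 0),
    MotifSpec("TCT", "YYCTTTYY", -10, 10, 0),
)

DPR_ELEMENTS = frozenset({"MTE", "DPE", "PB"})
HK_ELEMENTS = frozenset({"DRE", "Ohler1", "Ohler6", "Ohler7"})


@dataclass
class PromoterTypeCall:
    promoter_id: str
    present_elements: frozenset[str]
    labels: frozenset[str]
    primary_label: str


def iupac_mismatches(consensus: str, seq: str) -> int:
    """Count positions where ``seq`` falls outside the IUPAC class of ``consensus``.

    An N in ``seq`` mismatches every consensus code except N.
    """
    if len(consensus) != len(seq):
        raise ValueError("consensus and sequence lengths differ")
    mm = 0
    for code, base in zip(consensus.upper(), seq.upper()):
        klass = IUPAC.get(code)
        if klass is None:
            raise ValueError(f"invalid IUPAC code {code!r}")
        if base == "N":
            if code != "N":
                mm += 1
        elif base not in "ACGT":
            raise ValueError(f"invalid sequence base {base!r}")
        elif base not in klass:
            mm += 1
    return mm


def scan_window(
    promoter_seq: str, spec: MotifSpec, seq_start_offset: int
) -> list[tuple[int, int]]:
    """All motif placements fully inside the spec's window.

    ``promoter_seq`` is the sense strand 5'->3'; ``seq_start_offset`` is the
    TSS-relative offset of its first base.  Returns (start_offset, mismatches)
    for every placement with mismatches <= ``spec.max_mismatch``; the element
    is "present" iff the list is nonempty.
    """
    k = len(spec.consensus)
    seq_end_offset = seq_start_offset + len(promoter_seq) - 1
    if spec.window_start < seq_start_offset or spec.window_end > seq_end_offset:
        raise ValueError(
            f"window of {spec.name} ({spec.window_start},{spec.window_end}) not "
            f"covered by sequence ({seq_start_offset},{seq_end_offset})"
        )
    hits = []
    for start in range(spec.window_start, spec.window_end - k + 2):
        i = start - seq_start_offset
        mm = iupac_mismatches(spec.consensus, promoter_seq[i : i + k])
        if mm <= spec.max_mismatch:
            hits.append((start, mm))
    return hits


def element_presence(
    seqs: dict[str, str],
    seq_start_offset: int,
    motifs: tuple[MotifSpec, ...] = DEFAULT_MOTIFS,
    zero_mismatch: bool = False,
) -> pd.DataFrame:
    """Boolean promoters x elements presence matrix.

    ``zero_mismatch=True`` overrides every spec's mismatch allowance with 0
    (the convention used for enrichment scoring, as opposed to type calling).
    """
    specs = motifs
    if zero_mismatch:
        specs = tuple(
            MotifSpec(m.name, m.consensus, m.window_start, m.window_end, 0)
            for m in motifs
        )
    data = {
        m.name: [
            bool(scan_window(seq, m, seq_start_offset))
            for seq in seqs.values()
        ]
        for m in specs
    }
    return pd.DataFrame(data, index=list(seqs.keys()))


def _labels_from_presence(present: frozenset[str]) -> frozenset[str]:
    labels = set()
    if "TATA" in present:
        labels.add("TATA")
    if "TCT" in present:
        labels.add("TCT")
    if present & DPR_ELEMENTS and not present & ({"TATA", "TCT"} | HK_ELEMENTS):
        labels.add("DPR")
    if present & HK_ELEMENTS and not present & ({"TATA", "TCT"} | DPR_ELEMENTS):
        labels.add("HK")
    return frozenset(labels)


PRIMARY_PRIORITY = ("TATA", "TCT", "DPR", "HK")


def classify_promoters(
    seqs: dict[str, str],
    seq_start_offset: int,
    motifs: tuple[MotifSpec, ...] = DEFAULT_MOTIFS,
) -> list[PromoterTypeCall]:
    """Call promoter types from element presence.

    TATA and TCT promoters only require their element and are not excluded by
    others.  DPR promoters need MTE, DPE or PB and none of TATA/TCT/DRE/Ohler;
    HK promoters need DRE or an Ohler element and none of TATA/TCT/MTE/DPE/PB.
    The primary label resolves multi-label promoters by the fixed priority
    TATA > TCT > DPR > HK; promoters matching no rule are "unclassified".
    """
    presence = element_presence(seqs, seq_start_offset, motifs)
    calls = []
    for pid in presence.index:
        present = frozenset(presence.columns[presence.loc[pid]])
        labels = _labels_from_presence(present)
        primary = next((lab for lab in PRIMARY_PRIORITY if lab in labels), "unclassified")
        calls.append(PromoterTypeCall(pid, present, labels, primary))
    return calls


def element_enrichment(
    cluster_assignment: pd.Series,
    element_presence_df: pd.DataFrame,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per (cluster, element) enrichment ratio with Fisher exact p and BH q.

    For each cluster and element the 2x2 table (in cluster / has element) is
    tested with Fisher's exact test; the ratio is the in-cluster presence
    fraction over the presence fraction in all other clusters.  q-values are
    Benjamini-Hochberg adjusted across all cluster x element tests.
    """
    common = cluster_assignment.index.intersection(element_presence_df.index)
    clusters = cluster_assignment.loc[common]
    presence = element_presence_df.loc[common]
    rows = []
    for cl in sorted(pd.unique(clusters)):
        in_cl = clusters == cl
        n_in = int(in_cl.sum())
        n_out = int((~in_cl).sum())
        for el in presence.columns:
            has = presence[el]
            a = int((in_cl & has).sum())  # in cluster, has element
            b = n_in - a
            c = int((~in_cl & has).sum())
            d = n_out - c
            if n_in == 0 or n_out == 0:
                ratio, p, undefined = np.nan, np.nan, True
            else:
                frac_in = a / n_in
                frac_out = c / n_out
                if frac_out > 0:
                    ratio = frac_in / frac_out
                else:
                    ratio = np.nan if frac_in == 0 else np.inf
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
                undefined = False
            rows.append(
                {"cluster": cl, "element": el, "n_in": n_in, "k_in": a,
                 "n_out": n_out, "k_out": c, "ratio": ratio, "p": p,
                 "undefined": undefined}
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def build_pwm(
    seqs: list[str], pseudocount: float = 0.5
) -> pd.DataFrame:
    """Position x base probability matrix with per-position information content.

    All sequences must share one length.  Returns a DataFrame with columns
    A, C, G, T and ``ic`` (bits), where ic = 2 + sum_b p_b log2 p_b.
    """
    if not seqs:
        raise ValueError("build_pwm requires at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must share one length")
    bases = "ACGT"
    counts = np.full((length, 4), pseudocount, dtype=float)
    for s in seqs:
        for i, base in enumerate(s.upper()):
            j = bases.find(base)
            if j >= 0:
                counts[i, j] += 1
            else:  # N and ambiguity codes spread uniformly
                counts[i] += 0.25
    probs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    out = pd.DataFrame(probs, columns=list(bases))
    out["ic"] = ic
    return out


def write_meme(pwms: dict[str, pd.DataFrame], path) -> None:
    """Write PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for name, pwm in pwms.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)}\n"
            )
            for _, row in pwm.iterrows():
                fh.write(
                    f" {row['A']:.6f} {row['C']:.6f} {row['G']:.6f} {row['T']:.6f}\n"
                )
            fh.write("\n")


def read_motif_table(path) -> tuple[MotifSpec, ...]:
    """Read a motif TSV: name, consensus, start, end, max_mismatch."""
    df = pd.read_csv(path, sep="\t")
    return tuple(
        MotifSpec(r["name"], r["consensus"], int(r["start"]), int(r["end"]),
                  int(r.get("max_mismatch", 0)))
        for _, r in df.iterrows()
    )


def write_motif_table(motifs: tuple[MotifSpec, ...], path) -> None:
    pd.DataFrame(
        [
            {"name": m.name, "consensus": m.consensus, "start": m.window_start,
             "end": m.window_end, "max_mismatch": m.max_mismatch}
            for m in motifs
        ]
    ).to_csv(path, sep="\t", index=False)
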