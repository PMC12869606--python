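"""Synthetic promoter data with the statistical structure the pipeline assumes.

The generator builds a self-contained study: a random genome with promoters of
the four architectural types (TATA, DPR, TCT, HK) carrying exact instances of
their defining core elements at legal offsets (and rejection-sampled to be
free of excluded elements), CAGE tag tables with narrow or broad initiation
windows and heavy-tailed per-position counts, strand-paired ChIP-nexus
footprint tracks whose peak geometry follows the canonical promoter regions
and whose occupancies are correlated within structural modules, and a Pol II
time course whose pause signal decays exponentially with a known half-life.

Every output is paired with a :class:`TruthTable` carrying the planted ground
truth, so recovery (classification accuracy, clustering ARI, half-life error)
can be scored exactly.  All randomness flows from one root seed through named
substreams, so each data modality can be regenerated independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import elements as el
from .signal_io import PromoterRecord, StrandedTrack

__all__ = [
    "TruthTable",
    "Footprint",
    "MODULES",
    "default_archetypes",
    "make_genome",
    "simulate_ctss",
    "simulate_chipnexus",
    "simulate_pause_timecourse",
    "write_fasta",
    "read_fasta",
]

PROMOTER_TYPES = ("TATA", "DPR", "TCT", "HK")

# Structural modules of the TFIID subunits used for correlated occupancies.
MODULES: dict[str, tuple[str, ...]] = {
    "downstream": ("TAF1", "TAF2", "TAF7", "TAF3"),
    "middle": ("TAF6", "TAF8", "TAF11"),
    "upstream_narrow": ("TBP", "TAF5", "TAF9", "TAF13"),
    "upstream_broad": ("TAF4", "TAF10", "TAF12"),
}

HALF_LIFE_CHOICES = (2.0, 5.0, 10.0, 30.0, 50.0)  # min


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent named substream of the root seed."""
    digest = hashlib.sha256(name.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([int(seed) % (2**31), sub])


@dataclass
class TruthTable:
    """Planted ground truth for one synthetic study."""

    promoters: pd.DataFrame  # id, contig, tss, strand, ptype, expression, ...
    planted: pd.DataFrame  # promoter_id, element, offset, sequence
    occupancy: pd.DataFrame  # promoters x factors multipliers
    seed: int
    params: dict = field(default_factory=dict)

    def records(self) -> list[PromoterRecord]:
        return [
            PromoterRecord(
                promoter_id=r.Index, contig=r.contig, tss=int(r.tss),
                strand=r.strand, tpm=float(r.expression),
                narrow=bool(r.narrow),
            )
            for r in self.promoters.itertuples()
        ]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "promoters": self.promoters.reset_index().to_dict(orient="list"),
            "planted": self.planted.to_dict(orient="list"),
            "occupancy": self.occupancy.reset_index().to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        promoters = pd.DataFrame(payload["promoters"]).set_index("promoter_id")
        occupancy = pd.DataFrame(payload["occupancy"]).set_index("promoter_id")
        return cls(
            promoters=promoters,
            planted=pd.DataFrame(payload["planted"]),
            occupancy=occupancy,
            seed=payload["seed"],
            params=payload["params"],
        )


def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    """Sample a concrete sequence uniformly within each IUPAC class."""
    return "".join(
        sorted(el.IUPAC[c])[rng.integers(len(el.IUPAC[c]))] for c in consensus
    )


# Planting plans: (element name, sense-strand start offset choices).
_PLANT_PLAN: dict[str, list[tuple[str, tuple[int, ...]]]] = {
    "TATA": [("TATA", (-31, -30, -32)), ("INR", (-2,))],
    "DPR": [("INR", (-2,))],  # plus one sampled DPR element, below
    "TCT": [("TCT", (-2,))],
    "HK": [],  # one sampled HK element, below
}
_DPR_CHOICES: list[tuple[str, tuple[int, ...]]] = [
    ("MTE", (12, 16, 18)),
    ("DPE", (27, 28, 29)),
    ("PB", (26, 30, 34)),
]
_HK_CHOICES: list[tuple[str, tuple[int, ...]]] = [
    ("DRE", (-45, -40, -30)),
    ("Ohler1", (-5, -2, 0)),
    ("Ohler6", (-32, -28, -24)),
    ("Ohler7", (-35, -25, -15)),
]

# Elements that must NOT match (at classification mismatch allowances) for the
# planted type to be recovered with exactly the planted label set.
_FORBIDDEN: dict[str, frozenset[str]] = {
    "TATA": frozenset({"TCT"}),
    "DPR": frozenset({"TATA", "TCT"}) | el.HK_ELEMENTS,
    "TCT": frozenset({"TATA"}),
    "HK": frozenset({"TATA", "TCT"}) | el.DPR_ELEMENTS,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _specs_by_name() -> dict[str, el.MotifSpec]:
    return {m.name: m for m in el.DEFAULT_MOTIFS}


def make_genome(
    n_promoters: int = 400,
    type_mix: dict[str, float] | None = None,
    spacing: int = 700,
    plant_window: tuple[int, int] = (-80, 60),
    broad_frac: float = 0.0,
    expression_mean: float = 20.0,
    expression_sigma: float = 1.0,
    seed: int = 0,
    contig: str = "chrS",
    max_attempts: int = 500,
) -> tuple[dict[str, str], TruthTable]:
    """Build a random genome with classifiable planted promoters.

    Promoters are spaced ``spacing`` bp apart on a single contig with random
    strands; each carries exact consensus instances of its type's defining
    elements at legal offsets and is rejection-sampled until no excluded
    element matches (at the classification mismatch allowances) anywhere in
    its scan window.  Returns (genome dict contig->sequence, truth table).
    """
    type_mix = type_mix or {t: 0.25 for t in PROMOTER_TYPES}
    if abs(sum(type_mix.values()) - 1.0) > 1e-9:
        raise ValueError("type_mix must sum to 1")
    w_lo, w_hi = plant_window
    win_len = w_hi - w_lo + 1
    if spacing < 2 * win_len:
        raise ValueError("promoters too dense for non-overlapping plant windows")
    rng = _stream(seed, "genome")
    specs = _specs_by_name()
    # deterministic type sequence honoring the mix
    counts = {t: int(round(type_mix.get(t, 0) * n_promoters)) for t in PROMOTER_TYPES}
    while sum(counts.values()) < n_promoters:
        counts[max(type_mix, key=type_mix.get)] += 1
    while sum(counts.values()) > n_promoters:
        counts[max(counts, key=counts.get)] -= 1
    types = [t for t in PROMOTER_TYPES for _ in range(counts[t])]
    rng.shuffle(types)

    contig_length = spacing * (n_promoters + 1)
    genome_arr = rng.choice(list("ACGT"), size=contig_length)
    prom_rows = []
    plant_rows = []
    for i, ptype in enumerate(types):
        tss = spacing * (i + 1) + int(rng.integers(-spacing // 4, spacing // 4 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        pid = f"p{i:05d}"
        plan = list(_PLANT_PLAN[ptype])
        if ptype == "DPR":
            plan.append(_DPR_CHOICES[rng.integers(len(_DPR_CHOICES))])
        if ptype == "HK":
            plan.append(_HK_CHOICES[rng.integers(len(_HK_CHOICES))])
        forbidden = [specs[name] for name in sorted(_FORBIDDEN[ptype])]
        for attempt in range(max_attempts):
            window = "".join(rng.choice(list("ACGT"), size=win_len))
            planted_here = []
            for name, starts in plan:
                start = int(starts[rng.integers(len(starts))])
                inst = _instantiate(specs[name].consensus, rng)
                j = start - w_lo
                window = window[:j] + inst + window[j + len(inst):]
                planted_here.append((name, start, inst))
            if any(el.scan_window(window, m, w_lo) for m in forbidden):
                continue
            # planting order may clobber an earlier element; verify all present
            if all(
                el.scan_window(window, specs[name], w_lo) for name, _, _ in planted_here
            ):
                break
        else:
            raise RuntimeError(f"could not plant a clean {ptype} promoter")
        # place the oriented window into the genome
        if strand == "+":
            g0 = tss + w_lo
            genome_arr[g0 : g0 + win_len] = list(window)
        else:
            g0 = tss - w_hi
            genome_arr[g0 : g0 + win_len] = list(_revcomp(window))
        narrow = rng.random() >= broad_frac
        prom_rows.append(
            {
                "promoter_id": pid,
                "contig": contig,
                "tss": tss,
                "strand": strand,
                "ptype": ptype,
                "expression": float(
                    rng.lognormal(np.log(expression_mean), expression_sigma)
                ),
                "tss_sd": 1.2 if narrow else 10.0,
                "narrow": narrow,
                "half_life": float(
                    HALF_LIFE_CHOICES[rng.integers(len(HALF_LIFE_CHOICES))]
                ),
                "pause_pos": int(rng.integers(25, 56)),
            }
        )
        for name, start, inst in planted_here:
            plant_rows.append(
                {"promoter_id": pid, "element": name, "offset": start,
                 "sequence": inst}
            )
    promoters = pd.DataFrame(prom_rows).set_index("promoter_id")
    # module-correlated occupancy multipliers via shared per-module latents
    occ_rng = _stream(seed, "occupancy")
    factors = [f for fs in MODULES.values() for f in fs]
    latents = {
        m: occ_rng.lognormal(0.0, 0.5, size=n_promoters) for m in MODULES
    }
    occ = {}
    for module, fs in MODULES.items():
        for f in fs:
            occ[f] = latents[module] * occ_rng.lognormal(0.0, 0.15, size=n_promoters)
    occupancy = pd.DataFrame(occ, index=promoters.index)[factors]
    genome = {contig: "".join(genome_arr)}
    truth = TruthTable(
        promoters=promoters,
        planted=pd.DataFrame(plant_rows),
        occupancy=occupancy,
        seed=seed,
        params={
            "n_promoters": n_promoters, "spacing": spacing,
            "plant_window": list(plant_window), "broad_frac": broad_frac,
            "contig_length": contig_length, "contig": contig,
        },
    )
    return genome, truth


def promoter_window_seq(
    genome: dict[str, str], p: PromoterRecord | pd.Series, lo: int, hi: int
) -> str:
    """Sense-strand sequence over inclusive TSS-relative offsets [lo, hi]."""
    contig = p.contig
    tss = int(p.tss)
    seq = genome[contig]
    if p.strand == "+":
        return seq[tss + lo : tss + hi + 1]
    return _revcomp(seq[tss - hi : tss - lo + 1])


def truth_window_seqs(
    genome: dict[str, str], truth: TruthTable, lo: int = -80, hi: int = 60
) -> dict[str, str]:
    out = {}
    for r in truth.promoters.itertuples():
        out[r.Index] = promoter_window_seq(genome, r, lo, hi)
    return out


def simulate_ctss(
    truth: TruthTable,
    n_replicates: int = 2,
    dispersion: float = 10.0,
    tags_per_expression: float = 1.0,
    background_rate: float = 0.0,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """CAGE CTSS tables, one per replicate.

    Per promoter, the replicate's total tag count is negative-binomial around
    ``expression * tags_per_expression`` (size ``dispersion``) and tags spread
    normally around the TSS with the promoter's initiation-window sd (narrow
    1-2 bp, broad ~10 bp).  ``background_rate`` adds sparse uniform singleton
    tags per bp.  Positions are 1-based, on the promoter strand.
    """
    seed = truth.seed if seed is None else seed
    contig_length = truth.params["contig_length"]
    tables = []
    for rep in range(n_replicates):
        rng = _stream(seed, f"ctss-rep{rep}")
        recs: dict[tuple[str, int, str], int] = {}
        for r in truth.promoters.itertuples():
            mu = float(r.expression) * tags_per_expression
            if mu <= 0:
                continue
            p = dispersion / (dispersion + mu)
            total = int(rng.negative_binomial(dispersion, p))
            if total == 0:
                continue
            offs = np.rint(rng.normal(0.0, r.tss_sd, size=total)).astype(int)
            sign = 1 if r.strand == "+" else -1
            positions = int(r.tss) + sign * offs + 1  # 1-based
            positions = positions[(positions >= 1) & (positions <= contig_length)]
            for pos in positions:
                key = (r.contig, int(pos), r.strand)
                recs[key] = recs.get(key, 0) + 1
        if background_rate > 0:
            n_bg = int(rng.poisson(background_rate * contig_length))
            for _ in range(n_bg):
                key = (
                    truth.params["contig"],
                    int(rng.integers(1, contig_length + 1)),
                    "+" if rng.random() < 0.5 else "-",
                )
                recs[key] = recs.get(key, 0) + 1
        rows = [
            {"contig": c, "pos": p, "strand": s, "count": n}
            for (c, p, s), n in recs.items()
        ]
        df = pd.DataFrame(rows, columns=["contig", "pos", "strand", "count"])
        df = df.sort_values(["contig", "strand", "pos"]).reset_index(drop=True)
        tables.append(df)
    return tables


@dataclass(frozen=True)
class Footprint:
    """One strand-paired footprint of a factor archetype.

    Offsets are TSS-relative on the promoter's sense strand; the antisense
    peak is always downstream of the sense peak.  ``type_scale`` and
    ``condition_scale`` modulate the expected peak height per promoter type /
    condition (missing keys default to 1).
    """

    sense_offset: int
    antisense_offset: int
    height: float
    type_scale: tuple[tuple[str, float], ...] = ()
    condition_scale: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.antisense_offset <= self.sense_offset:
            raise ValueError("antisense peak must be downstream of sense peak")

    def scale(self, ptype: str, condition: str) -> float:
        ts = dict(self.type_scale)
        cs = dict(self.condition_scale)
        return self.height * ts.get(ptype, 1.0) * cs.get(condition, 1.0)


def default_archetypes() -> dict[str, list[Footprint]]:
    """Footprint archetypes reproducing the six canonical promoter regions.

    Upstream TBP (-18 midpoint) only at TATA promoters; downstream TBP (+32)
    strongest at DPR promoters and absent under triptolide; downstream-module
    TAFs at +10/+19/+32; middle module straddling the TSS; narrow upstream
    module at -30/-18; broad upstream module diffuse over -150/-50.
    """
    tata_only = (("TATA", 1.0), ("DPR", 0.0), ("TCT", 0.0), ("HK", 0.0))
    dpr_major = (("DPR", 1.0), ("TATA", 0.3), ("TCT", 0.4), ("HK", 0.15))
    diffuse_types = (("TCT", 1.0), ("HK", 0.4), ("TATA", 0.1), ("DPR", 0.15))
    no_tri = (("triptolide", 0.0),)
    down = [Footprint(6, 14, 0.8), Footprint(15, 23, 0.9), Footprint(28, 36, 1.0)]
    middle = [Footprint(-32, -28, 0.7), Footprint(6, 14, 0.7), Footprint(15, 23, 0.6)]
    up_narrow = [Footprint(-32, -28, 0.8), Footprint(-20, -16, 1.0)]
    up_broad = [
        Footprint(-125, -115, 0.6),
        Footprint(-95, -85, 0.6),
        Footprint(-65, -55, 0.6),
    ]
    arch: dict[str, list[Footprint]] = {}
    for f in MODULES["downstream"]:
        arch[f] = list(down)
    for f in MODULES["middle"]:
        arch[f] = list(middle)
    for f in MODULES["upstream_narrow"]:
        arch[f] = list(up_narrow)
    for f in MODULES["upstream_broad"]:
        arch[f] = list(up_broad)
    arch["TBP"] = [
        Footprint(-20, -16, 1.0, type_scale=tata_only),
        Footprint(-6, 2, 0.5, type_scale=diffuse_types),
        Footprint(28, 36, 0.8, type_scale=dpr_major, condition_scale=no_tri),
    ]
    return arch


def _deposit(
    track: StrandedTrack,
    contig: str,
    pos: np.ndarray,
    strand: str,
) -> None:
    length = track.contig_lengths[contig]
    pos = pos[(pos >= 0) & (pos < length)]
    arr = track.plus[contig] if strand == "+" else track.minus[contig]
    np.add.at(arr, pos, 1.0)


def simulate_chipnexus(
    truth: TruthTable,
    archetypes: dict[str, list[Footprint]] | None = None,
    condition: str = "control",
    replicate: int = 0,
    reads_per_footprint: float = 30.0,
    jitter: tuple[float, ...] = (0.2, 0.6, 0.2),  # P(offset-1, offset, offset+1)
    background_rate: float = 0.005,
    seed: int | None = None,
) -> dict[str, StrandedTrack]:
    """Stop-base count tracks for every factor under one condition.

    Per promoter and archetype footprint, Poisson read counts (mean
    ``reads_per_footprint * height * occupancy multiplier * type/condition
    scale``) are deposited at the peak offsets with +/-1 bp jitter; sparse
    uniform background reads are added on both strands.  Tracks carry raw
    integer counts with ``total_aligned_reads`` in meta, ready for RPM
    normalization.
    """
    archetypes = archetypes or default_archetypes()
    seed = truth.seed if seed is None else seed
    contig = truth.params["contig"]
    contig_lengths = {contig: truth.params["contig_length"]}
    jit_offsets = np.array([-1, 0, 1])
    jit_p = np.asarray(jitter, dtype=float)
    jit_p = jit_p / jit_p.sum()
    tracks: dict[str, StrandedTrack] = {}
    for factor in sorted(archetypes):
        rng = _stream(seed, f"nexus-{factor}-{condition}-rep{replicate}")
        track = StrandedTrack.zeros(
            contig_lengths, factor=factor, condition=condition,
            replicate=replicate,
        )
        for r in truth.promoters.itertuples():
            mult = float(truth.occupancy.loc[r.Index, factor]) if factor in truth.occupancy.columns else 1.0
            sign = 1 if r.strand == "+" else -1
            sense_strand = r.strand
            anti_strand = "-" if r.strand == "+" else "+"
            for fp in archetypes[factor]:
                lam = reads_per_footprint * fp.scale(r.ptype, condition) * mult
                if lam <= 0:
                    continue
                n_s = int(rng.poisson(lam))
                n_a = int(rng.poisson(lam))
                if n_s:
                    offs = fp.sense_offset + rng.choice(jit_offsets, size=n_s, p=jit_p)
                    _deposit(track, r.contig, int(r.tss) + sign * offs, sense_strand)
                if n_a:
                    offs = fp.antisense_offset + rng.choice(jit_offsets, size=n_a, p=jit_p)
                    _deposit(track, r.contig, int(r.tss) + sign * offs, anti_strand)
        if background_rate > 0:
            for strand_arrs, strand in ((track.plus, "+"), (track.minus, "-")):
                n_bg = int(rng.poisson(background_rate * contig_lengths[contig]))
                if n_bg:
                    pos = rng.integers(0, contig_lengths[contig], size=n_bg)
                    _deposit(track, contig, pos, strand)
        track.meta["total_aligned_reads"] = max(int(track.total()), 1)
        tracks[factor] = track
    return tracks


def simulate_pause_timecourse(
    truth: TruthTable,
    time_points: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 20.0),
    reads_t0: float = 300.0,
    noise_sd: float = 0.05,
    footprint_halfspan: int = 8,
    background_rate: float = 0.002,
    seed: int | None = None,
) -> dict[float, StrandedTrack]:
    """Pol II stop-count tracks over a decay time course.

    Each promoter's pause footprint (sense peak at pause-halfspan, antisense
    at pause+halfspan) starts with ``reads_t0`` expected reads per strand and
    decays as exp(-ln2 * t / half_life) with multiplicative Gaussian noise of
    sd ``noise_sd``.
    """
    seed = truth.seed if seed is None else seed
    contig = truth.params["contig"]
    contig_lengths = {contig: truth.params["contig_length"]}
    out: dict[float, StrandedTrack] = {}
    for t in time_points:
        rng = _stream(seed, f"timecourse-t{t}")
        track = StrandedTrack.zeros(
            contig_lengths, factor="PolII", condition=f"t{t}", replicate=0,
        )
        for r in truth.promoters.itertuples():
            decay = np.exp(-np.log(2) * t / float(r.half_life))
            lam = reads_t0 * decay * max(
                0.0, 1.0 + rng.normal(0.0, noise_sd)
            )
            sign = 1 if r.strand == "+" else -1
            sense_strand = r.strand
            anti_strand = "-" if r.strand == "+" else "+"
            pause = int(r.pause_pos)
            n_s, n_a = int(rng.poisson(lam)), int(rng.poisson(lam))
            if n_s:
                offs = (pause - footprint_halfspan) + rng.integers(-1, 2, size=n_s)
                _deposit(track, r.contig, int(r.tss) + sign * offs, sense_strand)
            if n_a:
                offs = (pause + footprint_halfspan) + rng.integers(-1, 2, size=n_a)
                _deposit(track, r.contig, int(r.tss) + sign * offs, anti_strand)
        if background_rate > 0:
            for strand in "+-":
                n_bg = int(rng.poisson(background_rate * contig_lengths[contig]))
                if n_bg:
                    pos = rng.integers(0, contig_lengths[contig], size=n_bg)
                    _deposit(track, contig, pos, strand)
        track.meta["total_aligned_reads"] = max(int(track.total()), 1)
        out[t] = track
    return out


def _bump(offsets: np.ndarray, center: float, sd: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((offsets - center) / sd) ** 2)


def dense_tbp_profiles(
    types: list[str],
    window: tuple[int, int] = (-40, 40),
    noise_sd_frac: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Dense per-promoter TBP profile archetypes with additive Gaussian noise.

    Each promoter type maps to a characteristic strand-paired profile shape
    over the inclusive TSS-relative ``window``: TATA promoters a sharp
    -20/-16 peak pair, DPR promoters a dominant +28/+36 downstream pair, TCT
    promoters broad diffuse signal around the TSS, HK promoters the same
    diffuse shape at low amplitude.  Gaussian noise with sd
    ``noise_sd_frac`` of each archetype's peak amplitude is added per
    position.  Returns a promoters x (sense, antisense positions) frame ready
    for rank transformation and clustering.
    """
    rng = _stream(seed, "dense-profiles")
    offs = np.arange(window[0], window[1] + 1)
    shapes: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "TATA": (
            _bump(offs, -20, 1.5, 1.0) + _bump(offs, -6, 4, 0.15),
            _bump(offs, -16, 1.5, 1.0) + _bump(offs, 2, 4, 0.15),
        ),
        "DPR": (
            _bump(offs, 28, 2.0, 1.0) + _bump(offs, -6, 4, 0.2),
            _bump(offs, 36, 2.0, 1.0) + _bump(offs, 2, 4, 0.2),
        ),
        "TCT": (_bump(offs, -4, 9, 0.6), _bump(offs, 4, 9, 0.6)),
        "HK": (_bump(offs, -4, 9, 0.2), _bump(offs, 4, 9, 0.2)),
    }
    cols = [f"sense_{o}" for o in offs] + [f"anti_{o}" for o in offs]
    # noise scales with the global signal amplitude, so the low-amplitude
    # archetype is genuinely noise-dominated in rank space
    amp = max(max(s.max(), a.max()) for s, a in shapes.values())
    rows = []
    for ptype in types:
        sense, anti = shapes[ptype]
        vec = np.concatenate([sense, anti])
        rows.append(vec + rng.normal(0.0, noise_sd_frac * amp, size=vec.size))
    return pd.DataFrame(
        rows, index=[f"p{i:05d}" for i in range(len(types))], columns=cols
    )


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in sorted(genome):
            fh.write(f">{contig}\n")
            seq = genome[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a (small) FASTA into memory via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
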