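"""End-to-end orchestration: simulate -> cluster -> classify -> quantify.

Runs the full promoter-architecture analysis on a synthetic study in
dependency order, writing each stage's tables under an output directory with
a manifest recording config hash, seeds, package version and per-stage
runtimes.  Stages are resumable: a stage whose outputs already exist is
skipped when ``resume=True``, and deleting an intermediate regenerates only
that stage and everything downstream of it on the next run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cage, elements, footprints, occupancy, pause, simulate, tbp_typing
from .signal_io import (
    PromoterRecord,
    extract_profiles,
    pool_replicates,
    read_promoter_bed,
    read_stranded_bedgraph,
    rpm_normalize,
    window_signal,
    write_promoter_bed,
    write_stranded_bedgraph,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

FLOAT_FMT = "%.8g"


@dataclass
class RunConfig:
    outdir: str = "promarch_run"
    seed: int = 1
    n_promoters: int = 200
    conditions: tuple[str, str] = ("control", "triptolide")
    n_cage_replicates: int = 2
    time_points: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 20.0)
    flank: int = 200
    binding_window: tuple[int, int] = (-50, 50)
    cage_window: tuple[int, int] = (-150, 150)
    tbp_cluster_window: tuple[int, int] = (-40, 40)
    upstream_window: tuple[int, int] = (-25, -10)
    downstream_window: tuple[int, int] = (25, 40)
    kmeans_k: int = 4
    kmeans_restarts: int = 100
    kmeans_max_iter: int = 30
    cluster_max_dist: int = 30
    aggregate_max_dist: int = 100
    tpm_min: float = 0.5
    single_tss_tpm_min: float = 3.0
    narrow_width_max: int = 11
    pause_min_mean_signal: float = 1.0  # synthetic scale; 20 for genome-scale RPM data
    resume: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class _Ctx:
    cfg: RunConfig
    out: Path
    manifest: dict = field(default_factory=dict)


def _done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def _factors() -> list[str]:
    return sorted(simulate.default_archetypes())


def _bedgraph_paths(out: Path, factor: str, condition: str) -> tuple[Path, Path]:
    base = out / "sim"
    return (
        base / f"{factor}_{condition}_plus.bedgraph",
        base / f"{factor}_{condition}_minus.bedgraph",
    )


def _timecourse_paths(out: Path, t: float) -> tuple[Path, Path]:
    base = out / "sim"
    return (
        base / f"PolII_t{t:g}_plus.bedgraph",
        base / f"PolII_t{t:g}_minus.bedgraph",
    )


def _stage_simulate(ctx: _Ctx) -> list[Path]:
    cfg = ctx.cfg
    sim_dir = ctx.out / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    outputs = [sim_dir / "genome.fa", sim_dir / "truth.json",
               sim_dir / "promoters_true.bed"]
    outputs += [sim_dir / f"ctss_rep{r}.tsv" for r in range(cfg.n_cage_replicates)]
    for factor in _factors():
        for cond in cfg.conditions:
            outputs += list(_bedgraph_paths(ctx.out, factor, cond))
    for t in cfg.time_points:
        outputs += list(_timecourse_paths(ctx.out, t))
    if cfg.resume and _done(outputs):
        return outputs
    genome, truth = simulate.make_genome(
        n_promoters=cfg.n_promoters, seed=cfg.seed
    )
    simulate.write_fasta(genome, sim_dir / "genome.fa")
    truth.to_json(sim_dir / "truth.json")
    write_promoter_bed(truth.records(), sim_dir / "promoters_true.bed")
    for r, df in enumerate(
        simulate.simulate_ctss(truth, n_replicates=cfg.n_cage_replicates)
    ):
        cage.write_ctss(df, sim_dir / f"ctss_rep{r}.tsv")
    for cond in cfg.conditions:
        tracks = simulate.simulate_chipnexus(truth, condition=cond)
        for factor, track in tracks.items():
            write_stranded_bedgraph(track, *_bedgraph_paths(ctx.out, factor, cond))
    for t, track in simulate.simulate_pause_timecourse(
        truth, time_points=cfg.time_points
    ).items():
        write_stranded_bedgraph(track, *_timecourse_paths(ctx.out, t))
    return outputs


def _contig_lengths(ctx: _Ctx) -> dict[str, int]:
    truth = simulate.TruthTable.from_json(ctx.out / "sim" / "truth.json")
    return {truth.params["contig"]: truth.params["contig_length"]}


def _load_track(ctx: _Ctx, factor: str, condition: str):
    plus, minus = _bedgraph_paths(ctx.out, factor, condition)
    track = read_stranded_bedgraph(
        plus, minus, _contig_lengths(ctx), factor=factor, condition=condition
    )
    track.meta["total_aligned_reads"] = max(int(track.total()), 1)
    return rpm_normalize(track)


def _stage_cage(ctx: _Ctx) -> list[Path]:
    cfg = ctx.cfg
    cage_dir = ctx.out / "cage"
    cage_dir.mkdir(parents=True, exist_ok=True)
    outputs = [cage_dir / "consensus_clusters.tsv", cage_dir / "promoters.bed"]
    if cfg.resume and _done(outputs):
        return outputs
    tables = [
        cage.read_ctss(ctx.out / "sim" / f"ctss_rep{r}.tsv")
        for r in range(cfg.n_cage_replicates)
    ]
    normalized = [cage.powerlaw_normalize(df) for df in tables]
    per_sample = [cage.cluster_ctss(df, cfg.cluster_max_dist) for df in normalized]
    consensus = cage.aggregate_clusters(
        per_sample, normalized, cfg.aggregate_max_dist, cfg.tpm_min
    )
    promoters = cage.select_promoters(
        consensus, cfg.single_tss_tpm_min, cfg.narrow_width_max
    )
    rows = [
        {"promoter_id": p.promoter_id, "contig": c.contig, "strand": c.strand,
         "start": c.start, "end": c.end, "q_low": c.q_low, "q_up": c.q_up,
         "iq_width": c.iq_width, "dominant_tss": c.dominant, "tpm": c.tpm,
         "tpm_max_sample": c.tpm_max_sample}
        for p, c in zip(
            cage.select_promoters(consensus, -1.0, cfg.narrow_width_max), consensus
        )
    ]
    pd.DataFrame(rows).to_csv(
        outputs[0], sep="\t", index=False, float_format=FLOAT_FMT
    )
    narrow = [p for p in promoters if p.narrow]
    write_promoter_bed(narrow, outputs[1])
    return outputs


def _load_promoters(ctx: _Ctx) -> list[PromoterRecord]:
    return read_promoter_bed(ctx.out / "cage" / "promoters.bed")


def _stage_classify(ctx: _Ctx) -> list[Path]:
    out_dir = ctx.out / "classify"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "calls.tsv"]
    if ctx.cfg.resume and _done(outputs):
        return outputs
    genome = simulate.read_fasta(ctx.out / "sim" / "genome.fa")
    promoters = _load_promoters(ctx)
    seqs = {
        p.promoter_id: simulate.promoter_window_seq(genome, p, -80, 60)
        for p in promoters
    }
    calls = elements.classify_promoters(seqs, -80)
    pd.DataFrame(
        [
            {"promoter_id": c.promoter_id,
             "present_elements": ",".join(sorted(c.present_elements)),
             "labels": ",".join(sorted(c.labels)),
             "primary_label": c.primary_label}
            for c in calls
        ]
    ).to_csv(outputs[0], sep="\t", index=False)
    return outputs


def _stage_profiles(ctx: _Ctx) -> list[Path]:
    cfg = ctx.cfg
    out_dir = ctx.out / "profiles"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [
        out_dir / f"binding_totals_{cond}.tsv" for cond in cfg.conditions
    ] + [out_dir / "metaprofiles_control.tsv"]
    if cfg.resume and _done(outputs):
        return outputs
    promoters = _load_promoters(ctx)
    meta_rows = {}
    for cond in cfg.conditions:
        totals = {}
        for factor in _factors():
            track = _load_track(ctx, factor, cond)
            prof = extract_profiles(track, promoters, cfg.flank)
            totals[factor] = pd.Series(
                window_signal(prof, cfg.binding_window, "sum", "both"),
                index=prof.promoter_ids,
            )
            if cond == "control":
                sense, anti = prof.metaprofile()
                meta_rows[f"{factor}_sense"] = sense
                meta_rows[f"{factor}_antisense"] = anti
        df = pd.DataFrame(totals)
        df.index.name = "promoter_id"
        df.to_csv(
            out_dir / f"binding_totals_{cond}.tsv", sep="\t",
            float_format=FLOAT_FMT,
        )
    meta = pd.DataFrame(meta_rows, index=np.arange(-cfg.flank, cfg.flank + 1))
    meta.index.name = "offset"
    meta.to_csv(outputs[-1], sep="\t", float_format=FLOAT_FMT)
    return outputs


def _stage_footprints(ctx: _Ctx) -> list[Path]:
    cfg = ctx.cfg
    out_dir = ctx.out / "footprints"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "footprint_calls.tsv", out_dir / "modules.tsv"]
    if cfg.resume and _done(outputs):
        return outputs
    promoters = _load_promoters(ctx)
    cond = cfg.conditions[1] if len(cfg.conditions) > 1 else cfg.conditions[0]
    rows = []
    pca_profiles = {}
    for factor in _factors():
        track = _load_track(ctx, factor, cond)
        prof = extract_profiles(track, promoters, cfg.flank)
        sense, anti = prof.metaprofile()
        s_peaks = footprints.find_peaks(sense, prof.offsets)
        a_peaks = footprints.find_peaks(anti, prof.offsets)
        for call in footprints.pair_and_midpoint(s_peaks, a_peaks, factor=factor):
            call.region_label = footprints.assign_region(call.midpoint)
            rows.append(
                {"factor": factor, "sense_peak": call.sense_peak_offset,
                 "antisense_peak": call.antisense_peak_offset,
                 "midpoint": call.midpoint, "height": call.height,
                 "region": call.region_label}
            )
        i0 = prof.offset_index(-50)
        i1 = prof.offset_index(50)
        pca_profiles[factor] = np.concatenate(
            [sense[i0 : i1 + 1], anti[i0 : i1 + 1]]
        )
    pd.DataFrame(rows).to_csv(
        outputs[0], sep="\t", index=False, float_format=FLOAT_FMT
    )
    mod = footprints.pca_modules(pca_profiles, seed=cfg.seed)
    mod_df = mod.coordinates.iloc[:, :2].copy()
    mod_df["module"] = mod.modules
    mod_df.index.name = "factor"
    mod_df.to_csv(outputs[1], sep="\t", float_format=FLOAT_FMT)
    return outputs


def _stage_tbp(ctx: _Ctx) -> list[Path]:
    cfg = ctx.cfg
    out_dir = ctx.out / "tbp"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "clusters.tsv", out_dir / "centroids.tsv",
               out_dir / "enrichment.tsv", out_dir / "cluster_labels.tsv"]
    if cfg.resume and _done(outputs):
        return outputs
    promoters = _load_promoters(ctx)
    track = _load_track(ctx, "TBP", cfg.conditions[0])
    prof = extract_profiles(track, promoters, cfg.flank)
    kept = tbp_typing.select_top_signal(prof, cfg.tbp_cluster_window)
    feats = tbp_typing.profile_feature_matrix(
        prof, cfg.tbp_cluster_window, kept
    )
    ranked = tbp_typing.rank_transform(feats)
    model = tbp_typing.kmeans_profiles(
        ranked, cfg.kmeans_k, cfg.kmeans_restarts, cfg.kmeans_max_iter, cfg.seed
    )
    genome = simulate.read_fasta(ctx.out / "sim" / "genome.fa")
    by_id = {p.promoter_id: p for p in promoters}
    seqs = {
        pid: simulate.promoter_window_seq(genome, by_id[pid], -80, 60)
        for pid in kept
    }
    presence = elements.element_presence(seqs, -80, zero_mismatch=True)
    enrich = elements.element_enrichment(model.labels, presence)
    amplitude = (
        feats.sum(axis=1).groupby(model.labels).mean()
    )
    names = tbp_typing.label_clusters(model, enrich, amplitude)
    model.labels.rename("cluster").to_frame().assign(
        type_label=lambda d: d["cluster"].map(names)
    ).rename_axis("promoter_id").to_csv(outputs[0], sep="\t")
    pd.DataFrame(model.centroids, columns=feats.columns).rename_axis(
        "cluster"
    ).to_csv(outputs[1], sep="\t", float_format=FLOAT_FMT)
    enrich.to_csv(outputs[2], sep="\t", index=False, float_format=FLOAT_FMT)
    pd.Series(names, name="type_label").rename_axis("cluster").to_csv(
        outputs[3], sep="\t"
    )
    return outputs


def _cage_scores(ctx: _Ctx, promoters: list[PromoterRecord]) -> pd.Series:
    """CAGE expression score per promoter: normalized tag signal in the
    cage_window around the TSS, summed over replicates and averaged."""
    cfg = ctx.cfg
    tables = [
        cage.powerlaw_normalize(
            cage.read_ctss(ctx.out / "sim" / f"ctss_rep{r}.tsv")
        )
        for r in range(cfg.n_cage_replicates)
    ]
    scores = {}
    lo, hi = cfg.cage_window
    for p in promoters:
        total = 0.0
        for df in tables:
            sel = df[
                (df["contig"] == p.contig)
                & (df["strand"] == p.strand)
                & (df["pos"] >= p.tss + 1 + (lo if p.strand == "+" else -hi))
                & (df["pos"] <= p.tss + 1 + (hi if p.strand == "+" else -lo))
            ]
            total += float(sel["count"].sum())
        scores[p.promoter_id] = total / len(tables)
    return pd.Series(scores, name="cage_score")


def _stage_normalize(ctx: _Ctx) -> list[Path]:
    cfg = ctx.cfg
    out_dir = ctx.out / "normalize"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "normalized_occupancy.tsv", out_dir / "type_tests.tsv"]
    if cfg.resume and _done(outputs):
        return outputs
    promoters = _load_promoters(ctx)
    scores = _cage_scores(ctx, promoters)
    totals = pd.read_csv(
        ctx.out / "profiles" / f"binding_totals_{cfg.conditions[0]}.tsv",
        sep="\t", index_col="promoter_id",
    )
    calls = pd.read_csv(
        ctx.out / "classify" / "calls.tsv", sep="\t", index_col="promoter_id"
    )
    norm = {}
    for factor in totals.columns:
        norm[factor] = occupancy.normalize_by_cage(totals[factor], scores)
    norm_df = pd.DataFrame(norm)
    norm_df.index.name = "promoter_id"
    norm_df.to_csv(outputs[0], sep="\t", float_format=FLOAT_FMT)
    rows = []
    labels = calls["primary_label"].reindex(norm_df.index)
    for factor in norm_df.columns:
        a = norm_df.loc[labels == "TATA", factor].dropna()
        b = norm_df.loc[labels == "DPR", factor].dropna()
        if len(a) >= 2 and len(b) >= 2:
            stat, p, med = occupancy.compare_types(a, b)
            rows.append(
                {"factor": factor, "group_a": "TATA", "group_b": "DPR",
                 "n_a": len(a), "n_b": len(b), "U": stat, "p": p,
                 "median_diff": med}
            )
    pd.DataFrame(rows).to_csv(
        outputs[1], sep="\t", index=False, float_format=FLOAT_FMT
    )
    return outputs


def _stage_correlate(ctx: _Ctx) -> list[Path]:
    cfg = ctx.cfg
    out_dir = ctx.out / "correlate"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "similarity_pcc.tsv", out_dir / "linkage.tsv",
               out_dir / "correlation_delta.tsv"]
    if cfg.resume and _done(outputs):
        return outputs
    totals = {
        cond: pd.read_csv(
            ctx.out / "profiles" / f"binding_totals_{cond}.tsv",
            sep="\t", index_col="promoter_id",
        )
        for cond in cfg.conditions
    }
    sim = occupancy.factor_similarity(totals[cfg.conditions[0]])
    sim.correlation.rename_axis("factor").to_csv(
        outputs[0], sep="\t", float_format=FLOAT_FMT
    )
    pd.DataFrame(
        sim.linkage, columns=["left", "right", "height", "size"]
    ).to_csv(outputs[1], sep="\t", index=False, float_format=FLOAT_FMT)
    promoters = _load_promoters(ctx)
    tbp_windows = {}
    for cond in cfg.conditions:
        track = _load_track(ctx, "TBP", cond)
        prof = extract_profiles(track, promoters, cfg.flank)
        tbp_windows[cond] = {
            "upstream": pd.Series(
                window_signal(prof, cfg.upstream_window, "sum", "both"),
                index=prof.promoter_ids,
            ),
            "downstream": pd.Series(
                window_signal(prof, cfg.downstream_window, "sum", "both"),
                index=prof.promoter_ids,
            ),
        }
    tafs = [f for f in totals[cfg.conditions[0]].columns if f != "TBP"]
    delta = occupancy.correlation_delta(
        tbp_windows,
        {c: totals[c][tafs] for c in cfg.conditions},
        control=cfg.conditions[0],
        treated=cfg.conditions[1],
    )
    delta.to_csv(outputs[2], sep="\t", index=False, float_format=FLOAT_FMT)
    return outputs


def _stage_halflife(ctx: _Ctx) -> list[Path]:
    cfg = ctx.cfg
    out_dir = ctx.out / "halflife"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "halflife.tsv"]
    if cfg.resume and _done(outputs):
        return outputs
    promoters = _load_promoters(ctx)
    contigs = _contig_lengths(ctx)
    profiles = {}
    # time-course tracks are depth-matched by construction; per-time-point
    # read-depth rescaling would cancel the very decay being fitted
    for t in cfg.time_points:
        plus, minus = _timecourse_paths(ctx.out, t)
        track = read_stranded_bedgraph(plus, minus, contigs, factor="PolII")
        profiles[t] = extract_profiles(track, promoters, cfg.flank)
    t0 = cfg.time_points[0]
    criteria = pause.PauseCriteria(min_mean_signal=cfg.pause_min_mean_signal)
    paused = pause.select_paused(profiles[t0], criteria)
    times = np.asarray(cfg.time_points, dtype=float)
    rows = []
    fits = {}
    for pid, row in paused.iterrows():
        w = (
            row["pause_pos"] - criteria.quant_window_halfwidth,
            row["pause_pos"] + criteria.quant_window_halfwidth,
        )
        sigs = []
        for t in cfg.time_points:
            prof = profiles[t]
            i = prof.promoter_ids.index(pid)
            vals = window_signal(prof, w, "sum", "both")
            sigs.append(float(vals[i]))
        fit = pause.fit_decay(times, np.asarray(sigs), promoter_id=pid)
        fits[pid] = fit
    if fits:
        hl = pd.Series({pid: f.half_life for pid, f in fits.items()})
        quint = pause.quintile_rank(hl) if len(hl) >= 5 else pd.Series(
            1, index=hl.index
        )
        for pid, f in fits.items():
            rows.append(
                {"promoter_id": pid,
                 "pause_pos": int(paused.loc[pid, "pause_pos"]),
                 "s0": f.s0, "k": f.k, "half_life": f.half_life,
                 "floored": f.floored, "quintile": int(quint.loc[pid])}
            )
    pd.DataFrame(
        rows, columns=["promoter_id", "pause_pos", "s0", "k", "half_life",
                       "floored", "quintile"]
    ).to_csv(outputs[0], sep="\t", index=False, float_format=FLOAT_FMT)
    return outputs


STAGES = (
    ("simulate", _stage_simulate),
    ("cage", _stage_cage),
    ("classify", _stage_classify),
    ("profiles", _stage_profiles),
    ("footprints", _stage_footprints),
    ("cluster_tbp", _stage_tbp),
    ("normalize", _stage_normalize),
    ("correlate", _stage_correlate),
    ("halflife", _stage_halflife),
)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages in dependency order; returns (and writes) the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ctx = _Ctx(cfg=cfg, out=out)
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }
    for name, fn in STAGES:
        t0 = time.monotonic()
        logger.info("stage %s starting", name)
        try:
            outputs = fn(ctx)
        except Exception:
            logger.error("stage %s failed", name)
            raise
        manifest["stages"][name] = {
            "outputs": [str(p.relative_to(out)) for p in outputs],
            "runtime_s": round(time.monotonic() - t0, 3),
        }
        logger.info("stage %s done", name)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
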