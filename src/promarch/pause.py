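"""Paused Pol II selection, exponential-decay fitting and half-life quintiles.

Promoter-proximally paused Pol II leaves a paired-peak ChIP-nexus footprint
just downstream of the TSS.  After blocking initiation, the paused signal
decays; fitting S(t) = S0 * exp(-k t) to a time course of signal in a 51 bp
window centered on the pause position gives a per-promoter pausing half-life
ln(2)/k.  Half-lives above 60 min are floored to 60 min (noise inflates slow
decays), and promoters are ranked into five quintiles from shortest- to
longest-lived pausing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .signal_io import ProfileMatrix, window_signal

__all__ = [
    "PauseCriteria",
    "DecayFit",
    "select_paused",
    "fit_decay",
    "quintile_rank",
]

HALF_LIFE_CAP = 60.0  # min


@dataclass
class PauseCriteria:
    """Selection thresholds for promoters with a paused Pol II footprint."""

    min_mean_signal: float = 20.0  # RPM, mean over assessment_window both strands
    max_footprint_span: int = 80  # bp between sense and antisense maxima
    max_pause_offset: int = 80  # bp downstream of TSS
    quant_window_halfwidth: int = 25  # 51 bp window centered on pause midpoint
    assessment_window: tuple[int, int] = (-100, 100)


@dataclass
class DecayFit:
    promoter_id: str
    s0: float
    k: float  # 1/min
    half_life: float  # min, capped at 60
    rss: float
    floored: bool = False
    quintile: int = 0


def select_paused(
    profile: ProfileMatrix, criteria: PauseCriteria | None = None
) -> pd.DataFrame:
    """Promoters with a typical paused Pol II footprint, and their pause position.

    A promoter is kept when (1) its mean Pol II signal over the assessment
    window (both strands) exceeds ``min_mean_signal``, (2) the antisense-strand
    maximum lies downstream of the sense-strand maximum by less than
    ``max_footprint_span`` bp, and (3) the pause position (midpoint of the two
    maxima, truncated toward zero) lies within [0, ``max_pause_offset``) bp
    downstream of the TSS.  Returns a frame indexed by promoter id with
    sense_max, antisense_max and pause_pos columns.
    """
    criteria = criteria or PauseCriteria()
    mean_sig = window_signal(
        profile, criteria.assessment_window, mode="mean", strands="both"
    )
    rows = []
    for i, pid in enumerate(profile.promoter_ids):
        if mean_sig[i] <= criteria.min_mean_signal:
            continue
        s_off = int(profile.offsets[np.argmax(profile.sense[i])])
        a_off = int(profile.offsets[np.argmax(profile.antisense[i])])
        if a_off <= s_off or a_off - s_off >= criteria.max_footprint_span:
            continue
        pause = int((s_off + a_off) / 2)
        if not 0 <= pause < criteria.max_pause_offset:
            continue
        rows.append(
            {"promoter_id": pid, "sense_max": s_off, "antisense_max": a_off,
             "pause_pos": pause}
        )
    return pd.DataFrame(rows, columns=["promoter_id", "sense_max",
                                       "antisense_max", "pause_pos"]
                        ).set_index("promoter_id")


def _exp_decay(t, s0, k):
    return s0 * np.exp(-k * t)


def fit_decay(
    time_points: np.ndarray, signals: np.ndarray, promoter_id: str = ""
) -> DecayFit:
    """Least-squares exponential decay fit of a pause-signal time course.

    The fit is initialized from a log-linear regression on the positive
    signals and refined by nonlinear least squares.  A non-positive decay
    rate (non-decaying signal) and any half-life above 60 min are floored to
    a 60 min half-life with ``floored=True``.
    """
    t = np.asarray(time_points, dtype=float)
    s = np.asarray(signals, dtype=float)
    if len(t) != len(s):
        raise ValueError("time and signal lengths differ")
    if len(t) < 2:
        raise ValueError("fit_decay requires >= 2 time points")
    if np.any(s < 0):
        raise ValueError("signals must be non-negative")
    if not np.any(s > 0):
        raise ValueError("all-zero signal cannot be fitted")
    pos = s > 0
    if pos.sum() >= 2 and len(np.unique(t[pos])) >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(s[pos]), 1)
        k0, s0_0 = -float(slope), float(np.exp(intercept))
    else:
        k0, s0_0 = np.log(2) / 10.0, float(s.max())
    floored = False
    if k0 <= 0:
        k, s0 = k0, s0_0
        floored = True
    else:
        try:
            popt, _ = curve_fit(
                _exp_decay, t, s, p0=(max(s0_0, 1e-9), max(k0, 1e-9)),
                maxfev=10_000, xtol=1e-10, ftol=1e-12,
            )
            s0, k = float(popt[0]), float(popt[1])
        except RuntimeError:
            s0, k = s0_0, k0
    if k <= 0 or np.log(2) / k > HALF_LIFE_CAP:
        half_life = HALF_LIFE_CAP
        floored = True
    else:
        half_life = float(np.log(2) / k)
    rss = float(np.sum((s - _exp_decay(t, s0 if k > 0 else s0_0, max(k, 0))) ** 2))
    return DecayFit(
        promoter_id=promoter_id, s0=float(s0), k=float(k),
        half_life=half_life, rss=rss, floored=floored,
    )


def quintile_rank(half_lives: pd.Series) -> pd.Series:
    """Quintile (1 = shortest, 5 = longest half-life) per promoter.

    Promoters are sorted by half-life ascending, ties broken by promoter id,
    and split into five groups whose sizes differ by at most one; when n is
    not divisible by 5 the extra promoters go to the extreme quintiles first
    (1, 5, 2, 4, then 3).
    """
    n = len(half_lives)
    if n < 5:
        raise ValueError("quintile_rank requires >= 5 promoters")
    order = half_lives.reset_index()
    order.columns = ["promoter_id", "half_life"]
    order = order.sort_values(["half_life", "promoter_id"], kind="stable")
    base, rem = divmod(n, 5)
    sizes = [base] * 5
    for q in [0, 4, 1, 3, 2][:rem]:
        sizes[q] += 1
    labels = np.repeat(np.arange(1, 6), sizes)
    out = pd.Series(labels, index=order["promoter_id"], name="quintile")
    return out.loc[half_lives.index]
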