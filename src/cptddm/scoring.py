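"""Standard CPT-AX performance measures and EZ input moments.

A *hit* is a go trial answered within the 200-1,650 ms window from
target onset; responses faster than 200 ms are treated as anticipatory
and count as misses under the single hit definition used throughout
(they are excluded from the accuracy numerator, not merely from the RT
pool).  A *commission error* is any response on one of the 360 no-go
trials.  RT mean and variability are computed over hit RTs only, with
the sample (n-1) denominator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import Session
from .ddm import SummaryStats

__all__ = [
    "RT_WINDOW_MS",
    "StandardMeasures",
    "InsufficientData",
    "score_session",
    "ez_inputs_from_session",
    "N_GO",
    "N_NOGO",
]

#: Valid response window for a hit, ms from target onset.
RT_WINDOW_MS = (200.0, 1650.0)

N_GO = 40
N_NOGO = 360


class InsufficientData(ValueError):
    """Too few hits to form the RT moments (n_hits <= 1)."""


@dataclass(frozen=True)
class StandardMeasures:
    """The four standard task-performance measures for one session.

    ``mrt_ms``/``sdrt_ms`` are NaN when undefined (no hits, or a single
    hit for the SD).
    """

    hit_rate_pct: float
    commission_pct: float
    mrt_ms: float
    sdrt_ms: float
    n_hits: int


def _hit_rts(session: Session) -> tuple[np.ndarray, int, int]:
    """Return (hit RTs in ms, n_go, n_nogo_responses)."""
    lo, hi = RT_WINDOW_MS
    hits = []
    n_go = 0
    n_nogo_resp = 0
    for t in session.trials:
        if t.trial_type == "go":
            n_go += 1
            if t.responded and lo <= t.rt_ms <= hi:
                hits.append(t.rt_ms)
        elif t.responded:
            n_nogo_resp += 1
    return np.asarray(hits, dtype=float), n_go, n_nogo_resp


def score_session(session: Session) -> StandardMeasures:
    """Compute hit rate, commission rate and correct-RT moments.

    Raises ValueError if the session violates its structural invariants.
    """
    session.validate()
    rts, n_go, n_nogo_resp = _hit_rts(session)
    n_nogo = len(session.trials) - n_go
    n_hits = rts.size
    mrt = float(rts.mean()) if n_hits >= 1 else math.nan
    sdrt = float(rts.std(ddof=1)) if n_hits >= 2 else math.nan
    return StandardMeasures(
        hit_rate_pct=100.0 * n_hits / n_go,
        commission_pct=100.0 * n_nogo_resp / n_nogo,
        mrt_ms=mrt,
        sdrt_ms=sdrt,
        n_hits=int(n_hits),
    )


def ez_inputs_from_session(session: Session) -> SummaryStats:
    """EZ-DDM input moments (Pc, MRT in s, VRT in s^2) for one session.

    Uses the same windowed hit definition as :func:`score_session`, so
    Pc always equals hit_rate_pct / 100 on the same session.

    Raises
    ------
    InsufficientData
        If fewer than two hits exist (the RT variance is undefined).
    """
    session.validate()
    rts, n_go, _ = _hit_rts(session)
    if rts.size <= 1:
        raise InsufficientData(
            f"{rts.size} valid hit(s): cannot form RT variance"
        )
    rts_s = rts / 1000.0
    return SummaryStats(
        pc=rts.size / n_go,
        mrt=float(rts_s.mean()),
        vrt=float(rts_s.var(ddof=1)),
    )
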