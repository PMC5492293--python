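"""Resampling, synchronization, step detection and turn/straight segmentation.

A walking session is recorded by three tri-axial accelerometers (lower back
``LB``, left shank ``LS``, right shank ``RS``) whose clocks drift slightly
around a nominal 50 Hz and whose recordings start at slightly different
moments.  This module brings the three streams onto a shared uniform 50 Hz
time base, detects foot strikes as vertical-acceleration peaks, and cuts the
session into *turn* sections (standardized to five steps, with a 0.2 s buffer
before the first and after the last step) and the complementary *straight*
sections.

Turns are located from the characteristic drop in vertical acceleration
magnitude while the walker pivots: a sliding-window RMS of the lower-back
vertical channel is compared against its session median, and sustained
low-RMS runs are taken as turn candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

log = logging.getLogger(__name__)

SITES = ("LB", "LS", "RS")
#: axis order of every tri-axial array: vertical, medial-lateral, anterior-posterior
AXES = ("V", "ML", "AP")
SAMPLE_RATE = 50.0
DT = 1.0 / SAMPLE_RATE


@dataclass(frozen=True)
class RawRecording:
    """One sensor's timestamped tri-axial acceleration trace (units: g)."""

    site: str
    time_s: np.ndarray          # (n,), strictly increasing
    accel: np.ndarray           # (n, 3): vertical, ML, AP
    nominal_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.accel, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "accel", a)
        if self.site not in SITES:
            raise ValueError(f"unknown sensor site {self.site!r}; expected one of {SITES}")
        if t.ndim != 1 or t.size < 2:
            raise ValueError("recording needs at least 2 samples")
        if a.shape != (t.size, 3):
            raise ValueError(f"accel must be (n, 3); got {a.shape} for n={t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time_s must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise ValueError("recording contains non-finite values")

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class Session:
    """Three synchronized, uniformly resampled 50 Hz signals on one time base."""

    time_s: np.ndarray                    # shared grid, spacing 0.02 s
    signals: dict                         # site -> (n, 3) array
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        if set(self.signals) != set(SITES):
            raise ValueError(f"session must contain exactly sites {SITES}")
        n = self.time_s.size
        for site, sig in self.signals.items():
            if sig.shape != (n, 3):
                raise ValueError(f"site {site} has shape {sig.shape}, expected ({n}, 3)")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class StepSeries:
    """Detected foot-strike peak indices for one sensor site."""

    site: str
    step_indices: np.ndarray      # strictly increasing sample indices

    def __post_init__(self) -> None:
        idx = np.asarray(self.step_indices, dtype=int)
        object.__setattr__(self, "step_indices", idx)
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("step indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.step_indices.size)


@dataclass(frozen=True)
class WalkSegment:
    """A labeled turn or straight section, closed-open in sample indices."""

    kind: str                     # "turn" | "straight"
    start_idx: int
    end_idx: int
    steps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.kind not in ("turn", "straight"):
            raise ValueError(f"segment kind must be turn|straight, got {self.kind!r}")
        if not self.start_idx < self.end_idx:
            raise ValueError("segment must satisfy start_idx < end_idx")
        object.__setattr__(self, "steps", np.asarray(self.steps, dtype=int))
        if self.kind == "turn" and len(self.steps) != 5:
            raise ValueError("turn segments are standardized to exactly 5 steps")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


def resample_50hz(rec: RawRecording) -> RawRecording:
    """Resample a recording onto a uniform 0.02 s grid.

    Cubic-spline interpolation is used (falling back to linear when fewer
    than 4 samples are available): at gait sampling rates a linear
    interpolant would distort frequency content near 5 Hz by several
    percent, while a spline keeps the waveform faithful to well below
    0.01 g.  The output grid spans the input time range starting at the
    first input timestamp.  Idempotent on already-uniform 50 Hz input.
    """
    t = rec.time_s
    n_out = int(np.floor((t[-1] - t[0]) / DT)) + 1
    grid = t[0] + DT * np.arange(n_out)
    if t.size >= 4:
        accel = CubicSpline(t, rec.accel, axis=0)(grid)
    else:
        accel = np.column_stack(
            [np.interp(grid, t, rec.accel[:, k]) for k in range(3)])
    return RawRecording(site=rec.site, time_s=grid, accel=accel, nominal_rate=SAMPLE_RATE)


def _first_sync_peak(rec: RawRecording, prominence: float) -> int:
    peaks, _ = find_peaks(rec.accel[:, 0], prominence=prominence)
    if peaks.size == 0:
        raise ValueError(
            f"no vertical peak with prominence >= {prominence} g found for site {rec.site}"
        )
    return int(peaks[0])


def synchronize(
    recs: list[RawRecording],
    prominence: float = 1.0,
    trim_s: float = 0.5,
) -> Session:
    """Align three resampled recordings on their first large vertical peak.

    Each signal is time-shifted so that its first vertical local maximum with
    the given prominence (in practice, the shared synchronization spike) lands
    at time 0; the signals are then truncated to their common overlap.
    ``trim_s`` seconds immediately after the sync peak are discarded so the
    spike itself does not contaminate step detection.
    """
    by_site = {r.site: r for r in recs}
    if set(by_site) != set(SITES):
        raise ValueError(f"synchronize needs one recording per site {SITES}")
    shifted = {}
    for site, rec in by_site.items():
        i0 = _first_sync_peak(rec, prominence)
        shifted[site] = (rec.time_s - rec.time_s[i0], rec)

    t_start = max(ts[0] for ts, _ in shifted.values())
    t_end = min(ts[-1] for ts, _ in shifted.values())
    t_start = max(t_start, trim_s)
    if t_end - t_start < 1.0:
        raise ValueError("recordings share less than 1 s of overlap after alignment")

    n = int(np.floor((t_end - t_start) / DT)) + 1
    grid = t_start + DT * np.arange(n)
    signals = {}
    for site, (ts, rec) in shifted.items():
        signals[site] = np.column_stack(
            [np.interp(grid, ts, rec.accel[:, k]) for k in range(3)]
        )
    return Session(time_s=grid, signals=signals)


def detect_steps(
    session: Session,
    site: str,
    min_separation_s: float = 0.3,
    prominence: float = 0.3,
) -> StepSeries:
    """Detect foot strikes as vertical-acceleration peaks.

    Peaks must be separated by at least ``min_separation_s`` (default 0.3 s,
    i.e. a cadence ceiling of 200 steps/min) and exceed ``prominence`` g.
    """
    v = session.signals[site][:, 0]
    distance = max(1, int(round(min_separation_s * session.sample_rate)))
    peaks, _ = find_peaks(v, distance=distance, prominence=prominence)
    return StepSeries(site=site, step_indices=peaks)


def _low_rms_runs(low: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, keeping those >= min_len."""
    padded = np.diff(np.concatenate(([0], low.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def segment_turns(
    session: Session,
    steps_by_site: dict,
    theta: float = 0.7,
    window_s: float = 1.0,
    min_run_s: float = 0.5,
    buffer_s: float = 0.2,
    driver_site: str = "LB",
) -> list[WalkSegment]:
    """Locate turns from the drop in vertical acceleration magnitude.

    The sliding-window RMS (window ``window_s``) of the driver site's vertical
    channel is compared with its session median; maximal runs where
    RMS < theta * median lasting at least ``min_run_s`` are turn candidates.
    Each candidate is standardized to five steps: the detected driver-site
    step nearest the RMS minimum plus two steps on each side, with a
    ``buffer_s`` margin before the first and after the last step.  Candidates
    without five available steps are dropped; overlaps are resolved by keeping
    the candidate with the deeper RMS minimum.
    """
    rate = session.sample_rate
    v = session.signals[driver_site][:, 0]
    win = max(1, int(round(window_s * rate)))
    rms = np.sqrt(uniform_filter1d(v**2, size=win, mode="nearest"))
    med = float(np.median(rms))
    runs = _low_rms_runs(rms < theta * med, max(1, int(round(min_run_s * rate))))

    steps = steps_by_site[driver_site].step_indices
    buf = int(round(buffer_s * rate))
    candidates = []
    seen_centres = set()
    for s, e in runs:
        i_min = s + int(np.argmin(rms[s:e]))
        if steps.size == 0:
            continue
        c = int(np.argmin(np.abs(steps - i_min)))
        if c - 2 < 0 or c + 2 >= steps.size:
            log.debug("turn candidate at %d dropped: fewer than 5 available steps", i_min)
            continue
        if c in seen_centres:
            continue
        seen_centres.add(c)
        five = steps[c - 2 : c + 3]
        start = int(five[0]) - buf
        end = int(five[-1]) + buf + 1
        if start < 0 or end > session.n_samples:
            continue
        candidates.append((float(rms[i_min]), start, end, five))

    # greedy overlap resolution: deeper RMS minimum wins
    candidates.sort(key=lambda c: c[0])
    kept: list[tuple[float, int, int, np.ndarray]] = []
    for cand in candidates:
        if all(cand[2] <= k[1] or cand[1] >= k[2] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c[1])
    return [WalkSegment("turn", s, e, five) for _, s, e, five in kept]


def segment_straight(
    session: Session,
    turns: list[WalkSegment],
    steps: StepSeries,
    buffer_s: float = 0.2,
    min_strides: int = 3,
) -> list[WalkSegment]:
    """Complement of the turn segments, trimmed and filtered by stride count.

    Gaps between consecutive turns (and the session edges) are trimmed by
    ``buffer_s`` at every turn junction; gaps holding fewer than
    ``min_strides`` strides of the reference foot (consecutive same-site
    strike pairs) are discarded.
    """
    buf = int(round(buffer_s * session.sample_rate))
    bounds = [0] + [b for t in sorted(turns, key=lambda t: t.start_idx)
                    for b in (t.start_idx, t.end_idx)] + [session.n_samples]
    out = []
    for i in range(0, len(bounds), 2):
        s, e = bounds[i], bounds[i + 1]
        if i > 0:
            s += buf
        if i + 2 < len(bounds):
            e -= buf
        if s >= e:
            continue
        inside = steps.step_indices[(steps.step_indices >= s) & (steps.step_indices < e)]
        if inside.size - 1 < min_strides:
            log.debug("straight gap [%d, %d) dropped: %d strides", s, e, inside.size - 1)
            continue
        out.append(WalkSegment("straight", int(s), int(e), inside))
    return out


def segment_session(
    session: Session,
    theta: float = 0.7,
    window_s: float = 1.0,
    step_separation_s: float = 0.3,
    step_prominence: float = 0.3,
    reference_site: str = "LS",
) -> tuple[dict, list[WalkSegment], list[WalkSegment]]:
    """Full segmentation convenience: detect steps on all sites, then cut.

    Returns ``(steps_by_site, turns, straights)``.  Sessions yielding fewer
    than two turns are flagged via a warning (candidates for exclusion, as
    poor turn segmentation makes the turn condition unusable).
    """
    steps_by_site = {site: detect_steps(session, site, step_separation_s, step_prominence)
                     for site in SITES}
    turns = segment_turns(session, steps_by_site, theta=theta, window_s=window_s)
    if len(turns) < 2:
        log.warning("session flagged: only %d turn(s) segmented", len(turns))
    straights = segment_straight(session, turns, steps_by_site[reference_site])
    return steps_by_site, turns, straights


__all__ = [
    "SITES", "AXES", "SAMPLE_RATE",
    "RawRecording", "Session", "StepSeries", "WalkSegment",
    "resample_50hz", "synchronize", "detect_steps",
    "segment_turns", "segment_straight", "segment_session",
]
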