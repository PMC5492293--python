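"""Seeded generator of labeled synthetic six-minute-walk accelerometer sessions.

Real cohort recordings for this kind of study are rarely shareable, so the
generator emulates the statistical structure the downstream analysis relies
on: ~6 min sessions of alternating straight passes and turns; periodic foot
strike impulses in the vertical channel; a reduced vertical magnitude over
each five-step turn; and three class-relevant knobs —

* ``asymmetry`` scales alternate (left vs right) step amplitudes by
  ``1 +/- asymmetry``.  A symmetric gait is periodic at the *step* period, so
  its spectrum lives only on even harmonics of the stride frequency; the
  alternate-step scaling injects odd stride harmonics and therefore lowers
  the ratio of even to odd harmonics (REOH).
* ``hf_noise_power`` adds band-limited noise above 12.5 Hz, lowering the
  first-quartile FFT fraction (FQFFT).
* ``section_variability`` draws a per-section amplitude scale with the given
  coefficient of variation, inflating the across-section SD aggregates.

Signal model (vertical channel, in g): each foot strike contributes a
raised-cosine impulse ``a * 0.5 * (1 + cos(2*pi*(t - t_step)/w))`` of width
``w`` equal to half the step period, on top of a small harmonic series of the
step frequency.  The whole vertical channel is multiplied by
``turn_attenuation`` inside each planted turn interval.  The AP channel
carries phase-lagged biphasic (sine-lobe) impulses with the same left/right
amplitude scaling; the ML channel carries a stride-frequency sway plus an
extra low-frequency component during turns.  A sharp synchronization spike
(3x step amplitude) is planted at a common instant on all three sensors,
whose clocks start at different offsets and run at slightly different rates.

All times in the planted truth are relative to the synchronization spike, so
they line up with session time after :func:`turngait.preprocess.synchronize`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .preprocess import RawRecording, SITES

#: labels for the two prospective-fall outcome classes
LABELS = ("NF", "PF")

_SYNC_SPIKE_WIDTH = 0.08     # s
_SYNC_SPIKE_GAIN = 3.0       # x step_amplitude; unambiguous first peak
_WALK_START = 1.0            # s between spike and first step
_NOISE_FLOOR = 0.01          # g, broadband sensor noise


@dataclass(frozen=True)
class GaitProfile:
    """Generative parameters of one walker.

    Defaults describe a clean, symmetric, steady gait: 1.9 Hz step frequency
    (cadence 114 steps/min), 1 g vertical impulse peaks, straight passes of
    25 s walkway cycle time, and a vertical magnitude drop to half during
    turns.
    """

    step_frequency: float = 1.9           # Hz
    step_amplitude: float = 1.0           # g, vertical impulse peak
    harmonic_weights: tuple = (1.0, 0.35, 0.15)   # step-frequency harmonics
    asymmetry: float = 0.0                # in [0, 1): left/right amplitude split
    hf_noise_power: float = 0.0           # g^2, band-limited > 12.5 Hz
    section_variability: float = 0.0      # CV of per-section amplitude
    turn_attenuation: float = 0.5         # in (0, 1): vertical multiplier in turns
    walkway_time_s: float = 25.0          # s per straight pass incl. the turn
    sample_rate_jitter: float = 0.004     # fractional deviation from 50 Hz

    def validate(self) -> None:
        if not self.step_frequency > 0:
            raise ValueError("step_frequency must be > 0")
        if not 0 <= self.asymmetry < 1:
            raise ValueError("asymmetry must lie in [0, 1)")
        if not 0 < self.turn_attenuation < 1:
            raise ValueError("turn_attenuation must lie in (0, 1)")
        if self.hf_noise_power < 0:
            raise ValueError("hf_noise_power must be >= 0")
        if not self.step_amplitude > 0:
            raise ValueError("step_amplitude must be > 0")
        if not self.walkway_time_s > 0:
            raise ValueError("walkway_time_s must be > 0")
        if self.section_variability < 0:
            raise ValueError("section_variability must be >= 0")
        if self.sample_rate_jitter < 0:
            raise ValueError("sample_rate_jitter must be >= 0")


def nf_profile(**overrides) -> GaitProfile:
    """Default non-faller profile: mild asymmetry, low noise, steady sections."""
    base = dict(asymmetry=0.05, hf_noise_power=0.0005, section_variability=0.05)
    base.update(overrides)
    return GaitProfile(**base)


def pf_profile(**overrides) -> GaitProfile:
    """Default prospective-faller profile.

    Elevated step-to-step asymmetry (lower REOH), high-frequency content
    (lower FQFFT) and inter-section variability (larger SD aggregates)
    relative to :func:`nf_profile`.  Effect sizes are the generator's own
    choices, not measured population values.
    """
    base = dict(asymmetry=0.20, hf_noise_power=0.003, section_variability=0.12)
    base.update(overrides)
    return GaitProfile(**base)


@dataclass(frozen=True)
class SyntheticSession:
    """Three per-site recordings plus the planted ground truth."""

    recordings: dict                 # site -> RawRecording
    label: str                       # "PF" | "NF"
    truth: dict                      # turn intervals, per-foot step times, sections

    def __post_init__(self) -> None:
        if set(self.recordings) != set(SITES):
            raise ValueError(f"session needs exactly one recording per site {SITES}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        iv = self.truth["turn_intervals"]
        for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
            if not (a0 < a1 <= b0 < b1):
                raise ValueError("truth turn intervals must be disjoint and ordered")


def _build_schedule(profile: GaitProfile, duration: float):
    """Plant step times and alternating straight/turn sections.

    One walkway cycle (straight pass plus the turn at its end) lasts
    ``walkway_time_s``.  Feet alternate left, right, ...; every turn consists
    of exactly 5 consecutive steps.  Times are relative to the sync spike.
    """
    dt = 1.0 / profile.step_frequency
    pulse_half = 0.25 * dt            # half width of the raised-cosine impulse
    n_turn = 5
    straight_span = profile.walkway_time_s - n_turn * dt
    n_straight = max(2, int(round(straight_span * profile.step_frequency)))

    t = _WALK_START
    foot = 0                          # 0 = left, 1 = right
    step_times, step_feet, step_section = [], [], []
    sections = []                     # (kind, t_start, t_end)
    turn_intervals = []
    end_margin = 0.5

    # walking continues until the clock runs out: turns only happen when the
    # full five-step pivot fits, but the final straight pass may be partial
    # (the walker is stopped mid-pass when the test ends)
    while t + dt <= duration - end_margin:
        kind = "turn" if sections and sections[-1][0] == "straight" else "straight"
        if kind == "turn" and t + n_turn * dt > duration - end_margin:
            kind = "straight"
        n_steps = n_turn if kind == "turn" else n_straight
        s_start = t
        planted = 0
        for _ in range(n_steps):
            if kind == "straight" and t + dt > duration - end_margin:
                break
            step_times.append(t)
            step_feet.append(foot)
            step_section.append(len(sections))
            foot ^= 1
            t += dt
            planted += 1
        if planted == 0:
            break
        sections.append((kind, s_start, t))
        if kind == "turn":
            first, last = step_times[-n_turn], step_times[-1]
            turn_intervals.append((first - pulse_half, last + pulse_half))
    return (
        np.array(step_times),
        np.array(step_feet),
        np.array(step_section),
        sections,
        turn_intervals,
        pulse_half,
    )


def _add_pulses(t: np.ndarray, out: np.ndarray, times: np.ndarray,
                amps: np.ndarray, half_width: float, biphasic: bool) -> None:
    """Accumulate compact-support impulses centred at ``times`` into ``out``."""
    for t0, a in zip(times, amps):
        i0 = int(np.searchsorted(t, t0 - half_width))
        i1 = int(np.searchsorted(t, t0 + half_width))
        if i1 <= i0:
            continue
        ph = (t[i0:i1] - t0) / (2.0 * half_width)       # in [-0.5, 0.5]
        if biphasic:
            out[i0:i1] += a * np.sin(2.0 * np.pi * ph)
        else:
            out[i0:i1] += a * 0.5 * (1.0 + np.cos(2.0 * np.pi * ph))


def _hf_noise(rng: np.random.Generator, n: int, rate: float, power: float) -> np.ndarray:
    """Band-limited Gaussian noise above 12.5 Hz with the requested power (g^2)."""
    if power <= 0 or n < 30:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = butter(4, 12.5 / (rate / 2.0), btype="highpass", output="sos")
    x = sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x * (np.sqrt(power) / rms) if rms > 0 else np.zeros(n)


def simulate_session(profile: GaitProfile, duration: float, label: str,
                     seed: int) -> SyntheticSession:
    """Simulate one walking session on three jittered-clock sensors.

    ``duration`` is the nominal session length in seconds (>= 30).  Identical
    arguments (including ``seed``) reproduce bit-identical recordings.
    """
    profile.validate()
    if not duration >= 30:
        raise ValueError("duration must be >= 30 s")
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    rng = np.random.default_rng(int(seed))

    (step_times, step_feet, step_section, sections,
     turn_intervals, pulse_half) = _build_schedule(profile, duration)

    # per-section amplitude scale (CV = section_variability); the tails are
    # clipped at 0.8-1.3 of nominal, since a walker does not halve or double
    # their vertical impulse between passes of the same test
    n_sections = len(sections)
    sec_scale = 1.0 + profile.section_variability * rng.standard_normal(n_sections)
    sec_scale = np.clip(sec_scale, 0.8, 1.3)

    # per-step amplitudes: side split (left 1+a, right 1-a) times section scale
    side = np.where(step_feet == 0, 1.0 + profile.asymmetry, 1.0 - profile.asymmetry)
    step_amp = profile.step_amplitude * side * sec_scale[step_section]

    f_step = profile.step_frequency
    f_stride = f_step / 2.0
    A = profile.step_amplitude
    hw = np.asarray(profile.harmonic_weights, dtype=float)
    if hw.size:
        hw = hw / hw[0]

    # piecewise-constant section envelope for the continuous components
    sec_edges = np.array([s[1] for s in sections] + [np.inf])

    def envelope(t: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(sec_edges, t, side="right") - 0, 0, n_sections - 1)
        return sec_scale[idx]

    # per-sensor clocks: rate jitter and start offset (sensor started first)
    site_jitter = {s: profile.sample_rate_jitter * rng.uniform(-1.0, 1.0) for s in SITES}
    # every sensor is switched on 0.1-0.4 s before the sync tap, so the
    # spike is never the literal first sample of a recording
    site_offset = {s: rng.uniform(-0.4, -0.1) for s in SITES}
    site_weights = {  # own-foot impulses dominate the shank sensors; the
        # contralateral strike arrives only as a small transmitted transient
        "LB": (1.0, 1.0), "LS": (1.0, 0.1), "RS": (0.1, 1.0),
    }
    phase = {"LB": 0.0, "LS": 0.7, "RS": 2.1}
    # the trunk rides a continuous harmonic sway; a shank is comparatively
    # quiet between its own strikes
    harm_gain = {"LB": 0.15, "LS": 0.05, "RS": 0.05}

    recordings = {}
    for site in SITES:
        rate = 50.0 * (1.0 + site_jitter[site])
        n = int(np.floor((duration - site_offset[site]) * rate))
        rec_time = np.arange(n) / rate
        t = rec_time + site_offset[site]          # true (spike-relative) time

        wl, wr = site_weights[site]
        foot_w = np.where(step_feet == 0, wl, wr)

        vert = np.zeros(n)
        _add_pulses(t, vert, step_times, step_amp * foot_w, pulse_half, biphasic=False)
        env = envelope(t)
        walking = (t >= _WALK_START) & (t <= sections[-1][2] if sections else False)
        for k, w in enumerate(hw[1:], start=2):
            vert += np.where(walking, harm_gain[site] * A * w * env
                             * np.cos(2 * np.pi * k * f_step * t + phase[site]), 0.0)
        # vertical magnitude drop over each planted turn window
        for a0, a1 in turn_intervals:
            mask = (t >= a0) & (t < a1)
            vert[mask] *= profile.turn_attenuation

        ap = np.zeros(n)
        _add_pulses(t, ap, step_times + 0.08, 0.5 * step_amp * foot_w,
                    pulse_half, biphasic=True)

        ml = np.where(walking, 0.3 * A * env
                      * np.sin(2 * np.pi * f_stride * t + phase[site]), 0.0)
        for a0, a1 in turn_intervals:
            mask = (t >= a0) & (t < a1)
            ml[mask] += 0.35 * A * np.sin(2 * np.pi * 0.4 * (t[mask] - a0))

        # shared synchronization spike at true t = 0 on the vertical channel
        _add_pulses(t, vert, np.array([0.0]),
                    np.array([_SYNC_SPIKE_GAIN * A]), _SYNC_SPIKE_WIDTH / 2,
                    biphasic=False)

        accel = np.column_stack([vert, ml, ap])
        accel += _NOISE_FLOOR * rng.standard_normal(accel.shape)
        for k in range(3):
            accel[:, k] += _hf_noise(rng, n, rate, profile.hf_noise_power)

        recordings[site] = RawRecording(site=site, time_s=rec_time, accel=accel,
                                        nominal_rate=rate)

    truth = {
        "turn_intervals": [(float(a), float(b)) for a, b in turn_intervals],
        "steps": {
            "left": [float(x) for x in step_times[step_feet == 0]],
            "right": [float(x) for x in step_times[step_feet == 1]],
        },
        "sections": [(k, float(a), float(b)) for k, a, b in sections],
        "sync_offset_s": {s: float(-site_offset[s]) for s in SITES},
    }
    return SyntheticSession(recordings=recordings, label=label, truth=truth)


def simulate_cohort(n_nf: int, n_pf: int, nf: GaitProfile | None = None,
                    pf: GaitProfile | None = None, duration: float = 360.0,
                    seed: int = 0) -> list[SyntheticSession]:
    """Simulate a labeled cohort; participant ``i`` uses seed ``seed + i``.

    NF sessions come first.  By default the PF profile carries elevated
    asymmetry, high-frequency noise power and section variability.
    """
    if n_nf < 0 or n_pf < 0:
        raise ValueError("cohort counts must be >= 0")
    if n_nf + n_pf < 4:
        raise ValueError("cohort must contain at least 4 participants")
    nf = nf if nf is not None else nf_profile()
    pf = pf if pf is not None else pf_profile()
    sessions = []
    for i in range(n_nf + n_pf):
        label = "NF" if i < n_nf else "PF"
        profile = nf if label == "NF" else pf
        sessions.append(simulate_session(profile, duration, label, int(seed) + i))
    return sessions


def write_session(session: SyntheticSession, outdir: str | Path,
                  participant_id: str) -> list[Path]:
    """Write one CSV per sensor site plus a JSON truth/label sidecar.

    CSV columns: ``time_s, ax, ay, az`` with axes ordered vertical, ML, AP;
    files named ``{participant_id}_{site}.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for site, rec in session.recordings.items():
        path = outdir / f"{participant_id}_{site}.csv"
        data = np.column_stack([rec.time_s, rec.accel])
        header = "time_s,ax,ay,az"
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.6f")
        written.append(path)
    sidecar = outdir / f"{participant_id}_truth.json"
    with open(sidecar, "w") as fh:
        json.dump({"participant_id": participant_id, "label": session.label,
                   "truth": session.truth}, fh, indent=1)
    written.append(sidecar)
    return written


__all__ = [
    "LABELS", "GaitProfile", "SyntheticSession",
    "nf_profile", "pf_profile",
    "simulate_session", "simulate_cohort", "write_session",
]
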