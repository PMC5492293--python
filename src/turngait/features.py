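"""Per-section gait features and their participant-level aggregation.

Each turn or straight section yields 74 named features:

* per shank site (LS, RS): 18 directional descriptive statistics
  (max/mean/SD of the positive- and negative-direction samples, for each of
  the vertical, ML and AP axes), 3 FQFFT values and 3 REOH values = 24;
* for the lower back (LB): the same 24 plus cadence (steps/min) and stride
  time (s) = 26.

Directional statistics are computed per stride and averaged over the
section's strides; FQFFT and REOH are computed once on the whole section
signal, since a single ~1 s stride at 50 Hz cannot resolve stride-frequency
harmonics.  A participant's feature vector per walking condition takes the
maximum, minimum, mean and sample SD of each of the 74 features across all
of that participant's sections of the condition (4 x 74 = 296 features);
concatenating both conditions gives 592.

Feature names are ``{site}|{stat}_{direction}|{axis}`` for directional
statistics (e.g. ``LS|max_anterior|AP``), ``{site}|FQFFT|{axis}`` and
``{site}|REOH|{axis}`` for the spectral ratios, and ``LB|cadence``,
``LB|stride_time`` for the temporal pair.  Aggregated names are prefixed
``{agg}|``, condition-combined names ``{condition}|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import AXES, SITES, Session, StepSeries, WalkSegment

log = logging.getLogger(__name__)

#: positive/negative direction labels per axis (axis order V, ML, AP)
DIRECTIONS = {"V": ("up", "down"), "ML": ("right", "left"),
              "AP": ("anterior", "posterior")}
STATS = ("max", "mean", "sd")
AGGREGATES = ("max", "min", "mean", "sd")
N_SECTION_FEATURES = 74
N_CONDITION_FEATURES = 296
N_COMBINED_FEATURES = 592


def section_feature_names() -> list[str]:
    """The 74 canonical per-section feature names, in fixed order."""
    names = []
    for site in SITES:
        for axis in AXES:
            for direction in DIRECTIONS[axis]:
                for stat in STATS:
                    names.append(f"{site}|{stat}_{direction}|{axis}")
        for axis in AXES:
            names.append(f"{site}|FQFFT|{axis}")
        for axis in AXES:
            names.append(f"{site}|REOH|{axis}")
        if site == "LB":
            names.append("LB|cadence")
            names.append("LB|stride_time")
    assert len(names) == N_SECTION_FEATURES
    return names


SECTION_FEATURE_NAMES = section_feature_names()


@dataclass(frozen=True)
class SectionFeatures:
    """The 74 named features of one turn or straight section."""

    kind: str
    values: dict                      # name -> float (NaN = missing)

    def __post_init__(self) -> None:
        if len(self.values) != N_SECTION_FEATURES:
            raise ValueError(
                f"section must carry exactly {N_SECTION_FEATURES} features, "
                f"got {len(self.values)}"
            )


@dataclass(frozen=True)
class ParticipantFeatures:
    """Aggregated feature vector of one participant for one condition."""

    participant_id: str
    label: str
    condition: str                    # "turn" | "straight" | "combined"
    values: dict                      # name -> float

    def __post_init__(self) -> None:
        expected = (N_COMBINED_FEATURES if self.condition == "combined"
                    else N_CONDITION_FEATURES)
        if len(self.values) != expected:
            raise ValueError(
                f"{self.condition} vector must have {expected} features, "
                f"got {len(self.values)}"
            )


@dataclass(frozen=True)
class FeatureMatrix:
    """Participants x named features, plus the PF/NF label per row."""

    X: pd.DataFrame                   # index: participant_id
    labels: pd.Series                 # "PF" | "NF", aligned with X

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.labels.index):
            raise ValueError("feature rows and labels must share an index")
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.X.isna().any().any():
            raise ValueError("feature matrix must have no missing values")

    @property
    def n(self) -> int:
        return len(self.X)


def directional_stats(stride_signal: np.ndarray) -> tuple[float, ...]:
    """(max, mean, SD) over positive samples and over |negative| samples.

    A direction with no samples yields zeros; SD uses ddof=1 and is 0 when a
    direction holds fewer than 2 samples.
    """
    x = np.asarray(stride_signal, dtype=float)
    if x.size < 2:
        raise ValueError("stride must have at least 2 samples")
    out = []
    for part in (x[x > 0], -x[x < 0]):
        if part.size == 0:
            out += [0.0, 0.0, 0.0]
        else:
            sd = float(np.std(part, ddof=1)) if part.size > 1 else 0.0
            out += [float(part.max()), float(part.mean()), sd]
    return tuple(out)


def fqfft(section_signal: np.ndarray, rate: float = 50.0,
          band_edge: float = 12.5, use_power: bool = False) -> float:
    """Fraction of spectral content below ``band_edge`` (first-quartile FFT).

    The mean is removed, the one-sided magnitude (or power) spectrum is taken,
    and the sum over 0 < f < band_edge is divided by the sum over
    0 < f <= Nyquist.  An all-zero signal is defined as 1.0 (no
    high-frequency content).
    """
    x = np.asarray(section_signal, dtype=float)
    if x.size < rate:
        raise ValueError("FQFFT needs at least 1 s of signal")
    x = x - x.mean()
    amp = np.abs(np.fft.rfft(x))
    if use_power:
        amp = amp**2
    f = np.fft.rfftfreq(x.size, d=1.0 / rate)
    num = amp[(f > 0) & (f < band_edge)].sum()
    den = amp[(f > 0) & (f <= rate / 2.0)].sum()
    if den == 0:
        log.debug("FQFFT of an all-zero signal defined as 1.0")
        return 1.0
    return float(num / den)


def reoh(section_signal: np.ndarray, stride_frequency: float,
         n_harmonics: int = 20, rate: float = 50.0,
         normalized: bool = True) -> float:
    """Ratio of even to odd harmonics of the stride frequency.

    The amplitude of harmonic k is the magnitude-spectrum value at the FFT
    bin nearest ``k * stride_frequency`` (k = 1..n_harmonics, capped at
    Nyquist).  With ``normalized=True`` (default) the bounded form
    ``sum_even / (sum_even + sum_odd)`` in [0, 1] is returned; otherwise the
    literal quotient ``sum_even / sum_odd``.  A symmetric gait concentrates
    its energy on even stride harmonics (the step frequency and its
    multiples), so lower values indicate step-to-step asymmetry.
    """
    if not stride_frequency > 0:
        raise ValueError("stride_frequency must be > 0")
    x = np.asarray(section_signal, dtype=float)
    x = x - x.mean()
    amp = np.abs(np.fft.rfft(x))
    df = rate / x.size
    even = odd = 0.0
    for k in range(1, n_harmonics + 1):
        fk = k * stride_frequency
        if fk > rate / 2.0:
            break
        b = min(int(round(fk / df)), amp.size - 1)
        if k % 2 == 0:
            even += amp[b]
        else:
            odd += amp[b]
    if even + odd == 0:
        log.debug("REOH undefined on zero spectrum; returning 0.0")
        return 0.0
    return float(even / (even + odd)) if normalized else float(even / odd)


def temporal_features(lb_steps: np.ndarray, ls_steps: np.ndarray,
                      rate: float = 50.0) -> tuple[float, float]:
    """(cadence in steps/min, mean stride time in s) for one section.

    Cadence counts lower-back steps; stride time averages consecutive
    reference-foot (left shank) strike-to-strike intervals.
    """
    lb_steps = np.asarray(lb_steps)
    ls_steps = np.asarray(ls_steps)
    if lb_steps.size < 2 or ls_steps.size < 2:
        raise ValueError("temporal features need >= 2 steps of each series")
    span_s = (lb_steps[-1] - lb_steps[0]) / rate
    cadence = 60.0 * (lb_steps.size - 1) / span_s
    stride_time = float(np.mean(np.diff(ls_steps))) / rate
    return float(cadence), stride_time


def _steps_inside(series: StepSeries, segment: WalkSegment) -> np.ndarray:
    idx = series.step_indices
    return idx[(idx >= segment.start_idx) & (idx < segment.end_idx)]


def section_features(session: Session, segment: WalkSegment,
                     steps_by_site: dict, n_harmonics: int = 20,
                     reoh_normalized: bool = True,
                     fqfft_power: bool = False) -> SectionFeatures | None:
    """Compute the 74 features of one section; None if no complete stride.

    Stride windows are consecutive same-site strike pairs for the shanks;
    lower-back strides are anchored on the left-shank strikes.  Missing
    spectral features (too few strides to estimate stride frequency) are NaN.
    """
    rate = session.sample_rate
    ls_inside = _steps_inside(steps_by_site["LS"], segment)
    lb_inside = _steps_inside(steps_by_site["LB"], segment)

    # stride frequency of the section = 1 / mean stride time (LS reference)
    if ls_inside.size >= 2:
        stride_t = float(np.mean(np.diff(ls_inside))) / rate
        stride_f = 1.0 / stride_t
    else:
        stride_t = stride_f = np.nan

    values: dict[str, float] = {}
    for site in SITES:
        sig = session.signals[site][segment.start_idx:segment.end_idx]
        anchors = ls_inside if site == "LB" else _steps_inside(steps_by_site[site], segment)
        windows = [(int(a - segment.start_idx), int(b - segment.start_idx))
                   for a, b in zip(anchors, anchors[1:]) if b - a >= 2]
        if not windows:
            log.debug("segment [%d, %d) has no complete %s stride; skipped",
                      segment.start_idx, segment.end_idx, site)
            return None
        for ax, axis in enumerate(AXES):
            per_stride = np.array(
                [directional_stats(sig[a:b, ax]) for a, b in windows]
            )
            mean_stats = per_stride.mean(axis=0)
            pos_dir, neg_dir = DIRECTIONS[axis]
            for j, stat in enumerate(STATS):
                values[f"{site}|{stat}_{pos_dir}|{axis}"] = float(mean_stats[j])
            for j, stat in enumerate(STATS):
                values[f"{site}|{stat}_{neg_dir}|{axis}"] = float(mean_stats[3 + j])
        for ax, axis in enumerate(AXES):
            values[f"{site}|FQFFT|{axis}"] = fqfft(sig[:, ax], rate,
                                                   use_power=fqfft_power)
        for ax, axis in enumerate(AXES):
            if np.isfinite(stride_f):
                values[f"{site}|REOH|{axis}"] = reoh(
                    sig[:, ax], stride_f, n_harmonics, rate, reoh_normalized)
            else:
                values[f"{site}|REOH|{axis}"] = np.nan
        if site == "LB":
            if lb_inside.size >= 2 and ls_inside.size >= 2:
                cadence, stime = temporal_features(lb_inside, ls_inside, rate)
            else:
                log.debug("segment lacks steps for temporal features; NaN")
                cadence = stime = np.nan
            values["LB|cadence"] = cadence
            values["LB|stride_time"] = stime

    ordered = {name: values[name] for name in SECTION_FEATURE_NAMES}
    return SectionFeatures(kind=segment.kind, values=ordered)


class ParticipantExcluded(ValueError):
    """Raised when a participant has no usable sections for a condition."""


def aggregate_participant(sections: list[SectionFeatures], condition: str,
                          participant_id: str, label: str) -> ParticipantFeatures:
    """Max/min/mean/SD of each base feature across a participant's sections.

    SD uses ddof=1 and is 0 with a single section.  NaN per-section values
    are excluded from the aggregates; a base feature missing in every section
    excludes the participant.
    """
    matching = [s for s in sections if s.kind == condition]
    if not matching:
        raise ParticipantExcluded(
            f"participant {participant_id} has no {condition} sections")
    table = np.array([[s.values[n] for n in SECTION_FEATURE_NAMES]
                      for s in matching])
    values: dict[str, float] = {}
    for j, name in enumerate(SECTION_FEATURE_NAMES):
        col = table[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ParticipantExcluded(
                f"participant {participant_id}: feature {name} missing in all "
                f"{condition} sections")
        if col.size < table.shape[0]:
            log.debug("participant %s: %d/%d sections missing %s",
                      participant_id, table.shape[0] - col.size,
                      table.shape[0], name)
        values[f"max|{name}"] = float(col.max())
        values[f"min|{name}"] = float(col.min())
        values[f"mean|{name}"] = float(col.mean())
        values[f"sd|{name}"] = float(np.std(col, ddof=1)) if col.size > 1 else 0.0
    return ParticipantFeatures(participant_id=participant_id, label=label,
                               condition=condition, values=values)


def combine_conditions(straight: ParticipantFeatures,
                       turn: ParticipantFeatures) -> ParticipantFeatures:
    """Concatenate a participant's straight and turn vectors (592 features)."""
    if straight.participant_id != turn.participant_id:
        raise ValueError("cannot combine different participants: "
                         f"{straight.participant_id} vs {turn.participant_id}")
    if (straight.condition, turn.condition) != ("straight", "turn"):
        raise ValueError("combine_conditions expects a (straight, turn) pair")
    values = {f"straight|{k}": v for k, v in straight.values.items()}
    values.update({f"turn|{k}": v for k, v in turn.values.items()})
    return ParticipantFeatures(participant_id=straight.participant_id,
                               label=straight.label, condition="combined",
                               values=values)


def build_feature_matrix(participants: list[ParticipantFeatures]) -> FeatureMatrix:
    """Stack participant vectors of one condition into a FeatureMatrix."""
    if not participants:
        raise ValueError("no participants to assemble")
    conditions = {p.condition for p in participants}
    if len(conditions) != 1:
        raise ValueError(f"mixed conditions in one matrix: {conditions}")
    X = pd.DataFrame([p.values for p in participants],
                     index=[p.participant_id for p in participants])
    labels = pd.Series([p.label for p in participants], index=X.index,
                       name="label")
    return FeatureMatrix(X=X, labels=labels)


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """CSV with participant_id, label, then the named feature columns."""
    out = fm.X.copy()
    out.insert(0, "label", fm.labels)
    out.to_csv(path, index_label="participant_id")


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="participant_id")
    labels = df.pop("label")
    return FeatureMatrix(X=df, labels=labels)


__all__ = [
    "DIRECTIONS", "STATS", "AGGREGATES",
    "N_SECTION_FEATURES", "N_CONDITION_FEATURES", "N_COMBINED_FEATURES",
    "SECTION_FEATURE_NAMES", "section_feature_names",
    "SectionFeatures", "ParticipantFeatures", "FeatureMatrix",
    "ParticipantExcluded",
    "directional_stats", "fqfft", "reoh", "temporal_features",
    "section_features", "aggregate_participant", "combine_conditions",
    "build_feature_matrix", "write_feature_matrix", "read_feature_matrix",
]
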