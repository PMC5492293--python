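"""File formats, run configuration, and the session-to-features pipeline.

On-disk formats (all plain text):

* recordings — one CSV per sensor site, columns ``time_s, ax, ay, az``
  (axes ordered vertical, ML, AP), named ``{participant_id}_{site}.csv``;
* truth/label sidecar — ``{participant_id}_truth.json``;
* segments — a TSV with ``kind, start_s, end_s, n_steps`` plus a JSON twin;
* feature matrices — CSV with ``participant_id``, ``label`` and the named
  feature columns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import preprocess as pre
from .preprocess import RawRecording, WalkSegment
from .synthgait import GaitProfile, SyntheticSession, nf_profile, pf_profile

log = logging.getLogger(__name__)

_SITE_RE = re.compile(r"_(LB|LS|RS)\.csv$")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved parameters of a pipeline run.

    Unknown keys are rejected when loading; the resolved config is echoed
    into every output so artifacts are reproducible from (config, seed).
    """

    # cohort
    n_nf: int = 20
    n_pf: int = 20
    duration_s: float = 360.0
    seed: int = 0
    nf_profile_overrides: dict = field(default_factory=dict)
    pf_profile_overrides: dict = field(default_factory=dict)
    # segmentation
    turn_theta: float = 0.7
    rms_window_s: float = 1.0
    step_separation_s: float = 0.3
    step_prominence: float = 0.3
    sync_prominence: float = 1.0
    turn_driver_site: str = "LB"
    reference_site: str = "LS"
    # features
    n_harmonics: int = 20
    reoh_normalized: bool = True
    fqfft_power: bool = False
    # protocol
    n_iter: int = 2500
    test_frac: float = 0.2
    mfo_frac: float = 0.1
    mfo_max_features: int | None = None
    top_n: int = 9

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(d or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_recording(path: str | Path, site: str | None = None) -> RawRecording:
    """Parse a recording CSV; the site is inferred from the filename suffix."""
    path = Path(path)
    if site is None:
        m = _SITE_RE.search(path.name)
        if not m:
            raise ValueError(f"cannot infer sensor site from filename {path.name!r}")
        site = m.group(1)
    df = pd.read_csv(path)
    expected = ["time_s", "ax", "ay", "az"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    bad = df.isna().any(axis=1) | ~np.isfinite(df.to_numpy()).all(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"{path}: malformed value at line {line}")
    t = df["time_s"].to_numpy()
    if not np.all(np.diff(t) > 0):
        line = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise ValueError(f"{path}: non-monotone time at line {line}")
    return RawRecording(site=site, time_s=t,
                        accel=df[["ax", "ay", "az"]].to_numpy())


def write_recording(rec: RawRecording, path: str | Path) -> None:
    data = np.column_stack([rec.time_s, rec.accel])
    np.savetxt(path, data, delimiter=",", header="time_s,ax,ay,az",
               comments="", fmt="%.9f")


def segments_to_frame(segments: list[WalkSegment], rate: float = 50.0,
                      t0: float = 0.0) -> pd.DataFrame:
    rows = [{"kind": s.kind, "start_s": t0 + s.start_idx / rate,
             "end_s": t0 + s.end_idx / rate, "n_steps": len(s.steps)}
            for s in sorted(segments, key=lambda s: s.start_idx)]
    return pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "n_steps"])


def write_segments(segments: list[WalkSegment], path_tsv: str | Path,
                   rate: float = 50.0, t0: float = 0.0) -> None:
    """Segment table as TSV plus a JSON twin next to it."""
    df = segments_to_frame(segments, rate, t0)
    df.to_csv(path_tsv, sep="\t", index=False)
    with open(Path(path_tsv).with_suffix(".json"), "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=1)


# ---------------------------------------------------------------------------
# session -> participant features


def preprocess_recordings(recordings: dict, cfg: RunConfig = RunConfig()):
    """Resample, synchronize and segment one participant's three recordings."""
    resampled = [pre.resample_50hz(r) for r in recordings.values()]
    session = pre.synchronize(resampled, prominence=cfg.sync_prominence)
    steps, turns, straights = pre.segment_session(
        session, theta=cfg.turn_theta, window_s=cfg.rms_window_s,
        step_separation_s=cfg.step_separation_s,
        step_prominence=cfg.step_prominence,
        reference_site=cfg.reference_site)
    return session, steps, turns, straights


def participant_features(recordings: dict, participant_id: str, label: str,
                         cfg: RunConfig = RunConfig()):
    """Full single-participant pipeline to (straight, turn) feature vectors.

    Returns ``(straight, turn)`` ParticipantFeatures; raises
    :class:`~turngait.features.ParticipantExcluded` when a condition yields
    no usable sections.
    """
    session, steps, turns, straights = preprocess_recordings(recordings, cfg)
    sections = []
    for seg in turns + straights:
        sf = feat.section_features(session, seg, steps,
                                   n_harmonics=cfg.n_harmonics,
                                   reoh_normalized=cfg.reoh_normalized,
                                   fqfft_power=cfg.fqfft_power)
        if sf is not None:
            sections.append(sf)
    straight_pf = feat.aggregate_participant(sections, "straight",
                                             participant_id, label)
    turn_pf = feat.aggregate_participant(sections, "turn",
                                         participant_id, label)
    return straight_pf, turn_pf


def cohort_feature_matrices(sessions: list[SyntheticSession],
                            cfg: RunConfig = RunConfig(),
                            ids: list[str] | None = None):
    """Extract (straight, turn) FeatureMatrix pair from simulated sessions.

    Participants whose sessions cannot produce both conditions are excluded
    with a log entry, mirroring cohort exclusions for poor segmentation.
    """
    ids = ids or [f"P{i:03d}" for i in range(len(sessions))]
    straight_rows, turn_rows = [], []
    for pid, session in zip(ids, sessions):
        try:
            s_pf, t_pf = participant_features(session.recordings, pid,
                                              session.label, cfg)
        except (feat.ParticipantExcluded, ValueError) as exc:
            log.warning("participant %s excluded: %s", pid, exc)
            continue
        straight_rows.append(s_pf)
        turn_rows.append(t_pf)
    return (feat.build_feature_matrix(straight_rows),
            feat.build_feature_matrix(turn_rows))


def profiles_from_config(cfg: RunConfig) -> tuple[GaitProfile, GaitProfile]:
    return (nf_profile(**cfg.nf_profile_overrides),
            pf_profile(**cfg.pf_profile_overrides))


__all__ = [
    "RunConfig", "read_recording", "write_recording",
    "segments_to_frame", "write_segments",
    "preprocess_recordings", "participant_features",
    "cohort_feature_matrices", "profiles_from_config",
]
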