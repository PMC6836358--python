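"""Waveform containers, delimited-text I/O, breath segmentation, and
occlusion-maneuver detection.

The universal input is a :class:`WaveformRecording`: synchronized flow,
airway pressure (Paw), esophageal pressure (Pes) and optionally diaphragm
electrical activity (Edi) channels on a uniform time grid, plus recording
metadata (patient id, study day, set PEEP, mode, demographics).

Recordings are stored as comma-delimited text with a single header line
``time,flow,paw,pes[,edi]`` and fixed units (s, L/s, cm H2O, cm H2O, uV).
Metadata travels in a side-car YAML file.  Values are written with 17
significant digits so a write/read round trip is bit-exact.

Breath segmentation follows the flow signal: a breath starts at an upward
flow crossing of a small hysteresis threshold sustained for a minimum
duration, inspiration ends at the subsequent downward zero crossing, and the
breath ends where the next one starts.  Whole-breath end-expiratory
occlusions carry no flow, so they are instead delimited by the Paw
deflection episode below set PEEP.  Spans are 0-based and half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: required channel columns, in file order (edi is optional)
REQUIRED_COLUMNS = ("time", "flow", "paw", "pes")

#: tolerance on time-grid uniformity, seconds
TIME_GRID_TOL = 1e-6


class LoadError(ValueError):
    """Raised when a waveform file fails validation."""


@dataclass
class RecordingMeta:
    """Per-recording metadata.

    ``peep`` is the *set* PEEP (ventilator setting, cm H2O) and is the
    reference for all airway-pressure deflections.  ``sex`` ('M'/'F') and
    ``height_cm`` feed the predicted chest-wall-elastance formula.
    """

    patient_id: str = "P01"
    day: int = 1
    peep: float | None = None
    mode: str = "PSV"
    sex: str | None = None
    height_cm: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "patient_id": self.patient_id,
            "day": int(self.day),
            "peep": None if self.peep is None else float(self.peep),
            "mode": self.mode,
            "sex": self.sex,
            "height_cm": None if self.height_cm is None else float(self.height_cm),
        }
        if self.extra:
            d["extra"] = dict(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        return cls(
            patient_id=str(d.get("patient_id", "P01")),
            day=int(d.get("day", 1)),
            peep=d.get("peep"),
            mode=str(d.get("mode", "PSV")),
            sex=d.get("sex"),
            height_cm=d.get("height_cm"),
            extra=dict(d.get("extra", {})),
        )


@dataclass
class WaveformRecording:
    """Synchronized multi-channel recording on a uniform time grid."""

    time: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    pes: np.ndarray
    sampling_rate: float
    edi: np.ndarray | None = None
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        self.pes = np.asarray(self.pes, dtype=float)
        if self.edi is not None:
            self.edi = np.asarray(self.edi, dtype=float)
        n = self.time.size
        if n < 2:
            raise LoadError("recording must contain at least 2 samples")
        for name in ("flow", "paw", "pes", "edi"):
            ch = getattr(self, name)
            if ch is None:
                continue
            if ch.size != n:
                raise LoadError(
                    f"channel '{name}' length {ch.size} != time length {n}"
                )
            bad = np.flatnonzero(~np.isfinite(ch))
            if bad.size:
                raise LoadError(
                    f"non-finite value in column '{name}' at row {bad[0]}"
                )
        dt = np.diff(self.time)
        step = 1.0 / self.sampling_rate
        if np.max(np.abs(dt - step)) > TIME_GRID_TOL:
            row = int(np.argmax(np.abs(dt - step))) + 1
            raise LoadError(
                f"non-uniform time grid at row {row}: step deviates from "
                f"1/sampling_rate by more than {TIME_GRID_TOL} s"
            )

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_offset(self, paw_offset: float = 0.0, pes_offset: float = 0.0) -> "WaveformRecording":
        """Return a copy with constants added to Paw / Pes (sensor re-zeroing)."""
        return replace(self, paw=self.paw + paw_offset, pes=self.pes + pes_offset)


@dataclass(frozen=True)
class Breath:
    """One respiratory cycle: half-open spans ``[start, insp_end)``
    (inspiration) and ``[insp_end, end)`` (expiration), 0-based sample
    indices.  ``occluded`` marks a whole-breath end-expiratory occlusion."""

    start: int
    insp_end: int
    end: int
    occluded: bool = False

    def __post_init__(self) -> None:
        if not (self.start < self.insp_end < self.end):
            raise ValueError(
                f"invalid breath span ({self.start}, {self.insp_end}, {self.end})"
            )


def default_meta_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.yaml")


def write_recording(rec: WaveformRecording, path: str | Path,
                    meta_path: str | Path | None = None) -> Path:
    """Write a recording as delimited text plus a side-car metadata YAML."""
    path = Path(path)
    cols = {"time": rec.time, "flow": rec.flow, "paw": rec.paw, "pes": rec.pes}
    if rec.edi is not None:
        cols["edi"] = rec.edi
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta_path = default_meta_path(path) if meta_path is None else Path(meta_path)
    meta = rec.meta.to_dict()
    meta["sampling_rate"] = float(rec.sampling_rate)
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_recording(path: str | Path, meta_path: str | Path | None = None,
                   meta: RecordingMeta | None = None) -> WaveformRecording:
    """Read and validate a delimited waveform file.

    Raises :class:`LoadError` naming the offending column/row for missing
    columns, non-finite samples, or a non-uniform time grid.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise LoadError(f"missing required column '{col}' in {path.name}")
    sampling_rate = None
    if meta is None:
        mp = default_meta_path(path) if meta_path is None else Path(meta_path)
        if mp.exists():
            with open(mp) as fh:
                d = yaml.safe_load(fh) or {}
            sampling_rate = d.pop("sampling_rate", None)
            meta = RecordingMeta.from_dict(d)
        else:
            meta = RecordingMeta()
    time = df["time"].to_numpy(dtype=float)
    if sampling_rate is None:
        if time.size < 2:
            raise LoadError("recording must contain at least 2 samples")
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    return WaveformRecording(
        time=time,
        flow=df["flow"].to_numpy(dtype=float),
        paw=df["paw"].to_numpy(dtype=float),
        pes=df["pes"].to_numpy(dtype=float),
        edi=df["edi"].to_numpy(dtype=float) if "edi" in df.columns else None,
        sampling_rate=float(sampling_rate),
        meta=meta,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as half-open (start, stop)."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def _flow_breath_starts(flow: np.ndarray, fs: float, flow_threshold: float,
                        min_insp_s: float) -> list[tuple[int, int]]:
    """(start, insp_end) pairs from hysteresis flow crossings.

    A start is an upward crossing of ``flow_threshold`` sustained for at
    least ``min_insp_s``; inspiration ends at the next downward crossing of
    zero.  Short crossings (cardiac artifact, noise) are rejected.
    """
    min_n = max(1, int(round(min_insp_s * fs)))
    events = []
    for s, e in _runs(flow > flow_threshold):
        if e - s < min_n:
            continue
        # inspiration ends at the first non-positive flow sample after the run
        below = np.flatnonzero(flow[e:] <= 0.0)
        insp_end = e + int(below[0]) if below.size else flow.size
        events.append((int(s), int(insp_end)))
    return events


def _occlusion_episodes(paw: np.ndarray, flow: np.ndarray, fs: float,
                        set_peep: float, flow_threshold: float,
                        paw_threshold: float) -> list[tuple[int, int]]:
    """(start, insp_end) spans of whole-breath occlusion maneuvers.

    An episode is a contiguous stretch where Paw falls more than
    ``paw_threshold`` below set PEEP while flow stays near zero (the one-way
    valve blocks inspiratory flow).  The span is extended outward to where
    the deflection begins/ends (Paw within 0.05 cm H2O of PEEP), capped at
    0.5 s each side.
    """
    mask = (paw < set_peep - paw_threshold) & (np.abs(flow) < flow_threshold)
    pad = int(round(0.5 * fs))
    episodes = []
    for s, e in _runs(mask):
        if e - s < max(2, int(round(0.05 * fs))):
            continue
        s0 = s
        lo = max(0, s - pad)
        while s0 > lo and paw[s0 - 1] < set_peep - 0.05:
            s0 -= 1
        e0 = e
        hi = min(paw.size, e + pad)
        while e0 < hi and paw[e0] < set_peep - 0.05:
            e0 += 1
        episodes.append((int(s0), int(e0)))
    # merge episodes that touch after extension
    merged: list[tuple[int, int]] = []
    for s, e in episodes:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    # report sub-threshold deflections (flagged nowhere, logged only)
    sub = (paw < set_peep - 0.3) & (paw >= set_peep - paw_threshold) \
        & (np.abs(flow) < flow_threshold)
    n_sub = sum(1 for s, e in _runs(sub) if e - s >= int(round(0.2 * fs))
                and not any(a <= s < b for a, b in merged))
    if n_sub:
        logger.info("%d sub-threshold Paw deflections not counted as occlusions",
                    n_sub)
    return merged


def segment_breaths(rec: WaveformRecording, *, flow_threshold: float = 0.02,
                    min_insp_s: float = 0.1, occlusion_paw_threshold: float = 1.0,
                    set_peep: float | None = None) -> list[Breath]:
    """Segment a recording into an ordered, non-overlapping breath list.

    Flow breaths come from hysteresis flow crossings; occlusion maneuvers
    (no flow) are delimited by the Paw deflection episode relative to set
    PEEP (from metadata unless given).  Partial breaths at the recording
    edges are discarded.  Returns an empty list (with a warning) when no
    breaths are found.  Occluded flags are *not* set here; see
    :func:`detect_occlusions`.
    """
    fs = rec.sampling_rate
    events = _flow_breath_starts(rec.flow, fs, flow_threshold, min_insp_s)
    if set_peep is None:
        set_peep = rec.meta.peep
    if set_peep is not None:
        events += _occlusion_episodes(rec.paw, rec.flow, fs, set_peep,
                                      flow_threshold, occlusion_paw_threshold)
    events.sort()
    # drop events nested inside the previous one's inspiration
    pruned: list[tuple[int, int]] = []
    for s, ie in events:
        if pruned and s < pruned[-1][1]:
            continue
        pruned.append((s, ie))
    breaths: list[Breath] = []
    min_tail = int(round(0.3 * fs))
    for i, (s, ie) in enumerate(pruned):
        if ie >= rec.n_samples:  # truncated mid-inspiration
            continue
        end = pruned[i + 1][0] if i + 1 < len(pruned) else rec.n_samples
        if end <= ie:
            continue
        if i + 1 == len(pruned) and rec.n_samples - ie < min_tail:
            continue  # no usable expiration at the recording edge
        breaths.append(Breath(start=s, insp_end=ie, end=end))
    if not breaths:
        logger.warning("no breaths detected in recording %s day %s",
                       rec.meta.patient_id, rec.meta.day)
    return breaths


def detect_occlusions(rec: WaveformRecording, breaths: list[Breath], *,
                      flow_threshold: float = 0.02,
                      paw_threshold: float = 1.0,
                      set_peep: float | None = None) -> list[Breath]:
    """Return breaths with ``occluded`` flags set.

    A breath is flagged when inspiratory-phase flow magnitude stays below
    ``flow_threshold`` while Paw falls more than ``paw_threshold`` below set
    PEEP.  Set PEEP is the deflection reference and must be available.
    """
    if set_peep is None:
        set_peep = rec.meta.peep
    if set_peep is None:
        raise ValueError(
            "set PEEP missing from metadata: required as the reference for "
            "occlusion Paw deflections"
        )
    out: list[Breath] = []
    for b in breaths:
        insp_flow = rec.flow[b.start:b.insp_end]
        no_flow = float(np.max(np.abs(insp_flow))) < flow_threshold
        deflected = float(np.min(rec.paw[b.start:b.end])) < set_peep - paw_threshold
        out.append(replace(b, occluded=bool(no_flow and deflected)))
    n_occ = sum(b.occluded for b in out)
    logger.info("flagged %d occluded breaths of %d", n_occ, len(out))
    return out


def breaths_table(breaths: list[Breath], meta: RecordingMeta | None = None) -> pd.DataFrame:
    """Breath list as a DataFrame (CLI `segment` output)."""
    df = pd.DataFrame(
        [(b.start, b.insp_end, b.end, b.occluded) for b in breaths],
        columns=["start", "insp_end", "end", "occluded"],
    )
    if meta is not None:
        df.insert(0, "patient", meta.patient_id)
        df.insert(1, "day", meta.day)
    return df
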