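"""Audio and annotation I/O for respiratory-sound corpora.

Recordings are mono PCM WAV files; on load every recording is resampled to a
common analysis rate (4000 Hz by default, adequate because the adventitious
sounds of interest live below 2 kHz).  Event annotations use one canonical
per-event TSV dialect with header ``start\\tend\\tlabel`` (seconds, at least
three decimals).  A dataset manifest is a YAML file listing recordings,
participants and the train/test assignment; splitting is always performed at
the participant level so that no participant contributes to both sides.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile
from scipy.signal import resample_poly

from .exceptions import ParseError, ValidationError

DEFAULT_RATE = 4000.0

#: Recognized event labels: the two adventitious classes plus the four
#: negative-class ("other") variants used by the fixed- and variable-duration
#: experiment designs.
LABELS = ("crackle", "wheeze", "other50", "other150", "otherCrackle", "otherWheeze")
ARS_LABELS = ("crackle", "wheeze")
OTHER_LABELS = ("other50", "other150", "otherCrackle", "otherWheeze")


@dataclass
class AudioRecording:
    """A sampled waveform with provenance identifiers.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude samples, dimensionless, nominally in [-1, 1].
    rate : float
        Sampling rate in Hz, > 0.
    participant_id, recording_id : str
        Identifiers; ``recording_id`` must be unique within a manifest.
    """

    samples: np.ndarray
    rate: float
    participant_id: str = ""
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValidationError(f"rate must be > 0, got {self.rate}")
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional (mono)")
        if self.samples.size == 0:
            raise ValidationError("zero-length audio")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.samples.size / self.rate


@dataclass(frozen=True, order=True)
class AnnotatedEvent:
    """A labelled time interval, half-open ``[start, end)`` in seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ManifestEntry:
    recording_id: str
    participant_id: str
    audio_path: str
    events_path: str


@dataclass
class DatasetManifest:
    """Recording inventory plus a participant-level train/test assignment."""

    recordings: list[ManifestEntry] = field(default_factory=list)
    split: dict[str, str] = field(default_factory=dict)  # participant_id -> train/test

    def __post_init__(self) -> None:
        ids = [r.recording_id for r in self.recordings]
        if len(ids) != len(set(ids)):
            raise ValidationError("recording_id values must be unique in a manifest")

    def participants(self) -> list[str]:
        return sorted({r.participant_id for r in self.recordings})


def _to_float(x: np.ndarray) -> np.ndarray:
    if np.issubdtype(x.dtype, np.integer):
        info = np.iinfo(x.dtype)
        scale = max(abs(info.min), info.max)
        return x.astype(np.float64) / scale
    return x.astype(np.float64)


def resample(samples: np.ndarray, rate: float, target_rate: float) -> np.ndarray:
    """Polyphase anti-aliased resampling to ``target_rate``.

    Idempotent when ``rate == target_rate``.
    """
    if target_rate <= 0:
        raise ValidationError("target_rate must be > 0")
    if rate == target_rate:
        return np.asarray(samples, dtype=np.float64)
    ratio = Fraction(target_rate / rate).limit_denominator(10000)
    return resample_poly(np.asarray(samples, dtype=np.float64), ratio.numerator, ratio.denominator)


def load_recording(
    path: str | Path,
    target_rate: float = DEFAULT_RATE,
    participant_id: str = "",
    recording_id: str = "",
) -> AudioRecording:
    """Read a PCM WAV file, average stereo to mono, and resample.

    Downsampling applies an anti-aliasing low-pass filter (polyphase FIR).
    The duration is preserved to within one sample period.
    """
    path = Path(path)
    rate, data = wavfile.read(str(path))
    data = np.atleast_1d(np.asarray(data))
    if data.size == 0:
        raise ValidationError(f"{path}: zero-length audio")
    if data.ndim == 2:
        warnings.warn(f"{path.name}: stereo input averaged to mono", stacklevel=2)
        data = _to_float(data).mean(axis=1)
    else:
        data = _to_float(data)
    out = resample(data, float(rate), float(target_rate))
    return AudioRecording(
        samples=out,
        rate=float(target_rate),
        participant_id=participant_id,
        recording_id=recording_id or path.stem,
    )


def write_recording(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as 16-bit PCM mono WAV (values clipped to [-1, 1])."""
    x = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(str(path), int(round(rec.rate)), (x * 32767.0).astype(np.int16))


def read_events(path: str | Path) -> list[AnnotatedEvent]:
    """Read the canonical event TSV; events are returned sorted by start.

    Raises
    ------
    ParseError
        On a malformed header or row; the message names the line number.
    """
    path = Path(path)
    events: list[AnnotatedEvent] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if header != ["start", "end", "label"]:
            raise ParseError(f"{path}: line 1: expected header 'start\\tend\\tlabel'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(row)}")
            try:
                start, end = float(row[0]), float(row[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric start/end") from None
            if row[2] not in LABELS:
                raise ParseError(f"{path}: line {lineno}: unknown label {row[2]!r}")
            if not (0 <= start < end):
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            events.append(AnnotatedEvent(start, end, row[2]))
    return sorted(events, key=lambda e: (e.start, e.end, e.label))


def write_events(path: str | Path, events: list[AnnotatedEvent]) -> None:
    """Write events in canonical form (sorted, 6-decimal seconds)."""
    events = sorted(events, key=lambda e: (e.start, e.end, e.label))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("start\tend\tlabel\n")
        for ev in events:
            fh.write(f"{ev.start:.6f}\t{ev.end:.6f}\t{ev.label}\n")


def import_rsd_events(path: str | Path, kind: str) -> list[AnnotatedEvent]:
    """Map an ICBHI-style per-event text file onto the canonical dialect.

    The source files are header-less ``start<TAB>end`` listings, one file per
    recording and per class (``kind`` is ``'crackle'`` or ``'wheeze'``).
    """
    if kind not in ARS_LABELS:
        raise ValidationError(f"kind must be one of {ARS_LABELS}")
    events = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns")
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric interval") from None
            events.append(AnnotatedEvent(start, end, kind))
    return sorted(events, key=lambda e: (e.start, e.end))


def split_by_participant(
    manifest: DatasetManifest, assignment: dict[str, str]
) -> tuple[DatasetManifest, DatasetManifest]:
    """Partition a manifest into participant-disjoint train/test manifests.

    Every participant present in the manifest must be assigned to exactly one
    of ``{"train", "test"}``.
    """
    for pid in manifest.participants():
        if pid not in assignment:
            raise ValidationError(f"participant {pid!r} has no train/test assignment")
    for pid, side in assignment.items():
        if side not in ("train", "test"):
            raise ValidationError(f"assignment for {pid!r} must be 'train' or 'test'")
    train = DatasetManifest(
        [r for r in manifest.recordings if assignment[r.participant_id] == "train"],
        {p: "train" for p, s in assignment.items() if s == "train"},
    )
    test = DatasetManifest(
        [r for r in manifest.recordings if assignment[r.participant_id] == "test"],
        {p: "test" for p, s in assignment.items() if s == "test"},
    )
    overlap = set(train.participants()) & set(test.participants())
    assert not overlap, f"participant leakage: {overlap}"
    return train, test


def make_split(manifest: DatasetManifest, test_fraction: float = 0.3, seed: int = 0) -> dict[str, str]:
    """Random participant-level assignment with approximately the requested test share."""
    if not (0 <= test_fraction <= 1):
        raise ValidationError("test_fraction must be in [0, 1]")
    pids = manifest.participants()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    n_test = int(round(test_fraction * len(pids)))
    test_set = {pids[i] for i in order[:n_test]}
    return {p: ("test" if p in test_set else "train") for p in pids}


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    doc = {
        "recordings": [
            {
                "recording_id": r.recording_id,
                "participant_id": r.participant_id,
                "audio": r.audio_path,
                "events": r.events_path,
            }
            for r in manifest.recordings
        ],
        "split": dict(sorted(manifest.split.items())),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path: str | Path) -> DatasetManifest:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = [
        ManifestEntry(
            recording_id=r["recording_id"],
            participant_id=r["participant_id"],
            audio_path=r["audio"],
            events_path=r["events"],
        )
        for r in doc.get("recordings", [])
    ]
    return DatasetManifest(entries, doc.get("split", {}))


def event_to_samples(ev: AnnotatedEvent, rate: float) -> tuple[int, int]:
    """Convert an event interval to sample indices.

    The start is rounded down and the end rounded up so that no sample
    covered by the annotation is dropped.
    """
    return int(math.floor(ev.start * rate)), int(math.ceil(ev.end * rate))


__all__ = [
    "AudioRecording",
    "AnnotatedEvent",
    "DatasetManifest",
    "ManifestEntry",
    "LABELS",
    "ARS_LABELS",
    "OTHER_LABELS",
    "DEFAULT_RATE",
    "load_recording",
    "write_recording",
    "resample",
    "read_events",
    "write_events",
    "import_rsd_events",
    "split_by_participant",
    "make_split",
    "read_manifest",
    "write_manifest",
    "event_to_samples",
]
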