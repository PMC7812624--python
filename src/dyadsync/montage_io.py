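"""Probe/channel data model and file I/O for recordings and coding logs.

The default probe layout is the 16-channel, four-probe-set cap used for
mother-child hyperscanning: 2x2 optode sets over left/right dorsolateral
prefrontal cortex (around AF3/AF4) and left/right temporo-parietal junction
(around CP5/CP6), 3 cm source-detector separation throughout.

Recordings travel as a plain-text TSV dialect (``#key<TAB>value`` header lines
followed by one row per sample with ``w<wavelength>_ch<k>`` columns) so test
fixtures double as format documentation.  A minimal read-only SNIRF (HDF5)
loader is provided for interoperability; nothing in the pipeline requires it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ROIS = ("dlPFC-L", "dlPFC-R", "TPJ-L", "TPJ-R")

#: Conversation-pattern code vocabulary (category composites are built from
#: counts of these codes; ``vocalization`` is the neutral utterance code).
CODE_VOCABULARY = frozenset({
    "alternating_turn",
    "long_turn",
    "relevant",
    "irrelevant",
    "contingent",
    "noncontingent",
    "no_time_for_response",
    "interrupts",
    "simultaneous",
    "vocalization",
})

ROLES = ("mother", "child")


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


@dataclass(frozen=True)
class Channel:
    channel_id: int
    source_id: int
    detector_id: int
    roi: str
    separation_mm: float = 30.0


@dataclass(frozen=True)
class Montage:
    """Source/detector/channel/ROI geometry of the optode cap."""

    sources: tuple[tuple[int, str], ...]
    detectors: tuple[tuple[int, str], ...]
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        src_ids = {s for s, _ in self.sources}
        det_ids = {d for d, _ in self.detectors}
        for ch in self.channels:
            if ch.source_id not in src_ids:
                raise ValidationError(
                    f"channel {ch.channel_id} references unknown source {ch.source_id}")
            if ch.detector_id not in det_ids:
                raise ValidationError(
                    f"channel {ch.channel_id} references unknown detector {ch.detector_id}")
            if ch.roi not in ROIS:
                raise ValidationError(f"channel {ch.channel_id} has unknown ROI {ch.roi!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(ch.channel_id for ch in self.channels)

    def roi_of(self, channel_id: int) -> str:
        for ch in self.channels:
            if ch.channel_id == channel_id:
                return ch.roi
        raise KeyError(channel_id)

    def channels_in_roi(self, roi: str) -> tuple[int, ...]:
        return tuple(ch.channel_id for ch in self.channels if ch.roi == roi)


def build_default_montage() -> Montage:
    """Return the default 8-source/8-detector, 16-channel, 4-ROI montage.

    Four 2x2 probe sets (two sources + two detectors each) yield four channels
    per set.  Channel->ROI assignment is a declared convention: channels 1-4 ->
    dlPFC-L (around AF3), 5-8 -> dlPFC-R (around AF4), 9-12 -> TPJ-L (around
    CP5), 13-16 -> TPJ-R (around CP6).  All separations are 30 mm.
    """
    sources = tuple((i, f"S{i}") for i in range(1, 9))
    detectors = tuple((i, f"D{i}") for i in range(1, 9))
    channels = []
    ch_id = 1
    for probe_set, roi in enumerate(ROIS):
        s1, s2 = 2 * probe_set + 1, 2 * probe_set + 2
        d1, d2 = 2 * probe_set + 1, 2 * probe_set + 2
        # 2x2 set: each source pairs with each detector at 30 mm.
        for s, d in ((s1, d1), (s1, d2), (s2, d1), (s2, d2)):
            channels.append(Channel(ch_id, s, d, roi))
            ch_id += 1
    return Montage(sources, detectors, tuple(channels))


@dataclass
class RawRecording:
    """One subject's raw two-wavelength intensity recording."""

    subject_role: str
    dyad_id: str
    fs: float
    intensity: np.ndarray  # (2 wavelengths, n_channels, n_samples), > 0
    montage: Montage
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        if self.subject_role not in ROLES:
            raise ValidationError(f"subject_role must be one of {ROLES}")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[0] != 2:
            raise ValidationError(
                "intensity must have shape (2, n_channels, n_samples), got "
                f"{self.intensity.shape}")
        if self.intensity.shape[1] != self.montage.n_channels:
            raise ValidationError(
                f"{self.intensity.shape[1]} channels in data but montage has "
                f"{self.montage.n_channels}")
        bad = np.argwhere(~(self.intensity > 0))
        if bad.size:
            w, c, t = bad[0]
            raise ValidationError(
                f"non-positive intensity at wavelength index {w}, channel "
                f"{self.montage.channel_ids[c]}, sample {t}")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class DyadRecording:
    """Paired mother/child recordings, sample counts equalized."""

    mother: RawRecording
    child: RawRecording

    def __post_init__(self) -> None:
        if self.mother.fs != self.child.fs:
            raise ValidationError("mother and child sampling rates differ")
        if self.mother.montage != self.child.montage:
            raise ValidationError("mother and child montages differ")
        if self.mother.n_samples != self.child.n_samples:
            raise ValidationError("member sample counts differ (use pair_dyad)")

    @property
    def dyad_id(self) -> str:
        return self.mother.dyad_id

    @property
    def fs(self) -> float:
        return self.mother.fs

    @property
    def duration_s(self) -> float:
        return self.mother.duration_s


@dataclass(frozen=True)
class CodingEvent:
    speaker: str
    onset_ms: float
    offset_ms: float
    code: str

    def __post_init__(self) -> None:
        if self.speaker not in ROLES:
            raise ValidationError(f"unknown speaker {self.speaker!r}")
        if self.code not in CODE_VOCABULARY:
            raise ValidationError(f"unknown conversation code {self.code!r}")
        if not self.offset_ms > self.onset_ms:
            raise ValidationError(
                f"event offset ({self.offset_ms}) must exceed onset ({self.onset_ms})")


@dataclass
class CodingLog:
    """Per-dyad conversation-coding event log (sorted by onset)."""

    dyad_id: str
    events: list[CodingEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset_ms, e.offset_ms))

    def counts_by_code(self) -> dict[str, int]:
        out = {code: 0 for code in sorted(CODE_VOCABULARY)}
        for ev in self.events:
            out[ev.code] += 1
        return out


def pair_dyad(mother: RawRecording, child: RawRecording) -> DyadRecording:
    """Pair two recordings into a dyad, truncating to the shorter series."""
    if mother.dyad_id != child.dyad_id:
        raise ValidationError(
            f"dyad ids differ: {mother.dyad_id!r} vs {child.dyad_id!r}")
    if mother.fs != child.fs:
        raise ValidationError("sampling rates differ")
    if mother.montage != child.montage:
        raise ValidationError("montages differ")
    if {mother.subject_role, child.subject_role} != {"mother", "child"}:
        raise ValidationError("dyad needs one mother and one child recording")
    n = min(mother.n_samples, child.n_samples)
    if mother.n_samples != n:
        mother = replace(mother, intensity=mother.intensity[:, :, :n])
    if child.n_samples != n:
        child = replace(child, intensity=child.intensity[:, :, :n])
    return DyadRecording(mother=mother, child=child)


# ---------------------------------------------------------------------------
# Recording TSV dialect
# ---------------------------------------------------------------------------

def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording in the documented TSV dialect."""
    path = Path(path)
    wl = rec.wavelengths_nm
    cols = [f"w{int(w)}_ch{cid}" for w in wl for cid in rec.montage.channel_ids]
    data = np.vstack([rec.intensity[iw] for iw in range(2)]).T  # samples x (2*nch)
    with path.open("w") as fh:
        fh.write(f"#fs\t{rec.fs!r}\n")
        fh.write(f"#role\t{rec.subject_role}\n")
        fh.write(f"#dyad_id\t{rec.dyad_id}\n")
        fh.write(f"#wavelengths_nm\t{int(wl[0])},{int(wl[1])}\n")
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, data, delimiter="\t", fmt="%.10g")


def read_recording(path: str | Path, dialect: str = "tsv",
                   montage: Montage | None = None) -> RawRecording:
    """Read a recording written as the TSV dialect or as SNIRF (read-only)."""
    if dialect == "tsv":
        return _read_recording_tsv(path, montage)
    if dialect == "snirf":
        return _read_recording_snirf(path, montage)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_recording_tsv(path: str | Path, montage: Montage | None) -> RawRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    header_rows = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            parts = line[1:].rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"malformed header line {line!r} in {path}")
            meta[parts[0]] = parts[1]
    for key in ("fs", "role", "dyad_id", "wavelengths_nm"):
        if key not in meta:
            raise FormatError(f"missing header key {key!r} in {path}")
    try:
        fs = float(meta["fs"])
        wl = tuple(float(v) for v in meta["wavelengths_nm"].split(","))
    except ValueError as exc:
        raise FormatError(f"unparseable header value in {path}: {exc}") from exc
    if len(wl) != 2:
        raise FormatError("expected exactly two wavelengths")
    frame = pd.read_csv(path, sep="\t", skiprows=header_rows)
    montage = montage or build_default_montage()
    cols = [f"w{int(w)}_ch{cid}" for w in wl for cid in montage.channel_ids]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise FormatError(f"missing data columns {missing[:3]}... in {path}")
    arr = frame[cols].to_numpy(float).T  # (2*nch, nsamp)
    nch = montage.n_channels
    intensity = np.stack([arr[:nch], arr[nch:]], axis=0)
    return RawRecording(subject_role=meta["role"], dyad_id=meta["dyad_id"], fs=fs,
                        intensity=intensity, montage=montage,
                        wavelengths_nm=(wl[0], wl[1]))


def _read_recording_snirf(path: str | Path, montage: Montage | None) -> RawRecording:
    """Minimal SNIRF (HDF5) reader: continuous-wave intensity, one data block."""
    import h5py

    montage = montage or build_default_montage()
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"], dtype=float)  # (nsamp, nmeas)
        t = np.asarray(data["time"], dtype=float)
        if t.size == 2:  # start, step convention
            fs = 1.0 / float(t[1])
        else:
            fs = 1.0 / float(np.median(np.diff(t)))
        wls = np.asarray(nirs["probe"]["wavelengths"], dtype=float)
        meta = nirs.get("metaDataTags", {})

        def _tag(name: str, default: str) -> str:
            if name in meta:
                v = meta[name][()]
                return v.decode() if isinstance(v, bytes) else str(v)
            return default

        role = _tag("SubjectRole", _tag("SubjectID", "mother"))
        dyad = _tag("DyadID", "unknown")
        nch = montage.n_channels
        intensity = np.zeros((2, nch, ts.shape[0]))
        for name, grp in data.items():
            if not name.startswith("measurementList"):
                continue
            idx = int(name[len("measurementList"):]) - 1
            wl_idx = int(np.asarray(grp["wavelengthIndex"])) - 1
            src = int(np.asarray(grp["sourceIndex"]))
            det = int(np.asarray(grp["detectorIndex"]))
            ch = next((c.channel_id for c in montage.channels
                       if c.source_id == src and c.detector_id == det), None)
            if ch is None:
                continue
            intensity[wl_idx, ch - 1] = ts[:, idx]
    if role not in ROLES:
        role = "mother"
    return RawRecording(subject_role=role, dyad_id=dyad, fs=fs,
                        intensity=intensity, montage=montage,
                        wavelengths_nm=(float(wls[0]), float(wls[1])))


# ---------------------------------------------------------------------------
# Coding-log TSV
# ---------------------------------------------------------------------------

CODING_COLUMNS = ("dyad_id", "speaker", "onset_ms", "offset_ms", "code")


def write_coding_log(log: CodingLog, path: str | Path) -> None:
    rows = [(log.dyad_id, e.speaker, e.onset_ms, e.offset_ms, e.code)
            for e in log.events]
    pd.DataFrame(rows, columns=list(CODING_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_coding_log(path: str | Path) -> CodingLog:
    """Read a conversation-coding event table (TSV export).

    Events are sorted by onset and validated against the code vocabulary.
    Identical-speaker events with identical code that overlap in time are
    merged (with a warning) into a single spanning event.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in CODING_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"coding log missing columns {missing}")
    if frame.empty:
        return CodingLog(dyad_id="unknown", events=[])
    dyads = frame["dyad_id"].unique()
    if len(dyads) != 1:
        raise FormatError(f"coding log must contain one dyad, found {list(dyads)}")
    events = [CodingEvent(r.speaker, float(r.onset_ms), float(r.offset_ms), r.code)
              for r in frame.itertuples()]
    events.sort(key=lambda e: (e.onset_ms, e.offset_ms))
    merged: list[CodingEvent] = []
    for ev in events:
        if (merged and ev.speaker == merged[-1].speaker
                and ev.code == merged[-1].code
                and ev.onset_ms < merged[-1].offset_ms):
            warnings.warn(
                f"merging overlapping {ev.speaker} events at {ev.onset_ms} ms",
                stacklevel=2)
            prev = merged.pop()
            ev = CodingEvent(ev.speaker, prev.onset_ms,
                             max(prev.offset_ms, ev.offset_ms), ev.code)
        merged.append(ev)
    return CodingLog(dyad_id=str(dyads[0]), events=merged)
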