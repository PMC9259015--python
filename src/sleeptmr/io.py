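"""Data model and file I/O for the TMR sleep-EEG pipeline.

Holds the four containers every stage shares — the continuous recording,
the 30-s-epoch hypnogram, the auditory cue list and the derived
stimulation/rest intervals — together with readers/writers for EDF,
BrainVision and the package's plain-text/npz internal formats.

Conventions: time is in seconds from recording start, sample indices are
0-based, and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Hypnogram",
    "EventList",
    "IntervalSet",
    "STAGE_LABELS",
    "read_recording",
    "write_edf",
    "write_events_tsv",
    "read_events_tsv",
    "write_hypnogram_tsv",
    "read_hypnogram_tsv",
    "restrict_to_stages",
    "build_intervals",
    "qc_min_stimulations",
]

STAGE_LABELS = ("W", "N1", "N2", "N3", "REM")

# numeric AASM stagings as exported by common scoring software
_NUMERIC_STAGES = {0: "W", 1: "N1", 2: "N2", 3: "N3", 4: "REM", 5: "REM", -1: "W"}

CONDITIONS = ("associated", "unassociated")


@dataclass
class Recording:
    """Multichannel uniformly sampled EEG in microvolts.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel names, one per row of ``signal``.
    t0 : float
        Recording start time in seconds (default 0).
    """

    signal: np.ndarray
    fs: float
    channels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class Hypnogram:
    """Sleep-stage labels in 30-s epochs (AASM convention)."""

    stages: list[str]
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        normed = []
        for s in self.stages:
            s = _normalize_stage(s)
            normed.append(s)
        self.stages = normed

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_len_s

    def stage_at(self, t_s: float) -> str:
        """Stage label of the epoch containing time ``t_s``."""
        idx = int(t_s // self.epoch_len_s)
        if idx < 0 or idx >= len(self.stages):
            raise IndexError(f"time {t_s} s outside hypnogram")
        return self.stages[idx]


def _normalize_stage(s) -> str:
    if isinstance(s, (int, np.integer)):
        try:
            return _NUMERIC_STAGES[int(s)]
        except KeyError:
            raise ValueError(f"unknown numeric stage {s}") from None
    s = str(s).strip().upper()
    aliases = {"WAKE": "W", "R": "REM", "S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3"}
    s = aliases.get(s, s)
    if s not in STAGE_LABELS:
        raise ValueError(f"unknown stage label {s!r}")
    return s


@dataclass
class EventList:
    """Auditory cue onsets with condition labels and kept flags.

    ``kept`` marks cues that survived artifact screening; QC and
    downstream epoching honour it.
    """

    onset_s: np.ndarray
    condition: np.ndarray
    kept: np.ndarray = None

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.kept is None:
            self.kept = np.ones(len(self.onset_s), dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        if not (len(self.onset_s) == len(self.condition) == len(self.kept)):
            raise ValueError("onset/condition/kept lengths differ")
        for cond in np.unique(self.condition):
            o = self.onset_s[self.condition == cond]
            if np.any(np.diff(o) <= 0):
                raise ValueError(f"onsets not strictly increasing for {cond!r}")

    def __len__(self) -> int:
        return len(self.onset_s)

    def counts(self, kept_only: bool = True) -> dict[str, int]:
        sel = self.kept if kept_only else np.ones(len(self), bool)
        return {
            str(c): int(np.sum(sel & (self.condition == c)))
            for c in np.unique(self.condition)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onset_s, "condition": self.condition, "kept": self.kept}
        )


@dataclass
class IntervalSet:
    """Non-overlapping labelled intervals with per-kind totals in minutes.

    Kinds are ``associated`` / ``unassociated`` stimulation intervals and
    ``rest`` (NREM2-3 outside stimulation).  The totals are the
    denominators of the event-density features (events per minute).
    """

    start_s: np.ndarray
    end_s: np.ndarray
    kind: np.ndarray

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.end_s = np.asarray(self.end_s, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        if np.any(self.end_s < self.start_s):
            raise ValueError("interval with negative duration")
        order = np.argsort(self.start_s)
        s, e = self.start_s[order], self.end_s[order]
        if np.any(s[1:] < e[:-1] - 1e-9):
            raise ValueError("intervals overlap")

    def __len__(self) -> int:
        return len(self.start_s)

    def totals_min(self) -> dict[str, float]:
        """Total duration per kind, in minutes."""
        out: dict[str, float] = {}
        for k in np.unique(self.kind):
            sel = self.kind == k
            out[str(k)] = float(np.sum(self.end_s[sel] - self.start_s[sel]) / 60.0)
        return out

    def kind_at(self, t_s: float) -> str | None:
        """Kind of the interval containing ``t_s`` (half-open), else None."""
        hit = (self.start_s <= t_s) & (t_s < self.end_s)
        idx = np.flatnonzero(hit)
        return str(self.kind[idx[0]]) if idx.size else None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_recording(path, format: str | None = None) -> Recording:
    """Read a multichannel recording into µV.

    ``format`` is one of ``edf``, ``brainvision`` or ``internal`` (npz with
    ``signal``/``fs``/``channels`` keys); inferred from the suffix when
    omitted. EDF/BrainVision go through MNE, which returns volts; the
    signal is rescaled to µV here.
    """
    path = Path(path)
    if format is None:
        format = {".edf": "edf", ".vhdr": "brainvision", ".npz": "internal"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if format == "internal":
        with np.load(path, allow_pickle=False) as z:
            sig = np.atleast_2d(z["signal"])
            if sig.ndim != 2 or len({len(row) for row in sig}) != 1:
                raise ValueError("inconsistent channel lengths")
            return Recording(
                signal=sig,
                fs=float(z["fs"]),
                channels=[str(c) for c in z["channels"]],
            )
    import mne

    if format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported format {format!r}")
    return Recording(
        signal=raw.get_data() * 1e6,  # V -> µV
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
    )


def write_internal(path, rec: Recording) -> None:
    np.savez(
        path,
        signal=rec.signal,
        fs=rec.fs,
        channels=np.array(rec.channels, dtype="U32"),
    )


def write_edf(path, rec: Recording) -> None:
    """Write an EDF+ file with one data record per second.

    Minimal writer (16-bit samples, µV units) sufficient for round-trip
    through standard EDF readers; physical range is set per channel to the
    signal's own extrema so quantization error is ≤ range/2^16.
    """
    path = Path(path)
    n_ch = len(rec.channels)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires integer sampling rate")
    fs = int(round(fs))
    spr = fs  # samples per record (1-s records)
    n_rec = int(np.ceil(rec.n_samples / spr))
    sig = np.zeros((n_ch, n_rec * spr))
    sig[:, : rec.n_samples] = rec.signal

    pmin = np.floor(sig.min(axis=1) - 1.0)
    pmax = np.ceil(sig.max(axis=1) + 1.0)
    dmin, dmax = -32768, 32767

    def _f(x, n):  # fixed-width ascii field
        s = str(x)[:n]
        return s.ljust(n).encode("ascii")

    now = datetime(2000, 1, 1)
    hdr = b"".join(
        [
            _f("0", 8),
            _f("X X X X", 80),
            _f("synthetic", 80),
            _f(now.strftime("%d.%m.%y"), 8),
            _f(now.strftime("%H.%M.%S"), 8),
            _f(256 * (1 + n_ch), 8),
            _f("EDF+C", 44),
            _f(n_rec, 8),
            _f("1", 8),  # record duration s
            _f(n_ch, 4),
        ]
    )
    hdr += b"".join(_f(ch, 16) for ch in rec.channels)
    hdr += b"".join(_f("EEG", 80) for _ in range(n_ch))
    hdr += b"".join(_f("uV", 8) for _ in range(n_ch))
    hdr += b"".join(_f(f"{v:g}", 8) for v in pmin)
    hdr += b"".join(_f(f"{v:g}", 8) for v in pmax)
    hdr += b"".join(_f(dmin, 8) for _ in range(n_ch))
    hdr += b"".join(_f(dmax, 8) for _ in range(n_ch))
    hdr += b"".join(_f("", 80) for _ in range(n_ch))
    hdr += b"".join(_f(spr, 8) for _ in range(n_ch))
    hdr += b"".join(_f("", 32) for _ in range(n_ch))

    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            chunk = sig[:, r * spr : (r + 1) * spr]
            dig = np.rint((chunk - pmin[:, None]) * scale[:, None] + dmin)
            dig = np.clip(dig, dmin, dmax).astype("<i2")
            fh.write(dig.tobytes())


def write_events_tsv(path, events: EventList) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> EventList:
    df = pd.read_csv(path, sep="\t")
    kept = df["kept"].astype(bool).to_numpy() if "kept" in df else None
    return EventList(df["onset_s"].to_numpy(), df["condition"].to_numpy(), kept)


def write_hypnogram_tsv(path, hyp: Hypnogram) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(hyp.stages)), "stage": hyp.stages}
    ).to_csv(path, sep="\t", index=False)


def read_hypnogram_tsv(path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    return Hypnogram(list(df.sort_values("epoch_index")["stage"]))


# ---------------------------------------------------------------------------
# interval bookkeeping
# ---------------------------------------------------------------------------

def restrict_to_stages(rec: Recording, hyp: Hypnogram, stages) -> np.ndarray:
    """Boolean per-sample mask, true where the sample's 30-s epoch is in ``stages``."""
    if hyp.duration < rec.duration - 1.0 / rec.fs:
        raise ValueError(
            f"hypnogram ({hyp.duration:g} s) shorter than recording "
            f"({rec.duration:g} s)"
        )
    stages = {_normalize_stage(s) for s in stages}
    mask = np.zeros(rec.n_samples, dtype=bool)
    if not stages:
        return mask
    epoch_samp = hyp.epoch_len_s * rec.fs
    for i, st in enumerate(hyp.stages):
        if st in stages:
            lo = int(round(i * epoch_samp))
            hi = min(int(round((i + 1) * epoch_samp)), rec.n_samples)
            mask[lo:hi] = True
    return mask


def build_intervals(
    events: EventList,
    hyp: Hypnogram,
    gap_s: float = 10.0,
    isi_s: float = 5.0,
    stages=("N2", "N3"),
    recording_duration_s: float | None = None,
) -> IntervalSet:
    """Group cue trains into stimulation intervals and call the rest "rest".

    Consecutive same-condition cues separated by at most ``gap_s`` (default
    2×ISI, tolerating one dropped cue) form one stimulation interval running
    from the first onset to the last onset + one ISI.  NREM2-3 time outside
    any stimulation interval becomes rest.  Totals in minutes are the
    density denominators downstream.
    """
    dur = recording_duration_s if recording_duration_s is not None else hyp.duration
    starts, ends, kinds = [], [], []
    for cond in np.unique(events.condition):
        o = np.sort(events.onset_s[events.condition == cond])
        if o.size == 0:
            continue
        brk = np.flatnonzero(np.diff(o) > gap_s)
        run_start = np.r_[o[0], o[brk + 1]]
        run_end = np.r_[o[brk], o[-1]] + isi_s
        starts.extend(run_start)
        ends.extend(np.minimum(run_end, dur))
        kinds.extend([str(cond)] * len(run_start))

    order = np.argsort(starts) if starts else []
    starts = list(np.asarray(starts)[order])
    ends = list(np.asarray(ends)[order])
    kinds = list(np.asarray(kinds, dtype=object)[order])
    for i in range(1, len(starts)):
        if starts[i] < ends[i - 1] - 1e-9:
            raise ValueError("overlapping opposite-condition stimulation intervals")

    # rest: NREM2-3 epochs outside every stimulation interval
    epoch = hyp.epoch_len_s
    rest_starts, rest_ends = [], []
    cur = None
    n_ep = int(np.ceil(dur / epoch))
    want = {_normalize_stage(s) for s in stages}
    for i in range(n_ep):
        lo, hi = i * epoch, min((i + 1) * epoch, dur)
        if i >= len(hyp.stages) or hyp.stages[i] not in want:
            continue
        # carve out stimulation overlap at sub-epoch resolution
        segs = [(lo, hi)]
        for s, e in zip(starts, ends):
            segs = _subtract(segs, s, e)
        for s, e in segs:
            if cur is not None and abs(s - cur[1]) < 1e-9:
                cur = (cur[0], e)
            else:
                if cur is not None:
                    rest_starts.append(cur[0])
                    rest_ends.append(cur[1])
                cur = (s, e)
    if cur is not None:
        rest_starts.append(cur[0])
        rest_ends.append(cur[1])

    all_start = np.r_[starts, rest_starts]
    all_end = np.r_[ends, rest_ends]
    all_kind = np.r_[kinds, ["rest"] * len(rest_starts)]
    order = np.argsort(all_start)
    return IntervalSet(all_start[order], all_end[order], all_kind[order])


def _subtract(segs, s, e):
    out = []
    for lo, hi in segs:
        if e <= lo or s >= hi:
            out.append((lo, hi))
            continue
        if s > lo:
            out.append((lo, s))
        if e < hi:
            out.append((e, hi))
    return out


def qc_min_stimulations(
    events: EventList, min_per_condition: int = 50
) -> tuple[bool, dict[str, int]]:
    """Inclusion check: every condition must retain ≥ ``min_per_condition``
    artifact-free cues (kept flags). Returns (passed, per-condition counts)."""
    counts = events.counts(kept_only=True)
    passed = all(c >= min_per_condition for c in counts.values())
    return passed, counts
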