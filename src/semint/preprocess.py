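"""Recording containers, line-noise removal, re-referencing and epoching.

A :class:`Recording` is a channels x time array of amplitudes in microvolts
with a sampling rate, channel labels and a bad-channel mask.  Event tables
are plain :class:`pandas.DataFrame` objects following a BIDS-style layout
(one row per word presentation; see :func:`validate_events`).  Epoching cuts
trials x channels x time blocks locked to the first word, the final word,
or the spoken response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "trial_id",
    "word_index",
    "onset",
    "duration",
    "condition",
    "coherence",
    "narrowing",
    "is_final_word",
    "response_onset",
    "correct",
]

LOCKS = ("first_word", "final_word", "response")


@dataclass
class Recording:
    """Multichannel time series (channels x samples, microvolts)."""

    data: np.ndarray
    rate: float
    channel_names: list[str]
    bad_channels: set[str] = field(default_factory=set)
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        self.bad_channels = set(self.bad_channels)
        unknown = self.bad_channels - set(self.channel_names)
        if unknown:
            raise ValueError(f"bad_channels not in channel_names: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.rate

    def good_mask(self) -> np.ndarray:
        return np.array([c not in self.bad_channels for c in self.channel_names])


def write_recording(rec: Recording, path) -> None:
    """Write a recording to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["rate"] = float(rec.rate)
        f.attrs["reference"] = rec.reference
        f.create_dataset(
            "channel_names", data=np.array(rec.channel_names, dtype="S")
        )
        f.create_dataset(
            "bad_channels", data=np.array(sorted(rec.bad_channels), dtype="S")
        )


def read_recording(path) -> Recording:
    """Read a recording from an HDF5 container (or EDF, if mne is present).

    Raises ``ValueError`` for unreadable or malformed files rather than
    crashing on partial content.
    """
    path = str(path)
    if path.lower().endswith(".edf"):
        return _read_edf(path)
    try:
        with h5py.File(path, "r") as f:
            if "data" not in f or "channel_names" not in f:
                raise ValueError(f"{path}: missing data/channel_names datasets")
            data = f["data"][()]
            rate = float(f.attrs["rate"])
            names = [n.decode() for n in f["channel_names"][()]]
            bad = {n.decode() for n in f["bad_channels"][()]} if "bad_channels" in f else set()
            ref = str(f.attrs.get("reference", "raw"))
    except OSError as exc:
        raise ValueError(f"{path}: not a readable HDF5 recording ({exc})") from exc
    return Recording(data, rate, names, bad, ref)


def _read_edf(path: str) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ValueError("EDF support requires mne") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(raw.get_data() * 1e6, raw.info["sfreq"], list(raw.ch_names))


def remove_line_noise(
    rec: Recording,
    base: float = 60.0,
    n_harmonics: int = 3,
    halfwidth: float = 1.0,
) -> Recording:
    """Zero-phase Butterworth band-stop at the line frequency and harmonics.

    Each stop band is ``base*k +/- halfwidth`` Hz for ``k = 1..n_harmonics``,
    removed with a forward-backward 2nd-order Butterworth filter (zero phase;
    the effective order doubles).  Harmonics at or above the Nyquist
    frequency are skipped with a warning.
    """
    nyq = rec.rate / 2.0
    if base <= 0:
        raise ValueError("line frequency must be positive")
    out = rec.data.copy()
    for k in range(1, n_harmonics + 1):
        f = base * k
        if f + halfwidth >= nyq:
            warnings.warn(
                f"harmonic {f:g} Hz at or above Nyquist ({nyq:g} Hz); skipped"
            )
            continue
        sos = signal.butter(
            2, [f - halfwidth, f + halfwidth], btype="bandstop", fs=rec.rate, output="sos"
        )
        out = signal.sosfiltfilt(sos, out, axis=-1)
    return replace(rec, data=out)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the per-sample mean over retained (non-bad) channels.

    Bad channels are excluded from the average and passed through
    unmodified.  Idempotent up to numerical precision.
    """
    good = rec.good_mask()
    if good.sum() < 2:
        raise ValueError("common average reference needs >= 2 retained channels")
    car = rec.data[good].mean(axis=0)
    out = rec.data.copy()
    out[good] -= car
    return replace(rec, data=out, reference="common_average")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table invariants; returns the table unchanged.

    Required columns: trial_id, word_index, onset (s), duration (s),
    condition ('referential'/'non_referential'), coherence ('coherent'/
    'incoherent'/'n/a'), narrowing ('strong'/'limited'/'n/a'),
    is_final_word, response_onset (s or NaN), correct.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    for tid, grp in events.groupby("trial_id"):
        if not grp["onset"].is_monotonic_increasing:
            raise ValueError(f"trial {tid}: onsets not non-decreasing")
        if int(grp["is_final_word"].sum()) != 1:
            raise ValueError(f"trial {tid}: must have exactly one final word")
        cond = grp["condition"].iloc[0]
        if cond == "referential" and (grp["coherence"] != "n/a").any():
            raise ValueError(f"trial {tid}: coherence defined for referential trial")
        if cond == "non_referential" and (grp["narrowing"] != "n/a").any():
            raise ValueError(f"trial {tid}: narrowing defined for non-referential trial")
    return events


@dataclass
class EpochSet:
    """Trials x channels x time block locked to a trial event.

    ``data`` has shape (n_trials, n_channels, n_times); ``time_axis`` is in
    milliseconds relative to the lock sample; ``trial_info`` carries one row
    of trial-level metadata per kept trial (indexed like ``data``).
    """

    data: np.ndarray
    time_axis: np.ndarray
    lock: str
    units: str = "uV"
    baseline_window: tuple[float, float] | None = None
    trial_info: pd.DataFrame | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.lock not in LOCKS:
            raise ValueError(f"lock must be one of {LOCKS}")
        if self.units not in ("uV", "analytic_amplitude", "percent_change"):
            raise ValueError(f"unknown units {self.units!r}")
        dt = np.diff(self.time_axis)
        if len(dt) and (dt <= 0).any():
            raise ValueError("time axis must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask for the half-open window [start, end) in ms."""
        return (self.time_axis >= window[0]) & (self.time_axis < window[1])


def _lock_rows(events: pd.DataFrame, lock: str) -> pd.DataFrame:
    if lock == "first_word":
        idx = events.groupby("trial_id")["word_index"].idxmin()
        return events.loc[idx]
    if lock == "final_word":
        return events[events["is_final_word"].astype(bool)]
    if lock == "response":
        rows = events[events["is_final_word"].astype(bool)].copy()
        rows = rows[np.isfinite(rows["response_onset"].astype(float))]
        rows["onset"] = rows["response_onset"].astype(float)
        return rows
    raise ValueError(f"unknown lock {lock!r}")


def epoch(
    rec: Recording,
    events: pd.DataFrame,
    lock: str,
    window: tuple[float, float],
    drop_incorrect: bool = True,
    bad_trials: set | None = None,
    units: str = "uV",
) -> EpochSet:
    """Cut trials x channels x time epochs from a recording.

    ``window`` is (start_ms, end_ms), half-open: the sample at the lock
    onset belongs to the epoch, the sample at ``end_ms`` does not.  Trials
    with an incorrect response, trials in ``bad_trials``, and trials whose
    window falls outside the recording are dropped (the latter with a
    warning).
    """
    validate_events(events)
    bad_trials = bad_trials or set()
    rows = _lock_rows(events, lock)
    i0 = int(round(window[0] / 1000.0 * rec.rate))
    i1 = int(round(window[1] / 1000.0 * rec.rate))
    if i1 <= i0:
        raise ValueError("empty epoch window")
    n_t = i1 - i0
    time_axis = (np.arange(i0, i1) / rec.rate) * 1000.0

    blocks, kept = [], []
    for _, row in rows.iterrows():
        tid = row["trial_id"]
        if tid in bad_trials:
            continue
        if drop_incorrect and not bool(row["correct"]):
            continue
        center = int(round(float(row["onset"]) * rec.rate))
        lo, hi = center + i0, center + i1
        if lo < 0 or hi > rec.n_samples:
            warnings.warn(f"trial {tid}: window outside recording; dropped")
            continue
        blocks.append(rec.data[:, lo:hi])
        kept.append(row)
    data = (
        np.stack(blocks) if blocks else np.empty((0, rec.n_channels, n_t))
    )
    info = pd.DataFrame(kept).reset_index(drop=True)
    return EpochSet(
        data,
        time_axis,
        lock,
        units=units,
        trial_info=info,
        channel_names=list(rec.channel_names),
    )
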