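"""Frequency-domain Hilbert band amplitude and percent-change traces.

Broadband gamma activity (BGA) is the analytic amplitude of the 70-150 Hz
band.  The band filter is applied in the frequency domain: the one-sided
spectrum is multiplied by a band weight built from paired logistic flanks
(half-width 1.5 Hz), doubled, and inverse-transformed; the magnitude of the
resulting complex analytic signal is the band amplitude.  The amplitude is
smoothed with a Savitzky-Golay FIR (3rd order, 251 ms frame) and expressed
as percent change from the per-trial pre-sentence baseline (-500 to -100 ms
before the first word).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sfft
from scipy import signal
from scipy.special import expit

from semint.preprocess import EpochSet, Recording

BGA_BAND = (70.0, 150.0)
THETA_BAND = (4.0, 8.0)  # hippocampal low-frequency analysis; configurable
DEFAULT_BASELINE = (-500.0, -100.0)


@dataclass(frozen=True)
class BandSpec:
    """Pass band in Hz with logistic flank half-width."""

    f_lo: float
    f_hi: float
    flank_halfwidth: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if self.flank_halfwidth <= 0:
            raise ValueError("flank_halfwidth must be positive")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


@dataclass(frozen=True)
class SmoothSpec:
    """Savitzky-Golay smoothing: polynomial order and frame length in ms."""

    polynomial_order: int = 3
    frame_ms: float = 251.0

    def frame_samples(self, rate: float) -> int:
        """Frame length in samples, rounded to the nearest odd integer."""
        n = int(round(self.frame_ms / 1000.0 * rate))
        if n % 2 == 0:
            n -= 1
        if n <= self.polynomial_order:
            raise ValueError(
                f"frame of {n} samples must exceed polynomial order "
                f"{self.polynomial_order}"
            )
        return n


def sigmoid_band_weights(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    """Band weight W(f) = L((f-f_lo)/h) * L((f_hi-f)/h), L the logistic.

    W is 0.5 at each band edge (for bands much wider than h), saturates to
    1 mid-band and decays to 0 outside.
    """
    f = np.asarray(freqs, dtype=np.float64)
    h = band.flank_halfwidth
    return expit((f - band.f_lo) / h) * expit((band.f_hi - f) / h)


def hilbert_band_amplitude(rec: Recording, band: BandSpec) -> Recording:
    """Analytic amplitude of the band, computed in the frequency domain.

    The full FFT is taken per channel; negative frequencies are zeroed,
    positive frequencies are multiplied by ``2 * W(f)`` (DC and Nyquist are
    zeroed -- the band weight excludes them anyway), and the magnitude of
    the inverse transform is returned as a new Recording.
    """
    if band.f_hi >= rec.rate / 2.0:
        raise ValueError(
            f"band upper edge {band.f_hi:g} Hz not below Nyquist {rec.rate / 2:g} Hz"
        )
    if rec.n_samples < 4:
        raise ValueError("need at least 4 samples")
    n = rec.n_samples
    n_fft = sfft.next_fast_len(n)  # zero-pad to a fast length
    freqs = np.fft.fftfreq(n_fft, d=1.0 / rec.rate)
    gain = np.zeros(n_fft)
    pos = freqs > 0
    gain[pos] = 2.0 * sigmoid_band_weights(freqs[pos], band)
    if n_fft % 2 == 0:  # Nyquist bin
        gain[n_fft // 2] = 0.0
    spec = sfft.fft(rec.data, n=n_fft, axis=-1) * gain
    analytic = sfft.ifft(spec, axis=-1)[..., :n]
    return replace(rec, data=np.abs(analytic))


def smooth_amplitude(
    amplitude: np.ndarray, rate: float, spec: SmoothSpec = SmoothSpec()
) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing along time."""
    amplitude = np.asarray(amplitude, dtype=np.float64)
    n_frame = spec.frame_samples(rate)
    if amplitude.shape[-1] <= n_frame:
        raise ValueError(
            f"series of {amplitude.shape[-1]} samples shorter than "
            f"{n_frame}-sample frame"
        )
    return signal.savgol_filter(
        amplitude, n_frame, spec.polynomial_order, axis=-1
    )


def band_amplitude_recording(
    rec: Recording,
    band: BandSpec,
    smooth: SmoothSpec | None = SmoothSpec(),
) -> Recording:
    """Convenience: Hilbert band amplitude followed by SG smoothing."""
    amp = hilbert_band_amplitude(rec, band)
    if smooth is not None:
        amp = replace(amp, data=smooth_amplitude(amp.data, rec.rate, smooth))
    return amp


def percent_change(
    epochs: EpochSet,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    baseline_epochs: EpochSet | None = None,
) -> EpochSet:
    """Express analytic amplitude as percent change from the trial baseline.

    The baseline is the mean amplitude over ``baseline`` (ms, half-open)
    taken from the *first-word-locked* epoch of the same trial: pass
    ``baseline_epochs`` when ``epochs`` is locked to the final word or the
    response.  Trials with a non-positive or non-finite baseline are
    dropped with a warning.
    """
    if epochs.units != "analytic_amplitude":
        raise ValueError(
            f"percent_change requires analytic_amplitude input, got {epochs.units!r}"
        )
    base_src = baseline_epochs if baseline_epochs is not None else epochs
    if base_src.units != "analytic_amplitude":
        raise ValueError("baseline epochs must be analytic_amplitude")
    if base_src.lock != "first_word":
        raise ValueError("baseline must come from first-word-locked epochs")
    bmask = base_src.time_mask(baseline)
    if not bmask.any():
        raise ValueError("baseline window not covered by baseline epochs")

    base_by_trial = dict(
        zip(
            base_src.trial_info["trial_id"],
            base_src.data[:, :, bmask].mean(axis=-1),  # trials x channels
        )
    )
    out_rows, kept = [], []
    for i, tid in enumerate(epochs.trial_info["trial_id"]):
        base = base_by_trial.get(tid)
        if base is None:
            warnings.warn(f"trial {tid}: no baseline epoch; dropped")
            continue
        if not np.all(np.isfinite(base)) or np.any(base <= 0):
            warnings.warn(f"trial {tid}: non-positive baseline; dropped")
            continue
        out_rows.append(100.0 * (epochs.data[i] - base[:, None]) / base[:, None])
        kept.append(i)
    data = (
        np.stack(out_rows)
        if out_rows
        else np.empty((0,) + epochs.data.shape[1:])
    )
    info = epochs.trial_info.iloc[kept].reset_index(drop=True)
    return EpochSet(
        data,
        epochs.time_axis,
        epochs.lock,
        units="percent_change",
        baseline_window=tuple(baseline),
        trial_info=info,
        channel_names=epochs.channel_names,
    )


def log_spaced_bands(
    f_min: float, f_max: float, n_bands: int, rel_width: float = 0.25,
    flank_halfwidth: float = 1.5,
) -> list[BandSpec]:
    """Log-spaced constant-Q filter bank for spectrogram displays."""
    centers = np.geomspace(f_min, f_max, n_bands)
    return [
        BandSpec(c * (1 - rel_width / 2), c * (1 + rel_width / 2), flank_halfwidth)
        for c in centers
    ]


def spectrogram(rec: Recording, band_grid: list[BandSpec]) -> np.ndarray:
    """Stack of band amplitudes: channels x bands x time."""
    if not band_grid:
        raise ValueError("empty band grid")
    return np.stack(
        [hilbert_band_amplitude(rec, b).data for b in band_grid], axis=1
    )
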