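"""Ground-truthed synthetic multi-subject iEEG cohorts.

Emulates the statistical structure the analysis assumes: 1/f background
noise, 60 Hz line noise with harmonics, a rapid-serial-visual-presentation
sentence paradigm (1000 ms fixation, 500 ms per word, 3-12 words, 1 s
post-sentence blank, 2 s response window; 42 referential + 42
non-referential trials), sparse electrode coverage of a shared spherical
mesh, and word-locked band-limited gamma bursts whose amplitude depends on
condition.  Injected effects are calibrated so that the *expected percent
change of the window-averaged analytic band amplitude* equals the
requested amplitude, which makes them recoverable by the downstream
percent-change contrast machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy.optimize import brentq
from scipy.signal.windows import hann
from scipy.spatial import ConvexHull

from semint.band import BandSpec, hilbert_band_amplitude, sigmoid_band_weights
from semint.preprocess import EVENT_COLUMNS, Recording, validate_events
from semint.surface import SurfaceMesh

CONDITION_FACTORS = {
    "condition": {"referential", "non_referential"},
    "coherence": {"coherent", "incoherent", "n/a"},
    "narrowing": {"strong", "limited", "n/a"},
}


@dataclass(frozen=True)
class EffectSpec:
    """A condition-dependent band-limited burst to inject.

    ``condition`` selects matching trials by event-table columns (e.g.
    ``{"condition": "referential"}``).  ``nodes`` (cohort level) or
    ``channels`` (single-recording level) pick the targets; ``window_ms``
    is relative to the ``lock`` event; ``amplitude_pct`` is the expected
    percent change of window-averaged band amplitude over baseline.
    """

    name: str
    condition: dict
    band: tuple[float, float]
    window_ms: tuple[float, float]
    amplitude_pct: float
    nodes: tuple[int, ...] = ()
    channels: tuple[str, ...] = ()
    lock: str = "final_word"

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude_pct) or self.amplitude_pct < 0:
            raise ValueError("effect amplitude must be finite and >= 0")
        if self.window_ms[1] <= self.window_ms[0]:
            raise ValueError("effect window must be non-empty")
        for key, val in self.condition.items():
            if key not in CONDITION_FACTORS:
                raise ValueError(f"unknown condition factor {key!r}")
            if val not in CONDITION_FACTORS[key]:
                raise ValueError(f"unknown label {val!r} for factor {key!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generation parameters (defaults mirror the paradigm)."""

    n_subjects: int = 8
    electrodes_per_subject: int = 8
    sample_rate: float = 2000.0
    background_slope: float = 1.0  # 1/f^alpha exponent
    background_rms: float = 20.0  # microvolts
    line_freq: float = 60.0
    n_harmonics: int = 3
    line_amp: float = 5.0  # microvolts, fundamental
    trial_counts: dict = field(
        default_factory=lambda: {"referential": 42, "non_referential": 42}
    )
    words_range: tuple[int, int] = (3, 12)
    word_duration_ms: float = 500.0
    fixation_ms: float = 1000.0
    post_sentence_blank_ms: float = 1000.0
    response_window_ms: float = 2000.0
    inter_trial_ms: float = 500.0
    p_correct: float = 0.95
    rt_mean_ms: float = 1765.0
    rt_sd_ms: float = 680.0
    mesh_vertices: int = 500
    mesh_radius: float = 50.0
    anchor_nodes: tuple[int, ...] = ()  # nodes covered by every subject
    effect_specs: tuple[EffectSpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_subjects, self.electrodes_per_subject, self.mesh_vertices]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if min(self.trial_counts.values()) <= 0:
            raise ValueError("trial counts must be positive")
        if self.word_duration_ms <= 0:
            raise ValueError("word duration must be positive")
        lo, hi = self.words_range
        if not (3 <= lo <= hi <= 12):
            raise ValueError("sentence length range must lie within [3, 12]")
        if self.electrodes_per_subject > self.mesh_vertices:
            raise ValueError("more electrodes than mesh vertices")
        if len(self.anchor_nodes) > self.electrodes_per_subject:
            raise ValueError("more anchor nodes than electrodes per subject")


@dataclass
class SubjectData:
    subject_id: str
    electrodes: pd.DataFrame  # name, x, y, z, node
    recording: Recording
    events: pd.DataFrame


@dataclass
class CohortDataset:
    """Mesh, per-subject data, and the injected ground truth."""

    mesh: SurfaceMesh
    subjects: dict
    ground_truth: pd.DataFrame  # contrast, node, amplitude_pct
    norming: pd.DataFrame
    norming_targets: dict
    config: SyntheticConfig


def make_mesh(n_vertices: int, radius: float = 50.0, seed: int = 0) -> SurfaceMesh:
    """Closed sphere-like triangulated mesh with ``n_vertices`` vertices.

    Seeded uniform points on a sphere are triangulated by their convex
    hull (every point is extreme, so all vertices are used), then a small
    seeded radial jitter roughens the edge lengths.
    """
    if n_vertices < 12:
        raise ValueError("need at least 12 vertices for a closed surface")
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_vertices, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    hull = ConvexHull(pts)
    radii = radius * (1.0 + 0.02 * rng.uniform(-1, 1, size=n_vertices))
    return SurfaceMesh(pts * radii[:, None], hull.simplices)


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, rate: float,
    slope: float, rms: float,
) -> np.ndarray:
    """Gaussian 1/f^slope noise synthesized in the frequency domain."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-slope / 2.0)
    spec = (
        rng.standard_normal((n_channels, len(freqs)))
        + 1j * rng.standard_normal((n_channels, len(freqs)))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x *= rms / x.std(axis=-1, keepdims=True)
    return x


def _line_noise(
    n_samples: int, rate: float, base: float, n_harmonics: int, amp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    t = np.arange(n_samples) / rate
    out = np.zeros(n_samples)
    for k in range(1, n_harmonics + 1):
        f = base * k
        if f >= rate / 2:
            break
        out += (amp / k) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def make_events(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One block of RSVP sentence trials as a BIDS-style event table."""
    trials = []
    for cond, count in config.trial_counts.items():
        sub = (
            ["coherent", "incoherent"] if cond == "non_referential"
            else ["strong", "limited"] if cond == "referential"
            else ["n/a"]
        )
        for i in range(count):
            trials.append((cond, sub[i % len(sub)]))
    order = rng.permutation(len(trials))
    rows = []
    t = 1.0  # lead-in seconds
    for tid, k in enumerate(order):
        cond, sub = trials[k]
        n_words = int(rng.integers(config.words_range[0], config.words_range[1] + 1))
        word_dur = config.word_duration_ms / 1000.0
        t_first = t + config.fixation_ms / 1000.0
        final_off = t_first + n_words * word_dur
        rt = float(np.clip(rng.normal(config.rt_mean_ms, config.rt_sd_ms), 400.0,
                           config.post_sentence_blank_ms + config.response_window_ms))
        resp = final_off + rt / 1000.0
        correct = bool(rng.random() < config.p_correct)
        for w in range(n_words):
            rows.append(
                {
                    "trial_id": tid,
                    "word_index": w,
                    "onset": t_first + w * word_dur,
                    "duration": word_dur,
                    "condition": cond,
                    "coherence": sub if cond == "non_referential" else "n/a",
                    "narrowing": sub if cond == "referential" else "n/a",
                    "is_final_word": w == n_words - 1,
                    "response_onset": resp,
                    "correct": correct,
                }
            )
        t = final_off + (config.post_sentence_blank_ms
                         + config.response_window_ms
                         + config.inter_trial_ms) / 1000.0
    return validate_events(pd.DataFrame(rows, columns=EVENT_COLUMNS))


def _matching_lock_rows(events: pd.DataFrame, spec: EffectSpec) -> pd.DataFrame:
    if spec.lock == "final_word":
        rows = events[events["is_final_word"].astype(bool)]
    elif spec.lock == "first_word":
        rows = events.loc[events.groupby("trial_id")["word_index"].idxmin()]
    else:
        raise ValueError(f"unsupported effect lock {spec.lock!r}")
    for key, val in spec.condition.items():
        rows = rows[rows[key] == val]
    return rows


def _calibrated_peak_power(
    background_band_power: float, envelope_sq: np.ndarray, amplitude_pct: float
) -> float:
    """Solve for the burst peak power that yields the requested % change.

    For independent circular-Gaussian band signals the expected analytic
    amplitude scales as sqrt of band power, so the expected percent change
    at time t is 100*(sqrt(1 + 2*Ps*h(t)^2/Pa) - 1); the window average of
    that expression is matched to ``amplitude_pct``.
    """
    pa = background_band_power
    target = amplitude_pct / 100.0

    def gap(ps: float) -> float:
        return np.mean(np.sqrt(1.0 + 2.0 * ps * envelope_sq / pa) - 1.0) - target

    hi = pa
    while gap(hi) < 0:
        hi *= 4.0
        if hi > pa * 1e9:  # pragma: no cover
            raise RuntimeError("burst calibration failed to bracket")
    return brentq(gap, 0.0, hi)


def inject_effect(
    rec: Recording,
    events: pd.DataFrame,
    spec: EffectSpec,
    seed: int = 0,
) -> Recording:
    """Add condition-locked band-limited bursts to target channels.

    The burst is Hann-enveloped narrowband Gaussian noise confined to
    ``spec.band``, scaled per channel so the expected percent change of
    window-averaged analytic amplitude equals ``spec.amplitude_pct``
    relative to the channel's current band power.  Only samples in the
    effect window of matching-condition trials on target channels change.
    """
    lo, hi = spec.band
    nyq = rec.rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {spec.band} outside (0, Nyquist={nyq:g})")
    targets = [rec.channel_names.index(c) for c in spec.channels]
    if not targets and spec.channels == ():
        raise ValueError("effect spec names no channels")
    if spec.amplitude_pct == 0:
        return replace(rec, data=rec.data.copy())

    rng = np.random.default_rng(seed)
    band = BandSpec(lo, hi)
    rows = _matching_lock_rows(events, spec)
    i0 = int(round(spec.window_ms[0] / 1000.0 * rec.rate))
    i1 = int(round(spec.window_ms[1] / 1000.0 * rec.rate))
    n_w = i1 - i0
    env = hann(n_w)
    env_sq = env**2
    # amplitude gain of the band filter on the full (two-sided) FFT grid;
    # unit white noise filtered by it has expected variance mean(w_full^2)
    freqs_full = np.abs(np.fft.fftfreq(n_w, d=1.0 / rec.rate))
    w_full = sigmoid_band_weights(freqs_full, band)
    e_scale = 1.0 / np.sqrt(np.mean(w_full**2))

    out = rec.data.copy()
    for ch in targets:
        single = Recording(rec.data[ch:ch + 1], rec.rate, [rec.channel_names[ch]])
        amp = hilbert_band_amplitude(single, band).data[0]
        pa = float(np.mean(amp**2))
        ps = _calibrated_peak_power(pa, env_sq, spec.amplitude_pct)
        for _, row in rows.iterrows():
            center = int(round(float(row["onset"]) * rec.rate))
            a, b = center + i0, center + i1
            if a < 0 or b > rec.n_samples:
                warnings.warn(
                    f"trial {row['trial_id']}: effect window outside recording"
                )
                continue
            noise = rng.standard_normal(n_w)
            e = np.real(np.fft.ifft(np.fft.fft(noise) * w_full)) * e_scale
            out[ch, a:b] += np.sqrt(ps) * env * e
    return replace(rec, data=out)


def make_norming_table(
    events: pd.DataFrame,
    rng: np.random.Generator,
    n_participants: int = 80,
) -> tuple[pd.DataFrame, dict]:
    """Simulated norming responses for the referential sentences.

    Each referential trial becomes a sentence with a latent identification
    curve: the probability of typing the target word is monotone
    non-decreasing across word positions, reaching 1 at the final word.
    Returns the long-format table (sentence_id, participant,
    word_position, answer) and the sentence -> target mapping.
    """
    finals = events[
        events["is_final_word"].astype(bool)
        & (events["condition"] == "referential")
    ]
    rows, targets = [], {}
    for _, trial in finals.iterrows():
        sid = int(trial["trial_id"])
        n_words = int(trial["word_index"]) + 1
        target = f"target{sid}"
        targets[sid] = target
        p_pen = float(rng.uniform(0.05, 0.95))  # identifiability before final word
        for pos in range(1, n_words + 1):
            if pos == n_words:
                p = 1.0
            else:
                p = p_pen * ((pos / (n_words - 1)) ** 2) if n_words > 1 else p_pen
            hits = rng.random(n_participants) < p
            for part in range(n_participants):
                rows.append(
                    (sid, part, pos, target if hits[part] else "unknown")
                )
    return (
        pd.DataFrame(
            rows, columns=["sentence_id", "participant", "word_position", "answer"]
        ),
        targets,
    )


def make_cohort(
    config: SyntheticConfig, mesh: SurfaceMesh | None = None
) -> CohortDataset:
    """Generate a full multi-subject cohort with known injected effects.

    A prebuilt shared ``mesh`` may be supplied (e.g. when effect node sets
    were chosen from its adjacency); otherwise one is generated from the
    config seed.
    """
    root = np.random.SeedSequence(config.rng_seed)
    mesh_seed, norming_seed, *subject_seeds = root.spawn(2 + config.n_subjects)
    if mesh is None:
        mesh = make_mesh(
            config.mesh_vertices,
            config.mesh_radius,
            seed=int(mesh_seed.generate_state(1)[0] % (2**31)),
        )
    elif mesh.n_vertices != config.mesh_vertices:
        raise ValueError("supplied mesh does not match config.mesh_vertices")
    for spec in config.effect_specs:
        bad = [n for n in spec.nodes if not (0 <= n < mesh.n_vertices)]
        if bad:
            raise ValueError(f"effect {spec.name!r}: invalid mesh nodes {bad}")

    subjects: dict = {}
    norming = None
    targets: dict = {}
    for s, seed_seq in enumerate(subject_seeds):
        rng = np.random.default_rng(seed_seq)
        sid = f"sub-{s + 1:02d}"
        anchors = np.array(config.anchor_nodes, dtype=int)
        n_free = config.electrodes_per_subject - len(anchors)
        free_pool = np.setdiff1d(np.arange(mesh.n_vertices), anchors)
        nodes = np.concatenate(
            [anchors, rng.choice(free_pool, size=n_free, replace=False)]
        ).astype(int)
        names = [f"{sid}_e{j + 1:02d}" for j in range(len(nodes))]
        electrodes = pd.DataFrame(
            {
                "subject": sid,
                "name": names,
                "x": mesh.vertices[nodes, 0],
                "y": mesh.vertices[nodes, 1],
                "z": mesh.vertices[nodes, 2],
                "node": nodes,
            }
        )
        events = make_events(config, rng)
        last = events["response_onset"].max() + 1.0
        n_samples = sfft.next_fast_len(int(np.ceil(last * config.sample_rate)))
        data = _one_over_f_noise(
            rng,
            len(names),
            n_samples,
            config.sample_rate,
            config.background_slope,
            config.background_rms,
        )
        rec = Recording(data, config.sample_rate, names)
        for spec in config.effect_specs:
            chans = tuple(
                electrodes.loc[electrodes["node"].isin(spec.nodes), "name"]
            )
            if not chans:
                continue
            rec = inject_effect(
                rec,
                events,
                replace(spec, channels=chans, nodes=()),
                seed=int(rng.integers(2**31)),
            )
        line = _line_noise(
            n_samples,
            config.sample_rate,
            config.line_freq,
            config.n_harmonics,
            config.line_amp,
            rng,
        )
        rec = replace(rec, data=rec.data + line)
        subjects[sid] = SubjectData(sid, electrodes, rec, events)
        if norming is None:
            norming, targets = make_norming_table(
                events, np.random.default_rng(norming_seed)
            )

    gt_rows = [
        {"contrast": spec.name, "node": int(n), "amplitude_pct": spec.amplitude_pct}
        for spec in config.effect_specs
        for n in spec.nodes
    ]
    ground_truth = pd.DataFrame(
        gt_rows, columns=["contrast", "node", "amplitude_pct"]
    )
    return CohortDataset(mesh, subjects, ground_truth, norming, targets, config)


def write_cohort(cohort: CohortDataset, out_dir) -> None:
    """Serialize a cohort: GIFTI mesh, HDF5 signals, TSV tables."""
    from pathlib import Path

    from semint.preprocess import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.mesh.to_gifti(out / "mesh.surf.gii")
    cohort.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    if cohort.norming is not None:
        cohort.norming.to_csv(out / "norming.tsv", sep="\t", index=False)
    elec_frames = []
    for sid, sub in cohort.subjects.items():
        write_recording(sub.recording, out / f"{sid}_ieeg.h5")
        sub.events.to_csv(out / f"{sid}_events.tsv", sep="\t", index=False)
        elec_frames.append(sub.electrodes)
    pd.concat(elec_frames).to_csv(out / "electrodes.tsv", sep="\t", index=False)
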