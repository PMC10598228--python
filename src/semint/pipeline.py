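"""Config-driven orchestration: simulate -> preprocess -> BGA -> stats ->
surface maps -> conjunction, with a JSON run manifest.

The pipeline realizes the production chain of the analysis: per-word group
maps (window-averaged percent-change BGA 100-400 ms after each word
relative to the pre-sentence baseline), final-word condition contrasts
(reference, coherence, narrowing), cluster-corrected surface maps, and the
Boolean conjunction map, all on a synthetic cohort with known ground
truth.  Configuration is TOML; every stage is seeded and checksummed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from semint import __version__
from semint.band import (
    BandSpec,
    SmoothSpec,
    band_amplitude_recording,
    percent_change,
)
from semint.preprocess import (
    EpochSet,
    Recording,
    common_average_reference,
    epoch,
    remove_line_noise,
)
from semint.stats import classify_narrowing, group_traces, paired_contrast
from semint.surface import (
    SubjectNodeMap,
    SurfaceMesh,
    conjunction,
    estimate_cluster_threshold,
    geodesic_smooth,
    mema,
    mema_to_frame,
    smoothing_kernel,
    threshold_map,
)
from semint.synthetic import CohortDataset, EffectSpec, SyntheticConfig, make_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_subjects": 8,
        "electrodes_per_subject": 8,
        "mesh_vertices": 500,
        "effects": [],
    },
    "line": {"freq": 60.0, "n_harmonics": 3, "notch_halfwidth_hz": 1.0},
    "band": {"f_lo": 70.0, "f_hi": 150.0, "flank_halfwidth_hz": 1.5},
    "theta": {"f_lo": 4.0, "f_hi": 8.0},
    "sg": {"order": 3, "frame_ms": 251.0},
    "baseline": {"start_ms": -500.0, "end_ms": -100.0},
    "fdr": {"q": 0.05},
    "contrast": {"alpha": 0.01, "windows": [[500.0, 700.0], [700.0, 900.0]]},
    "mema": {"min_coverage": 3, "t_threshold": 2.57, "pct_threshold": 5.0},
    "conjunction": {"min_coverage": 2, "t_threshold": 2.57, "pct_threshold": 5.0},
    "cluster": {"alpha": 0.01, "n_iter": 500, "vertex_threshold": 2.5758},
    "smooth": {"fwhm_mm": 3.0},
    "word_window": [100.0, 400.0],
    "epoch_window": [-500.0, 1000.0],
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None) -> dict:
    """Load a TOML config merged over the shipped defaults."""
    cfg = _merge(DEFAULT_CONFIG, {})
    if path is not None:
        with open(path, "rb") as f:
            cfg = _merge(cfg, tomllib.load(f))
    return cfg


def validate_config(config: dict) -> list[str]:
    """Return a list of 'error: ...' / 'warning: ...' findings."""
    problems: list[str] = []
    q = config["fdr"]["q"]
    if not (0 < q < 1):
        problems.append(f"error: fdr.q must be in (0,1), got {q}")
    alpha = config["cluster"]["alpha"]
    if not (0 < alpha < 1):
        problems.append(f"error: cluster.alpha must be in (0,1), got {alpha}")
    b = config["band"]
    if not (0 < b["f_lo"] < b["f_hi"]):
        problems.append("error: band edges must satisfy 0 < f_lo < f_hi")
    base = config["baseline"]
    if base["end_ms"] <= base["start_ms"]:
        problems.append("error: baseline window is empty")
    if base["end_ms"] > 0:
        problems.append(
            "warning: baseline window overlaps the first word onset "
            "(convention is -500..-100 ms)"
        )
    for w in config["contrast"]["windows"]:
        if len(w) != 2 or w[1] <= w[0]:
            problems.append(f"error: malformed contrast window {w}")
    for eff in config["cohort"].get("effects", []):
        try:
            _effect_from_dict(eff)
        except (ValueError, KeyError) as exc:
            problems.append(f"error: effect spec {eff.get('name', '?')!r}: {exc}")
    return problems


def _effect_from_dict(d: dict) -> EffectSpec:
    return EffectSpec(
        name=d["name"],
        condition=dict(d["condition"]),
        band=tuple(d.get("band", (70.0, 150.0))),
        window_ms=tuple(d.get("window_ms", (100.0, 400.0))),
        amplitude_pct=float(d["amplitude_pct"]),
        nodes=tuple(int(n) for n in d.get("nodes", ())),
        lock=d.get("lock", "final_word"),
    )


def synthetic_config_from(config: dict) -> SyntheticConfig:
    c = config["cohort"]
    return SyntheticConfig(
        n_subjects=int(c.get("n_subjects", 8)),
        electrodes_per_subject=int(c.get("electrodes_per_subject", 8)),
        sample_rate=float(c.get("sample_rate", 2000.0)),
        trial_counts=dict(c.get("trial_counts", {"referential": 42, "non_referential": 42})),
        words_range=tuple(c.get("words_range", (3, 12))),
        mesh_vertices=int(c.get("mesh_vertices", 500)),
        anchor_nodes=tuple(int(n) for n in c.get("anchor_nodes", ())),
        effect_specs=tuple(_effect_from_dict(e) for e in c.get("effects", [])),
        line_freq=float(config["line"]["freq"]),
        n_harmonics=int(config["line"]["n_harmonics"]),
        rng_seed=int(config["seed"]),
    )


def preprocess_recording(rec: Recording, config: dict) -> Recording:
    """Line-noise removal followed by common-average re-referencing."""
    line = config["line"]
    rec = remove_line_noise(
        rec, line["freq"], line["n_harmonics"], line["notch_halfwidth_hz"]
    )
    return common_average_reference(rec)


def subject_bga_epochs(
    rec: Recording,
    events: pd.DataFrame,
    config: dict,
    lock: str = "final_word",
    window: tuple[float, float] | None = None,
) -> EpochSet:
    """Percent-change BGA epochs for one subject, baseline-corrected.

    The recording must already be preprocessed.  The baseline is taken
    from first-word-locked epochs of the same trials.
    """
    b = config["band"]
    band = BandSpec(b["f_lo"], b["f_hi"], b["flank_halfwidth_hz"])
    sg = SmoothSpec(config["sg"]["order"], config["sg"]["frame_ms"])
    amp = band_amplitude_recording(rec, band, sg)
    base = (config["baseline"]["start_ms"], config["baseline"]["end_ms"])
    window = tuple(window or config["epoch_window"])
    first = epoch(
        amp, events, "first_word", (base[0], max(base[1], window[1])),
        units="analytic_amplitude",
    )
    if lock == "first_word":
        return percent_change(first, base)
    locked = epoch(amp, events, lock, window, units="analytic_amplitude")
    return percent_change(locked, base, baseline_epochs=first)


def _trial_window_means(
    epochs: EpochSet, window: tuple[float, float]
) -> np.ndarray:
    mask = epochs.time_mask(window)
    return epochs.data[:, :, mask].mean(axis=-1)  # trials x channels


def subject_contrast_map(
    mesh: SurfaceMesh,
    electrodes: pd.DataFrame,
    epochs_a: EpochSet,
    epochs_b: EpochSet,
    window: tuple[float, float],
    subject_id: str = "",
) -> SubjectNodeMap:
    """Electrode-level A-B window contrast projected to mesh nodes.

    Per electrode: effect = difference of trial-mean window-averaged
    percent change; within-subject variance = var_A/n_A + var_B/n_B of
    trial window means.  Electrodes of one subject sharing a node are
    combined precision-weighted.
    """
    wa = _trial_window_means(epochs_a, window)
    wb = _trial_window_means(epochs_b, window)
    if wa.shape[0] < 2 or wb.shape[0] < 2:
        raise ValueError("need >= 2 trials per condition")
    eff = wa.mean(axis=0) - wb.mean(axis=0)
    var = wa.var(axis=0, ddof=1) / wa.shape[0] + wb.var(axis=0, ddof=1) / wb.shape[0]
    nodes = electrodes["node"].to_numpy()

    n = mesh.n_vertices
    effect = np.zeros(n)
    variance = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    for node in np.unique(nodes):
        sel = nodes == node
        w = 1.0 / np.maximum(var[sel], 1e-12)
        effect[node] = np.sum(w * eff[sel]) / np.sum(w)
        variance[node] = 1.0 / np.sum(w)
        covered[node] = True
    return SubjectNodeMap(subject_id, effect, variance, covered)


def subject_activation_map(
    mesh: SurfaceMesh,
    electrodes: pd.DataFrame,
    epochs: EpochSet,
    window: tuple[float, float],
    subject_id: str = "",
) -> SubjectNodeMap:
    """Window-mean percent change vs 0, projected to mesh nodes."""
    w = _trial_window_means(epochs, window)
    if w.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    eff = w.mean(axis=0)
    var = w.var(axis=0, ddof=1) / w.shape[0]
    nodes = electrodes["node"].to_numpy()
    n = mesh.n_vertices
    effect = np.zeros(n)
    variance = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    for node in np.unique(nodes):
        sel = nodes == node
        wts = 1.0 / np.maximum(var[sel], 1e-12)
        effect[node] = np.sum(wts * eff[sel]) / np.sum(wts)
        variance[node] = 1.0 / np.sum(wts)
        covered[node] = True
    return SubjectNodeMap(subject_id, effect, variance, covered)


def smooth_subject_map(
    mesh: SurfaceMesh, m: SubjectNodeMap, fwhm: float, kernel=None
) -> SubjectNodeMap:
    """Geodesic-Gaussian smooth a subject map; coverage spreads with the
    same kernel (a node is covered if any covered node lies in its
    kernel support)."""
    w = m.covered.astype(float)
    eff = geodesic_smooth(mesh, m.effect, fwhm, weights=w, kernel=kernel)
    var = geodesic_smooth(mesh, m.variance, fwhm, weights=w, kernel=kernel)
    if kernel is None:
        kernel = smoothing_kernel(mesh, fwhm)
    cov = np.asarray(kernel @ w) > 1e-12
    return SubjectNodeMap(m.subject_id, eff, var, cov)


def group_surface_map(
    mesh: SurfaceMesh,
    subject_maps: list[SubjectNodeMap],
    config: dict,
    kernel=None,
):
    """Smooth subject maps and combine them node-wise (random effects)."""
    fwhm = config["smooth"]["fwhm_mm"]
    if kernel is None:
        kernel = smoothing_kernel(mesh, fwhm)
    smoothed = [smooth_subject_map(mesh, m, fwhm, kernel) for m in subject_maps]
    return mema(smoothed, min_coverage=config["mema"]["min_coverage"])


def split_epochs(epochs: EpochSet, column: str, value: str) -> EpochSet:
    """Subset an EpochSet by a trial-info column value."""
    sel = (epochs.trial_info[column] == value).to_numpy()
    return EpochSet(
        epochs.data[sel],
        epochs.time_axis,
        epochs.lock,
        units=epochs.units,
        baseline_window=epochs.baseline_window,
        trial_info=epochs.trial_info[sel].reset_index(drop=True),
        channel_names=epochs.channel_names,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    checksums: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        with open(path, "w") as f:
            json.dump(self.__dict__, f, indent=2, sort_keys=True)


def run_full(config: dict, out_dir, cohort: CohortDataset | None = None) -> RunManifest:
    """Run the complete chain on a (generated or supplied) cohort.

    Writes per-word group maps, final-word contrast maps, the conjunction
    map, grouped traces, the narrowing classification, the reaction-time
    comparison, and a checksummed manifest under ``out_dir``.
    """
    problems = validate_config(config)
    errors = [p for p in problems if p.startswith("error")]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(cfg_hash, __version__, int(config["seed"]))
    t_start = time.time()

    if cohort is None:
        cohort = make_cohort(synthetic_config_from(config))
    manifest.timings["simulate"] = time.time() - t_start
    mesh = cohort.mesh
    kernel = smoothing_kernel(mesh, config["smooth"]["fwhm_mm"])

    # --- per-subject preprocessing and BGA epochs (final-word locked) ---
    t0 = time.time()
    per_subject: dict[str, dict] = {}
    max_words = 0
    for sid, sub in cohort.subjects.items():
        clean = preprocess_recording(sub.recording, config)
        final_pct = subject_bga_epochs(clean, sub.events, config, lock="final_word")
        first_pct = subject_bga_epochs(
            clean, sub.events, config, lock="first_word",
            window=(config["baseline"]["start_ms"],
                    config["cohort"].get("first_epoch_end_ms", 2500.0)),
        )
        per_subject[sid] = {
            "sub": sub,
            "final_pct": final_pct,
            "first_pct": first_pct,
        }
        max_words = max(
            max_words,
            int(sub.events.groupby("trial_id")["word_index"].max().max()) + 1,
        )
    manifest.timings["preprocess_bga"] = time.time() - t0

    # --- grouped traces and pointwise activation ---
    traces = {
        sid: d["final_pct"].data.mean(axis=0)  # electrodes x time
        for sid, d in per_subject.items()
    }
    gmean, gsem = group_traces(traces)
    trace_df = pd.DataFrame(
        {
            "time_ms": per_subject[next(iter(per_subject))]["final_pct"].time_axis,
            "mean_pct": gmean.mean(axis=0) if gmean.ndim == 2 else gmean,
            "sem_pct": gsem.mean(axis=0) if gsem.ndim == 2 else gsem,
        }
    )
    trace_df.to_csv(out / "group_trace_final_word.tsv", sep="\t", index=False)

    # --- per-word group activation maps (100-400 ms after each word) ---
    word_w = tuple(config["word_window"])
    n_words_mapped = 0
    for w_idx in range(max_words):
        offset = w_idx * 500.0
        window = (offset + word_w[0], offset + word_w[1])
        maps = []
        for sid, d in per_subject.items():
            ep = d["first_pct"]
            # length filter: trials must contain this word and cover the window
            has_word = (
                ep.trial_info["trial_id"]
                .map(
                    d["sub"].events.groupby("trial_id")["word_index"].max()
                )
                .to_numpy()
                >= w_idx
            )
            if window[1] > ep.time_axis[-1] or has_word.sum() < 2:
                continue
            sel = EpochSet(
                ep.data[has_word], ep.time_axis, ep.lock, units=ep.units,
                baseline_window=ep.baseline_window,
                trial_info=ep.trial_info[has_word].reset_index(drop=True),
                channel_names=ep.channel_names,
            )
            maps.append(
                subject_activation_map(mesh, d["sub"].electrodes, sel, window, sid)
            )
        if len(maps) < config["mema"]["min_coverage"]:
            continue
        gmap = group_surface_map(mesh, maps, config, kernel)
        mema_to_frame(gmap).to_csv(
            out / f"word{w_idx + 1}_mema.tsv", sep="\t", index=False
        )
        n_words_mapped += 1

    # --- final-word contrasts and conjunction ---
    t0 = time.time()
    narrow = classify_narrowing(cohort.norming, cohort.norming_targets)
    narrow_by_trial = dict(zip(narrow["sentence_id"], narrow["label"]))
    contrast_defs = {
        "reference": ("condition", "referential", "condition", "non_referential"),
        "coherence": ("coherence", "coherent", "coherence", "incoherent"),
        "narrowing": ("derived_narrowing", "limited", "derived_narrowing", "strong"),
    }
    cluster = estimate_cluster_threshold(
        mesh,
        config["smooth"]["fwhm_mm"],
        config["cluster"]["vertex_threshold"],
        config["cluster"]["alpha"],
        config["cluster"]["n_iter"],
        seed=int(config["seed"]) + 1,
        kernel=kernel,
    )
    adjacency = mesh.adjacency(weighted=False)
    windows = [tuple(w) for w in config["contrast"]["windows"]]
    binary_maps: dict[str, np.ndarray] = {}
    contrast_rows = []
    for name, (col_a, val_a, col_b, val_b) in contrast_defs.items():
        maps = []
        unit_a, unit_b = [], []
        for sid, d in per_subject.items():
            ep = d["final_pct"]
            info = ep.trial_info.copy()
            info["derived_narrowing"] = info["trial_id"].map(narrow_by_trial)
            ep = EpochSet(
                ep.data, ep.time_axis, ep.lock, units=ep.units,
                baseline_window=ep.baseline_window, trial_info=info,
                channel_names=ep.channel_names,
            )
            try:
                ep_a = split_epochs(ep, col_a, val_a)
                ep_b = split_epochs(ep, col_b, val_b)
                m = subject_contrast_map(
                    mesh, d["sub"].electrodes, ep_a, ep_b, windows[0], sid
                )
            except (ValueError, KeyError):
                continue
            maps.append(m)
            for win in windows:
                unit_a.append((sid, win, _trial_window_means(ep_a, win).mean()))
                unit_b.append((sid, win, _trial_window_means(ep_b, win).mean()))
        if len(maps) < 2:
            logger.warning("contrast %s: insufficient subjects; skipped", name)
            continue
        gmap = group_surface_map(mesh, maps, config, kernel)
        mema_to_frame(gmap).to_csv(out / f"{name}_mema.tsv", sep="\t", index=False)
        cj = config["conjunction"]
        binary_maps[name] = threshold_map(
            gmap,
            t_min=cj["t_threshold"],
            pct_min=cj["pct_threshold"],
            min_coverage=cj["min_coverage"],
            cluster=cluster,
            adjacency=adjacency,
        )
        # subject-level window contrasts (paired over subjects)
        for win in windows:
            a = [v for s, w, v in unit_a if w == win]
            b = [v for s, w, v in unit_b if w == win]
            if len(a) >= 2:
                res = paired_contrast(np.array(a), np.array(b), win, unit="subject")
                contrast_rows.append(
                    {
                        "contrast": name,
                        "window_start_ms": win[0],
                        "window_end_ms": win[1],
                        "beta": res.beta,
                        "sd": res.dispersion,
                        "t": res.t_stat,
                        "p": res.p_value,
                        "n_subjects": res.n_units,
                    }
                )
    pd.DataFrame(contrast_rows).to_csv(out / "contrasts.tsv", sep="\t", index=False)
    if binary_maps:
        cmap = conjunction(binary_maps)
        pd.DataFrame(
            {
                "node": np.arange(mesh.n_vertices),
                "code": cmap.code,
                "label": cmap.labels(),
            }
        ).to_csv(out / "conjunction.tsv", sep="\t", index=False)
    narrow.to_csv(out / "narrowing_labels.tsv", sep="\t", index=False)
    manifest.timings["surface_stats"] = time.time() - t0

    # --- reaction times (response onset minus final-word offset) ---
    rt_rows = []
    for sid, d in per_subject.items():
        ev = d["sub"].events
        fin = ev[ev["is_final_word"].astype(bool) & ev["correct"].astype(bool)]
        rts = (
            fin["response_onset"].to_numpy()
            - (fin["onset"].to_numpy() + fin["duration"].to_numpy())
        ) * 1000.0
        for cond in ("referential", "non_referential"):
            sel = fin["condition"].to_numpy() == cond
            if sel.any():
                rt_rows.append(
                    {"subject": sid, "condition": cond, "mean_rt_ms": rts[sel].mean()}
                )
    pd.DataFrame(rt_rows).to_csv(out / "reaction_times.tsv", sep="\t", index=False)

    for p in sorted(out.glob("*.tsv")):
        manifest.checksums[p.name] = _sha256(p)
    manifest.timings["total"] = time.time() - t_start
    manifest.to_json(out / "manifest.json")
    return manifest
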