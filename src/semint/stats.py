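"""Electrode-level statistics: activation traces, contrasts, ROI grouping.

Pointwise activation is tested with a one-tailed one-sample t-test at each
time point against zero percent change, corrected with the
Benjamini-Hochberg step-up rule (q < 0.05) across the time points of the
trace.  Condition differences are window means of percent-change BGA
compared with a two-sided paired t-test; the mean paired difference is the
reported effect (beta) with the SD of the differences as its dispersion.
Grouped traces average electrodes within subject and then subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from semint.preprocess import EpochSet

# Regions of interest as sets of HCP-parcellation labels.
ROI_GROUPS: dict[str, set[str]] = {
    "MPC": {"RSC", "POS1", "POS2", "v23ab", "7m", "31pv", "31pd", "d23ab"},
    "hippocampus_PHG": {"PreS", "EC", "PHA1"},
    "vmPFC": {"a24", "p32", "10r", "s32", "10v", "25", "OFC"},
    "OFC": {"11l", "13l"},
    "MFG": {"8C", "46", "p9", "46v"},
    "IFS": {"IFSa"},
    "pSTS": {"TPOJ1", "TPOJ2"},
}


@dataclass
class ActivationResult:
    """Pointwise activation statistics along one trace."""

    time_axis: np.ndarray
    t_stat: np.ndarray
    p_raw: np.ndarray
    significant: np.ndarray
    q: float


@dataclass
class ContrastResult:
    """Windowed paired condition contrast.

    ``beta`` is the mean over paired units of the A-minus-B difference of
    window-averaged percent-change BGA; ``dispersion`` is the SD of those
    paired differences.
    """

    window: tuple[float, float]
    beta: float
    dispersion: float
    t_stat: float
    p_value: float
    df: int
    n_units: int
    unit: str


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``.

    Rejects all sorted p_(i) with i <= max{i : p_(i) <= (i/m) q}.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def activation_significance(epochs: EpochSet, q: float = 0.05) -> ActivationResult:
    """One-tailed pointwise t-test of mean percent change > 0, BH-corrected.

    ``epochs.data`` must be trials x time (a single electrode or a grouped
    trace stack).  Time points with zero variance across trials are flagged
    (p set to 1) with a warning.
    """
    if epochs.units != "percent_change":
        raise ValueError("activation test requires percent_change units")
    data = epochs.data
    if data.ndim == 3:
        if data.shape[1] != 1:
            raise ValueError("pass one electrode at a time (trials x time)")
        data = data[:, 0, :]
    if data.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    sd = data.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance time points; p set to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_1samp(data, 0.0, axis=0, alternative="greater")
    t = np.where(degenerate, 0.0, res.statistic)
    p = np.where(degenerate | ~np.isfinite(res.pvalue), 1.0, res.pvalue)
    return ActivationResult(epochs.time_axis, t, p, bh_fdr(p, q), q)


def group_traces(
    traces_by_subject: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage average: electrodes within subject, then across subjects.

    Each value is an electrodes x time array.  Returns (group mean trace,
    SEM over subjects); SEM is zero when only one subject contributes.
    Subjects with no electrodes are excluded with a warning.
    """
    per_subject = []
    for sid, traces in traces_by_subject.items():
        traces = np.atleast_2d(np.asarray(traces, dtype=np.float64))
        if traces.size == 0:
            warnings.warn(f"subject {sid}: no electrode traces; excluded")
            continue
        per_subject.append(traces.mean(axis=0))
    if not per_subject:
        raise ValueError("no subjects with traces")
    stack = np.stack(per_subject)
    mean = stack.mean(axis=0)
    if stack.shape[0] == 1:
        return mean, np.zeros_like(mean)
    return mean, stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])


def paired_contrast(
    vals_a: np.ndarray,
    vals_b: np.ndarray,
    window: tuple[float, float] = (np.nan, np.nan),
    unit: str = "unit",
) -> ContrastResult:
    """Two-sided paired t-test on per-unit condition means."""
    a = np.asarray(vals_a, dtype=np.float64)
    b = np.asarray(vals_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired units")
    d = a - b
    beta = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        warnings.warn("zero variance of paired differences; t degenerate")
        t = 0.0 if beta == 0 else np.inf * np.sign(beta)
        p = 1.0 if beta == 0 else 0.0
    else:
        t = beta / (sd / np.sqrt(n))
        p = float(2 * sps.t.sf(abs(t), df=n - 1))
    return ContrastResult(
        window=tuple(window),
        beta=beta,
        dispersion=sd,
        t_stat=float(t),
        p_value=p,
        df=n - 1,
        n_units=n,
        unit=unit,
    )


def window_means(epochs: EpochSet, window: tuple[float, float]) -> np.ndarray:
    """Per-channel mean over trials and the half-open time window."""
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError(f"window {window} not covered by epochs")
    return epochs.data[:, :, mask].mean(axis=(0, 2))


def window_contrast(
    epochs_a: EpochSet,
    epochs_b: EpochSet,
    window: tuple[float, float],
    unit: str = "electrode",
) -> ContrastResult:
    """Windowed condition contrast paired over electrodes.

    Per electrode: the mean percent change over the window and the
    condition's trials; the paired A-minus-B differences are tested with a
    two-sided paired t-test (evaluated at alpha 0.01 by convention).
    """
    if unit != "electrode":
        raise ValueError("window_contrast pairs electrodes; aggregate subjects "
                         "with group-level paired_contrast instead")
    if epochs_a.units != "percent_change" or epochs_b.units != "percent_change":
        raise ValueError("window contrast requires percent_change units")
    return paired_contrast(
        window_means(epochs_a, window),
        window_means(epochs_b, window),
        window=window,
        unit=unit,
    )


def group_by_parcel(
    electrodes: pd.DataFrame,
    grouping: dict[str, set[str]] = ROI_GROUPS,
) -> dict[str, list[str]]:
    """Assign electrodes to ROIs by their parcel label.

    ``electrodes`` needs columns ``name`` and ``parcel``.  An electrode
    whose parcel appears in several ROI sets is assigned to all of them
    (with a warning); unknown parcels are left unassigned with a warning.
    """
    rois: dict[str, list[str]] = {roi: [] for roi in grouping}
    for _, row in electrodes.iterrows():
        hits = [roi for roi, parcels in grouping.items() if row["parcel"] in parcels]
        if not hits:
            warnings.warn(f"electrode {row['name']}: parcel {row['parcel']!r} "
                          "not in any ROI; unassigned")
            continue
        if len(hits) > 1:
            warnings.warn(f"electrode {row['name']}: parcel in multiple ROIs {hits}")
        for roi in hits:
            rois[roi].append(row["name"])
    return rois


def classify_narrowing(
    norming: pd.DataFrame,
    targets: dict,
    rule: str = "median",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Label sentences as strong vs limited semantic narrowing.

    The identification probability of a sentence is the fraction of norming
    participants whose typed answer at the *penultimate* word position
    matches the target word (case-insensitive, whitespace-trimmed exact
    match).  Sentences at or above the cut (the median probability by
    default, or an explicit ``threshold``) are labelled ``strong``, the
    rest ``limited``.  Sentences without penultimate-position responses are
    excluded with a warning.

    ``norming`` is long-format with columns sentence_id, participant,
    word_position (1-based), answer.
    """
    records = []
    for sid, grp in norming.groupby("sentence_id"):
        if sid not in targets:
            warnings.warn(f"sentence {sid}: no target word; excluded")
            continue
        penult = int(grp["word_position"].max()) - 1
        at_pen = grp[grp["word_position"] == penult]
        if at_pen.empty:
            warnings.warn(f"sentence {sid}: no penultimate-position data; excluded")
            continue
        target = str(targets[sid]).strip().lower()
        answers = at_pen["answer"].astype(str).str.strip().str.lower()
        records.append((sid, float((answers == target).mean())))
    result = pd.DataFrame(records, columns=["sentence_id", "identification_probability"])
    if result.empty:
        return result.assign(label=pd.Series(dtype=str))
    if rule == "median":
        cut = float(result["identification_probability"].median())
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a threshold value")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown narrowing rule {rule!r}")
    result["label"] = np.where(
        result["identification_probability"] >= cut, "strong", "limited"
    )
    return result


def rt_compare(
    rt_a: np.ndarray, rt_b: np.ndarray, alternative: str = "two-sided"
) -> ContrastResult:
    """Paired t-test on per-subject mean reaction times (ms)."""
    a = np.asarray(rt_a, dtype=np.float64)
    b = np.asarray(rt_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("reaction-time vectors must be paired (equal length)")
    res = paired_contrast(a, b, unit="subject")
    if alternative != "two-sided":
        if res.t_stat == 0 and res.dispersion == 0:
            return res
        p_one = float(sps.t.sf(res.t_stat, df=res.df))
        if alternative == "less":
            p_one = 1.0 - p_one
        return ContrastResult(
            res.window, res.beta, res.dispersion, res.t_stat, p_one,
            res.df, res.n_units, res.unit,
        )
    return res
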