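"""Model assessment and clinical reporting.

AUC is computed in the Mann-Whitney formulation — the probability that a
randomly drawn dyskinetic sample scores above a randomly drawn
non-dyskinetic one, with ties counting one half — and cross-checked against
the trapezoidal area under the swept ROC curve.  On top of that sit the
reporting tools: bootstrap confidence envelopes for the ROC, per-grade
optimal thresholds (Youden's J), activity-stratified AUC tables, the mean
waveforms of the highest-scoring windows (the "what did it learn" view),
and the 24-hour episode timeline used for clinical summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import sklearn.metrics

from . import cgp
from .signal import WINDOW_WIDTH, magnitude


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("degenerate labels: scores/labels shape mismatch")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("degenerate labels: one class is empty")
    return scores, labels


def auc(scores, binary_labels) -> float:
    """Mann-Whitney AUC: (#{pos > neg} + 0.5 #{ties}) / (n_pos * n_neg).

    Rank-based, hence invariant under strictly increasing transforms of
    the scores.

    Raises
    ------
    ValueError
        ``"degenerate labels"`` when either class is empty.
    """
    scores, labels = _check_binary(scores, binary_labels)
    ranks = scipy.stats.rankdata(scores)  # midranks handle ties as 1/2
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class RocCurve:
    """A swept ROC curve: (FPR, TPR) points from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    bands: Optional["RocBands"] = None

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


@dataclass
class RocBands:
    """Pointwise bootstrap quantile envelope on a fixed FPR grid."""

    fpr_grid: np.ndarray
    tpr_lo: np.ndarray
    tpr_hi: np.ndarray
    level: float = 0.95


def roc_curve(scores, binary_labels) -> RocCurve:
    """Sweep every distinct score threshold; trapezoidal area equals the
    Mann-Whitney AUC to numerical precision."""
    scores, labels = _check_binary(scores, binary_labels)
    fpr, tpr, thr = sklearn.metrics.roc_curve(labels, scores, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=area)


def _interp_tpr(fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray) -> np.ndarray:
    # ROC points are already sorted by FPR; np.interp needs strict handling
    # of plateaus, so take the max TPR attainable at each grid FPR.
    out = np.interp(grid, fpr, tpr)
    return out


def bootstrap_bands(
    scores,
    binary_labels,
    n_boot: int = 200,
    rng=None,
    fpr_grid: Optional[np.ndarray] = None,
    level: float = 0.95,
) -> RocBands:
    """Stratified-bootstrap TPR envelope on a fixed FPR grid.

    Resampling is with replacement within each class so both classes stay
    non-empty; the 2.5/97.5 percentile TPR at each grid point forms the
    confidence boundaries drawn around the ROC curve.
    """
    scores, labels = _check_binary(scores, binary_labels)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng)
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    tprs = np.empty((n_boot, fpr_grid.size))
    for b in range(n_boot):
        ps = rng.choice(pos, size=pos.size, replace=True)
        ns = rng.choice(neg, size=neg.size, replace=True)
        s = np.concatenate([ps, ns])
        l = np.concatenate([np.ones(ps.size, int), np.zeros(ns.size, int)])
        curve = roc_curve(s, l)
        tprs[b] = _interp_tpr(curve.fpr, curve.tpr, fpr_grid)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(tprs, alpha, axis=0)
    hi = np.quantile(tprs, 1.0 - alpha, axis=0)
    return RocBands(fpr_grid=fpr_grid, tpr_lo=lo, tpr_hi=hi, level=level)


#: Grade boundaries reported in the threshold table, as (name, cut) pairs:
#: positives are items with grade >= cut.
GRADE_BOUNDARIES: Tuple[Tuple[str, float], ...] = (
    (">=1", 1.0),
    (">=2", 2.0),
    (">=3", 3.0),
    (">=4", 4.0),
)


@dataclass
class ThresholdEntry:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def _best_youden(neg: np.ndarray, pos: np.ndarray) -> ThresholdEntry:
    """Exhaustive cut-point scan maximising sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct pooled scores,
    plus sentinels below and above everything; classification is
    score >= threshold -> positive.  Ties prefer the lowest threshold.
    """
    pooled = np.unique(np.concatenate([neg, pos]))
    candidates = [pooled[0] - 1.0]
    candidates += list((pooled[:-1] + pooled[1:]) / 2.0)
    candidates += [pooled[-1] + 1.0]
    best: Optional[ThresholdEntry] = None
    for t in candidates:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = ThresholdEntry(float(t), sens, spec, j)
    return best


def grade_thresholds(scores_by_grade: Mapping[float, Sequence[float]]) -> Dict[str, ThresholdEntry]:
    """Optimal score thresholds between adjacent clinical grade boundaries.

    For each boundary (no dyskinesia vs any, <2 vs >=2, <3 vs >=3, <4 vs 4)
    the threshold maximises Youden's J; sensitivity and specificity at the
    optimum are reported.  Thresholds are coerced to be non-decreasing
    across boundaries so the fitted model maps scores to grade bands
    consistently.

    Raises
    ------
    ValueError
        ``"missing grade"`` when a boundary has an empty side.
    """
    groups = {float(g): np.asarray(v, dtype=float) for g, v in scores_by_grade.items()}
    if len(groups) < 2:
        raise ValueError("missing grade: need at least two grade groups")
    out: Dict[str, ThresholdEntry] = {}
    prev_threshold = -np.inf
    for name, cut in GRADE_BOUNDARIES:
        neg = np.concatenate([v for g, v in groups.items() if g < cut] or [np.array([])])
        pos = np.concatenate([v for g, v in groups.items() if g >= cut] or [np.array([])])
        if neg.size == 0 or pos.size == 0:
            continue
        entry = _best_youden(neg, pos)
        if entry.threshold < prev_threshold:  # coerce monotone
            entry = ThresholdEntry(
                prev_threshold,
                float((pos >= prev_threshold).mean()),
                float((neg < prev_threshold).mean()),
                float((pos >= prev_threshold).mean() + (neg < prev_threshold).mean() - 1.0),
            )
        prev_threshold = entry.threshold
        out[name] = entry
    if not out:
        raise ValueError("missing grade: no computable boundary")
    return out


def stratified_auc(scores, binary_labels, activity_tags) -> pd.DataFrame:
    """Per-activity AUC table.

    Strata in which either class is absent are flagged (``auc`` is NaN and
    ``flag`` names the missing class) rather than computed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=int)
    tags = np.asarray(activity_tags, dtype=object)
    rows = []
    for tag in sorted(set(tags.tolist())):
        m = tags == tag
        n_pos = int(labels[m].sum())
        n_neg = int(m.sum() - n_pos)
        if n_pos == 0 or n_neg == 0:
            rows.append(
                {"activity": tag, "n_pos": n_pos, "n_neg": n_neg,
                 "auc": np.nan, "flag": "missing class"}
            )
        else:
            rows.append(
                {"activity": tag, "n_pos": n_pos, "n_neg": n_neg,
                 "auc": auc(scores[m], labels[m]), "flag": ""}
            )
    return pd.DataFrame(rows, columns=["activity", "n_pos", "n_neg", "auc", "flag"])


def top_window_pattern(
    model,
    windows: np.ndarray,
    k_list: Sequence[int] = (10, 100, 1000),
) -> Dict[int, np.ndarray]:
    """Element-wise mean of the k highest-output time-series windows.

    This visualises the acceleration pattern the classifier responds to.
    Windows are ranked by the model's output on its own feature
    representation of each window, but the returned waveforms are always
    the raw 32-sample windows.

    Raises
    ------
    ValueError
        ``"insufficient windows"`` when fewer than max(k) windows exist.
    """
    from .evolution import FeatureMode  # local import avoids a cycle

    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    if windows.shape[0] < max(k_list):
        raise ValueError(
            f"insufficient windows: {windows.shape[0]} < {max(k_list)}"
        )
    mode = FeatureMode(model.feature_mode)
    if mode is FeatureMode.SPECTRAL_LONG:
        raise ValueError("insufficient windows: long-spectrum models score "
                         "whole segments, not windows")
    if mode is FeatureMode.TIME:
        feats = windows
    else:
        from .signal import short_term_spectra

        feats = short_term_spectra(windows)
    outputs = cgp.evaluate_batch(model.genome, feats)
    order = np.argsort(outputs)[::-1]
    return {int(k): windows[order[:k]].mean(axis=0) for k in k_list}


@dataclass
class Episode:
    start_s: float
    end_s: float
    band: int  # grade band (3 or 4)


@dataclass
class EpisodeTimeline:
    """Epoch-level scores/bands for one recording plus merged episodes of
    significant (grade >= 3) dyskinesia."""

    epochs: pd.DataFrame  # columns: start_s, score, band (band NaN in sleep)
    episodes: List[Episode]
    epoch_length_s: float
    medication_times: List[float] = field(default_factory=list)
    sleep_intervals: List[Tuple[float, float]] = field(default_factory=list)


def _band_of(score: float, thresholds: Mapping[str, float]) -> int:
    """Highest grade boundary whose fitted threshold the score reaches."""
    band = 0
    for name, cut in GRADE_BOUNDARIES:
        t = thresholds.get(name)
        if t is not None and score >= t:
            band = int(cut)
    return band


def episode_summary(
    recording,
    model,
    epoch_length_s: float = 60.0,
    medication_times: Optional[Sequence[float]] = None,
    sleep_intervals: Optional[Sequence[Tuple[float, float]]] = None,
    channel_group: str = "accel",
) -> EpisodeTimeline:
    """Cut a recording into consecutive epochs, score and band each, and
    merge adjacent same-band epochs at grade >= 3 into episodes.

    Sleep epochs (any overlap with a supplied sleep interval) are excluded
    from banding.  No gap-bridging: a single lower-band epoch splits an
    episode in two.

    Raises
    ------
    ValueError
        ``"model not calibrated"`` when the model has no fitted thresholds.
    """
    from .evolution import FeatureMode, segment_score  # local: avoids cycle

    if not model.thresholds:
        raise ValueError("model not calibrated: fit grade thresholds first")
    if epoch_length_s < WINDOW_WIDTH / recording.sample_rate:
        raise ValueError("model not calibrated: epoch shorter than one window")
    medication_times = list(medication_times or [])
    sleep_intervals = [tuple(map(float, s)) for s in (sleep_intervals or [])]
    series = magnitude(recording, channel_group).values
    n_epoch = int(round(epoch_length_s * recording.sample_rate))
    rows = []
    mode = FeatureMode(model.feature_mode)
    for start in range(0, series.shape[0] - WINDOW_WIDTH + 1, n_epoch):
        chunk = series[start : start + n_epoch]
        if chunk.shape[0] < WINDOW_WIDTH:
            break
        t0 = start / recording.sample_rate
        t1 = t0 + chunk.shape[0] / recording.sample_rate
        score = segment_score(model.genome, chunk, mode, recording.sample_rate)
        asleep = any(t0 < e and t1 > s for s, e in sleep_intervals)
        band = np.nan if asleep else _band_of(score, model.thresholds)
        rows.append({"start_s": t0, "end_s": t1, "score": score, "band": band})
    epochs = pd.DataFrame(rows, columns=["start_s", "end_s", "score", "band"])

    episodes: List[Episode] = []
    current: Optional[Episode] = None
    for row in epochs.itertuples(index=False):
        band = row.band
        if not np.isnan(band) and band >= 3:
            if current is not None and current.band == int(band) and abs(current.end_s - row.start_s) < 1e-9:
                current.end_s = row.end_s
            else:
                if current is not None:
                    episodes.append(current)
                current = Episode(row.start_s, row.end_s, int(band))
        else:
            if current is not None:
                episodes.append(current)
                current = None
    if current is not None:
        episodes.append(current)
    return EpisodeTimeline(
        epochs=epochs,
        episodes=episodes,
        epoch_length_s=epoch_length_s,
        medication_times=medication_times,
        sleep_intervals=sleep_intervals,
    )


def fit_model_thresholds(model, scores_by_grade: Mapping[float, Sequence[float]]) -> None:
    """Calibrate a trained model's grade thresholds in place."""
    table = grade_thresholds(scores_by_grade)
    model.thresholds = {name: entry.threshold for name, entry in table.items()}


# ---------------------------------------------------------------------------
# Plots (clinical summary chart and AUC distribution box plots)


def plot_episode_timeline(timeline: EpisodeTimeline, path) -> None:
    """Render the daily summary chart: score trace, grade-3/4 episode bars,
    medication dots and sleep shading."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    t = timeline.epochs["start_s"] / 3600.0
    ax.plot(t, timeline.epochs["score"], color="0.3", lw=0.8, label="classifier output")
    for ep in timeline.episodes:
        colour = "darkgreen" if ep.band >= 4 else "yellowgreen"
        ax.axvspan(ep.start_s / 3600.0, ep.end_s / 3600.0, color=colour, alpha=0.4)
    for s, e in timeline.sleep_intervals:
        ax.axvspan(s / 3600.0, e / 3600.0, color="purple", alpha=0.15)
    for m in timeline.medication_times:
        ax.plot([m / 3600.0], [timeline.epochs["score"].max()], "rv", ms=6)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("output")
    ax.set_title("Dyskinesia summary (dark: grade 4, light: grade 3, shaded: sleep)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_auc_distributions(distributions: Mapping[str, Sequence[float]], path) -> None:
    """Box plots of test-AUC distributions over independent runs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(distributions)
    ax.boxplot([distributions[n] for n in names], tick_labels=names, notch=False)
    ax.set_ylabel("test AUC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
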