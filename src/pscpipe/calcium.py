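"""Ca2+ imaging trace analysis: ΔF/F, transient detection, kinetics, stats.

Traces are uniformly sampled fluorescence time series (one per ROI).  The
detector finds transients as peaks exceeding a robust-noise threshold, with
a 20%-of-peak convention for onset and offset: rise time is peak minus the
last sub-20% sample before it, fall time the first sub-20% sample after it
(right-censored events are flagged and excluded from kinetic means).
Group comparisons use the nonparametric tests standard for such metrics:
Mann–Whitney for two groups, Kruskal–Wallis plus Dunn's post-hoc for more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

logger = logging.getLogger(__name__)

__all__ = [
    "TraceSet",
    "TransientEvent",
    "TransientMetrics",
    "delta_f_over_f",
    "detect_transients",
    "transient_metrics",
    "classify_stimulus_response",
    "dunn_posthoc",
    "compare_groups",
    "p_to_stars",
]


@dataclass
class TraceSet:
    """Uniformly sampled fluorescence traces, one column per ROI."""

    time: np.ndarray  # seconds
    traces: pd.DataFrame  # rows = time points, columns = ROI ids
    sampling_hz: float
    condition: str | None = None
    stimulus_time_s: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if len(self.time) != len(self.traces):
            raise ValueError("time axis and traces have different lengths")
        dt = np.diff(self.time)
        if len(dt) and not np.allclose(dt, 1.0 / self.sampling_hz, rtol=1e-6):
            raise ValueError("time axis is not uniform at 1/sampling_hz")

    @property
    def duration_s(self) -> float:
        return float(len(self.time) / self.sampling_hz)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.traces.columns)


@dataclass
class TransientEvent:
    onset_s: float
    peak_s: float
    amplitude: float  # ΔF/F above baseline
    rise_s: float
    fall_s: float  # NaN when right-censored
    censored: bool = False

    def __post_init__(self) -> None:
        if self.onset_s > self.peak_s + 1e-9:
            raise ValueError("onset after peak")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class TransientMetrics:
    """Per-ROI transient summary; period is defined only with >= 2 events."""

    count: int
    mean_period_s: float  # NaN when count < 2
    mean_amplitude: float
    mean_rise_s: float
    mean_fall_s: float


def delta_f_over_f(
    raw: np.ndarray | pd.Series,
    baseline_method: str = "percentile",
    percentile: float = 10.0,
) -> np.ndarray:
    """(F − F0)/F0 with F0 from the chosen baseline estimator.

    ``percentile`` (default, 10th percentile of the whole trace) is robust to
    sparse transients; ``median`` and ``mean`` are provided for comparison.
    """
    x = np.asarray(raw, dtype=float)
    if baseline_method == "percentile":
        f0 = float(np.percentile(x, percentile))
    elif baseline_method == "median":
        f0 = float(np.median(x))
    elif baseline_method == "mean":
        f0 = float(np.mean(x))
    else:
        raise ValueError(f"unknown baseline method {baseline_method!r}")
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0} is not positive")
    return (x - f0) / f0


def robust_noise_sd(trace: np.ndarray) -> float:
    """Noise SD via 1.4826 × MAD of first differences / sqrt(2).

    First-differencing removes slow drift and the transients themselves
    contribute few samples, so the estimate tracks the additive noise floor.
    """
    d = np.diff(np.asarray(trace, dtype=float))
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_transients(
    trace: np.ndarray | pd.Series,
    sampling_hz: float,
    threshold_k: float = 3.0,
    min_separation_s: float = 4.0,
    start_time_s: float = 0.0,
) -> list[TransientEvent]:
    """Detect Ca2+ transients in a ΔF/F trace.

    A sample is a candidate peak when it exceeds baseline (trace median)
    plus ``threshold_k`` robust noise SDs and rises at least that much above
    its surroundings (peak prominence), so noise ripples riding on a slowly
    decaying shoulder are not counted as separate events.  Peaks closer than
    ``min_separation_s`` are merged to the larger one.  Onset/offset use the
    20%-of-peak-amplitude crossing convention.
    """
    x = np.asarray(trace, dtype=float)
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be positive")
    baseline = float(np.median(x))
    sigma = robust_noise_sd(x)
    height = baseline + threshold_k * sigma
    distance = max(1, int(round(min_separation_s * sampling_hz)))
    peaks, _ = signal.find_peaks(
        x,
        height=height if sigma > 0 else None,
        prominence=threshold_k * sigma if sigma > 0 else None,
        distance=distance,
    )
    if sigma == 0:
        peaks = peaks[x[peaks] > baseline]
    dt = 1.0 / sampling_hz
    events: list[TransientEvent] = []
    for idx, p in enumerate(peaks):
        amp = x[p] - baseline
        if amp <= 0:
            continue
        level = baseline + 0.2 * amp
        left_bound = peaks[idx - 1] if idx > 0 else -1
        onset_i = None
        for i in range(p - 1, left_bound, -1):
            if x[i] <= level:
                onset_i = i
                break
        if onset_i is None:
            onset_i = left_bound + 1 if left_bound >= 0 else 0
        right_bound = peaks[idx + 1] if idx + 1 < len(peaks) else len(x)
        fall_i = None
        for i in range(p + 1, right_bound):
            if x[i] <= level:
                fall_i = i
                break
        censored = fall_i is None
        events.append(TransientEvent(
            onset_s=start_time_s + onset_i * dt,
            peak_s=start_time_s + p * dt,
            amplitude=float(amp),
            rise_s=(p - onset_i) * dt,
            fall_s=float("nan") if censored else (fall_i - p) * dt,
            censored=censored,
        ))
    return events


def transient_metrics(
    events: Sequence[TransientEvent], duration_s: float
) -> TransientMetrics:
    """Count, mean oscillation period (inter-peak interval) and kinetic means."""
    count = len(events)
    peaks = np.asarray([e.peak_s for e in events], dtype=float)
    if np.any(np.diff(peaks) < 0):
        raise ValueError("events must be sorted by time")
    period = float(np.mean(np.diff(peaks))) if count >= 2 else float("nan")
    amp = float(np.mean([e.amplitude for e in events])) if count else float("nan")
    rise = float(np.mean([e.rise_s for e in events])) if count else float("nan")
    falls = [e.fall_s for e in events if not e.censored]
    fall = float(np.mean(falls)) if falls else float("nan")
    return TransientMetrics(
        count=count,
        mean_period_s=period,
        mean_amplitude=amp,
        mean_rise_s=rise,
        mean_fall_s=fall,
    )


def metrics_table(traceset: TraceSet, **detect_kwargs) -> pd.DataFrame:
    """Per-ROI transient metrics for every trace in a TraceSet."""
    rows = []
    for roi in traceset.roi_ids:
        events = detect_transients(
            traceset.traces[roi].to_numpy(), traceset.sampling_hz, **detect_kwargs
        )
        m = transient_metrics(events, traceset.duration_s)
        rows.append({
            "roi": roi,
            "count": m.count,
            "mean_period_s": m.mean_period_s,
            "mean_amplitude": m.mean_amplitude,
            "mean_rise_s": m.mean_rise_s,
            "mean_fall_s": m.mean_fall_s,
        })
    return pd.DataFrame(rows).set_index("roi")


def classify_stimulus_response(
    trace: np.ndarray | pd.Series,
    time: np.ndarray,
    stimulus_time_s: float,
    window_s: float = 60.0,
    threshold_k: float = 3.0,
) -> tuple[bool, float]:
    """Responder call for a depolarization (e.g. high-KCl) stimulus.

    A ROI responds when its post-stimulus maximum within ``window_s``
    exceeds the pre-stimulus baseline (median) by ``threshold_k`` robust
    noise SDs of the pre-stimulus segment.  Returns (responder, amplitude),
    amplitude in ΔF/F above the pre-stimulus baseline.
    """
    x = np.asarray(trace, dtype=float)
    t = np.asarray(time, dtype=float)
    if not (t[0] <= stimulus_time_s <= t[-1]):
        raise ValueError("stimulus time outside the trace")
    pre = x[t < stimulus_time_s]
    if len(pre) < 3:
        raise ValueError("too few pre-stimulus samples")
    if stimulus_time_s + window_s > t[-1]:
        logger.warning("response window extends past trace end; truncated")
    post_mask = (t >= stimulus_time_s) & (t <= stimulus_time_s + window_s)
    baseline = float(np.median(pre))
    sigma = robust_noise_sd(pre)
    amp = float(x[post_mask].max() - baseline)
    return amp > threshold_k * sigma, amp


def p_to_stars(p: float) -> str:
    """Significance stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


def dunn_posthoc(
    values: np.ndarray, labels: np.ndarray, adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal–Wallis.

    Uses pooled ranks with the standard tie correction; z statistics are
    referred to the normal distribution and p values adjusted across pairs
    (Bonferroni by default, BH optional).
    """
    from .expression import bh_adjust

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels).tolist())
    N = len(values)
    ranks = stats.rankdata(values)
    # tie correction term
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            g1, g2 = groups[i], groups[j]
            var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[g1] + 1.0 / sizes[g2])
            if var <= 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[g1] - mean_ranks[g2]) / np.sqrt(var)
                p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": g1, "group2": g2, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["adj_p"] = np.minimum(out["p"] * len(out), 1.0)
    elif adjust == "bh":
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    elif adjust == "none":
        out["adj_p"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["stars"] = out["adj_p"].map(p_to_stars)
    return out


def compare_groups(metric_table: pd.DataFrame, value_col: str = "value",
                   group_col: str = "group") -> dict:
    """Nonparametric comparison of a metric across condition groups.

    Two groups: Mann–Whitney U (two-sided).  More: Kruskal–Wallis followed
    by Dunn's pairwise post-hoc with Bonferroni adjustment.  All-tied data
    yields p = 1 with an explanatory note.
    """
    values = metric_table[value_col].to_numpy(dtype=float)
    labels = metric_table[group_col].to_numpy()
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = {g: int((labels == g).sum()) for g in groups}
    if min(sizes.values()) < 3:
        raise ValueError("every group needs at least three observations")
    if np.ptp(values) == 0:
        return {"method": "degenerate", "statistic": float("nan"), "p": 1.0,
                "stars": "ns", "note": "all observations tied", "pairwise": None}
    if len(groups) == 2:
        a = values[labels == groups[0]]
        b = values[labels == groups[1]]
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return {"method": "mann-whitney", "statistic": float(res.statistic),
                "p": float(res.pvalue), "stars": p_to_stars(res.pvalue),
                "pairwise": None}
    samples = [values[labels == g] for g in groups]
    kw = stats.kruskal(*samples)
    pairwise = dunn_posthoc(values, labels)
    return {"method": "kruskal-wallis+dunn", "statistic": float(kw.statistic),
            "p": float(kw.pvalue), "stars": p_to_stars(kw.pvalue),
            "pairwise": pairwise}
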