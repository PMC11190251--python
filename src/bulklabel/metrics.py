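"""Annotation-efficiency metrics.

The central quantity is *labels per second* (LPS): objects labeled divided by
elapsed time.  For an assisted session it comes in two flavours — *human*
time (model training and embedding excluded, since the annotator can walk
away) and *total* time (compute included).  The unaided baseline rate
``LPS_M`` is extrapolated from a timed subset labeled one object at a time,
and the speed-up ``θ = LPS_assisted / LPS_M`` summarizes the efficiency gain.
Windowed LPS (15-minute sliding window, 5-minute stride by default) gives
robust lower/upper bounds by smoothing outliers.  Label fidelity between two
labeling runs is measured as *concordance*: the percentage of commonly
labeled objects with identical labels (multiclass accuracy), optionally
excluding uncertainty labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import SessionLog

__all__ = [
    "EfficiencyReport",
    "WindowSpec",
    "lps",
    "efficiency_from_log",
    "windowed_lps",
    "manual_baseline",
    "speedup",
    "concordance",
    "format_report",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding window for LPS bounds: 15-min window, 5-min stride."""

    window_seconds: float = 900.0
    stride_seconds: float = 300.0

    def __post_init__(self):
        if not self.window_seconds >= self.stride_seconds > 0:
            raise ValueError("need window >= stride > 0")


@dataclass
class EfficiencyReport:
    """Summary of one labeling session."""

    n_labels: int
    human_seconds: float
    total_seconds: float
    lps_human: float
    lps_total: float
    lps_manual: float | None = None
    theta: float | None = None
    window_min: float | None = None
    window_max: float | None = None


def lps(n_labels: int, elapsed_seconds: float) -> float:
    """Labels per second: ``n_labels / elapsed_seconds``."""
    if elapsed_seconds <= 0:
        raise ValueError("elapsed_seconds must be positive")
    if n_labels < 0:
        raise ValueError("n_labels must be non-negative")
    return n_labels / elapsed_seconds


def _check_intervals(log: SessionLog) -> None:
    ivs = sorted((s, e) for s, e, _ in log.compute_intervals)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError("compute intervals overlap")
    if log.human_seconds < 0:
        raise ValueError("compute time exceeds the session span")


def efficiency_from_log(log: SessionLog, lps_manual: float | None = None,
                        window: WindowSpec | None = None) -> EfficiencyReport:
    """Derive the full efficiency report from a session log.

    ``n_labels`` counts distinct objects with a final confirmed label;
    human time is the session span minus all training/embedding intervals.
    When ``lps_manual`` is supplied, θ is computed against human-time LPS.
    """
    _check_intervals(log)
    total = log.span
    human = log.human_seconds
    n = log.n_labeled()
    report = EfficiencyReport(
        n_labels=n,
        human_seconds=human,
        total_seconds=total,
        lps_human=lps(n, human),
        lps_total=lps(n, total),
    )
    if lps_manual is not None:
        report.lps_manual = lps_manual
        report.theta = speedup(report.lps_human, lps_manual)
    if log.events:
        _, report.window_min, report.window_max = windowed_lps(
            log, window or WindowSpec())
    return report


def windowed_lps(log: SessionLog, spec: WindowSpec | None = None,
                 ) -> tuple[list[tuple[float, float]], float, float]:
    """Per-window LPS series and its min/max bounds.

    Windows start at the session start and advance by the stride; the last
    window is clipped to the session end.  A window's numerator counts the
    labels of events with timestamp in ``[start, start + window)``; its
    denominator excludes compute time falling inside the window (keeping the
    windowed rate a *human*-time rate).  Windows whose denominator is zero
    (fully compute) are skipped.
    """
    if not log.events:
        raise ValueError("windowed LPS needs a non-empty event log")
    spec = spec or WindowSpec()
    t0 = log.start_time
    end = t0 + log.span
    series: list[tuple[float, float]] = []
    start = t0
    while True:
        w_end = min(start + spec.window_seconds, end)
        n = sum(e.n_objects for e in log.events
                if start <= e.timestamp < start + spec.window_seconds)
        compute = sum(
            max(0.0, min(e, w_end) - max(s, start))
            for s, e, _ in log.compute_intervals)
        denom = (w_end - start) - compute
        if denom > 0:
            series.append((start, n / denom))
        start += spec.stride_seconds
        if start >= end:
            break
    values = [v for _, v in series]
    return series, min(values), max(values)


def manual_baseline(subset_log: SessionLog, total_objects: int | None = None,
                    ) -> float:
    """Unaided labeling rate ``LPS_M`` from a timed subset session.

    The subset rate extrapolates unchanged to the full dataset (the
    ``total_objects`` argument documents the target population; it does not
    change the rate).
    """
    if not subset_log.events:
        raise ValueError("manual baseline needs a non-empty subset log")
    elapsed = subset_log.human_seconds
    if elapsed <= 0:
        raise ValueError("subset session has zero elapsed time")
    return subset_log.n_labeled() / elapsed


def speedup(lps_ps: float, lps_m: float) -> float:
    """Efficiency improvement θ = assisted LPS / manual LPS."""
    if lps_m <= 0:
        raise ValueError("manual LPS must be positive")
    return lps_ps / lps_m


def concordance(labels_a: dict, labels_b: dict,
                excluded_labels=frozenset()) -> float:
    """Percentage of commonly labeled objects with identical labels.

    Objects carrying an excluded label (e.g. "uncertain") in *either* map are
    dropped before comparison; the result is symmetric in the two maps.
    """
    excluded = set(excluded_labels)
    shared = [
        k for k in labels_a.keys() & labels_b.keys()
        if labels_a[k] not in excluded and labels_b[k] not in excluded
    ]
    if not shared:
        raise ValueError("no comparable objects after exclusions")
    agree = sum(labels_a[k] == labels_b[k] for k in shared)
    return 100.0 * agree / len(shared)


def format_report(report: EfficiencyReport, concordance_pct: float | None = None,
                  ) -> str:
    """Render a report at the conventional precisions: LPS to 3 decimals,
    θ to 2, concordance to integer percent."""
    lines = [
        f"objects labeled      {report.n_labels}",
        f"total time (s)       {report.total_seconds:.0f}",
        f"human time (s)       {report.human_seconds:.0f}",
        f"LPS (total time)     {report.lps_total:.3f}",
        f"LPS (human time)     {report.lps_human:.3f}",
    ]
    if report.lps_manual is not None:
        lines.append(f"LPS (manual)         {report.lps_manual:.3f}")
        lines.append(f"speed-up theta       {report.theta:.2f}x")
    if report.window_min is not None:
        lines.append(f"windowed LPS min     {report.window_min:.3f}")
        lines.append(f"windowed LPS max     {report.window_max:.3f}")
    if concordance_pct is not None:
        lines.append(f"concordance          {concordance_pct:.0f}%")
    return "\n".join(lines)
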