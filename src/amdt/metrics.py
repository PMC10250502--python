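"""Validation statistics: staircase convergence and event-timing accuracy.

Convergence statistics
----------------------
For each condition run *j* the *converged depths* are the depths presented on
the trials spanning the last ``n_reversals`` (six by default) reversals
recorded while the smallest step size was in effect — from the trial of the
n-th-from-last qualifying reversal through the trial of the last one,
inclusive.  With ``depth(i, j)`` those N depths:

* ``depth_mean(j)``       — their arithmetic mean,
* *convergence estimation*  — the average of ``depth_mean(j)`` over the M runs,
* ``depth_std(j)``        — their population standard deviation (divisor N),
* *convergence variability* — the average of ``depth_std(j)`` over runs,
* ``diff_depth(j) = depth_mean(j) - target``, and
* *estimation variability*  — the population standard deviation (divisor M)
  of ``diff_depth(j)`` about its own mean, which is translation-invariant in
  the target.

Timing statistics
-----------------
Given per-run, index-aligned marker timestamps ``xl(i, j)`` and physical
audio-onset timestamps ``xs(i, j)``:

* ``diff(i, j) = xl(i, j) - xs(i, j)``,
* ``x_mean(j)``  — the per-run mean latency,
* ``random_error(i, j) = diff(i, j) - x_mean(j)`` (zero-mean per run), and
* ``SEM`` — the population standard deviation of ``x_mean(j)`` across runs,

plus quartiles of the pooled random error (linear interpolation between
order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stimulus import AudioTrack

__all__ = [
    "MetricsError",
    "ConvergenceReport",
    "TimingReport",
    "converged_depths",
    "convergence_estimation",
    "convergence_variability",
    "estimation_variability",
    "analyze_runs",
    "detect_onsets",
    "timing_report",
    "generate_timing_streams",
]


class MetricsError(ValueError):
    """Analysis impossible on the given run (e.g. too few reversals)."""


def _run_label(run: pd.DataFrame, index: int) -> str:
    for col in ("participant", "run"):
        if col in run.columns and len(run):
            return f"run {index} ({col}={run[col].iloc[0]})"
    return f"run {index}"


def converged_depths(
    run: pd.DataFrame,
    n_reversals: int = 6,
    smallest_step: Optional[float] = None,
    label: str = "run",
) -> np.ndarray:
    """Depths of the trials spanning the last qualifying reversals.

    ``run`` is a staircase log table with columns ``trial_index``, ``depth``
    (or ``value``), ``step`` and ``reversal_flag``.  Qualifying reversals are
    those recorded while ``smallest_step`` was in effect (defaults to the
    smallest step present in the log).

    Raises
    ------
    MetricsError
        If the run contains fewer than ``n_reversals`` qualifying reversals.
    """
    depth_col = "depth" if "depth" in run.columns else "value"
    run = run.sort_values("trial_index")
    if smallest_step is None:
        smallest_step = float(run["step"].min())
    qualifying = run[(run["reversal_flag"] == 1)
                     & np.isclose(run["step"], smallest_step)]
    if len(qualifying) < n_reversals:
        raise MetricsError(
            f"{label}: only {len(qualifying)} reversals at step "
            f"{smallest_step} dB, need {n_reversals}"
        )
    t0 = int(qualifying["trial_index"].iloc[-n_reversals])
    t1 = int(qualifying["trial_index"].iloc[-1])
    window = run[(run["trial_index"] >= t0) & (run["trial_index"] <= t1)]
    return window[depth_col].to_numpy(dtype=float)


def _window_stats(runs: Sequence[pd.DataFrame], n_reversals: int,
                  smallest_step: Optional[float]) -> tuple[np.ndarray, np.ndarray, list[int]]:
    means, stds, sizes = [], [], []
    for i, run in enumerate(runs):
        depths = converged_depths(run, n_reversals, smallest_step,
                                  label=_run_label(run, i))
        means.append(float(np.mean(depths)))
        stds.append(float(np.std(depths)))  # population (1/N)
        sizes.append(len(depths))
    return np.asarray(means), np.asarray(stds), sizes


def convergence_estimation(
    runs: Sequence[pd.DataFrame],
    n_reversals: int = 6,
    smallest_step: Optional[float] = None,
) -> tuple[float, np.ndarray]:
    """Average of the per-run converged-window means (and those means)."""
    means, _, _ = _window_stats(runs, n_reversals, smallest_step)
    return float(means.mean()), means


def convergence_variability(
    runs: Sequence[pd.DataFrame],
    n_reversals: int = 6,
    smallest_step: Optional[float] = None,
) -> float:
    """Average across runs of the per-run population std of window depths."""
    _, stds, _ = _window_stats(runs, n_reversals, smallest_step)
    return float(stds.mean())


def estimation_variability(
    runs: Sequence[pd.DataFrame],
    target_depth: float,
    n_reversals: int = 6,
    smallest_step: Optional[float] = None,
) -> float:
    """Population std across runs of ``depth_mean(j) - target_depth``.

    Independent of ``target_depth`` (the deviations are centered on their own
    mean); the target is kept in the signature because the per-run
    ``diff_depth`` values are reported relative to it.
    """
    means, _, _ = _window_stats(runs, n_reversals, smallest_step)
    if len(means) < 2:
        raise MetricsError("estimation variability needs at least two runs")
    diff = means - target_depth
    return float(np.sqrt(np.mean((diff - diff.mean()) ** 2)))


@dataclass(frozen=True)
class ConvergenceReport:
    """Aggregate convergence statistics over M condition runs."""

    per_run_mean: np.ndarray        # depth_mean(j), dB
    per_run_std: np.ndarray         # depth_std(j), dB
    per_run_n_trials: list[int]     # N per run
    convergence_estimation: float   # dB
    convergence_variability: float  # dB
    diff_depth: np.ndarray          # depth_mean(j) - target, dB
    estimation_variability: Optional[float]  # dB; None when M < 2
    target_depth: float
    n_reversals: int
    smallest_step: float
    n_runs: int

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "n_reversals": self.n_reversals,
            "smallest_step_db": self.smallest_step,
            "target_depth_db": self.target_depth,
            "convergence_estimation_db": self.convergence_estimation,
            "convergence_variability_db": self.convergence_variability,
            "estimation_variability_db": self.estimation_variability,
            "per_run_mean_db": self.per_run_mean.tolist(),
            "per_run_std_db": self.per_run_std.tolist(),
            "per_run_n_trials": list(self.per_run_n_trials),
            "diff_depth_db": self.diff_depth.tolist(),
        }

    def summary(self) -> str:
        lines = [
            f"condition runs analyzed : {self.n_runs}",
            f"window                  : last {self.n_reversals} reversals at "
            f"step {self.smallest_step} dB",
            f"convergence estimation  : {self.convergence_estimation:.4f} dB",
            f"convergence variability : {self.convergence_variability:.4f} dB",
            f"target depth            : {self.target_depth:.4f} dB",
        ]
        if self.estimation_variability is not None:
            lines.append(
                f"estimation variability  : {self.estimation_variability:.4f} dB"
            )
        return "\n".join(lines)


def analyze_runs(
    runs: Sequence[pd.DataFrame],
    target_depth: float,
    n_reversals: int = 6,
    smallest_step: Optional[float] = None,
) -> ConvergenceReport:
    """Full convergence report over a set of condition-run log tables."""
    if len(runs) == 0:
        raise MetricsError("no runs to analyze")
    if smallest_step is None:
        smallest_step = float(min(run["step"].min() for run in runs))
    means, stds, sizes = _window_stats(runs, n_reversals, smallest_step)
    diff = means - target_depth
    est_var = None
    if len(means) >= 2:
        est_var = float(np.sqrt(np.mean((diff - diff.mean()) ** 2)))
    return ConvergenceReport(
        per_run_mean=means,
        per_run_std=stds,
        per_run_n_trials=sizes,
        convergence_estimation=float(means.mean()),
        convergence_variability=float(stds.mean()),
        diff_depth=diff,
        estimation_variability=est_var,
        target_depth=float(target_depth),
        n_reversals=n_reversals,
        smallest_step=float(smallest_step),
        n_runs=len(runs),
    )


def detect_onsets(
    track: AudioTrack,
    threshold_frac: float = 0.25,
    min_gap_s: float = 0.25,
    smooth_s: float = 0.002,
) -> np.ndarray:
    """Timestamps where the smoothed envelope first crosses a threshold.

    The rectified signal is smoothed with a moving average of ``smooth_s``
    seconds; onsets are upward crossings of ``threshold_frac`` times the
    envelope maximum, separated by at least ``min_gap_s``.  A silent track
    yields an empty array.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise MetricsError("threshold_frac must be in (0, 1)")
    env = np.abs(track.samples)
    win = max(1, int(round(smooth_s * track.rate)))
    # causal moving average: the envelope can lag but never lead the signal
    env = np.convolve(env, np.ones(win) / win, mode="full")[: len(env)]
    peak = env.max() if len(env) else 0.0
    if peak == 0.0:
        return np.array([])
    above = env >= threshold_frac * peak
    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        crossings = np.concatenate(([0], crossings[crossings != 0]))
    min_gap = int(round(min_gap_s * track.rate))
    onsets, last = [], -np.inf
    for idx in crossings:
        if idx - last >= min_gap:
            onsets.append(idx / track.rate)
            last = idx
    return np.asarray(onsets)


@dataclass(frozen=True)
class TimingReport:
    """Latency and jitter of event markers against physical audio onsets."""

    diffs: list[np.ndarray]          # diff(i, j) per run, seconds
    latency_per_run: np.ndarray      # x_mean(j), seconds
    random_error: list[np.ndarray]   # zero-mean per run, seconds
    mean_latency: float              # grand mean of x_mean(j), seconds
    sem: float                       # population std of x_mean(j), seconds
    quartiles: tuple[float, float, float]  # pooled random error, seconds
    jitter_sd: float                 # population sd of pooled random error, s
    n_events_per_run: list[int]
    n_runs: int

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "n_events_per_run": list(self.n_events_per_run),
            "mean_latency_s": self.mean_latency,
            "latency_per_run_s": self.latency_per_run.tolist(),
            "sem_s": self.sem,
            "jitter_sd_s": self.jitter_sd,
            "random_error_quartiles_s": list(self.quartiles),
            "random_error_iqr_s": self.quartiles[2] - self.quartiles[0],
        }

    def summary(self) -> str:
        q1, q2, q3 = (q * 1e3 for q in self.quartiles)
        return "\n".join([
            f"runs                 : {self.n_runs}",
            f"mean latency         : {self.mean_latency * 1e3:.3f} ms",
            f"SEM                  : {self.sem:.4f} s",
            f"jitter sd            : {self.jitter_sd * 1e3:.3f} ms",
            f"random-error quartiles: {q1:.1f} / {q2:.1f} / {q3:.1f} ms "
            f"(IQR {q3 - q1:.1f} ms)",
        ])


def timing_report(
    marker_ts: Sequence[Sequence[float]],
    onset_ts: Sequence[Sequence[float]],
) -> TimingReport:
    """Latency/jitter statistics from index-aligned timestamp streams.

    ``marker_ts[j]`` and ``onset_ts[j]`` are the event-marker and physical
    audio-onset timestamps of run *j* and must have equal lengths.
    """
    if len(marker_ts) != len(onset_ts) or len(marker_ts) == 0:
        raise MetricsError(
            f"need equal, nonzero run counts; got {len(marker_ts)} marker "
            f"and {len(onset_ts)} onset runs"
        )
    diffs, errors, latencies, sizes = [], [], [], []
    for j, (xl, xs) in enumerate(zip(marker_ts, onset_ts)):
        xl = np.asarray(xl, dtype=float)
        xs = np.asarray(xs, dtype=float)
        if len(xl) != len(xs) or len(xl) == 0:
            raise MetricsError(
                f"run {j}: {len(xl)} markers vs {len(xs)} onsets"
            )
        d = xl - xs
        diffs.append(d)
        latencies.append(float(d.mean()))
        errors.append(d - d.mean())
        sizes.append(len(d))
    latencies = np.asarray(latencies)
    pooled = np.concatenate(errors)
    q1, q2, q3 = np.percentile(pooled, [25, 50, 75])
    return TimingReport(
        diffs=diffs,
        latency_per_run=latencies,
        random_error=errors,
        mean_latency=float(latencies.mean()),
        sem=float(np.sqrt(np.mean((latencies - latencies.mean()) ** 2))),
        quartiles=(float(q1), float(q2), float(q3)),
        jitter_sd=float(np.std(pooled)),
        n_events_per_run=sizes,
        n_runs=len(diffs),
    )


def generate_timing_streams(
    n_events: int,
    latency_s: float,
    jitter_sd_s: float,
    n_runs: int,
    seed: int,
    first_onset_s: float = 0.5,
    period_s: float = 4.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Synthetic paired (marker, onset) timestamp streams.

    Physical onsets sit on the nominal session grid (``first_onset_s`` then
    every ``period_s``); markers lag them by ``latency_s`` plus zero-mean
    Gaussian jitter of standard deviation ``jitter_sd_s``.  Reproducible for
    a fixed seed.
    """
    if jitter_sd_s < 0:
        raise MetricsError("jitter_sd_s must be >= 0")
    rng = np.random.default_rng(seed)
    onsets, markers = [], []
    for _ in range(n_runs):
        xs = first_onset_s + period_s * np.arange(n_events, dtype=float)
        xl = xs + latency_s + rng.normal(0.0, jitter_sd_s, size=n_events)
        onsets.append(xs)
        markers.append(xl)
    return markers, onsets
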