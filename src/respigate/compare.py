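"""Agreement between two modalities' respiratory phase series.

Camera (20 Hz) and navigator (2 Hz) phase series are put on a common
uniform grid by nearest-neighbour resampling, then compared by normalised
cross-correlation over a lag window. The peak correlation ``C_phase``
measures similarity; the lag at the peak is the phase delay ``d_phase``
(positive when the second series lags the first). A delay converts to a
percentage of the breathing cycle via ``mismatch_percent``.

Amplitude-domain summaries (quartiles, 1.5*IQR whiskers, min/max) and the
cohort range ratios contrast the two sensors' raw signal scales, which --
unlike the phase series -- are not directly comparable between an
arbitrary-unit camera and a millimetre navigator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from respigate.signal_types import PhaseSeries, RespiratorySignal


@dataclass
class PhaseAgreement:
    """Peak normalised cross-correlation and the lag at which it occurs."""

    C_phase: float
    d_phase_ms: float
    lag_window_ms: float


@dataclass
class SignalSummary:
    """Five-number summary plus Tukey whiskers of a signal's amplitudes."""

    min: float
    Q1: float
    Q2: float
    Q3: float
    max: float

    @property
    def iqr(self) -> float:
        return self.Q3 - self.Q1

    @property
    def W_low(self) -> float:
        return self.Q1 - 1.5 * self.iqr

    @property
    def W_up(self) -> float:
        return self.Q3 + 1.5 * self.iqr


def resample_phase(phase: PhaseSeries, target_fs: float = 20.0,
                   t_start: float | None = None,
                   t_end: float | None = None,
                   method: str = "nearest") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample integer bins onto a uniform grid.

    ``method="nearest"`` repeats each source bin over its half-sample
    neighbourhood. ``method="linear"`` is cliff-aware: the per-cycle
    sawtooth is unwrapped (+100 per cycle), linearly interpolated onto the
    grid and wrapped back, which keeps the 100 -> 1 reset at the detected
    trough instead of half a source sample early -- important when a 2 Hz
    navigator series meets a 20 Hz grid.

    Returns ``(t_grid, bins, valid)``; ``valid`` marks grid points covered
    by assigned (bin > 0) source samples, the rest carry no weight.
    """
    if method not in ("nearest", "linear"):
        raise ValueError(f"unknown resampling method {method!r}")
    assigned = phase.bin > 0
    if assigned.sum() < 2:
        raise ValueError("phase series has fewer than 2 assigned samples")
    t0 = phase.t[0] if t_start is None else t_start
    t1 = phase.t[-1] if t_end is None else t_end
    grid = np.arange(t0, t1 + 0.5 / target_fs, 1.0 / target_fs)
    grid = grid[grid <= t1 + 1e-12]

    if method == "nearest":
        pos = np.searchsorted(phase.t, grid, side="left")
        pos = np.clip(pos, 1, len(phase.t) - 1)
        left_closer = grid - phase.t[pos - 1] <= phase.t[pos] - grid
        nearest = np.where(left_closer, pos - 1, pos)
        bins = phase.bin[nearest]
        return grid, bins, bins > 0

    n_bins = phase.n_bins
    bins = np.zeros(len(grid), dtype=int)
    valid = np.zeros(len(grid), dtype=bool)
    run_starts = np.flatnonzero(assigned & ~np.roll(assigned, 1))
    if assigned[0]:
        run_starts = np.unique(np.concatenate([[0], run_starts]))
    for start in run_starts:
        stop = start
        while stop + 1 < len(assigned) and assigned[stop + 1]:
            stop += 1
        if stop == start:
            continue
        tb = phase.t[start:stop + 1]
        bb = phase.bin[start:stop + 1].astype(float)
        is_wrap = np.diff(bb) < -n_bins / 2
        wraps = np.cumsum(np.concatenate([[0.0], is_wrap]))
        unwrapped = bb + n_bins * wraps
        # the expiration ramp reaches the last bin exactly at the trough,
        # then steps into the next cycle: pin the reset to the trough time
        pre_t = tb[1:][is_wrap] - 1e-9
        pre_v = wraps[1:][is_wrap] * n_bins  # bin n_bins of the closing cycle
        tb = np.concatenate([tb, pre_t])
        unwrapped = np.concatenate([unwrapped, pre_v])
        order = np.argsort(tb, kind="stable")
        tb, unwrapped = tb[order], unwrapped[order]
        sel = (grid >= tb[0]) & (grid <= tb[-1])
        interp = np.interp(grid[sel], tb, unwrapped)
        bins[sel] = ((np.round(interp).astype(int) - 1) % n_bins) + 1
        valid[sel] = True
    return grid, bins, valid


def phase_cross_correlation(phase_a: PhaseSeries, phase_b: PhaseSeries,
                            lag_window_ms: float = 2000.0,
                            target_fs: float = 20.0,
                            min_overlap_s: float = 10.0) -> PhaseAgreement:
    """Peak normalised cross-correlation between two phase series.

    Both series are resampled to ``target_fs`` on their overlapping time
    span. For every integer-sample lag within ``+/- lag_window_ms`` the
    mean-removed, norm-normalised correlation is computed over grid points
    where both series are assigned; ``C_phase`` is the maximum and
    ``d_phase_ms`` the lag at the maximum (ties take the smallest
    absolute lag; positive lag means the second series lags the first).
    """
    t0 = max(phase_a.t[0], phase_b.t[0])
    t1 = min(phase_a.t[-1], phase_b.t[-1])
    if t1 - t0 < min_overlap_s:
        raise ValueError(
            f"phase series overlap {t1 - t0:.1f} s is below {min_overlap_s} s"
        )
    _, a, va = resample_phase(phase_a, target_fs, t0, t1, method="linear")
    _, b, vb = resample_phase(phase_b, target_fs, t0, t1, method="linear")
    a = a.astype(float)
    b = b.astype(float)
    max_lag = int(round(lag_window_ms / 1000.0 * target_fs))
    lags = np.arange(-max_lag, max_lag + 1)
    # smallest |lag| first so ties resolve to it
    order = np.argsort(np.abs(lags), kind="stable")
    best_c, best_lag = -np.inf, 0
    n = len(a)
    for lag in lags[order]:
        # positive lag: b lags a, so align a[t] with b[t + lag]
        if lag >= 0:
            ai, bi = slice(0, n - lag), slice(lag, n)
        else:
            ai, bi = slice(-lag, n), slice(0, n + lag)
        m = va[ai] & vb[bi]
        if m.sum() < max(4, int(min_overlap_s * target_fs / 2)):
            continue
        x = a[ai][m]
        y = b[bi][m]
        x = x - x.mean()
        y = y - y.mean()
        denom = np.sqrt((x @ x) * (y @ y))
        if denom == 0:
            raise ValueError("correlation undefined for a constant phase series")
        c = float((x @ y) / denom)
        if c > best_c + 1e-15:
            best_c, best_lag = c, int(lag)
    if not np.isfinite(best_c):
        raise ValueError("no lag had sufficient overlapping assigned samples")
    return PhaseAgreement(C_phase=best_c,
                          d_phase_ms=best_lag / target_fs * 1000.0,
                          lag_window_ms=lag_window_ms)


def mismatch_percent(delay_ms: float, rate_bpm: float) -> float:
    """Phase delay as a percentage of one breathing cycle.

    ``100 * |delay_ms| / (60000 / rate_bpm)``; e.g. a 63 ms delay is 4.2%
    of a cycle at 40 breaths/min and 2.1% at 20 breaths/min.
    """
    if rate_bpm <= 0:
        raise ValueError(f"rate_bpm must be > 0, got {rate_bpm}")
    cycle_ms = 60000.0 / rate_bpm
    return 100.0 * abs(delay_ms) / cycle_ms


def summarize_signal(signal: RespiratorySignal | np.ndarray) -> SignalSummary:
    """Quartiles (linear interpolation), min/max and 1.5*IQR whiskers."""
    y = signal.y if isinstance(signal, RespiratorySignal) else np.asarray(signal, float)
    if y.size < 4:
        raise ValueError(f"need >= 4 samples for a summary, got {y.size}")
    q1, q2, q3 = np.percentile(y, [25, 50, 75])
    return SignalSummary(min=float(y.min()), Q1=float(q1), Q2=float(q2),
                         Q3=float(q3), max=float(y.max()))


def range_ratios(summaries_a: list[SignalSummary],
                 summaries_b: list[SignalSummary]) -> tuple[float, float]:
    """Cohort ratios of whisker ranges and of min-max ranges, A over B.

    Pooled as the cohort mean of ``(W_up - W_low)`` and of ``(max - min)``
    per modality. An outlier-heavy modality inflates the min-max ratio far
    beyond the whisker ratio.
    """
    if len(summaries_a) != len(summaries_b):
        raise ValueError("cohorts must have equal size")
    if not summaries_a:
        raise ValueError("empty cohorts")
    wa = float(np.mean([s.W_up - s.W_low for s in summaries_a]))
    wb = float(np.mean([s.W_up - s.W_low for s in summaries_b]))
    ma = float(np.mean([s.max - s.min for s in summaries_a]))
    mb = float(np.mean([s.max - s.min for s in summaries_b]))
    if wb == 0 or mb == 0:
        raise ValueError("zero denominator range in modality B")
    return wa / wb, ma / mb


__all__ = [
    "PhaseAgreement", "SignalSummary", "resample_phase",
    "phase_cross_correlation", "mismatch_percent", "summarize_signal",
    "range_ratios",
]
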