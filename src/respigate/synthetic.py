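"""Synthetic inputs for the gating pipeline.

Everything downstream (binning, agreement, image quality, statistics) is
exercised on data from this module: paired camera/navigator respiratory
traces driven by one latent breathing process, phantom volumes with a
logistic liver--lung edge of known width, ordinal rating tables and
per-subject condition tables with controlled effect sizes.

The latent breathing waveform is a warped cosine: each cycle rises from a
trough to a peak during the inspiration fraction of the cycle and falls
back during the remainder. The cosine phase advances at a constant speed
inside a symmetric "cap" around every extremum (default 0.6 s half-width)
and at piecewise-constant speeds in between. Rounded, locally symmetric
extrema are both physiologically plausible and ensure that moving-average
smoothing applied downstream does not displace peak/trough locations, so
the inspiration:expiration time split of the generated trace is exactly
``insp_fraction : 1 - insp_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from respigate.signal_types import RespiratorySignal

LATENT_FS = 100.0  # Hz, latent breathing process sampling rate

CONDITIONS = ("cam", "nav", "no")


class ParameterError(ValueError):
    """An invalid generator parameter; the message names the field."""


# --------------------------------------------------------------------------
# breathing waveform
# --------------------------------------------------------------------------

@dataclass
class BreathingParams:
    """Parameters of the latent quasi-periodic breathing process.

    ``noise_sd``, ``drift_*`` and ``outlier_*`` describe sensor-stage
    corruption; they are stored here as per-subject defaults but are only
    applied by :func:`gen_modality_pair` (via :class:`SensorParams`), never
    by :func:`gen_breathing_waveform` itself.
    """

    rate_bpm: float = 15.0          # mean breathing rate, breaths/min
    rate_jitter: float = 0.05       # fractional SD of cycle length
    insp_fraction: float = 0.4      # fraction of cycle spent inspiring
    drift_amp: float = 0.0          # baseline drift amplitude, signal units
    drift_period_s: float = 60.0    # drift period, s
    noise_sd: float = 0.0           # additive Gaussian noise SD, signal units
    outlier_rate_hz: float = 0.0    # expected spike rate, events/s
    outlier_scale: float = 5.0      # spike magnitude multiplier
    duration_s: float = 120.0       # trace length, s
    seed: int = 0
    cap_s: float = 0.6              # extremum rounding half-width, s

    def validate(self) -> None:
        if not (5.0 < self.rate_bpm < 60.0):
            raise ParameterError(f"rate_bpm must lie in (5, 60), got {self.rate_bpm}")
        if not (0.0 < self.insp_fraction < 1.0):
            raise ParameterError(
                f"insp_fraction must lie in (0, 1), got {self.insp_fraction}"
            )
        cycle = 60.0 / self.rate_bpm
        if self.duration_s <= 3 * cycle:
            raise ParameterError(
                f"duration_s must exceed 3 cycle lengths ({3 * cycle:.1f} s), "
                f"got {self.duration_s}"
            )
        for name in ("rate_jitter", "noise_sd", "drift_amp", "outlier_rate_hz"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cap_s <= 0:
            raise ParameterError(f"cap_s must be > 0, got {self.cap_s}")


def _cycle_phase(tau: np.ndarray, period: float, insp_fraction: float,
                 cap_s: float, v_cap: float) -> np.ndarray:
    """Cosine phase (0..1) within one cycle starting at a trough.

    Phase speed is ``v_cap`` within ``c`` of the trough and peak and
    piecewise constant elsewhere; the peak (phase 0.5) falls exactly at
    ``insp_fraction * period``.
    """
    a = insp_fraction * period
    e = period - a
    c = min(cap_s, 0.45 * a, 0.45 * e)
    # cap speed must leave positive phase budget for the mid-segments
    v0 = min(v_cap, 0.45 * 0.5 / c)
    v1 = (0.5 - 2 * v0 * c) / (a - 2 * c)      # mid-inspiration speed
    v2 = (0.5 - 2 * v0 * c) / (e - 2 * c)      # mid-expiration speed

    phi = np.empty_like(tau)
    # piecewise-linear integral of the speed profile
    m1 = tau < c
    m2 = (tau >= c) & (tau < a - c)
    m3 = (tau >= a - c) & (tau < a + c)
    m4 = (tau >= a + c) & (tau < period - c)
    m5 = tau >= period - c
    phi[m1] = v0 * tau[m1]
    phi[m2] = v0 * c + v1 * (tau[m2] - c)
    phi[m3] = 0.5 - v0 * c + v0 * (tau[m3] - (a - c))
    phi[m4] = 0.5 + v0 * c + v2 * (tau[m4] - (a + c))
    phi[m5] = 1.0 - v0 * c + v0 * (tau[m5] - (period - c))
    return phi


def gen_breathing_waveform(params: BreathingParams) -> RespiratorySignal:
    """Generate the latent breathing trace (unit amplitude, 100 Hz).

    The trace starts at a trough; cycle lengths are drawn independently
    around the nominal period with fractional SD ``rate_jitter`` (truncated
    at +/-3 SD). Drift, noise and outliers are *not* applied here.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    period = 60.0 / params.rate_bpm

    # enough cycles to cover the duration even with negative jitter
    n_cycles = int(np.ceil(params.duration_s / period * 1.5)) + 3
    z = np.clip(rng.standard_normal(n_cycles), -3.0, 3.0)
    periods = period * (1.0 + params.rate_jitter * z)
    periods = np.maximum(periods, 0.3 * period)
    starts = np.concatenate([[0.0], np.cumsum(periods)])

    t = np.arange(0.0, params.duration_s, 1.0 / LATENT_FS)
    # same cap speed in every cycle so troughs between unequal cycles
    # remain locally symmetric
    v_cap = 1.0 / period
    idx = np.searchsorted(starts, t, side="right") - 1
    y = np.empty_like(t)
    for k in np.unique(idx):
        sel = idx == k
        phi = _cycle_phase(t[sel] - starts[k], periods[k],
                           params.insp_fraction, params.cap_s, v_cap)
        y[sel] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phi))
    return RespiratorySignal(t=t, y=y, fs=LATENT_FS, modality="latent")


# --------------------------------------------------------------------------
# sensor models
# --------------------------------------------------------------------------

@dataclass
class SensorParams:
    """Sensor-stage corruption applied to the latent trace."""

    noise_sd: float = 0.0           # additive Gaussian noise SD, output units
    drift_amp: float = 0.0          # slow sinusoidal baseline drift amplitude
    drift_period_s: float = 60.0
    outlier_rate_hz: float = 0.0    # Poisson spike rate, events/s
    outlier_scale: float = 5.0      # spike magnitude, multiples of signal scale

    @classmethod
    def from_breathing(cls, params: BreathingParams) -> "SensorParams":
        return cls(
            noise_sd=params.noise_sd, drift_amp=params.drift_amp,
            drift_period_s=params.drift_period_s,
            outlier_rate_hz=params.outlier_rate_hz,
            outlier_scale=params.outlier_scale,
        )


def _sample_modality(latent: RespiratorySignal, fs: float, scale: float,
                     lag_s: float, sensor: SensorParams, rng: np.random.Generator,
                     modality: str, subject_id: str) -> RespiratorySignal:
    duration = latent.t[-1]
    if abs(lag_s) >= duration:
        raise ParameterError(f"lag ({lag_s} s) exceeds trace duration ({duration} s)")
    t = np.arange(0.0, duration - abs(lag_s) + 0.5 / fs, 1.0 / fs)
    t = t[t <= duration - abs(lag_s)]
    # a sensor lagging by lag_s reports at time t the state at t - lag_s
    src = np.clip(t - lag_s, 0.0, duration) if lag_s >= 0 else t - lag_s
    y = scale * np.interp(src, latent.t, latent.y)
    if sensor.drift_amp > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        y = y + sensor.drift_amp * np.sin(
            2 * np.pi * t / sensor.drift_period_s + phase0)
    if sensor.noise_sd > 0:
        y = y + rng.normal(0.0, sensor.noise_sd, size=len(t))
    if sensor.outlier_rate_hz > 0:
        n_spikes = rng.poisson(sensor.outlier_rate_hz * duration)
        if n_spikes:
            pos = rng.integers(0, len(t), size=n_spikes)
            sign = rng.choice([-1.0, 1.0], size=n_spikes)
            y[pos] = y[pos] + sign * sensor.outlier_scale * scale
    return RespiratorySignal(t=t, y=y, fs=fs, modality=modality,
                             subject_id=subject_id)


def gen_modality_pair(
    latent: RespiratorySignal,
    cam_scale: float = 1.0,
    nav_scale_mm: float = 10.0,
    cam_params: SensorParams | None = None,
    nav_params: SensorParams | None = None,
    nav_lag_s: float = 0.0,
    cam_fs: float = 20.0,
    nav_fs: float = 2.0,
    seed: int = 0,
    subject_id: str = "",
) -> tuple[RespiratorySignal, RespiratorySignal]:
    """Observe one latent breathing trace through both sensors.

    The camera reports arbitrary units at 20 Hz; the navigator reports
    millimetres at 2 Hz, optionally delayed by ``nav_lag_s``. Each sensor
    adds its own independent drift, Gaussian noise and one-sample-wide
    outlier spikes at Poisson times. Per-subject amplitude scales model the
    cohort's ~3x spread in navigator signal ranges.
    """
    if cam_scale <= 0 or nav_scale_mm <= 0:
        raise ParameterError("cam_scale and nav_scale_mm must be > 0")
    cam_params = cam_params or SensorParams()
    nav_params = nav_params or SensorParams()
    rng_cam, rng_nav = [np.random.default_rng(s)
                        for s in np.random.SeedSequence(seed).spawn(2)]
    cam = _sample_modality(latent, cam_fs, cam_scale, 0.0, cam_params,
                           rng_cam, "camera", subject_id)
    nav = _sample_modality(latent, nav_fs, nav_scale_mm, nav_lag_s, nav_params,
                           rng_nav, "navigator", subject_id)
    return cam, nav


# --------------------------------------------------------------------------
# phantom volumes
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """A 4D liver--lung phantom: a logistic intensity edge along z.

    Mean intensity follows ``lung + (liver - lung) * expit((z - z0) / w)``
    so the liver (bright) lies at high z. ``motion_blur_sd`` mixes each
    frame from copies shifted along z by Gaussian offsets, mimicking the
    blurred liver--lung border of a non-gated reconstruction.
    """

    shape: tuple[int, int, int, int] = (10, 10, 30, 5)   # (nx, ny, nz, nt)
    liver_intensity: float = 100.0
    lung_intensity: float = 0.0
    edge_z0: float = 15.0
    edge_width_w: float = 2.0
    noise_sd: float = 5.0
    motion_blur_sd: float = 0.0
    n_blur_draws: int = 25
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 4 or any(s < 1 for s in self.shape):
            raise ParameterError(f"shape must be 4 positive ints, got {self.shape}")
        if not self.liver_intensity > self.lung_intensity >= 0:
            raise ParameterError(
                "liver_intensity must exceed lung_intensity (both >= 0); got "
                f"liver={self.liver_intensity}, lung={self.lung_intensity}"
            )
        if not (0 < self.edge_z0 < self.shape[2]):
            raise ParameterError(f"edge_z0 must lie inside (0, nz), got {self.edge_z0}")
        if self.edge_width_w <= 0:
            raise ParameterError(f"edge_width_w must be > 0, got {self.edge_width_w}")
        if self.noise_sd < 0 or self.motion_blur_sd < 0:
            raise ParameterError("noise_sd and motion_blur_sd must be >= 0")


@dataclass
class PhantomVolume:
    """4D magnitude image plus the spec that generated it (ground truth)."""

    data: np.ndarray           # (nx, ny, nz, nt)
    spec: PhantomSpec = field(repr=False, default_factory=PhantomSpec)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.data.shape)


def _edge_profile(z: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    from scipy.special import expit

    amp = spec.liver_intensity - spec.lung_intensity
    return spec.lung_intensity + amp * expit((z - spec.edge_z0) / spec.edge_width_w)


def gen_phantom_volume(spec: PhantomSpec) -> PhantomVolume:
    """Build a phantom volume from its spec.

    Without blur each frame is the ideal logistic edge plus i.i.d. Gaussian
    noise. With ``motion_blur_sd > 0`` each frame averages ``n_blur_draws``
    copies of the ideal edge shifted along z by Gaussian offsets before the
    noise is added, which widens the effective edge.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz, nt = spec.shape
    z = np.arange(nz, dtype=float)
    vol = np.empty(spec.shape, dtype=float)
    for f in range(nt):
        if spec.motion_blur_sd > 0:
            shifts = rng.normal(0.0, spec.motion_blur_sd, size=spec.n_blur_draws)
            profile = np.mean([_edge_profile(z - s, spec) for s in shifts], axis=0)
        else:
            profile = _edge_profile(z, spec)
        frame = np.broadcast_to(profile, (nx, ny, nz)).copy()
        if spec.noise_sd > 0:
            frame += rng.normal(0.0, spec.noise_sd, size=(nx, ny, nz))
        vol[..., f] = frame
    return PhantomVolume(data=vol, spec=spec)


# --------------------------------------------------------------------------
# ratings and condition tables
# --------------------------------------------------------------------------

def gen_ordinal_ratings(
    n_items: int,
    n_raters: int,
    k_levels: int = 4,
    agreement: str = "high",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a raters-by-items ordinal (Likert) score table.

    ``perfect`` gives identical rater columns, ``random`` independent
    uniform scores, and ``high`` a shared per-item score with occasional
    one-level rater disagreement.

    Returns a DataFrame indexed by item with one column per rater,
    values in ``1..k_levels``.
    """
    if k_levels < 2:
        raise ParameterError(f"k_levels must be >= 2, got {k_levels}")
    if n_raters < 2:
        raise ParameterError(f"n_raters must be >= 2, got {n_raters}")
    if agreement not in ("perfect", "high", "random"):
        raise ParameterError(f"unknown agreement level {agreement!r}")
    rng = np.random.default_rng(seed)
    if agreement == "random":
        scores = rng.integers(1, k_levels + 1, size=(n_items, n_raters))
    else:
        base = rng.integers(1, k_levels + 1, size=n_items)
        scores = np.tile(base[:, None], (1, n_raters))
        if agreement == "high":
            flip = rng.random(size=scores.shape) < 0.15
            step = rng.choice([-1, 1], size=scores.shape)
            scores = np.clip(scores + flip * step, 1, k_levels)
    return pd.DataFrame(
        scores,
        index=pd.RangeIndex(n_items, name="item"),
        columns=[f"rater{r + 1}" for r in range(n_raters)],
    )


def gen_condition_table(
    n_subjects: int,
    means: tuple[float, float, float],
    subject_sd: float = 1.0,
    residual_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-subject metric values under the three gating conditions.

    value(subject, condition) = subject effect + condition mean + residual,
    with Gaussian subject effects (SD ``subject_sd``) and i.i.d. residuals
    (SD ``residual_sd``). Column order is ``cam, nav, no``.
    """
    if len(means) != 3:
        raise ParameterError(f"means must have 3 entries (cam, nav, no), got {means}")
    if subject_sd < 0 or residual_sd < 0:
        raise ParameterError("subject_sd and residual_sd must be >= 0")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, subject_sd, size=n_subjects)
    resid = rng.normal(0.0, residual_sd, size=(n_subjects, 3))
    values = subj[:, None] + np.asarray(means)[None, :] + resid
    df = pd.DataFrame(values, columns=list(CONDITIONS))
    df.insert(0, "subject_id", [f"S{i + 1:02d}" for i in range(n_subjects)])
    return df


__all__ = [
    "BreathingParams", "SensorParams", "PhantomSpec", "PhantomVolume",
    "ParameterError", "CONDITIONS", "LATENT_FS",
    "gen_breathing_waveform", "gen_modality_pair", "gen_phantom_volume",
    "gen_ordinal_ratings", "gen_condition_table", "replace",
]
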