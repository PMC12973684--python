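"""Seeded generator of ground-truthed synthetic nostril-temperature recordings.

The simulator emulates the physiological structure that the downstream
detection method assumes: a quasi-periodic nostril temperature oscillation
inside the bovine respiratory band (0.2-1.0 Hz), regurgitation events at
roughly 37.5 +/- 9.73 s intervals, each producing a brief apnea followed by
one deepened inspiratory trough (the post-regurgitation deep inhalation,
PRDI), on top of slow baseline drift and additive sensor noise.

Every random choice is driven by the configured seed, so equal configs
produce bit-identical recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict

import numpy as np
from scipy.optimize import brentq

from .io import FrameStack, TemperatureSeries, ValidationError

__all__ = ["SimulationConfig", "SyntheticRecording", "simulate_recording", "render_frames"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    Units: seconds, Hz, degrees Celsius.  ``prdi_depth_factor`` multiplies
    the amplitude of the inspiratory half-cycle immediately after each
    apnea; 1.0 disables the PRDI signature.
    """

    duration_s: float = 120.0
    fs: float = 8.7
    breath_rate_hz: float = 0.5
    breath_amp_C: float = 0.5
    baseline_C: float = 30.0
    drift_amp_C: float = 0.2
    noise_sd_C: float = 0.1
    regurg_interval_mean_s: float = 37.5
    regurg_interval_sd_s: float = 9.73
    regurg_interval_min_s: float = 10.0
    apnea_s: float = 1.0
    prdi_depth_factor: float = 2.0
    breath_jitter_sigma: float = 0.1
    harmonic2_amp: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValidationError(f"{f.name} must be finite, got {v!r}")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        if not 0.2 <= self.breath_rate_hz <= 1.0:
            raise ValidationError("breath_rate_hz must lie in the respiratory band [0.2, 1.0] Hz")
        if self.breath_amp_C <= 0:
            raise ValidationError("breath_amp_C must be > 0")
        if self.drift_amp_C < 0 or self.noise_sd_C < 0:
            raise ValidationError("drift_amp_C and noise_sd_C must be >= 0")
        if self.apnea_s < 0:
            raise ValidationError("apnea_s must be >= 0")
        if self.regurg_interval_min_s <= self.apnea_s:
            raise ValidationError("regurg_interval_min_s must exceed apnea_s")
        if self.prdi_depth_factor < 1:
            raise ValidationError("prdi_depth_factor must be >= 1")
        if self.breath_jitter_sigma < 0:
            raise ValidationError("breath_jitter_sigma must be >= 0")


@dataclass
class SyntheticRecording:
    """Simulator output: the series plus its ground-truth event times."""

    series: TemperatureSeries
    regurg_times_s: np.ndarray
    true_prdi_times_s: np.ndarray
    config: SimulationConfig

    def __post_init__(self) -> None:
        self.regurg_times_s = np.asarray(self.regurg_times_s, dtype=float)
        self.true_prdi_times_s = np.asarray(self.true_prdi_times_s, dtype=float)


def _waveform(phase: np.ndarray, h2: float) -> np.ndarray:
    """Base breathing waveform over phase (radians): fundamental + optional
    2nd harmonic so the pipeline cannot rely on exact sinusoidality."""
    return np.sin(phase) + h2 * np.sin(2.0 * phase)


def _trough_phase(h2: float) -> float:
    """Phase in [0, 2pi) of the waveform's inspiratory minimum."""
    if h2 == 0.0:
        return 1.5 * math.pi
    # minimum of sin(p) + h2*sin(2p): root of cos(p) + 2*h2*cos(2p) near 3pi/2
    g = lambda p: math.cos(p) + 2.0 * h2 * math.cos(2.0 * p)
    return brentq(g, math.pi, 2.0 * math.pi)


def _draw_intervals(rng: np.random.Generator, cfg: SimulationConfig, horizon: float) -> np.ndarray:
    """Truncated-normal inter-regurgitation intervals until past the horizon."""
    times = []
    t = 0.0
    while True:
        iv = rng.normal(cfg.regurg_interval_mean_s, cfg.regurg_interval_sd_s)
        while iv < cfg.regurg_interval_min_s:
            iv = rng.normal(cfg.regurg_interval_mean_s, cfg.regurg_interval_sd_s)
        t += iv
        if t > horizon:
            break
        times.append(t)
    return np.asarray(times)


def simulate_recording(config: SimulationConfig) -> SyntheticRecording:
    """Generate one recording with ground-truth regurgitation and PRDI times.

    The temperature signal is baseline + slow drift + breathing oscillation
    + white noise.  During each apnea the oscillation amplitude is ramped to
    zero over 0.1 s and held for ``apnea_s``; the first inspiratory
    half-cycle after apnea end has its amplitude multiplied by
    ``prdi_depth_factor`` and its trough time is recorded as the true PRDI
    time.  Regurgitation onsets are placed so that the deepened trough falls
    one quarter breath period after apnea end, which keeps it inside the 3-s
    post-regurgitation window at physiological settings.
    """
    cfg = config
    n = round(cfg.duration_s * cfg.fs)
    t = np.arange(n) / cfg.fs
    period = 1.0 / cfg.breath_rate_hz

    ss = np.random.SeedSequence(cfg.seed)
    rng_iv, rng_jit, rng_noise, rng_drift = (np.random.default_rng(c) for c in ss.spawn(4))

    phase = 2.0 * math.pi * cfg.breath_rate_hz * t
    wave = _waveform(phase, cfg.harmonic2_amp)

    # per-breath log-normal amplitude jitter
    cycle = np.floor(phase / (2.0 * math.pi)).astype(int)
    n_cycles = int(cycle[-1]) + 1 if n else 0
    if cfg.breath_jitter_sigma > 0:
        jit = np.exp(rng_jit.normal(0.0, cfg.breath_jitter_sigma, size=n_cycles))
    else:
        jit = np.ones(n_cycles)
    amp = cfg.breath_amp_C * jit[cycle]

    # regurgitation events: snap each nominal onset so that the first
    # post-apnea trough is exactly apnea_s + period/4 after the onset
    phi0 = _trough_phase(cfg.harmonic2_amp)
    lead = cfg.apnea_s + 0.25 * period  # onset-to-trough delay
    tail = 0.75 * period  # room for the deepened half-cycle to finish
    nominal = _draw_intervals(rng_iv, cfg, horizon=cfg.duration_s - lead - tail)
    regurg_times, prdi_times = [], []
    prev = -np.inf
    for t_nom in nominal:
        # first waveform trough at or after the nominal onset + apnea
        k = math.ceil(((t_nom + lead) * 2.0 * math.pi * cfg.breath_rate_hz - phi0) / (2.0 * math.pi))
        t_m = (phi0 + 2.0 * math.pi * k) / (2.0 * math.pi * cfg.breath_rate_hz)
        # keep the minimum-gap invariant after snapping
        while t_m - lead - prev < cfg.regurg_interval_min_s:
            t_m += period
        if t_m + tail > cfg.duration_s:
            continue
        t_r = t_m - lead
        regurg_times.append(t_r)
        prdi_times.append(t_m)
        prev = t_r

    # apnea gating and PRDI deepening applied to the amplitude envelope
    env = np.ones(n)
    ramp = min(0.1, cfg.apnea_s)  # s, amplitude ramp-down at apnea onset
    for t_r, t_m in zip(regurg_times, prdi_times):
        if cfg.apnea_s > 0:
            in_ramp = (t >= t_r) & (t < t_r + ramp)
            env[in_ramp] = np.minimum(env[in_ramp], 1.0 - (t[in_ramp] - t_r) / ramp)
            env[(t >= t_r + ramp) & (t < t_r + cfg.apnea_s)] = 0.0
        # deepened inspiratory half-cycle: quarter period either side of the trough
        deep = (t >= t_m - 0.25 * period) & (t < t_m + 0.25 * period)
        env[deep] = cfg.prdi_depth_factor

    breathing = amp * env * wave

    drift = np.zeros(n)
    if cfg.drift_amp_C > 0:
        ph = rng_drift.uniform(0.0, 2.0 * math.pi)
        slow = np.sin(2.0 * math.pi * 0.01 * t + ph)
        walk = np.cumsum(rng_drift.normal(0.0, 1.0, size=n))
        denom = np.max(np.abs(walk))
        if denom > 0:
            walk = walk / denom
        drift = cfg.drift_amp_C * (0.5 * slow + 0.5 * walk)
    elif cfg.drift_amp_C == 0:
        rng_drift.uniform(0.0, 2.0 * math.pi)  # keep stream alignment

    noise = rng_noise.normal(0.0, cfg.noise_sd_C, size=n) if cfg.noise_sd_C > 0 else np.zeros(n)

    values = cfg.baseline_C + drift + breathing + noise
    series = TemperatureSeries(
        recording_id=f"sim-{cfg.seed}",
        times_s=t,
        values_C=values,
        fs=cfg.fs,
    )
    return SyntheticRecording(
        series=series,
        regurg_times_s=np.asarray(regurg_times),
        true_prdi_times_s=np.asarray(prdi_times),
        config=cfg,
    )


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def render_frames(
    recording: SyntheticRecording,
    thermal_shape: tuple[int, int] = (120, 160),
    mask_shape: tuple[int, int] = (1080, 1440),
    pixel_noise_sd_C: float = 0.0,
    jitter_px: int = 0,
    background_offset_C: float = -5.0,
) -> FrameStack:
    """Render the recording as thermal frames plus binary nostril masks.

    Per sample, the mask is a nostril ellipse at ``mask_shape`` resolution
    (optionally jittered by up to ``jitter_px`` mask pixels per frame); the
    thermal frame paints the ellipse's thermal-grid footprint with the
    series value (plus optional pixel noise) over a cooler uniform
    background, so mask-guided extraction recovers the input series.
    """
    from .io import downscale_mask

    for name, shape in (("thermal_shape", thermal_shape), ("mask_shape", mask_shape)):
        if min(shape) < 4:
            raise ValidationError(f"{name} dimensions must be >= 4, got {shape}")
    series = recording.series
    H, W = mask_shape
    center0 = (H / 2.0, W / 2.0)
    axes = (H / 8.0, W / 10.0)
    rng = np.random.default_rng(np.random.SeedSequence([recording.config.seed, 0xF]).generate_state(1)[0])
    background = recording.config.baseline_C + background_offset_C

    thermal_frames, mask_frames = [], []
    for i in range(len(series)):
        if jitter_px > 0:
            dr, dc = rng.integers(-jitter_px, jitter_px + 1, size=2)
        else:
            dr = dc = 0
        mask = _ellipse_mask(mask_shape, (center0[0] + dr, center0[1] + dc), axes)
        footprint = downscale_mask(mask, thermal_shape)
        frame = np.full(thermal_shape, background)
        frame[footprint] = series.values_C[i]
        if pixel_noise_sd_C > 0:
            frame = frame + rng.normal(0.0, pixel_noise_sd_C, size=thermal_shape)
        thermal_frames.append(frame)
        mask_frames.append(mask)
    return FrameStack(timestamps_s=series.times_s.copy(), thermal=thermal_frames, masks=mask_frames)


def write_ground_truth_csv(recording: SyntheticRecording, regurg_path, prdi_path) -> None:
    """Write the ground-truth regurgitation and PRDI times as CSV."""
    import csv
    from pathlib import Path

    rid = recording.series.recording_id
    with Path(regurg_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["recording_id", "regurg_time_s"])
        for t in recording.regurg_times_s:
            w.writerow([rid, f"{t:.6f}"])
    with Path(prdi_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["recording_id", "prdi_time_s"])
        for t in recording.true_prdi_times_s:
            w.writerow([rid, f"{t:.6f}"])
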