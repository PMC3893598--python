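"""Synthetic fNIRS session generator.

Emulates the statistical structure of prefrontal fNIRS recordings during an
n-back session: condition-scaled hemodynamic responses (boxcar convolved
with a canonical double-gamma HRF), physiological nuisance oscillations
(heart beat ~1.1 Hz, respiration ~0.25 Hz, Mayer waves ~0.1 Hz, slow
drift, white sensor noise) and motion artifacts (exponential-decay spikes
and baseline shifts at Poisson times).  HbR is coupled to HbO with a
negative ratio, reflecting the strong anticorrelation of the two
chromophores.  A companion behavioral simulator produces key presses with
condition-dependent miss and false-alarm rates.

Everything is fully determined by the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .protocol import CONDITIONS, SessionTimeline, StimulusSequence, build_session_timeline
from .recording import CHROMOPHORES, N_CHANNELS, Recording, default_montage

NYQUIST_HZ = 12.5


class InvalidParameterError(ValueError):
    """Raised for simulator parameters outside their valid range."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class HRFParams:
    """Canonical hemodynamic response: gamma main lobe minus gamma undershoot.

    ``peak_delay_s`` is the mode of the positive lobe, ``undershoot_delay_s``
    the mode of the (subtracted) undershoot, ``undershoot_ratio`` the
    relative area of the undershoot.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0


@dataclass(frozen=True)
class NoiseParams:
    """Physiological and sensor noise amplitudes (same units as the signal)."""

    heart_freq_hz: float = 1.1
    heart_amp: float = 0.4
    resp_freq_hz: float = 0.25
    resp_amp: float = 0.2
    mayer_freq_hz: float = 0.1
    mayer_amp: float = 0.3
    drift_slope: float = 5e-4  # max |linear drift| per second
    white_sigma: float = 0.05


@dataclass(frozen=True)
class ArtifactParams:
    """Motion artifacts: spike transients and baseline shifts."""

    spike_rate_per_min: float = 1.0
    spike_amp: float = 2.0
    spike_tau_s: float = 0.5
    shift_rate_per_min: float = 0.2
    shift_amp: float = 1.0


@dataclass(frozen=True)
class BehaviorParams:
    """Per-condition response error probabilities.

    Defaults follow observed group behavior in this paradigm: miss rates
    rising from ~6% (1-back) to ~34% (3-back), and per-letter false-alarm
    probabilities derived from mean wrong-reaction counts.
    """

    miss_p: dict[int, float] = field(
        default_factory=lambda: {1: 0.057, 2: 0.167, 3: 0.337}
    )
    false_alarm_p: dict[int, float] = field(
        default_factory=lambda: {1: 0.0074, 2: 0.010, 3: 0.0237}
    )


@dataclass
class SimConfig:
    """Full simulator configuration; `seed` determines every random draw."""

    hrf: HRFParams = field(default_factory=HRFParams)
    #: HbO response amplitude per condition; must be non-decreasing in n.
    amp_hbo: dict[int, float] = field(default_factory=lambda: {1: 0.2, 2: 0.5, 3: 1.0})
    #: Coupling of the HbR response to the HbO response (negative).
    hbr_ratio: float = -0.3
    noise: NoiseParams = field(default_factory=NoiseParams)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    #: Channels carrying the workload response (exposed as config; which of
    #: the 8 montage channels are task-sensitive varies between subjects).
    active_channels: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    #: Per-channel gain spread: gains drawn once per subject from
    #: U(1 - jitter, 1 + jitter), so channels differ and feature selection
    #: has something to select.
    gain_jitter: float = 0.2
    #: Seconds for the neural drive to ramp from 0 to full amplitude after
    #: trial onset.  Working-memory load builds up while the letter buffer
    #: fills, so windows taken directly after trial start carry little
    #: workload signal; 0 gives a pure boxcar drive.
    onset_ramp_s: float = 44.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in (self.noise.heart_freq_hz, self.noise.resp_freq_hz, self.noise.mayer_freq_hz):
            if not 0 < f < NYQUIST_HZ:
                raise InvalidParameterError(f"noise frequency {f} Hz outside (0, {NYQUIST_HZ})")
        if self.hbr_ratio >= 0:
            raise InvalidParameterError("hbr_ratio must be negative")
        amps = [self.amp_hbo[c] for c in CONDITIONS]
        if not all(a <= b for a, b in zip(amps, amps[1:])):
            raise InvalidParameterError("amp_hbo must be non-decreasing in workload level")
        for p_map in (self.behavior.miss_p, self.behavior.false_alarm_p):
            for c, p in p_map.items():
                if not 0.0 <= p <= 1.0:
                    raise InvalidParameterError(f"probability {p} for condition {c} not in [0, 1]")
        if self.hrf.peak_delay_s <= 0 or self.hrf.undershoot_delay_s <= 0:
            raise InvalidParameterError("HRF delays must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, sub in (("hrf", HRFParams), ("noise", NoiseParams),
                         ("artifacts", ArtifactParams), ("behavior", BehaviorParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{k: _intkeys(v) if isinstance(v, dict) else v
                                for k, v in d[key].items()})
        if "amp_hbo" in d:
            d["amp_hbo"] = _intkeys(d["amp_hbo"])
        if "active_channels" in d:
            d["active_channels"] = tuple(d["active_channels"])
        return cls(**d)


def _intkeys(d: dict) -> dict:
    return {int(k): v for k, v in d.items()}


def noise_free_config(seed: int = 0, amp_hbo: dict[int, float] | None = None,
                      **overrides) -> SimConfig:
    """Config with all noise and artifact amplitudes zero and unit gains.

    In this limit each active channel carries exactly the boxcar-convolved
    HRF response; useful for pipeline integrity checks.
    """
    cfg = SimConfig(
        noise=NoiseParams(heart_amp=0.0, resp_amp=0.0, mayer_amp=0.0,
                          drift_slope=0.0, white_sigma=0.0),
        artifacts=ArtifactParams(spike_rate_per_min=0.0, shift_rate_per_min=0.0),
        gain_jitter=0.0,
        seed=seed,
        **overrides,
    )
    if amp_hbo is not None:
        cfg.amp_hbo = dict(amp_hbo)
        cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# hemodynamic response


def canonical_hrf(duration_s: float = 32.0, params: HRFParams | None = None,
                  sampling_rate: float = 25.0) -> np.ndarray:
    """Sampled canonical HRF kernel, normalized to unit peak amplitude.

    Difference of two gamma densities: a positive lobe with mode at
    ``peak_delay_s`` and an undershoot with mode at ``undershoot_delay_s``
    scaled by ``undershoot_ratio``.  The kernel rises after stimulus onset,
    peaks near ``peak_delay_s``, dips below baseline and returns to ~0 by
    ``duration_s``.
    """
    params = params or HRFParams()
    if params.peak_delay_s <= 0 or params.undershoot_delay_s <= 0:
        raise InvalidParameterError("HRF delays must be positive")
    if duration_s <= params.undershoot_delay_s:
        raise InvalidParameterError("duration must cover the undershoot")
    t = np.arange(int(round(duration_s * sampling_rate))) / sampling_rate
    # shape a, scale b with mode (a-1)*b at the requested delay
    a1, a2 = 6.0, 16.0
    lobe = stats.gamma.pdf(t, a1, scale=params.peak_delay_s / (a1 - 1))
    under = stats.gamma.pdf(t, a2, scale=params.undershoot_delay_s / (a2 - 1))
    kernel = lobe - params.undershoot_ratio * under
    return kernel / kernel.max()


# ---------------------------------------------------------------------------
# recording simulation


def _poisson_events(rng: np.random.Generator, rate_per_min: float, duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def simulate_recording(timeline: SessionTimeline, config: SimConfig) -> Recording:
    """Render a full-session recording for the given timeline.

    Each task event contributes ``amp_hbo[condition]`` times the
    HRF-convolved boxcar to the HbO trace of every active channel (scaled by
    that channel's gain), and ``hbr_ratio`` times that to HbR.  All noise
    components and motion artifacts are added on top; rest and relax
    periods carry noise only.
    """
    fs = timeline.sampling_rate
    n = int(round(timeline.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(config.seed)

    # neural design: condition-scaled boxcars over task events, with the
    # drive ramping up over onset_ramp_s as the memory buffer fills
    design = np.zeros(n)
    for event in timeline.task_events():
        start = int(round(event.onset_s * fs))
        stop = int(round(event.end_s * fs))
        profile = np.ones(stop - start)
        if config.onset_ramp_s > 0:
            t_rel = np.arange(stop - start) / fs
            profile = np.minimum(t_rel / config.onset_ramp_s, 1.0)
        design[start:stop] += config.amp_hbo[int(event.condition)] * profile
    kernel = canonical_hrf(params=config.hrf, sampling_rate=fs)
    # normalize kernel mass so a long boxcar of height A plateaus at ~A
    response = np.convolve(design, kernel / kernel.sum())[:n]

    gains = 1.0 + config.gain_jitter * rng.uniform(-1.0, 1.0, size=N_CHANNELS)
    noise, art = config.noise, config.artifacts

    # motion events are shared across channels (the whole optode holder moves)
    spike_times = _poisson_events(rng, art.spike_rate_per_min, timeline.duration_s)
    spike_signs = rng.choice([-1.0, 1.0], size=spike_times.size)
    spike_scales = rng.uniform(0.5, 1.5, size=spike_times.size)
    shift_times = _poisson_events(rng, art.shift_rate_per_min, timeline.duration_s)
    shift_signs = rng.choice([-1.0, 1.0], size=shift_times.size)
    shift_scales = rng.uniform(0.5, 1.5, size=shift_times.size)

    data = np.zeros((N_CHANNELS, len(CHROMOPHORES), n))
    for ch in range(N_CHANNELS):
        hemo = gains[ch] * response if ch in config.active_channels else np.zeros(n)
        # per-channel coupling of the shared motion events
        motion = np.zeros(n)
        coupling = rng.uniform(0.5, 1.5, size=spike_times.size + shift_times.size)
        for i, (t0, sign, scale) in enumerate(zip(spike_times, spike_signs, spike_scales)):
            mask = t >= t0
            motion[mask] += (coupling[i] * sign * scale * art.spike_amp
                             * np.exp(-(t[mask] - t0) / art.spike_tau_s))
        for i, (t0, sign, scale) in enumerate(zip(shift_times, shift_signs, shift_scales)):
            motion[t >= t0] += coupling[spike_times.size + i] * sign * scale * art.shift_amp
        for chromo_idx, chromo in enumerate(CHROMOPHORES):
            sig = hemo if chromo == "HbO" else config.hbr_ratio * hemo
            osc = np.zeros(n)
            for freq, amp in ((noise.heart_freq_hz, noise.heart_amp),
                              (noise.resp_freq_hz, noise.resp_amp),
                              (noise.mayer_freq_hz, noise.mayer_amp)):
                phase = rng.uniform(0, 2 * np.pi)
                osc += amp * np.sin(2 * np.pi * freq * t + phase)
            drift = rng.uniform(-noise.drift_slope, noise.drift_slope) * t
            white = (noise.white_sigma * rng.standard_normal(n)
                     if noise.white_sigma > 0 else np.zeros(n))
            data[ch, chromo_idx] = sig + osc + drift + white + motion
    return Recording(data=data, sampling_rate=fs, channel_meta=default_montage())


# ---------------------------------------------------------------------------
# behavior simulation


def simulate_behavior(seq: StimulusSequence, condition: int, config: SimConfig,
                      rng: np.random.Generator | None = None) -> list[int]:
    """Simulate key-press positions for one trial.

    Each target is answered with probability ``1 - miss_p[condition]``; each
    non-target draws a false alarm with ``false_alarm_p[condition]``.
    """
    if condition != seq.n:
        raise InvalidParameterError(f"condition {condition} does not match sequence n={seq.n}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    miss_p = config.behavior.miss_p[condition]
    fa_p = config.behavior.false_alarm_p[condition]
    responses: list[int] = []
    for pos, is_target in enumerate(seq.target_flags):
        if is_target:
            if rng.random() >= miss_p:
                responses.append(pos)
        elif rng.random() < fa_p:
            responses.append(pos)
    return responses


def simulate_session(seed: int, config: SimConfig | None = None
                     ) -> tuple[SessionTimeline, Recording]:
    """Build a timeline and render its recording, all derived from `seed`."""
    if config is None:
        config = SimConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    timeline = build_session_timeline(rng_seed=seed)
    recording = simulate_recording(timeline, config)
    return timeline, recording
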