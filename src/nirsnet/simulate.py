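"""Synthetic fNIRS generator with known ground truth.

Emulates the study design end to end: a 24-channel bilateral sensorimotor
montage sampled at 10 Hz, a 4-condition block design (Rest, MV, MO, MOV;
10 s tasks, 25-30 s rests, 4 sessions x 10 tasks), hemodynamic responses
built by convolving each task boxcar with a canonical double-gamma HRF and
scaling per hemisphere, physiological noise (cardiac, respiration, Mayer
waves, drift, white noise), and optionally injected directed channel-to-
channel couplings that serve as Granger-causality ground truth.

Tasks are performed with the left hand, so activation is contralateral:
right-hemisphere amplitudes dominate, strongest for the vibrotactile
conditions MV and MOV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import HbTimeSeries, RawIntensity
from .montage import Montage
from .optics import DEFAULT_DPF, DEFAULT_WAVELENGTHS, extinction_matrix
from .schedule import TaskSchedule, generate_schedule

__all__ = [
    "NoiseConfig",
    "Coupling",
    "SimulationConfig",
    "GroundTruth",
    "double_gamma_hrf",
    "block_response_template",
    "simulate_subject",
    "simulate_cohort",
    "inject_directed_coupling",
    "hb_to_intensity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseConfig:
    """Physiological-noise model: sinusoidal components plus drift and white noise.

    Frequencies in Hz, amplitudes in micromol/L. Sinusoids get a random phase
    and a mild (10%) random amplitude spread per channel; the linear drift
    slope is drawn uniformly in ``+-drift_amp`` over the whole recording.
    ``lfo_sd`` sets the standard deviation of a spontaneous low-frequency
    oscillation (white noise low-passed at ``lfo_cutoff``), the dominant
    resting-state fluctuation in real HbO recordings and typically of the
    same order as the evoked response.
    """

    cardiac_freq: float = 1.2
    cardiac_amp: float = 0.05
    resp_freq: float = 0.25
    resp_amp: float = 0.03
    mayer_freq: float = 0.1
    mayer_amp: float = 0.02
    drift_amp: float = 0.05
    white_sd: float = 0.05
    lfo_sd: float = 0.1
    lfo_cutoff: float = 0.08

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(
            cardiac_freq=self.cardiac_freq,
            cardiac_amp=self.cardiac_amp * factor,
            resp_freq=self.resp_freq,
            resp_amp=self.resp_amp * factor,
            mayer_freq=self.mayer_freq,
            mayer_amp=self.mayer_amp * factor,
            drift_amp=self.drift_amp * factor,
            white_sd=self.white_sd * factor,
            lfo_sd=self.lfo_sd * factor,
            lfo_cutoff=self.lfo_cutoff,
        )

    @property
    def max_freq(self) -> float:
        return max(self.cardiac_freq, self.resp_freq, self.mayer_freq)


@dataclass(frozen=True)
class Coupling:
    """Directed channel-to-channel dependence: receiver_t += gain * driver_{t-lag}.

    ``lag`` is in samples (>= 1). When ``condition`` is set, the simulator
    applies the coupling only inside task windows of that condition, which
    makes the planted effect condition-specific after block averaging.
    """

    driver: str
    receiver: str
    lag: int = 1
    gain: float = 1.0
    condition: str | None = None


# Default per-condition peak HbO response (left hemisphere, right hemisphere)
# in micromol/L. Left-hand tasks activate the right hemisphere; vibrotactile
# conditions (MV, MOV) respond more strongly and more asymmetrically than
# the visual-only MO, Rest not at all.
_DEFAULT_AMPLITUDES = {
    "Rest": (0.0, 0.0),
    "MV": (0.03, 0.30),
    "MO": (0.08, 0.15),
    "MOV": (0.05, 0.30),
}

# Planted cross-hemisphere couplings mirroring the study's observation that
# MV drives the densest causal network with a right-to-left dominant flow.
_DEFAULT_COUPLINGS = (
    Coupling("S1_D1", "S7_D5", lag=2, gain=0.9, condition="MV"),
    Coupling("S3_D1", "S8_D5", lag=1, gain=0.9, condition="MV"),
    Coupling("S3_D2", "S8_D7", lag=2, gain=0.9, condition="MV"),
    Coupling("S4_D2", "S10_D7", lag=1, gain=0.9, condition="MV"),
    Coupling("S4_D4", "S10_D8", lag=2, gain=0.9, condition="MV"),
    Coupling("S6_D5", "S2_D1", lag=1, gain=0.7, condition="MV"),
    Coupling("S3_D4", "S8_D8", lag=1, gain=0.8, condition="MOV"),
    Coupling("S5_D4", "S9_D8", lag=2, gain=0.8, condition="MOV"),
    Coupling("S8_D6", "S3_D3", lag=1, gain=0.6, condition="MOV"),
    Coupling("S1_D2", "S7_D7", lag=1, gain=0.7, condition="MO"),
    Coupling("S9_D6", "S5_D3", lag=1, gain=0.5, condition="MO"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Forward-model configuration for one synthetic subject.

    ``condition_amplitudes`` maps each condition to the (left, right)
    hemisphere peak HbO response in micromol/L. ``subject_amp_sd`` is the
    coefficient of variation of a per-subject gain, ``block_amp_jitter_sd``
    a per-block multiplicative jitter; both default to realistic inter- and
    intra-subject variability. ``hbr_ratio`` sets the HbR response as a
    fraction of the HbO response (negative: washout of deoxyhemoglobin).
    """

    fs: float = 10.0
    condition_amplitudes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES)
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    rng_seed: int = 0
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    dpf: float = DEFAULT_DPF
    subject_amp_sd: float = 0.2
    block_amp_jitter_sd: float = 0.1
    hbr_ratio: float = -1.0 / 3.0
    couplings: tuple[Coupling, ...] = _DEFAULT_COUPLINGS
    coupling_window: float = 20.0  # s after onset over which couplings act

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.noise.max_freq:
            raise ValueError(
                f"fs={self.fs} Hz must exceed twice the highest noise "
                f"frequency ({self.noise.max_freq} Hz)"
            )
        rest = self.condition_amplitudes.get("Rest")
        if rest is not None and tuple(rest) != (0.0, 0.0):
            raise ValueError("Rest amplitudes must be (0, 0)")

    def quiet(self) -> "SimulationConfig":
        """Copy with all noise and variability switched off (for oracles)."""
        return replace(
            self,
            noise=self.noise.scaled(0.0),
            subject_amp_sd=0.0,
            block_amp_jitter_sd=0.0,
            couplings=(),
        )


@dataclass
class GroundTruth:
    """What the simulator actually injected.

    ``amplitudes`` is (n_blocks, n_channels): the true peak HbO response of
    each channel in each task block, micromol/L. ``couplings`` lists every
    injected directed dependence.
    """

    amplitudes: np.ndarray
    conditions: tuple[str, ...]
    channels: tuple[str, ...]
    couplings: tuple[Coupling, ...] = ()

    def peak_amplitude(self, condition: str, channel: str) -> float:
        """Mean true peak response of one channel over one condition's blocks."""
        ch = self.channels.index(channel)
        mask = np.asarray([c == condition for c in self.conditions])
        if not mask.any():
            raise ValueError(f"no blocks with condition {condition!r}")
        return float(self.amplitudes[mask, ch].mean())


def double_gamma_hrf(fs: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Peak at 6 s, undershoot at 16 s, undershoot ratio 1/6; unit peak height.
    """
    from scipy.stats import gamma

    t = np.arange(0.0, duration, 1.0 / fs)
    peak = gamma.pdf(t, a=6, scale=1.0)
    undershoot = gamma.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def block_response_template(fs: float, task_duration: float = 10.0) -> np.ndarray:
    """HRF-convolved task boxcar, normalised to unit peak.

    Multiplying by a channel's configured amplitude yields that channel's
    noise-free response to one task block.
    """
    boxcar = np.ones(int(round(task_duration * fs)))
    resp = np.convolve(boxcar, double_gamma_hrf(fs))
    return resp / resp.max()


def _noise_traces(
    rng: np.random.Generator, noise: NoiseConfig, n_channels: int, n: int, fs: float
) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros((n_channels, n))
    for freq, amp in (
        (noise.cardiac_freq, noise.cardiac_amp),
        (noise.resp_freq, noise.resp_amp),
        (noise.mayer_freq, noise.mayer_amp),
    ):
        if amp == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi, size=n_channels)
        spread = 1 + 0.1 * rng.standard_normal(n_channels)
        out += (amp * spread)[:, None] * np.sin(
            2 * np.pi * freq * t[None, :] + phase[:, None]
        )
    if noise.drift_amp:
        slope = rng.uniform(-noise.drift_amp, noise.drift_amp, size=n_channels)
        out += slope[:, None] * (t[None, :] / max(t[-1], 1e-9))
    if noise.lfo_sd:
        from scipy.signal import butter, sosfiltfilt

        sos = butter(2, noise.lfo_cutoff, btype="lowpass", fs=fs, output="sos")
        slow = sosfiltfilt(sos, rng.standard_normal((n_channels, n)), axis=1)
        sd = slow.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out += noise.lfo_sd * slow / sd
    if noise.white_sd:
        out += noise.white_sd * rng.standard_normal((n_channels, n))
    return out


def simulate_subject(
    montage: Montage,
    schedule: TaskSchedule,
    config: SimulationConfig,
    *,
    tail: float = 40.0,
) -> tuple[HbTimeSeries, GroundTruth]:
    """Simulate one subject's HbO/HbR recording for a task schedule.

    Each block contributes an HRF-convolved boxcar scaled by the condition's
    per-hemisphere amplitude, a per-subject gain (CV ``subject_amp_sd``) and
    per-block jitter; physiological noise is added on top and configured
    couplings are injected inside their condition's task windows. The HbR
    trace is ``hbr_ratio`` times the HbO response plus independent noise at
    30% amplitude.

    Returns the recording and a :class:`GroundTruth` manifest with the true
    per-block per-channel amplitudes and the injected couplings.
    """
    fs = config.fs
    onsets = np.asarray([b.onset for b in schedule.blocks])
    durations = np.asarray([b.duration for b in schedule.blocks])
    ends = onsets + durations
    if np.any(onsets[1:] < ends[:-1]):
        i = int(np.argmax(onsets[1:] < ends[:-1]))
        raise ValueError(
            f"task blocks overlap: block {i} ends at {ends[i]:.1f} s, "
            f"block {i + 1} starts at {onsets[i + 1]:.1f} s"
        )
    n = int(round((schedule.end_time + tail) * fs)) + 1
    names = montage.channel_names
    hemis = montage.hemispheres
    n_ch = len(names)
    hemi_col = np.asarray([0 if h == "left" else 1 for h in hemis])

    rng = np.random.default_rng(config.rng_seed)
    subject_gain = max(0.1, 1 + config.subject_amp_sd * rng.standard_normal())
    template = block_response_template(fs, float(durations[0]))

    amplitudes = np.zeros((len(schedule.blocks), n_ch))
    response = np.zeros((n_ch, n))
    for i, block in enumerate(schedule.blocks):
        try:
            pair = config.condition_amplitudes[block.condition]
        except KeyError:
            raise KeyError(
                f"no amplitude configured for condition {block.condition!r}"
            ) from None
        jitter = 1 + config.block_amp_jitter_sd * rng.standard_normal()
        amp = np.asarray(pair)[hemi_col] * subject_gain * jitter
        amplitudes[i] = amp
        start = int(round(block.onset * fs))
        stop = min(n, start + template.size)
        if start >= n:
            raise ValueError(f"block {i} at {block.onset} s falls outside the series")
        response[:, start:stop] += amp[:, None] * template[None, : stop - start]

    hbo = response + _noise_traces(rng, config.noise, n_ch, n, fs)
    hbr = config.hbr_ratio * response + _noise_traces(
        rng, config.noise.scaled(0.3), n_ch, n, fs
    )

    ts = HbTimeSeries(hbo=hbo, hbr=hbr, fs=fs, channels=names, hemispheres=hemis)
    gt = GroundTruth(
        amplitudes=amplitudes,
        conditions=schedule.conditions,
        channels=names,
        couplings=(),
    )
    for coupling in config.couplings:
        ts, gt = _apply_coupling(ts, gt, coupling, schedule, config.coupling_window)
    return ts, gt


def _apply_coupling(
    ts: HbTimeSeries,
    gt: GroundTruth,
    coupling: Coupling,
    schedule: TaskSchedule,
    window: float,
) -> tuple[HbTimeSeries, GroundTruth]:
    """Inject a coupling inside its condition's task windows (whole series if
    the coupling has no condition)."""
    if coupling.condition is None:
        new = inject_directed_coupling(ts, coupling)
        return new, replace_couplings(gt, gt.couplings + (coupling,))
    if coupling.lag < 1:
        raise ValueError(f"coupling lag must be >= 1 sample, got {coupling.lag}")
    src = ts.channel_index(coupling.driver)
    dst = ts.channel_index(coupling.receiver)
    new = ts.copy()
    driver = ts.hbo[src]
    for block in schedule.blocks:
        if block.condition != coupling.condition:
            continue
        a = int(round(block.onset * ts.fs))
        b = min(ts.n_samples, a + int(round(window * ts.fs)))
        a = max(a, coupling.lag)
        new.hbo[dst, a:b] += coupling.gain * driver[a - coupling.lag : b - coupling.lag]
    return new, replace_couplings(gt, gt.couplings + (coupling,))


def replace_couplings(gt: GroundTruth, couplings: tuple[Coupling, ...]) -> GroundTruth:
    return GroundTruth(
        amplitudes=gt.amplitudes,
        conditions=gt.conditions,
        channels=gt.channels,
        couplings=couplings,
    )


def inject_directed_coupling(
    ts: HbTimeSeries,
    coupling: Coupling,
    ground_truth: GroundTruth | None = None,
) -> HbTimeSeries | tuple[HbTimeSeries, GroundTruth]:
    """Make ``receiver`` lag-dependent on ``driver`` over the whole series.

    Adds ``gain * driver_{t-lag}`` (the HbO trace) to the receiver's HbO for
    every sample with ``t >= lag``; the driver is unchanged. If a
    ``ground_truth`` manifest is given, the coupling is recorded in it and
    the updated manifest returned alongside the series.
    """
    if coupling.lag < 1:
        raise ValueError(f"coupling lag must be >= 1 sample, got {coupling.lag}")
    src = ts.channel_index(coupling.driver)
    dst = ts.channel_index(coupling.receiver)
    new = ts.copy()
    if coupling.gain != 0:
        new.hbo[dst, coupling.lag :] += coupling.gain * ts.hbo[src, : -coupling.lag]
    if ground_truth is None:
        return new
    return new, replace_couplings(ground_truth, ground_truth.couplings + (coupling,))


def hb_to_intensity(
    ts: HbTimeSeries,
    montage: Montage,
    config: SimulationConfig,
    reference: float = 1.0,
) -> RawIntensity:
    """Forward model: concentration changes to dual-wavelength intensities.

    Inverts the modified Beer-Lambert relation so that
    ``od_to_hb(intensity_to_od(...))`` recovers the input concentrations.
    """
    e = extinction_matrix(config.wavelengths)  # (2 wl, 2 chromo)
    conc = np.stack([ts.hbo, ts.hbr], axis=1) * 1e-6  # micromol/L -> mol/L
    d_od = np.einsum("wc,ncs->nws", e, conc) * montage.inter_optode_distance * config.dpf
    intensity = reference * np.power(10.0, -d_od)
    ref = np.full((ts.n_channels, 2), reference)
    return RawIntensity(
        data=intensity,
        fs=ts.fs,
        channels=ts.channels,
        wavelengths=config.wavelengths,
        hemispheres=ts.hemispheres,
        reference=ref,
    )


def simulate_cohort(
    montage: Montage,
    config: SimulationConfig,
    n_subjects: int = 14,
    *,
    n_sessions: int = 4,
    tasks_per_session: int = 10,
    seed: int | None = None,
) -> list[tuple[TaskSchedule, HbTimeSeries, GroundTruth]]:
    """Simulate a cohort with independent schedules and noise per subject.

    Per-subject seeds are spawned deterministically from ``seed`` (falling
    back to ``config.rng_seed``), so a cohort is a pure function of its seed.
    """
    root = config.rng_seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    out = []
    for child in ss.spawn(n_subjects):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        sched = generate_schedule(n_sessions, tasks_per_session, rng_seed=sub_seed)
        cfg = replace(config, rng_seed=sub_seed)
        ts, gt = simulate_subject(montage, sched, cfg)
        out.append((sched, ts, gt))
    return out
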