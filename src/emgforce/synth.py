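"""Synthetic surface-EMG and reference-torque trials.

The generator realizes the textbook picture of the interference EMG: a
pool of motor units (MUs) with recruitment thresholds spread over the
excitation range, each firing as a renewal process whose rate follows
the common drive, each discharge adding a biphasic action-potential
waveform to the channel.  A commanded activation profile in [0, 1]
drives recruitment and rate coding; Gaussian noise is added relative to
the full-excitation signal level.

MU amplitudes follow the size principle (later-recruited units are
larger).  The amplitude profile is chosen so that the shot-noise
variance of the interference sum is proportional to the squared
command: with common-drive rates r(c) = r_min + (r_max - r_min) c, the
cumulative power of the units recruited below c must be
W(c) = c^2 / r(c) (up to scale), so unit i carries power
W(theta_{i+1}) - W(theta_i).  The rectified-and-smoothed envelope then
tracks the command linearly over the whole excitation range, which is
what makes MVC normalization meaningful for the downstream estimators.

Reference (ground-truth) torque for round-trip tests is produced by
running a chosen forward model on the *noise-free* command profile, so
estimator error can be separated from fixture noise.  Labelled segments
(mvc, plateau30, plateau70, fast_short, slow_long) travel with each
trial for windowed metrics.

All randomness flows from the single trial seed; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .activation import muscle_activation
from .hill import MuscleTendonParams, simulate_hill
from .joint import DEFAULT_MOMENT_ARMS, muscle_torque
from .physio import PhysioParams, chemical_drive_from_indicator, simulate_physio
from .series import UniformSeries

#: Inter-spike-interval coefficient of variation of the renewal firing.
ISI_CV = 0.15

#: Onset threshold on the command profile for the reference chemical
#: indicator (forward physio model).
COMMAND_ONSET = 0.01

FORWARD_MODELS = ("hill_linear", "hill_nonlinear", "physio")


@dataclass(frozen=True)
class SynthTrialConfig:
    """One synthetic trial: command profile plus generator settings."""

    fs: float = 2048.0
    profile: np.ndarray = field(default=None)  # type: ignore[assignment]
    segments: tuple[tuple[str, int, int], ...] = ()
    n_motor_units: int = 50
    firing_rate_range: tuple[float, float] = (8.0, 35.0)
    ap_duration: float = 0.008
    noise_rms: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        prof = np.asarray(self.profile, dtype=float)
        if prof.ndim != 1 or prof.size < 2:
            raise ValueError("profile must be a 1-D command array")
        if prof.min() < 0 or prof.max() > 1:
            raise ValueError("profile must lie in [0, 1]")
        if not (self.fs > 2.0 / self.ap_duration):
            raise ValueError("fs must exceed twice the AP bandwidth 1/ap_duration")
        object.__setattr__(self, "profile", prof)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return (self.profile.size - 1) * self.dt


def _ap_waveform(fs: float, duration: float) -> np.ndarray:
    """Biphasic zero-mean action potential: derivative of a Gaussian."""
    sigma = duration / 6.0
    t = np.arange(-3 * sigma, 3 * sigma + 0.5 / fs, 1.0 / fs)
    w = -t / sigma**2 * np.exp(-(t**2) / (2 * sigma**2))
    return w / np.abs(w).max()


def _mu_amplitudes(n_mu: int, r_min: float, r_max: float) -> np.ndarray:
    """Size-principle amplitude of each MU (thresholds i/n_mu).

    Derived from requiring interference variance proportional to the
    squared command under common-drive rate coding; see module docstring.
    """
    edges = np.arange(n_mu + 1) / n_mu
    W = edges**2 / (r_min + (r_max - r_min) * edges + 1e-12)
    return np.sqrt(np.diff(W))


def _mu_spike_train(
    profile: np.ndarray,
    dt: float,
    theta: float,
    r_min: float,
    r_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spike sample indices of one MU (renewal firing, rate coding).

    The MU is active where profile > theta; active units share the
    common-drive rate r_min + (r_max - r_min) * command.
    """
    active = np.flatnonzero(profile > theta)
    spikes: list[int] = []
    if active.size == 0:
        return np.array(spikes, dtype=int)
    n = profile.size

    def rate(i: int) -> float:
        return r_min + (r_max - r_min) * profile[i]

    i = active[0]
    t = i * dt + rng.uniform(0.0, 1.0 / rate(i))
    while t < n * dt:
        i = int(t / dt)
        if i >= n:
            break
        if profile[i] > theta:
            spikes.append(i)
            r = rate(i)
            isi = (1.0 + ISI_CV * rng.standard_normal()) / r
            t += max(isi, 0.2 / r)
        else:
            nxt = np.searchsorted(active, i)
            if nxt >= active.size:
                break
            j = active[nxt]
            t = j * dt + rng.uniform(0.0, 1.0 / rate(j))
    return np.array(spikes, dtype=int)


def generate_surface_emg(cfg: SynthTrialConfig) -> UniformSeries:
    """One channel of interference EMG following the command profile."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.profile.size
    r_min, r_max = cfg.firing_rate_range
    train = np.zeros(n)
    n_mu = cfg.n_motor_units
    amps = _mu_amplitudes(n_mu, r_min, r_max)
    for k in range(n_mu):
        theta = k / n_mu  # recruitment thresholds spread over [0, 1)
        idx = _mu_spike_train(cfg.profile, cfg.dt, theta, r_min, r_max, rng)
        if idx.size:
            np.add.at(train, idx, amps[k])
    w = _ap_waveform(cfg.fs, cfg.ap_duration)
    sig = fftconvolve(train, w, mode="same")
    if cfg.noise_rms > 0:
        # shot-noise RMS of the fully excited pool, independent of the profile
        full_rms = math.sqrt(r_max * np.sum(amps**2) * np.sum(w**2) * cfg.dt)
        sig = sig + rng.normal(0.0, cfg.noise_rms * full_rms, n)
    return UniformSeries(dt=cfg.dt, values=sig)


# ---------------------------------------------------------------------------
# command-profile builders (protocol emulation)
# ---------------------------------------------------------------------------


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def ramp_plateau_profile(
    fs: float,
    level: float,
    label: str,
    t_pre: float = 1.0,
    t_ramp: float = 1.0,
    t_hold: float = 4.0,
    t_post: float = 1.0,
) -> tuple[np.ndarray, tuple[tuple[str, int, int], ...]]:
    """Rest - smooth ramp - plateau - ramp down - rest."""
    dt = 1.0 / fs
    n = int(round((t_pre + 2 * t_ramp + t_hold + t_post) / dt)) + 1
    t = np.arange(n) * dt
    up = _smoothstep((t - t_pre) / t_ramp)
    down = _smoothstep((t - (t_pre + t_ramp + t_hold)) / t_ramp)
    prof = level * (up - down)
    i0 = int(round((t_pre + t_ramp) / dt))
    i1 = int(round((t_pre + t_ramp + t_hold) / dt))
    return prof, ((label, i0, i1),)


def burst_profile(
    fs: float,
    bursts: list[tuple[str, float, float]],
    t_pre: float = 1.0,
    t_gap: float = 2.0,
    t_edge: float = 0.05,
) -> tuple[np.ndarray, tuple[tuple[str, int, int], ...]]:
    """A sequence of (label, hold duration, amplitude) bursts.

    Each burst rises and falls over ``t_edge`` and holds its amplitude
    for the stated duration; bursts are separated by ``t_gap`` of rest.
    """
    dt = 1.0 / fs
    total = t_pre + sum(2 * t_edge + d + t_gap for _, d, _ in bursts)
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    prof = np.zeros(n)
    segments = []
    t0 = t_pre
    for label, dur, amp in bursts:
        up = _smoothstep((t - t0) / t_edge)
        down = _smoothstep((t - (t0 + t_edge + dur)) / t_edge)
        prof += amp * (up - down)
        segments.append((label, int(round(t0 / dt)), int(round((t0 + 2 * t_edge + dur) / dt))))
        t0 += 2 * t_edge + dur + t_gap
    return np.clip(prof, 0.0, 1.0), tuple(segments)


def random_contraction_profile(
    fs: float, seed: int, n_events: int = 6
) -> tuple[np.ndarray, tuple[tuple[str, int, int], ...]]:
    """Alternating fast-short bursts and slow-long ramps, random levels."""
    rng = np.random.default_rng(seed)
    bursts = []
    for k in range(n_events):
        if k % 2 == 0:
            bursts.append(("fast_short", float(rng.uniform(0.15, 0.4)), float(rng.uniform(0.5, 1.0))))
        else:
            bursts.append(("slow_long", float(rng.uniform(2.0, 3.5)), float(rng.uniform(0.3, 0.9))))
    return burst_profile(fs, bursts, t_edge=0.3, t_gap=1.5)


# ---------------------------------------------------------------------------
# reference trials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trial:
    """A synthetic trial: per-muscle EMG, reference torque, labels."""

    emg: dict[str, UniformSeries]
    torque: UniformSeries | None
    segments: tuple[tuple[str, int, int], ...]
    seed: int
    fs: float


def forward_torque(
    command: UniformSeries,
    model: str,
    muscles: dict[str, MuscleTendonParams],
    physio: dict[str, PhysioParams] | None = None,
    moment_arms: dict[str, float] | None = None,
    A: float = -1.7,
    dt_int: float = 1e-3,
) -> UniformSeries:
    """Ground-truth joint torque from the noise-free command profile."""
    if model not in FORWARD_MODELS:
        raise ValueError(f"unknown forward model {model!r}")
    arms = moment_arms or DEFAULT_MOMENT_ARMS
    total = None
    for name, mt in muscles.items():
        if model == "physio":
            pp = (physio or {}).get(name) or PhysioParams.from_muscle(mt)
            pi = command.with_values((command.values > COMMAND_ONSET).astype(float))
            drive = chemical_drive_from_indicator(pi, Uc=pp.Uc, Ur=pp.Ur)
            fc = simulate_physio(drive, command, pp, dt_int=dt_int).Fc
        else:
            a = command if model == "hill_linear" else muscle_activation(command, A)
            fc = simulate_hill(a, mt, dt_int=dt_int).Fc
        tq = muscle_torque(fc, mt.phi, arms[name])
        total = tq if total is None else total.with_values(total.values + tq.values)
    return total


def generate_reference_trial(
    cfg: SynthTrialConfig,
    forward_model: str,
    muscles: dict[str, MuscleTendonParams],
    physio: dict[str, PhysioParams] | None = None,
    moment_arms: dict[str, float] | None = None,
    A: float = -1.7,
) -> Trial:
    """EMG channels plus ground-truth torque for one command profile.

    Each muscle channel gets its own random substream derived from the
    trial seed; the torque comes from the noise-free command.
    """
    command = UniformSeries(dt=cfg.dt, values=cfg.profile)
    emg = {}
    for j, name in enumerate(muscles):
        emg[name] = generate_surface_emg(replace(cfg, seed=cfg.seed * 1000 + j))
    torque = forward_torque(
        command, forward_model, muscles, physio=physio, moment_arms=moment_arms, A=A
    )
    return Trial(emg=emg, torque=torque, segments=cfg.segments, seed=cfg.seed, fs=cfg.fs)


def default_muscles() -> dict[str, MuscleTendonParams]:
    return {
        "gas": MuscleTendonParams.gastrocnemius(),
        "sol": MuscleTendonParams.soleus(),
    }


def protocol_trials(
    seed: int,
    forward_model: str = "physio",
    fs: float = 2048.0,
    muscles: dict[str, MuscleTendonParams] | None = None,
) -> dict[str, Trial]:
    """The five-trial protocol: MVC, 30% and 70% plateaus, two random
    fast-short / slow-long trials."""
    muscles = muscles or default_muscles()
    specs: dict[str, tuple[np.ndarray, tuple]] = {
        "mvc": ramp_plateau_profile(fs, 1.0, "mvc"),
        "plateau30": ramp_plateau_profile(fs, 0.3, "plateau30"),
        "plateau70": ramp_plateau_profile(fs, 0.7, "plateau70"),
        "random1": random_contraction_profile(fs, seed * 7 + 1),
        "random2": random_contraction_profile(fs, seed * 7 + 2),
    }
    out = {}
    for k, (name, (prof, segs)) in enumerate(specs.items()):
        cfg = SynthTrialConfig(fs=fs, profile=prof, segments=segs, seed=seed * 100 + k)
        out[name] = generate_reference_trial(cfg, forward_model, muscles)
    return out
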