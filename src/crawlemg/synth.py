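"""Synthetic crawling-trial generator.

Emulates the statistical structure of a multi-channel crawling recording: one
left-palm pressure channel for cycle segmentation plus 30 surface-EMG channels
whose burst timing encodes which limb is swinging.  Each virtual participant
performs trials of the eight coordination modes (and optionally a self-selected
mode) at three speeds; cycle durations and stance fractions are drawn per cycle
from per-speed normal distributions, limb events get per-event timing jitter,
and participants differ by channel gains, systematic limb-phase biases and
activation-burst widths.

The EMG model is deliberately phenomenological: each channel is baseline noise
plus a band-limited Gaussian carrier amplitude-modulated by smooth Gaussian
bursts centred in the swing phase of the channel's limb(s).  It reproduces
exactly the property the analysis pipeline exploits — the cross-channel timing
of envelope bursts differs between coordination modes — without attempting
biophysical realism (no motor-unit potentials, no volume conduction, no muscle
synergies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .gait import LIMBS, GaitTiming, ILCMDefinition, get_mode

__all__ = [
    "SpeedParams",
    "ParticipantParams",
    "SynthConfig",
    "Trial",
    "default_muscle_map",
    "generate_timing",
    "generate_pressure",
    "generate_emg",
    "activation_profiles",
    "generate_trial",
    "generate_cohort",
    "draw_participant",
]

SAMPLE_RATE = 1000.0  # Hz, fixed by the acquisition protocol being emulated
N_CHANNELS = 30


@dataclass(frozen=True)
class SpeedParams:
    """Per-cycle duration and stance-fraction distribution for one speed."""

    cycle_mean_s: float
    cycle_sd_s: float
    stance_mean: float
    stance_sd: float

    def __post_init__(self):
        if not 0 < self.stance_mean < 1:
            raise ValueError("stance_mean must lie in (0, 1)")
        if self.cycle_sd_s < 0 or self.stance_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def default_muscle_map() -> dict[str, tuple[int, ...]]:
    """Limb → EMG channel indices preferentially active in that limb's swing.

    Seven channels per limb (arm/thigh muscles of that quadrant) plus two
    trunk channels shared between diagonal limb pairs.
    """
    return {
        "LP": tuple(range(0, 7)) + (28,),
        "RP": tuple(range(7, 14)) + (29,),
        "LK": tuple(range(14, 21)) + (29,),
        "RK": tuple(range(21, 28)) + (28,),
    }


# Predefined-mode speeds: audio-prompted cycle durations; stance fractions from
# the per-speed duty-factor statistics (70.40/64.97/58.98 %).
_DEFAULT_SPEEDS = {
    "low": SpeedParams(3.5, 0.25, 0.704, 0.0654),
    "medium": SpeedParams(2.33, 0.16, 0.650, 0.0532),
    "fast": SpeedParams(1.75, 0.12, 0.590, 0.0481),
}

# Self-selected crawling is faster (~2 / 1.5 / 1 s per cycle).
_DEFAULT_SELF_SPEEDS = {
    "low": SpeedParams(2.0, 0.18, 0.704, 0.0654),
    "medium": SpeedParams(1.5, 0.14, 0.650, 0.0532),
    "fast": SpeedParams(1.0, 0.10, 0.590, 0.0481),
}

# Mode choice probabilities for self-selected trials: trot (M2) dominates at
# every speed; the diagonal-sequence gait M3 appears mostly at fast speed.
_DEFAULT_SELF_MODE_PROBS = {
    "low": {"M2": 0.87, "M3": 0.09, "M1": 0.04},
    "medium": {"M2": 0.93, "M1": 0.05, "M5": 0.02},
    "fast": {"M2": 0.70, "M3": 0.25, "M1": 0.05},
}


@dataclass(frozen=True)
class ParticipantParams:
    """Parameters drawn once per virtual participant."""

    participant_id: str
    channel_gains: np.ndarray          # (30,) multiplicative, log-normal
    timing_jitter_sd_s: float          # per-event touchdown jitter
    phase_bias: dict[str, float]       # systematic limb-phase offset (cycle fraction)
    activation_width: float            # burst FWHM as fraction of swing duration


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults define the emulated study conditions."""

    speeds: dict[str, SpeedParams] = field(default_factory=lambda: dict(_DEFAULT_SPEEDS))
    self_speeds: dict[str, SpeedParams] = field(
        default_factory=lambda: dict(_DEFAULT_SELF_SPEEDS))
    self_mode_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SELF_MODE_PROBS.items()})
    muscle_map: dict[str, tuple[int, ...]] = field(default_factory=default_muscle_map)
    n_channels: int = N_CHANNELS
    sample_rate: float = SAMPLE_RATE
    # EMG synthesis
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    baseline_noise: float = 0.05       # baseline white-noise amplitude
    burst_amplitude: float = 1.0       # carrier modulation depth at burst peak
    # participant-level variability (drawn per participant)
    gain_log_sd: float = 0.25
    timing_jitter_sd_s: float = 0.02
    timing_jitter_sd_spread: float = 0.005
    phase_bias_sd: float = 0.05
    activation_width_mean: float = 0.40
    activation_width_sd: float = 0.05
    # pressure synthesis
    pressure_plateau: float = 1.0
    pressure_ramp_s: float = 0.05
    pressure_noise_sd: float = 0.01

    def __post_init__(self):
        chans = sorted({c for idx in self.muscle_map.values() for c in idx})
        if any(c < 0 or c >= self.n_channels for c in chans):
            raise ValueError("muscle_map channel index out of range")
        if len(chans) != self.n_channels:
            raise ValueError("every channel must be assigned to at least one limb")

    def noiseless(self) -> "SynthConfig":
        """Copy with all stochastic spreads set to zero (debug / oracle runs)."""
        zeroed = {k: replace(v, cycle_sd_s=0.0, stance_sd=0.0)
                  for k, v in self.speeds.items()}
        zself = {k: replace(v, cycle_sd_s=0.0, stance_sd=0.0)
                 for k, v in self.self_speeds.items()}
        return replace(self, speeds=zeroed, self_speeds=zself, baseline_noise=0.0,
                       gain_log_sd=0.0, timing_jitter_sd_s=0.0,
                       timing_jitter_sd_spread=0.0, phase_bias_sd=0.0,
                       activation_width_sd=0.0, pressure_noise_sd=0.0)


@dataclass
class Trial:
    """One synthetic crawling recording with its generator ground truth."""

    emg: np.ndarray            # (30, T)
    pressure: np.ndarray       # (T,)
    sample_rate: float
    participant_id: str
    speed: str
    mode: str                  # trial label: M1..M8 or "self"
    ilcm: str                  # coordination mode actually executed
    timing: GaitTiming | None = None   # generator-only ground truth

    def __post_init__(self):
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.emg.shape[1] != self.pressure.shape[0]:
            raise ValueError("emg and pressure must share the time axis")


def draw_participant(config: SynthConfig, participant_id: str,
                     rng: np.random.Generator) -> ParticipantParams:
    gains = np.exp(rng.normal(0.0, config.gain_log_sd, config.n_channels))
    jitter = abs(rng.normal(config.timing_jitter_sd_s, config.timing_jitter_sd_spread))
    # clipped at 2 sd: participants keep executing the instructed landing
    # order, so idiosyncratic phase shifts cannot swap adjacent event groups
    bias = {
        limb: float(np.clip(rng.normal(0.0, config.phase_bias_sd),
                            -2 * config.phase_bias_sd, 2 * config.phase_bias_sd))
        for limb in LIMBS
    }
    bias["LP"] = 0.0  # LP touchdown defines the cycle origin
    width = float(np.clip(rng.normal(config.activation_width_mean,
                                     config.activation_width_sd), 0.15, 0.8))
    return ParticipantParams(participant_id, gains, float(jitter), bias, width)


def _neutral_participant(config: SynthConfig) -> ParticipantParams:
    return ParticipantParams("P0", np.ones(config.n_channels), 0.0,
                             {l: 0.0 for l in LIMBS}, config.activation_width_mean)


def generate_timing(
    config: SynthConfig,
    mode: ILCMDefinition | str,
    speed: str,
    n_cycles: int,
    seed: int | np.random.Generator,
    participant: ParticipantParams | None = None,
    speed_params: SpeedParams | None = None,
    max_attempts: int = 100,
) -> GaitTiming:
    """Draw a jittered realization of one mode's limb-timing schedule.

    Per-cycle durations and stance fractions come from the speed's configured
    normal distributions; every non-LP touchdown gets Gaussian jitter plus the
    participant's systematic phase bias.  Jitter that would break the mode's
    landing order (or push an event out of its cycle) is resampled; after
    ``max_attempts`` failures the generation aborts.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if isinstance(mode, str):
        mode = get_mode(mode)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    participant = participant or _neutral_participant(config)
    sp = speed_params or config.speeds[speed]

    durations = np.clip(rng.normal(sp.cycle_mean_s, sp.cycle_sd_s, n_cycles),
                        0.3 * sp.cycle_mean_s, None)
    stance_fracs = np.clip(rng.normal(sp.stance_mean, sp.stance_sd, n_cycles),
                           0.05, 0.95)
    lp_starts = np.concatenate([[0.0], np.cumsum(durations)])

    group_of = {l: i for i, grp in enumerate(mode.landing_order) for l in grp}
    touchdowns: dict[str, list[float]] = {l: [] for l in LIMBS}
    liftoffs: dict[str, list[float]] = {l: [] for l in LIMBS}
    for k in range(n_cycles):
        t0, dur, sf = lp_starts[k], durations[k], stance_fracs[k]
        for attempt in range(max_attempts):
            times = {}
            for limb in LIMBS:
                if limb == "LP":
                    times[limb] = t0
                    continue
                phase = mode.ideal_phase[limb] + participant.phase_bias[limb]
                td = t0 + phase * dur + rng.normal(0.0, participant.timing_jitter_sd_s)
                # events are clamped into their own cycle (bias/jitter must not
                # move a touchdown across a cycle boundary)
                times[limb] = min(max(td, t0), t0 + dur * (1 - 1e-9))
            ordered = sorted(LIMBS, key=lambda l: (group_of[l], times[l]))
            order_ok = all(
                group_of[ordered[i]] <= group_of[ordered[i + 1]]
                and times[ordered[i]] <= times[ordered[i + 1]]
                for i in range(3)
            )
            if order_ok:
                break
        else:
            raise RuntimeError(
                f"could not realize landing order of {mode.mode_id} in cycle {k} "
                f"after {max_attempts} attempts (jitter too large)"
            )
        for limb in LIMBS:
            touchdowns[limb].append(times[limb])
            liftoffs[limb].append(times[limb] + sf * dur)
    # closing LP touchdown: the schedule holds n_cycles complete LP-to-LP cycles
    t_end = lp_starts[-1]
    touchdowns["LP"].append(t_end)
    liftoffs["LP"].append(t_end + stance_fracs[-1] * durations[-1])

    events = {l: np.column_stack([touchdowns[l], liftoffs[l]]) for l in LIMBS}
    return GaitTiming(events, cycle_duration_s=float(np.mean(durations)),
                      stance_fraction={l: float(np.mean(stance_fracs)) for l in LIMBS})


def _trial_length(timing: GaitTiming, config: SynthConfig) -> int:
    end_s = timing.touchdowns("LP")[-1] + max(4 * config.pressure_ramp_s, 0.25)
    return int(round(end_s * config.sample_rate))


def generate_pressure(
    timing: GaitTiming,
    config: SynthConfig,
    seed: int | np.random.Generator = 0,
    n_samples: int | None = None,
) -> np.ndarray:
    """Left-palm pressure: plateau during LP stance, zero during swing.

    Linear ramps of ``pressure_ramp_s`` start at each touchdown and liftoff;
    additive sensor noise is clipped at zero.
    """
    if config.pressure_plateau <= 0:
        raise ValueError("pressure plateau level must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = n_samples if n_samples is not None else _trial_length(timing, config)
    t = np.arange(T) / config.sample_rate
    ev = timing.events.get("LP", np.empty((0, 2)))
    if ev.size == 0:
        p = np.zeros(T)
    else:
        ramp = config.pressure_ramp_s
        stances = ev[:, 1] - ev[:, 0]
        swings = ev[1:, 0] - ev[:-1, 1]
        if np.any(stances <= ramp) or np.any(swings <= ramp):
            raise ValueError("pressure ramp longer than the shortest phase")
        xp, fp = [-1e9], [0.0]
        for td, lo in ev:
            xp += [td, td + ramp, lo, lo + ramp]
            fp += [0.0, config.pressure_plateau, config.pressure_plateau, 0.0]
        p = np.interp(t, xp, fp)
    if config.pressure_noise_sd > 0:
        p = p + rng.normal(0.0, config.pressure_noise_sd, T)
    return np.clip(p, 0.0, None)


def activation_profiles(
    timing: GaitTiming,
    config: SynthConfig,
    n_samples: int,
    activation_width: float | None = None,
) -> np.ndarray:
    """Programmed per-channel activation profiles, shape (n_channels, T).

    Each limb contributes a Gaussian burst per swing interval (liftoff to next
    touchdown of that limb), centred at mid-swing with FWHM equal to
    ``activation_width`` times the swing duration; a channel's profile is the
    sum over its assigned limbs.  This is the modulation envelope the EMG
    carrier is multiplied by, exposed for generator self-checks.
    """
    width = activation_width if activation_width is not None else config.activation_width_mean
    t = np.arange(n_samples) / config.sample_rate
    limb_act = {}
    for limb in LIMBS:
        ev = timing.events[limb]
        act = np.zeros(n_samples)
        for k in range(len(ev) - 1):
            lo, td_next = ev[k, 1], ev[k + 1, 0]
            swing = td_next - lo
            if swing <= 0:
                continue
            center = lo + swing / 2.0
            sd = width * swing / 2.3548200450309493  # FWHM -> sd
            act += np.exp(-0.5 * ((t - center) / sd) ** 2)
        limb_act[limb] = act
    out = np.zeros((config.n_channels, n_samples))
    for limb, chans in config.muscle_map.items():
        for c in chans:
            out[c] += limb_act[limb]
    return out


def generate_emg(
    timing: GaitTiming,
    config: SynthConfig,
    seed: int | np.random.Generator,
    participant: ParticipantParams | None = None,
    n_samples: int | None = None,
) -> np.ndarray:
    """Synthesize the (30, T) EMG matrix for one trial.

    channel = gain * (baseline white noise + band-limited carrier * burst profile).
    Coordination modes therefore differ in the cross-channel timing of envelope
    bursts, not in marginal amplitudes.
    """
    if not config.muscle_map:
        raise ValueError("muscle_map must not be empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    participant = participant or _neutral_participant(config)
    T = n_samples if n_samples is not None else _trial_length(timing, config)
    if T > (timing.span_s + 0.5) * config.sample_rate:
        raise ValueError("timing does not cover the requested trial span")

    profiles = activation_profiles(timing, config, T, participant.activation_width)
    lo, hi = config.carrier_band_hz
    nyq = config.sample_rate / 2.0
    sos = signal.butter(4, [lo / nyq, min(hi / nyq, 0.99)], btype="band", output="sos")
    white = rng.standard_normal((config.n_channels, T))
    carrier = signal.sosfilt(sos, white, axis=1)
    carrier /= max(carrier.std(), 1e-12)
    baseline = config.baseline_noise * rng.standard_normal((config.n_channels, T))
    emg = carrier * (config.burst_amplitude * profiles) + baseline
    return participant.channel_gains[:, None] * emg


def generate_trial(
    config: SynthConfig,
    mode: str,
    speed: str,
    n_cycles: int,
    seed: int | np.random.Generator,
    participant: ParticipantParams | None = None,
) -> Trial:
    """One complete synthetic trial (timing + pressure + EMG + metadata).

    ``mode`` may be ``"M1"``..``"M8"`` or ``"self"``; a self-selected trial
    draws its executed coordination mode from the per-speed choice
    distribution and uses the (faster) self-selected cadence parameters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    participant = participant or _neutral_participant(config)
    if mode == "self":
        probs = config.self_mode_probs[speed]
        ilcm = rng.choice(list(probs), p=np.array(list(probs.values())) / sum(probs.values()))
        sp = config.self_speeds[speed]
    else:
        ilcm = mode
        sp = config.speeds[speed]
    # The recorded window sits between a lead-in and a lead-out cycle: a
    # participant is already crawling when recording starts and keeps crawling
    # past its end, so swings that begin before the first recorded LP touchdown
    # (or end after the last) still contribute their EMG bursts to the first
    # and last recorded cycles.
    full = generate_timing(config, ilcm, speed, n_cycles + 2, rng,
                           participant=participant, speed_params=sp)
    shift = full.touchdowns("LP")[1]
    shifted = {l: ev - shift for l, ev in full.events.items()}
    window_end = shifted["LP"][n_cycles + 1, 0]
    gen_timing = GaitTiming({l: ev.copy() for l, ev in shifted.items()},
                            full.cycle_duration_s, full.stance_fraction)
    recorded = {
        l: ev[(ev[:, 0] >= -1e-9)
              & (ev[:, 0] <= window_end + (1e-9 if l == "LP" else -1e-9))]
        for l, ev in shifted.items()
    }
    timing = GaitTiming(recorded, full.cycle_duration_s, full.stance_fraction)
    T = _trial_length(timing, config)
    pressure = generate_pressure(gen_timing, config, rng, n_samples=T)
    emg = generate_emg(gen_timing, config, rng, participant=participant, n_samples=T)
    return Trial(emg, pressure, config.sample_rate, participant.participant_id,
                 speed, mode, str(ilcm), timing)


def generate_cohort(
    config: SynthConfig,
    n_participants: int,
    modes: list[str],
    speeds: list[str],
    cycles_per_trial: int,
    seed: int,
) -> list[Trial]:
    """One trial per (participant, mode, speed), reproducible from ``seed``.

    Participant-level parameters are drawn once per participant; every trial
    gets an independent child stream of the master seed, so the cohort is
    deterministic under a fixed configuration.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if not modes or not speeds:
        raise ValueError("modes and speeds must be non-empty")
    master = np.random.SeedSequence(seed)
    trials = []
    for p_idx, p_seq in enumerate(master.spawn(n_participants)):
        streams = p_seq.spawn(1 + len(modes) * len(speeds))
        participant = draw_participant(config, f"P{p_idx + 1}",
                                       np.random.default_rng(streams[0]))
        i = 1
        for mode in modes:
            for speed in speeds:
                trials.append(generate_trial(config, mode, speed, cycles_per_trial,
                                             np.random.default_rng(streams[i]),
                                             participant=participant))
                i += 1
    return trials
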