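"""Synthetic bistable-MEG dataset generation.

Emulates a continuous auditory-streaming experiment: an A-B-A tone triplet
(A = 1414 Hz, B = 1000 Hz) repeats every 600 ms while the listener's percept
alternates between a fused "gallop" rhythm and "segregated" tone streams.
Dominance durations follow a lognormal renewal process. A state-dependent
evoked-response difference is planted in temporal-cortex sources within a
configurable latency window (default 250-267 ms post triplet onset), projected
to sensors through a lead field, and buried in additive Gaussian sensor noise.
The listener's button report lags the true perceptual switch by a truncated
Gaussian motor latency and may pass through brief ambiguous ("none"/"both")
episodes around each switch.

All randomness flows from explicit seeds; identical (config, seed) pairs give
bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "StimulusConfig",
    "PerceptProcess",
    "SourceEffect",
    "Recording",
    "BUTTON_CODES",
    "BUTTON_NAMES",
    "generate_percept_sequence",
    "generate_stimulus_timeline",
    "default_evoked_waveform",
    "simulate_source_timecourses",
    "forward_project",
    "generate_dataset",
    "sensor_positions",
    "default_source_grid",
]

# Integer codes for the per-sample button stream.
BUTTON_CODES = {"none": 0, "gallop": 1, "segregated": 2, "both": 3}
BUTTON_NAMES = {v: k for k, v in BUTTON_CODES.items()}


@dataclass
class StimulusConfig:
    """Timing of the repeating A-B-A triplet stimulus and the recording.

    Defaults reproduce the study conditions: 100 ms tones with 50 ms
    inter-tone gaps and a 200 ms silence before the next triplet (600 ms
    trial), six 5-minute blocks of 500 trials each, sampled at 600 Hz.
    """

    tone_a_hz: float = 1414.0
    tone_b_hz: float = 1000.0
    tone_len_ms: float = 100.0
    inter_tone_ms: float = 50.0
    post_triplet_ms: float = 200.0
    trial_ms: float = 600.0
    block_s: float = 300.0
    n_blocks: int = 6
    fs_hz: float = 600.0

    def __post_init__(self) -> None:
        span = 3 * self.tone_len_ms + 2 * self.inter_tone_ms + self.post_triplet_ms
        if abs(span - self.trial_ms) > 1e-9:
            raise ValueError(
                f"tone timing ({span} ms) does not fill the {self.trial_ms} ms trial"
            )
        if abs(self.block_s * 1000 / self.trial_ms - round(self.block_s * 1000 / self.trial_ms)) > 1e-9:
            raise ValueError("block duration must hold an integer number of trials")
        spt = self.trial_ms * self.fs_hz / 1000.0
        if abs(spt - round(spt)) > 1e-9:
            raise ValueError("trial duration must be an integer number of samples")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_ms * self.fs_hz / 1000.0))

    @property
    def trials_per_block(self) -> int:
        return int(round(self.block_s * 1000.0 / self.trial_ms))

    @property
    def samples_per_block(self) -> int:
        return int(round(self.block_s * self.fs_hz))

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def total_s(self) -> float:
        return self.n_blocks * self.block_s

    @property
    def total_samples(self) -> int:
        return self.n_blocks * self.samples_per_block


@dataclass
class PerceptProcess:
    """Lognormal renewal process for percept dominance durations.

    Durations (seconds) are i.i.d. lognormal(mu_log, sigma_log); states
    strictly alternate.  Defaults give a mean dominance of ~8.7 s, within the
    wide range seen across listeners of streaming stimuli.
    """

    mu_log: float = float(np.log(8.0))
    sigma_log: float = 0.4
    state_labels: tuple[str, str] = ("gallop", "segregated")
    initial_state: str = "gallop"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")
        if self.initial_state not in self.state_labels:
            raise ValueError(f"initial_state {self.initial_state!r} not in state_labels")


@dataclass
class SourceEffect:
    """Ground-truth neural generators and the planted state effect.

    positions : (n, 3) MNI mm coordinates of active sources.
    evoked_waveform : per-trial source time course (arbitrary units over one
        trial); None selects a default tri-peaked auditory-like response.
    effect_window_ms : latency window in which the percept-dependent
        difference is added (defaults to 250-267 ms after triplet onset).
    effect_amplitude : additive amplitude at the effect sources during
        "segregated" trials, inside the window only.
    effect_sources : indices into ``positions`` carrying the effect
        (default: all).
    button_latency_mean_ms / button_latency_sd_ms : truncated-Gaussian motor
        report lag after a true perceptual switch (floored at zero).
    """

    positions: np.ndarray = field(
        default_factory=lambda: np.array([[54.0, -14.0, 11.0], [-49.0, -20.0, 5.0]])
    )
    evoked_waveform: np.ndarray | None = None
    effect_window_ms: tuple[float, float] = (250.0, 267.0)
    effect_amplitude: float = 1.0
    effect_sources: tuple[int, ...] | None = None
    button_latency_mean_ms: float = 400.0
    button_latency_sd_ms: float = 100.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3) MNI mm")
        lo, hi = self.effect_window_ms
        if not (0 <= lo < hi <= 600):
            raise ValueError("effect_window_ms must lie within [0, 600] ms")
        if self.effect_sources is not None:
            idx = np.asarray(self.effect_sources, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.positions)):
                raise ValueError("effect source index outside positions")


@dataclass
class Recording:
    """A continuous synthetic (or imported) MEG recording.

    data : (sensors, samples) field values, arbitrary units.
    channel_pos : (sensors, 3) sensor positions in metres.
    stim_onsets : sample indices of trial (triplet) onsets, strictly
        increasing.
    button_stream : per-sample reported state code (see BUTTON_CODES).
    lead_field : (sensors, sources) forward matrix.
    source_pos : (sources, 3) MNI mm grid positions.
    meta : provenance dict (configs, seeds, schema).
    """

    data: np.ndarray
    fs_hz: float
    channel_pos: np.ndarray
    stim_onsets: np.ndarray
    button_stream: np.ndarray
    lead_field: np.ndarray | None = None
    source_pos: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.stim_onsets = np.asarray(self.stim_onsets, dtype=np.int64)
        self.button_stream = np.asarray(self.button_stream, dtype=np.int8)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording data contains non-finite values")
        if self.stim_onsets.size and np.any(np.diff(self.stim_onsets) <= 0):
            raise ValueError("stim_onsets must be strictly increasing")
        if self.button_stream.shape[0] != self.data.shape[1]:
            raise ValueError("button_stream must cover every sample")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Percept process
# ---------------------------------------------------------------------------

def generate_percept_sequence(
    process: PerceptProcess, total_s: float, rng: np.random.Generator | None = None
) -> list[tuple[str, float]]:
    """Draw an alternating sequence of (state, duration_s) covering total_s.

    Durations are i.i.d. lognormal; the final segment is truncated so the
    summed durations equal ``total_s`` exactly.
    """
    if total_s <= 0:
        raise ValueError("total_s must be positive")
    if rng is None:
        rng = np.random.default_rng(process.seed)
    states = process.state_labels
    i = states.index(process.initial_state)
    seq: list[tuple[str, float]] = []
    t = 0.0
    while total_s - t > 1e-9 * max(total_s, 1.0):
        d = float(np.exp(rng.normal(process.mu_log, process.sigma_log)))
        if t + d > total_s:
            d = total_s - t
        seq.append((states[i], d))
        t += d
        i = 1 - i
    return seq


def percept_state_per_sample(
    percept_seq: list[tuple[str, float]], n_samples: int, fs_hz: float
) -> np.ndarray:
    """Expand a (state, duration) sequence to a per-sample state-code array."""
    out = np.zeros(n_samples, dtype=np.int8)
    t = 0.0
    for state, dur in percept_seq:
        i0 = int(round(t * fs_hz))
        i1 = min(int(round((t + dur) * fs_hz)), n_samples)
        out[i0:i1] = BUTTON_CODES[state]
        t += dur
    if t * fs_hz < n_samples - 0.5:
        # sequence shorter than the recording: hold the last state
        out[int(round(t * fs_hz)):] = out[int(round(t * fs_hz)) - 1]
    return out


# ---------------------------------------------------------------------------
# Stimulus timeline
# ---------------------------------------------------------------------------

def generate_stimulus_timeline(cfg: StimulusConfig) -> np.ndarray:
    """Sample indices of every triplet onset; blocks are contiguous segments."""
    onsets = []
    for b in range(cfg.n_blocks):
        start = b * cfg.samples_per_block
        onsets.append(start + np.arange(cfg.trials_per_block) * cfg.samples_per_trial)
    return np.concatenate(onsets).astype(np.int64)


# ---------------------------------------------------------------------------
# Source-level simulation
# ---------------------------------------------------------------------------

def default_evoked_waveform(cfg: StimulusConfig) -> np.ndarray:
    """Auditory-like evoked response over one trial: a ~M100 deflection
    following each of the three tone onsets (0, 150 and 300 ms)."""
    t = np.arange(cfg.samples_per_trial) / cfg.fs_hz * 1000.0  # ms
    wave = np.zeros_like(t)
    for onset, amp in ((0.0, 1.0), (150.0, 0.8), (300.0, 1.0)):
        peak = onset + 100.0
        wave += amp * np.exp(-0.5 * ((t - peak) / 25.0) ** 2)
    return wave


def simulate_source_timecourses(
    effect: SourceEffect,
    timeline: np.ndarray,
    percept_seq: list[tuple[str, float]],
    cfg: StimulusConfig,
) -> np.ndarray:
    """Noiseless source time courses (sources x samples).

    Every trial contributes the evoked waveform at each of the effect's
    sources; trials whose onset falls inside a "segregated" dominance segment
    additionally receive ``effect_amplitude`` at the designated effect sources
    within the effect window. Deterministic given its inputs.
    """
    n_src = len(effect.positions)
    n_samples = cfg.total_samples
    wave = effect.evoked_waveform
    if wave is None:
        wave = default_evoked_waveform(cfg)
    wave = np.asarray(wave, dtype=float)
    if wave.shape[0] != cfg.samples_per_trial:
        raise ValueError("evoked_waveform length must equal samples_per_trial")

    state = percept_state_per_sample(percept_seq, n_samples, cfg.fs_hz)
    lo = int(round(effect.effect_window_ms[0] * cfg.fs_hz / 1000.0))
    hi = int(round(effect.effect_window_ms[1] * cfg.fs_hz / 1000.0))
    eff_idx = (
        np.arange(n_src)
        if effect.effect_sources is None
        else np.asarray(effect.effect_sources, dtype=int)
    )

    src = np.zeros((n_src, n_samples))
    spt = cfg.samples_per_trial
    for onset in timeline:
        stop = min(onset + spt, n_samples)
        src[:, onset:stop] += wave[: stop - onset]
        if state[onset] == BUTTON_CODES["segregated"]:
            a, b = onset + lo, min(onset + hi, n_samples)
            if a < b:
                src[eff_idx, a:b] += effect.effect_amplitude
    return src


def forward_project(
    lead_field: np.ndarray,
    source_ts: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sensor data = lead_field @ source_ts + white Gaussian noise."""
    lead_field = np.asarray(lead_field, dtype=float)
    source_ts = np.asarray(source_ts, dtype=float)
    if lead_field.shape[1] != source_ts.shape[0]:
        raise ValueError(
            f"lead field has {lead_field.shape[1]} sources, "
            f"time courses have {source_ts.shape[0]}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = lead_field @ source_ts
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return data


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def sensor_positions(n_sensors: int = 274, radius_m: float = 0.11) -> np.ndarray:
    """Quasi-uniform helmet-like sensor array: Fibonacci points on the part
    of a sphere above z = -0.25 R (covers vertex down past the ears)."""
    i = np.arange(n_sensors)
    z = 1.0 - (1.0 + 0.25) * (i + 0.5) / n_sensors  # z/R in (-0.25, 1)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r_xy = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = radius_m * np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
    return pos


# A-priori ROI centers (right/left auditory cortex, right posterior
# intraparietal sulcus); included in the default grid so sphere-restricted
# analyses are never empty.
_APRIORI_CENTERS = np.array(
    [[54.0, -14.0, 11.0], [-49.0, -20.0, 5.0], [34.0, -72.0, 38.0]]
)


def default_source_grid(
    effect_positions: np.ndarray,
    n_background: int = 96,
    rng: np.random.Generator | None = None,
    include_positions: np.ndarray | None = None,
) -> np.ndarray:
    """Source grid: the effect positions, then any ``include_positions`` not
    already present (defaults to the a-priori ROI centers), then background
    positions drawn uniformly in a brain-sized MNI box."""
    if rng is None:
        rng = np.random.default_rng(0)
    eff = np.asarray(effect_positions, dtype=float).reshape(-1, 3)
    if include_positions is None:
        include_positions = _APRIORI_CENTERS
    extra = [
        p
        for p in np.asarray(include_positions, dtype=float).reshape(-1, 3)
        if eff.size == 0 or np.linalg.norm(eff - p, axis=1).min() > 1.0
    ]
    lo = np.array([-70.0, -95.0, -45.0])
    hi = np.array([70.0, 65.0, 75.0])
    n_bg = max(n_background - len(extra), 0)
    bg = rng.uniform(lo, hi, size=(n_bg, 3))
    parts = [eff] + ([np.asarray(extra)] if extra else []) + [bg]
    return np.vstack(parts)


def random_lead_field(
    n_sensors: int, n_sources: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-norm random Gaussian forward columns (synthetic head model)."""
    L = rng.standard_normal((n_sensors, n_sources))
    return L / np.linalg.norm(L, axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Button-report stream
# ---------------------------------------------------------------------------

def _truncated_gauss(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One truncated-Gaussian draw floored at zero (rejection sampling)."""
    if sd <= 0:
        return max(mean, 0.0)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return x
    return max(mean, 0.0)


def simulate_button_stream(
    percept_seq: list[tuple[str, float]],
    n_samples: int,
    fs_hz: float,
    effect: SourceEffect,
    rng: np.random.Generator,
    ambiguous_none_prob: float = 0.2,
    ambiguous_both_prob: float = 0.1,
    ambiguous_dur_s: float = 0.3,
) -> np.ndarray:
    """Per-sample reported state: the true percept sequence with each switch
    delayed by a sampled motor latency, plus optional brief "none" gaps or
    "both" overlaps around the realized button switches."""
    switch_times = np.cumsum([d for _, d in percept_seq])[:-1]
    states = [s for s, _ in percept_seq]

    # Realized button switch times (monotone; late reports may swallow the
    # following short segment, as happens with real observers).
    events: list[tuple[float, str]] = [(0.0, states[0])]
    t_prev = 0.0
    for k, t_sw in enumerate(switch_times):
        lat = _truncated_gauss(
            rng, effect.button_latency_mean_ms / 1000.0, effect.button_latency_sd_ms / 1000.0
        )
        t_btn = t_sw + lat
        if t_btn <= t_prev:
            t_btn = t_prev + 1.0 / fs_hz
        events.append((t_btn, states[k + 1]))
        t_prev = t_btn

    stream = np.zeros(n_samples, dtype=np.int8)
    for k, (t0, state) in enumerate(events):
        i0 = min(int(round(t0 * fs_hz)), n_samples)
        i1 = (
            min(int(round(events[k + 1][0] * fs_hz)), n_samples)
            if k + 1 < len(events)
            else n_samples
        )
        stream[i0:i1] = BUTTON_CODES[state]

    # Ambiguous episodes at realized switches: a release gap ("none") or an
    # overlap of the two buttons ("both").
    for t_btn, _state in events[1:]:
        i_btn = int(round(t_btn * fs_hz))
        if i_btn >= n_samples:
            continue
        dur = int(round(abs(rng.normal(ambiguous_dur_s, ambiguous_dur_s / 3)) * fs_hz))
        u = rng.uniform()
        if u < ambiguous_none_prob:
            stream[i_btn : min(i_btn + dur, n_samples)] = BUTTON_CODES["none"]
        elif u < ambiguous_none_prob + ambiguous_both_prob:
            stream[max(i_btn - dur, 0) : i_btn] = BUTTON_CODES["both"]
    return stream


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def generate_dataset(
    cfg: StimulusConfig,
    process: PerceptProcess,
    effect: SourceEffect,
    seed: int = 0,
    n_sensors: int = 274,
    n_background_sources: int = 96,
    noise_sd: float = 1.0,
    lead_field: np.ndarray | None = None,
    source_pos: np.ndarray | None = None,
    ambiguous_none_prob: float = 0.2,
    ambiguous_both_prob: float = 0.1,
) -> Recording:
    """Generate a complete synthetic Recording with known ground truth.

    The seed drives independent child streams for percept durations, the lead
    field, sensor noise and button-report latency, so the same (config, seed)
    pair is bit-reproducible.
    """
    ss = np.random.SeedSequence(seed)
    rng_percept, rng_forward, rng_noise, rng_button = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    percept_seq = generate_percept_sequence(process, cfg.total_s, rng_percept)
    timeline = generate_stimulus_timeline(cfg)
    src_ts = simulate_source_timecourses(effect, timeline, percept_seq, cfg)

    if source_pos is None:
        source_pos = default_source_grid(effect.positions, n_background_sources, rng_forward)
    else:
        source_pos = np.asarray(source_pos, dtype=float)
    n_sources = len(source_pos)
    if lead_field is None:
        lead_field = random_lead_field(n_sensors, n_sources, rng_forward)
    else:
        lead_field = np.asarray(lead_field, dtype=float)

    # Active sources occupy the leading columns of the lead field; silent
    # background sources need not be materialized.
    data = forward_project(
        lead_field[:, : len(effect.positions)], src_ts, noise_sd, rng_noise
    )

    button = simulate_button_stream(
        percept_seq,
        cfg.total_samples,
        cfg.fs_hz,
        effect,
        rng_button,
        ambiguous_none_prob=ambiguous_none_prob,
        ambiguous_both_prob=ambiguous_both_prob,
    )

    meta = {
        "schema_version": 1,
        "seed": seed,
        "stimulus": asdict(cfg),
        "percept": {**asdict(process), "state_labels": list(process.state_labels)},
        "effect": {
            "positions": effect.positions.tolist(),
            "effect_window_ms": list(effect.effect_window_ms),
            "effect_amplitude": effect.effect_amplitude,
            "effect_sources": (
                None if effect.effect_sources is None else list(effect.effect_sources)
            ),
            "button_latency_mean_ms": effect.button_latency_mean_ms,
            "button_latency_sd_ms": effect.button_latency_sd_ms,
        },
        "noise_sd": noise_sd,
        "n_sensors": n_sensors,
        "ambiguous_none_prob": ambiguous_none_prob,
        "ambiguous_both_prob": ambiguous_both_prob,
        "ground_truth_percept_seq": [[s, float(d)] for s, d in percept_seq],
        "channel_pos_units": "m",
    }
    # meta must be JSON-serializable for the container
    json.dumps(meta)

    return Recording(
        data=data,
        fs_hz=cfg.fs_hz,
        channel_pos=sensor_positions(n_sensors),
        stim_onsets=timeline,
        button_stream=button,
        lead_field=lead_field,
        source_pos=source_pos,
        meta=meta,
    )
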