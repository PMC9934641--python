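"""Synthetic delayed-recognition EEG sessions.

Emulates a single-item delayed-recognition working-memory task: on each
trial a child sees a visual, spatial, or verbal stimulus for 1 s, maintains
it over a 2 s blank delay, and judges whether a probe matches it.  The
generator produces (a) the trial schedule, (b) a continuous multichannel
EEG record built from 1/f background noise plus category-specific spatial
patterns that are strong while the stimulus is on screen and decay
exponentially during the delay, and (c) per-trial behavioral responses.

The forward model is deliberately minimal: each category c has a fixed
unit-norm channel topography p_c, and trial t of category c adds

    snr_multiplier * amp(t) * p_c

to the ongoing noise, where amp(t) equals ``amp_sensory`` throughout the
stimulus period and ``amp_sensory * exp(-(t - t_offset)/tau)`` during the
delay.  Visual and spatial topographies are constructed to be more similar
to each other (default cosine 0.6) than either is to the verbal topography
(default cosine 0.0), which is what drives the expected confusability
structure downstream.  No lead-field or blink modeling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft

from .exceptions import ConfigurationError

CATEGORIES: tuple[str, str, str] = ("visual", "spatial", "verbal")
N_STIMULI_PER_CATEGORY = 16
N_BLOCKS = 8

__all__ = [
    "CATEGORIES",
    "SessionConfig",
    "SignalModel",
    "SubjectSpec",
    "SubjectData",
    "schedule_session",
    "make_patterns",
    "pink_noise",
    "synthesize_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SessionConfig:
    """Timing and counting parameters of one experimental session.

    Durations are in milliseconds; ``fs_raw_hz`` is the synthesis rate of
    the continuous record (downsampling happens in preprocessing).
    """

    n_trials_per_category: int = 128
    iti_range_ms: tuple[int, int] = (800, 1200)
    iti_step_ms: int = 50
    sensory_ms: int = 1000
    delay_ms: int = 2000
    probe_ms: int = 1000
    response_ms: int = 2000
    probe_match_prob: float = 0.5
    n_channels: int = 64
    fs_raw_hz: float = 1000.0

    def __post_init__(self) -> None:
        lo, hi = self.iti_range_ms
        if self.n_trials_per_category < 1:
            raise ConfigurationError("n_trials_per_category must be >= 1")
        if self.iti_step_ms <= 0 or (hi - lo) % self.iti_step_ms != 0 or hi < lo:
            raise ConfigurationError(
                f"ITI range {self.iti_range_ms} not divisible by step {self.iti_step_ms}"
            )
        for name in ("sensory_ms", "delay_ms", "probe_ms", "response_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0.0 <= self.probe_match_prob <= 1.0:
            raise ConfigurationError("probe_match_prob must be in [0, 1]")
        if self.n_channels < 3:
            raise ConfigurationError("n_channels must be >= 3 (three topographies)")
        if self.fs_raw_hz <= 0:
            raise ConfigurationError("fs_raw_hz must be > 0")

    @property
    def n_trials_total(self) -> int:
        return 3 * self.n_trials_per_category

    @property
    def trial_span_ms(self) -> int:
        """Stimulus onset to end of the response window."""
        return self.sensory_ms + self.delay_ms + self.probe_ms + self.response_ms

    @property
    def iti_values_ms(self) -> np.ndarray:
        lo, hi = self.iti_range_ms
        return np.arange(lo, hi + self.iti_step_ms, self.iti_step_ms)


@dataclass(frozen=True)
class SignalModel:
    """Forward-model parameters for the planted category signals.

    amp_sensory
        Peak topography amplitude in microvolts while the stimulus is on
        screen.
    delay_decay_tau_ms
        Time constant of the exponential amplitude decay after stimulus
        offset; the pattern therefore persists attenuated into the delay.
    noise_pink_exponent, noise_sd
        Background noise is 1/f^exponent with per-channel standard
        deviation ``noise_sd`` microvolts.
    subject_snr_sd
        Log-normal spread of the between-subject SNR multiplier.
    artifact_rate, artifact_amp
        Probability that a trial receives a high-amplitude square pulse on
        a random channel subset, and its amplitude in microvolts.
    rotate_at_offset
        If True, the delay period uses a second, independent set of
        topographies (the representation "rotates" at stimulus offset);
        used to probe temporal-generalization contracts.
    """

    pattern_similarity_vs: float = 0.6
    pattern_similarity_other: float = 0.0
    amp_sensory: float = 18.0
    delay_decay_tau_ms: float = 600.0
    noise_pink_exponent: float = 1.0
    noise_sd: float = 20.0
    subject_snr_sd: float = 0.5
    artifact_rate: float = 0.05
    artifact_amp: float = 200.0
    artifact_width_ms: float = 100.0
    rotate_at_offset: bool = False
    temporal_profile: str = "phasic"
    delay_gain: float = 0.5

    def __post_init__(self) -> None:
        for name in ("pattern_similarity_vs", "pattern_similarity_other"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [-1, 1]")
        if self.amp_sensory < 0:
            raise ConfigurationError("amp_sensory must be >= 0")
        if self.delay_decay_tau_ms <= 0:
            raise ConfigurationError("delay_decay_tau_ms must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigurationError("artifact_rate must be in [0, 1]")
        if self.subject_snr_sd < 0:
            raise ConfigurationError("subject_snr_sd must be >= 0")
        if self.temporal_profile not in ("phasic", "sustained"):
            raise ConfigurationError("temporal_profile must be 'phasic' or 'sustained'")
        if not 0.0 <= self.delay_gain <= 1.0:
            raise ConfigurationError("delay_gain must be in [0, 1]")


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated participant."""

    subject_id: str
    age_months: int = 115
    snr_multiplier: float = 1.0
    behavioral_accuracy: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 <= self.behavioral_accuracy <= 1.0:
            raise ConfigurationError("behavioral_accuracy must be in [0, 1]")
        if self.snr_multiplier <= 0:
            raise ConfigurationError("snr_multiplier must be > 0")


@dataclass
class SubjectData:
    """Continuous recording + schedule for one subject."""

    subject: SubjectSpec
    data: np.ndarray  # channels x samples, float32, microvolts
    fs_hz: float
    trials: pd.DataFrame
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]


def schedule_session(cfg: SessionConfig, seed: int) -> pd.DataFrame:
    """Draw one session's trial schedule.

    Categories are randomly intermixed (no blocking), each category gets
    exactly ``round(probe_match_prob * n)`` probe-match trials, stimulus
    ids 1..16 are used as evenly as possible within each category, and
    inter-trial intervals are drawn uniformly from the permitted jitter
    grid.  Trials are partitioned in temporal order into 8 equal blocks
    (self-timed break points).
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_trials_per_category
    n_total = cfg.n_trials_total

    category = rng.permutation(np.repeat(np.array(CATEGORIES, dtype=object), n))

    # exact probe balance and near-balanced stimulus usage, per category
    probe_match = np.zeros(n_total, dtype=bool)
    stimulus_id = np.zeros(n_total, dtype=int)
    n_match = round(cfg.probe_match_prob * n)
    for cat in CATEGORIES:
        idx = np.flatnonzero(category == cat)
        flags = np.zeros(n, dtype=bool)
        flags[:n_match] = True
        probe_match[idx] = rng.permutation(flags)
        ids = np.resize(np.arange(1, N_STIMULI_PER_CATEGORY + 1), n)
        stimulus_id[idx] = rng.permutation(ids)

    itis = rng.choice(cfg.iti_values_ms, size=n_total, replace=True)
    onset_ms = np.cumsum(itis) + np.arange(n_total) * cfg.trial_span_ms

    block = 1 + (N_BLOCKS * np.arange(n_total)) // n_total

    return pd.DataFrame(
        {
            "trial_index": np.arange(n_total),
            "block": block.astype(int),
            "category": category,
            "stimulus_id": stimulus_id,
            "probe_match": probe_match,
            "iti_ms": itis.astype(float),
            "onset_ms": onset_ms.astype(float),
            "response": pd.array([pd.NA] * n_total, dtype="string"),
            "correct": pd.array([pd.NA] * n_total, dtype="boolean"),
        }
    )


def make_patterns(
    n_channels: int,
    similarity_vs: float,
    similarity_other: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Construct three unit-norm channel topographies with exact cosines.

    The requested Gram matrix ``[[1, a, b], [a, 1, b], [b, b, 1]]``
    (a = visual-spatial cosine, b = verbal-to-either cosine) is factored
    by symmetric eigendecomposition and mapped onto a random orthonormal
    3-frame in channel space, so realized pairwise cosines equal the
    request to machine precision rather than being sampled and checked.

    Returns an array of shape (3, n_channels), rows ordered as
    ``CATEGORIES``.
    """
    a, b = float(similarity_vs), float(similarity_other)
    gram = np.array([[1.0, a, b], [a, 1.0, b], [b, b, 1.0]])
    w, v = np.linalg.eigh(gram)
    if np.min(w) < -1e-9:
        raise ConfigurationError(
            f"infeasible similarity triple (vs={a}, other={b}): Gram matrix "
            "is not positive semidefinite"
        )
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))  # gram = factor @ factor.T
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    basis, _ = np.linalg.qr(rng.standard_normal((n_channels, 3)))
    return factor @ basis.T


def pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    exponent: float,
    sd: float,
    block: int = 8,
) -> np.ndarray:
    """1/f^exponent noise, independently per channel, scaled to ``sd``.

    Generated by shaping the spectrum of white noise; channels are
    processed in blocks to bound peak memory at full session length.
    """
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    if sd == 0 or n_samples == 0:
        out[:] = 0.0
        return out
    n_fft = fft.next_fast_len(n_samples)  # pad, shape, truncate
    freqs = np.fft.rfftfreq(n_fft)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    for start in range(0, n_channels, block):
        stop = min(start + block, n_channels)
        white = rng.standard_normal((stop - start, n_fft))
        shaped = fft.irfft(fft.rfft(white, axis=1) * scale, n=n_fft, axis=1)[:, :n_samples]
        shaped /= shaped.std(axis=1, keepdims=True)
        out[start:stop] = (sd * shaped).astype(np.float32)
    return out


def _raised_cosine(t_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    """Unit-amplitude raised-cosine bump of total support ``width_ms``."""
    x = np.zeros_like(t_ms)
    m = np.abs(t_ms - center_ms) < width_ms / 2.0
    x[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t_ms[m] - center_ms) / width_ms))
    return x


# phasic-kernel geometry (ms): a late-sensory positive deflection followed by
# a train of opposite-polarity delay-period reactivations whose amplitudes
# decay with delay_decay_tau_ms.  The timing was chosen so that, after the
# canonical zero-phase 1-40 Hz bandpass, the time-averaged voltage is strong
# in the Sensory window, attenuated (opposite polarity) in the Delay window,
# and near zero in the pre-stimulus Baseline window: activity within ~300 ms
# of stimulus onset would smear backward across the Baseline boundary under
# a zero-phase highpass, so the sensory response peaks late.
_SENSORY_BUMP_CENTER_MS = 850.0
_SENSORY_BUMP_WIDTH_MS = 300.0
_DELAY_BUMP_WIDTH_MS = 200.0
_DELAY_BUMP_SPACING_MS = 200.0
_DELAY_BUMP_START_MS = 150.0  # after stimulus offset
# anticipatory (CNV-like) reactivation straddling the delay/probe boundary;
# its filter counterpart lands in the (un-epoched) probe period, which is
# what lets the net Delay-window mean sit below the Sensory-window mean
_PREPROBE_GAIN = 0.4
_PREPROBE_WIDTH_MS = 300.0
_PREPROBE_CENTER_BEFORE_END_MS = 100.0


def _trial_envelope(cfg: SessionConfig, model: SignalModel) -> np.ndarray:
    """Per-sample signed amplitude envelope from stimulus onset through the delay.

    ``temporal_profile="phasic"`` (default) models the response as
    transient deflections: a late-sensory positive component and
    opposite-polarity delay reactivations (a CNV-like sustained
    negativity) whose amplitudes decay exponentially with
    ``delay_decay_tau_ms``.  This shape survives the canonical zero-phase
    1-40 Hz bandpass with the study's structure intact (Sensory strong,
    Delay attenuated, Baseline clean).

    ``temporal_profile="sustained"`` is the textbook time-invariant
    alternative (constant amplitude during the stimulus, exponential decay
    in the delay), useful for temporal-generalization contract checks; a
    strong highpass largely removes such a plateau, so analyses of it
    should use a permissive low band edge.
    """
    fs = cfg.fs_raw_hz
    n_sens = round(cfg.sensory_ms * fs / 1000.0)
    n_delay = round(cfg.delay_ms * fs / 1000.0)
    # phasic kernels run slightly past the delay so the anticipatory
    # pre-probe component is not truncated at the probe boundary
    n_extra = 0 if model.temporal_profile == "sustained" else round(
        _PREPROBE_WIDTH_MS / 2.0 * fs / 1000.0
    )
    n_total = n_sens + n_delay + n_extra
    t_ms = np.arange(n_total) * 1000.0 / fs
    if model.temporal_profile == "sustained":
        t_delay_ms = np.arange(n_delay) * 1000.0 / fs
        return np.concatenate(
            [
                np.full(n_sens, model.amp_sensory),
                model.amp_sensory
                * model.delay_gain
                * np.exp(-t_delay_ms / model.delay_decay_tau_ms),
            ]
        )
    env = _raised_cosine(t_ms, _SENSORY_BUMP_CENTER_MS, _SENSORY_BUMP_WIDTH_MS)
    offset = float(cfg.sensory_ms)
    center = offset + _DELAY_BUMP_START_MS
    while center <= offset + cfg.delay_ms - _DELAY_BUMP_WIDTH_MS / 2.0:
        amp = model.delay_gain * np.exp(-(center - offset) / model.delay_decay_tau_ms)
        env -= amp * _raised_cosine(t_ms, center, _DELAY_BUMP_WIDTH_MS)
        center += _DELAY_BUMP_SPACING_MS
    env += _PREPROBE_GAIN * _raised_cosine(
        t_ms, offset + cfg.delay_ms - _PREPROBE_CENTER_BEFORE_END_MS, _PREPROBE_WIDTH_MS
    )
    return model.amp_sensory * env


def synthesize_subject(
    cfg: SessionConfig,
    model: SignalModel,
    subj: SubjectSpec,
    seed: int,
) -> SubjectData:
    """Simulate one subject: schedule, continuous EEG, and responses.

    The continuous record is pink noise plus, for every trial, the
    category topography scaled by the sensory/delay envelope and the
    subject's SNR multiplier.  Artifact trials additionally receive a
    +/-``artifact_amp`` square pulse on a random channel subset, placed
    inside the epochable window so downstream rejection can see it.
    Responses are Bernoulli(``behavioral_accuracy``) correct.
    """
    ss = np.random.SeedSequence(seed)
    s_sched, s_pat, s_noise, s_trial = [np.random.default_rng(c) for c in ss.spawn(4)]

    trials = schedule_session(cfg, int(s_sched.integers(2**31)))
    patterns = make_patterns(
        cfg.n_channels, model.pattern_similarity_vs, model.pattern_similarity_other, s_pat
    )
    if model.rotate_at_offset:
        # continue the same stream: an independent random frame for the delay
        delay_patterns = make_patterns(
            cfg.n_channels, model.pattern_similarity_vs, model.pattern_similarity_other, s_pat
        )
    else:
        delay_patterns = patterns

    fs = cfg.fs_raw_hz
    tail_ms = 500.0
    total_ms = float(trials["onset_ms"].iloc[-1]) + cfg.trial_span_ms + tail_ms
    n_samples = int(np.ceil(total_ms * fs / 1000.0))

    data = pink_noise(s_noise, cfg.n_channels, n_samples, model.noise_pink_exponent, model.noise_sd)

    env = _trial_envelope(cfg, model).astype(np.float32)
    n_sens = round(cfg.sensory_ms * fs / 1000.0)
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    snr = float(subj.snr_multiplier)

    onset_samp = np.round(trials["onset_ms"].to_numpy() * fs / 1000.0).astype(int)
    for i in range(len(trials)):
        k = cat_index[trials["category"].iloc[i]]
        s0 = onset_samp[i]
        seg = slice(s0, s0 + len(env))
        if model.rotate_at_offset:
            data[:, s0 : s0 + n_sens] += (
                snr * np.outer(patterns[k], env[:n_sens])
            ).astype(np.float32)
            data[:, s0 + n_sens : s0 + len(env)] += (
                snr * np.outer(delay_patterns[k], env[n_sens:])
            ).astype(np.float32)
        else:
            data[:, seg] += (snr * np.outer(patterns[k], env)).astype(np.float32)

    # artifacts: square pulse fully inside the epochable [-300, 3000) ms window
    is_artifact = s_trial.random(len(trials)) < model.artifact_rate
    width = max(1, round(model.artifact_width_ms * fs / 1000.0))
    epoch_lo, epoch_hi = -300.0, 3000.0
    for i in np.flatnonzero(is_artifact):
        start_ms = s_trial.uniform(epoch_lo, epoch_hi - model.artifact_width_ms)
        a0 = onset_samp[i] + round(start_ms * fs / 1000.0)
        a0 = int(np.clip(a0, 0, n_samples - width))
        n_ch = int(s_trial.integers(1, max(2, cfg.n_channels // 8) + 1))
        chans = s_trial.choice(cfg.n_channels, size=n_ch, replace=False)
        sign = s_trial.choice([-1.0, 1.0])
        data[chans, a0 : a0 + width] += np.float32(sign * model.artifact_amp)
    trials["artifact_injected"] = is_artifact

    correct = s_trial.random(len(trials)) < subj.behavioral_accuracy
    match = trials["probe_match"].to_numpy(dtype=bool)
    # 'k' = "probe matched", 'd' = "probe did not match"
    key = np.where(match == correct, "k", "d")
    trials["response"] = pd.array(key, dtype="string")
    trials["correct"] = pd.array(correct, dtype="boolean")

    return SubjectData(subject=subj, data=data, fs_hz=fs, trials=trials)


def simulate_cohort(
    n_subjects: int,
    cfg: SessionConfig,
    model: SignalModel,
    age_effect: float = 0.0,
    seed: int = 0,
    age_range_months: tuple[int, int] = (84, 152),
    behavioral_accuracy: tuple[float, float] = (0.90, 0.08),
) -> list[SubjectData]:
    """Simulate ``n_subjects`` independent participants.

    SNR multipliers are drawn log-normally with spread ``subject_snr_sd``;
    ``age_effect`` optionally modulates them linearly (units: fractional
    SNR change per year of age relative to the mid-range age, 0 = the
    age-flat regime).  Ages are uniform on ``age_range_months``.  Each
    subject is synthesized from the derived seed ``seed + index`` so
    individual subjects are reproducible in isolation.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = age_range_months
    ages = rng.integers(lo, hi + 1, size=n_subjects)
    snr = np.exp(rng.normal(0.0, model.subject_snr_sd, size=n_subjects))
    if age_effect != 0.0:
        mid = 0.5 * (lo + hi)
        snr = snr * np.clip(1.0 + age_effect * (ages - mid) / 12.0, 0.05, None)
    mu, sd = behavioral_accuracy
    acc = np.clip(rng.normal(mu, sd, size=n_subjects), 0.05, 1.0)

    cohort = []
    for i in range(n_subjects):
        spec = SubjectSpec(
            subject_id=f"sub-{i + 1:03d}",
            age_months=int(ages[i]),
            snr_multiplier=float(snr[i]),
            behavioral_accuracy=float(acc[i]),
        )
        cohort.append(synthesize_subject(cfg, model, spec, seed=seed + i))
    return cohort
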