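"""Task structure and synthetic-cohort generation for a 10-day bimanual SRT study.

The task: eight spatial cues map onto the eight non-thumb fingers.  On each
trial one cue lights up and the subject presses the matching key as fast as
possible.  Sequence blocks cycle a fixed 32-item cue sequence eight times
(256 trials), starting at a random position; Random blocks use a
pseudo-random cue order with no immediate repeats.  A training day holds
nine 256-trial blocks: two Random, five adaptive Sequence blocks (response
window = previous block's mean + SD of RT, reset to 600 ms when the window
would drop below 200 ms or accuracy below 75%), then a Random probe and a
Sequence probe, both at the fixed 600 ms window.  All analyses downstream
consume only the two probe blocks.

The synthetic generator emulates the statistical structure the analyses
assume: day-linear sequence-specific RT improvement, quadratically
saturating accuracy, AR(1) coupling ("binding") of latent response plans
whose strength grows across days, geometric post-error slowing, per-key
response biases, independent motor noise, and censoring of responses slower
than the block's response window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "CANONICAL_SEQUENCE",
    "AWARENESS_KEYWORDS",
    "BlockType",
    "SequenceSpec",
    "SessionSchedule",
    "BlockSpec",
    "TrialRecord",
    "SubjectConfig",
    "canonical_sequence",
    "adaptive_window",
    "build_session",
    "simulate_subject",
    "simulate_cohort",
    "default_cohort",
    "score_questionnaire",
]

#: The fixed 32-item cue sequence used in every Sequence block (keys 1-8;
#: 1 = left pinky ... 4 = left index, 5 = right index ... 8 = right pinky).
CANONICAL_SEQUENCE: tuple[int, ...] = (
    6, 8, 5, 6, 3, 5, 4, 1, 3, 6, 8, 4, 1, 2, 7, 3,
    1, 8, 2, 7, 5, 2, 4, 5, 7, 3, 1, 6, 8, 2, 4, 7,
)

#: Keywords in the awareness questionnaire that count as naming the pattern.
AWARENESS_KEYWORDS = frozenset({"pattern", "sequence", "sequential", "order", "ordering"})

DEFAULT_WINDOW_MS = 600.0
MIN_WINDOW_MS = 200.0
MIN_WINDOW_ACCURACY = 0.75
TRIALS_PER_BLOCK = 256
N_DAYS = 10
N_KEYS = 8


class BlockType(str, Enum):
    RANDOM_TRAIN = "random_train"
    SEQUENCE_TRAIN = "sequence_train"
    RANDOM_PROBE = "random_probe"
    SEQUENCE_PROBE = "sequence_probe"

    @property
    def is_sequence(self) -> bool:
        return self in (BlockType.SEQUENCE_TRAIN, BlockType.SEQUENCE_PROBE)

    @property
    def is_probe(self) -> bool:
        return self in (BlockType.RANDOM_PROBE, BlockType.SEQUENCE_PROBE)


@dataclass(frozen=True)
class SequenceSpec:
    """A repeating cue sequence and how many times a block cycles it."""

    items: tuple[int, ...]
    repeats_per_block: int = 8

    def __post_init__(self):
        if not all(1 <= k <= N_KEYS for k in self.items):
            raise ValueError("sequence items must be keys in 1..8")
        if self.repeats_per_block < 1:
            raise ValueError("repeats_per_block must be positive")

    @property
    def trials_per_block(self) -> int:
        return len(self.items) * self.repeats_per_block

    def cues_for_block(self, start_offset: int = 0) -> np.ndarray:
        """Cue keys for one block, cycling circularly from ``start_offset``."""
        rolled = np.roll(np.asarray(self.items, dtype=np.int64), -int(start_offset) % len(self.items))
        return np.tile(rolled, self.repeats_per_block)


def canonical_sequence() -> SequenceSpec:
    """The study's 32-item sequence, cycled eight times per 256-trial block."""
    return SequenceSpec(items=CANONICAL_SEQUENCE, repeats_per_block=8)


def adaptive_window(prev_mean_rt_ms: float, prev_sd_rt_ms: float, prev_accuracy: float) -> float:
    """Response window for an adaptive Sequence block.

    The window is the previous block's mean + SD of reaction time, reset to
    the 600 ms default whenever that value falls below 200 ms or the previous
    block's accuracy falls below 75% correct.
    """
    for name, v in (("prev_mean_rt_ms", prev_mean_rt_ms),
                    ("prev_sd_rt_ms", prev_sd_rt_ms),
                    ("prev_accuracy", prev_accuracy)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if prev_sd_rt_ms < 0:
        raise ValueError("prev_sd_rt_ms must be >= 0")
    if not 0.0 <= prev_accuracy <= 1.0:
        raise ValueError("prev_accuracy must be in [0, 1]")
    window = prev_mean_rt_ms + prev_sd_rt_ms
    if window < MIN_WINDOW_MS or prev_accuracy < MIN_WINDOW_ACCURACY:
        return DEFAULT_WINDOW_MS
    return float(window)


@dataclass(frozen=True)
class BlockSpec:
    block_type: BlockType
    n_trials: int = TRIALS_PER_BLOCK
    window_policy: str = "fixed_600"  # "fixed_600" | "adaptive"
    start_offset: Optional[int] = None  # sequence blocks only


@dataclass(frozen=True)
class SessionSchedule:
    """The nine-block structure of one training day."""

    day: int
    blocks: tuple[BlockSpec, ...]


def build_session(day: int, rng: Optional[np.random.Generator] = None) -> SessionSchedule:
    """Canonical daily schedule: 2 random, 5 adaptive sequence, 2 probes.

    When ``rng`` is given, each sequence block receives a uniformly random
    start offset into the 32-item sequence (the block still contains eight
    complete circular cycles); otherwise offsets default to 0.
    """
    if not 1 <= day <= N_DAYS:
        raise ValueError(f"day must be in 1..{N_DAYS}, got {day}")

    def offset() -> int:
        return int(rng.integers(len(CANONICAL_SEQUENCE))) if rng is not None else 0

    blocks = [BlockSpec(BlockType.RANDOM_TRAIN), BlockSpec(BlockType.RANDOM_TRAIN)]
    blocks += [
        BlockSpec(BlockType.SEQUENCE_TRAIN, window_policy="adaptive", start_offset=offset())
        for _ in range(5)
    ]
    blocks.append(BlockSpec(BlockType.RANDOM_PROBE))
    blocks.append(BlockSpec(BlockType.SEQUENCE_PROBE, start_offset=offset()))
    return SessionSchedule(day=day, blocks=tuple(blocks))


@dataclass(frozen=True)
class TrialRecord:
    """One cued keypress with its RT, accuracy and block context.

    ``rt_ms`` is ``None`` when no response landed inside the block's
    response window (an omission); omissions are always incorrect.
    """

    subject: str
    day: int
    block_index: int
    block_type: BlockType
    trial_index: int
    cue_key: int
    pressed_key: Optional[int]
    rt_ms: Optional[float]
    correct: bool
    response_window_ms: float

    def __post_init__(self):
        if self.rt_ms is None and self.correct:
            raise ValueError("a missing RT cannot be a correct trial")
        expected = (
            self.pressed_key == self.cue_key
            and self.rt_ms is not None
            and self.rt_ms <= self.response_window_ms
        )
        if self.correct != expected:
            raise ValueError(
                f"correct flag inconsistent with press/RT/window on trial "
                f"{self.subject}/d{self.day}/b{self.block_index}/t{self.trial_index}"
            )


@dataclass(frozen=True)
class SubjectConfig:
    """Generative parameters of one synthetic subject.

    The latent response plan in sequence blocks follows an AR(1) process
    with day-specific coupling ``binding_alpha_by_day`` around a mean of
    ``base_rt_ms - rt_learning_slope_ms_per_day * day + key_bias_ms[cue]``;
    in random blocks the coupling is 0 and the day-linear improvement does
    not apply (the speedup is sequence-specific).  Errors are cue-independent
    Bernoulli draws with day-specific rate; each error delays the latent
    state of the following ``pes_decay_lags`` trials by a geometrically
    decaying amount whose lag-1 value is the day's PES magnitude
    (``pes_delay_by_day`` if given, else the constant ``pes_state_delay_ms``),
    in sequence blocks only.  Observed RT = latent plan + independent motor
    noise, censored to missing above the block's response window.
    """

    subject: str
    base_rt_ms: float = 420.0
    rt_learning_slope_ms_per_day: float = 14.0
    key_bias_ms: tuple[float, ...] = (0.0,) * N_KEYS
    binding_alpha_by_day: tuple[float, ...] = (0.0,) * N_DAYS
    binding_sd_ms: float = 25.0
    motor_sd_ms: float = 30.0
    pes_state_delay_ms: float = 15.0
    pes_decay_lags: int = 4
    pes_delay_by_day: Optional[tuple[float, ...]] = None
    error_rate_by_day: tuple[float, ...] = (0.1,) * N_DAYS
    seed: int = 0

    def __post_init__(self):
        if len(self.key_bias_ms) != N_KEYS:
            raise ValueError("key_bias_ms must have 8 entries")
        if len(self.binding_alpha_by_day) != N_DAYS or len(self.error_rate_by_day) != N_DAYS:
            raise ValueError("per-day schedules must have 10 entries")
        if not all(0.0 <= a < 1.0 for a in self.binding_alpha_by_day):
            raise ValueError("binding alphas must lie in [0, 1)")
        if not all(0.0 <= e <= 1.0 for e in self.error_rate_by_day):
            raise ValueError("error rates must lie in [0, 1]")
        if self.binding_sd_ms < 0 or self.motor_sd_ms < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.pes_delay_by_day is not None and len(self.pes_delay_by_day) != N_DAYS:
            raise ValueError("pes_delay_by_day must have 10 entries")

    def pes_for_day(self, day: int) -> float:
        if self.pes_delay_by_day is not None:
            return self.pes_delay_by_day[day - 1]
        return self.pes_state_delay_ms


def _random_cues(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random cue order on 1..8 with immediate repeats removed."""
    cues = np.empty(n, dtype=np.int64)
    cues[0] = rng.integers(1, N_KEYS + 1)
    for i in range(1, n):
        step = rng.integers(1, N_KEYS)  # 1..7 keys away, mod 8
        cues[i] = (cues[i - 1] - 1 + step) % N_KEYS + 1
    return cues


def _ar1_deviations(n: int, alpha: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean AR(1) draw: d_t = alpha * d_{t-1} + N(0, sd)."""
    eps = rng.normal(0.0, sd, size=n)
    if alpha == 0.0 or sd == 0.0:
        return eps
    d0 = rng.normal(0.0, sd / math.sqrt(1.0 - alpha * alpha))
    out, _ = lfilter([1.0], [1.0, -alpha], eps, zi=np.array([alpha * d0]))
    return out


def _simulate_block(
    config: SubjectConfig,
    day: int,
    block_index: int,
    spec: BlockSpec,
    window_ms: float,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    n = spec.n_trials
    if spec.block_type.is_sequence:
        cues = canonical_sequence().cues_for_block(spec.start_offset or 0)[:n]
        alpha = config.binding_alpha_by_day[day - 1]
        day_gain = config.rt_learning_slope_ms_per_day * day
        pes = config.pes_for_day(day)
    else:
        cues = _random_cues(n, rng)
        alpha, day_gain, pes = 0.0, 0.0, 0.0

    mean = config.base_rt_ms - day_gain + np.asarray(config.key_bias_ms)[cues - 1]

    errors = rng.random(n) < config.error_rate_by_day[day - 1]
    # post-error slowing: each error delays the latent state of the next
    # pes_decay_lags trials, halving per lag
    delay = np.zeros(n)
    if pes != 0.0:
        kernel = pes * 0.5 ** np.arange(config.pes_decay_lags)
        conv = np.convolve(errors.astype(float), kernel)
        delay[1:] = conv[: n - 1]

    latent = mean + delay + _ar1_deviations(n, alpha, config.binding_sd_ms, rng)
    rt = latent + rng.normal(0.0, config.motor_sd_ms, size=n)
    np.maximum(rt, 1.0, out=rt)

    presses = cues.copy()
    if errors.any():
        # a uniformly random non-cue key on error trials
        wrong = (cues[errors] - 1 + rng.integers(1, N_KEYS, size=int(errors.sum()))) % N_KEYS + 1
        presses[errors] = wrong

    records = []
    for t in range(n):
        censored = rt[t] > window_ms
        records.append(
            TrialRecord(
                subject=config.subject,
                day=day,
                block_index=block_index,
                block_type=spec.block_type,
                trial_index=t + 1,
                cue_key=int(cues[t]),
                pressed_key=None if censored else int(presses[t]),
                rt_ms=None if censored else float(rt[t]),
                correct=bool(not censored and not errors[t]),
                response_window_ms=float(window_ms),
            )
        )
    return records


def simulate_subject(config: SubjectConfig) -> list[TrialRecord]:
    """Generate the full 10-day, 9-blocks-per-day trial table of one subject.

    Deterministic given ``config.seed``.  Adaptive windows are computed from
    the previous block's recorded (non-missing) RTs and accuracy exactly as
    in the task; probe and random-training blocks stay at 600 ms.
    """
    rng = np.random.default_rng(config.seed)
    records: list[TrialRecord] = []
    for day in range(1, N_DAYS + 1):
        schedule = build_session(day, rng=rng)
        prev_stats: Optional[tuple[float, float, float]] = None
        for b, spec in enumerate(schedule.blocks, start=1):
            if spec.window_policy == "adaptive" and prev_stats is not None:
                window = adaptive_window(*prev_stats)
            else:
                window = DEFAULT_WINDOW_MS
            block = _simulate_block(config, day, b, spec, window, rng)
            rts = np.array([r.rt_ms for r in block if r.rt_ms is not None])
            acc = float(np.mean([r.correct for r in block]))
            if rts.size >= 2:
                prev_stats = (float(rts.mean()), float(rts.std(ddof=1)), acc)
            else:
                prev_stats = (DEFAULT_WINDOW_MS, 0.0, acc)
            records.extend(block)
    return records


def simulate_cohort(configs: Sequence[SubjectConfig]) -> list[TrialRecord]:
    records: list[TrialRecord] = []
    for cfg in configs:
        records.extend(simulate_subject(cfg))
    return records


def _sigmoid_schedule(asymptote: float, midpoint: float, rate: float) -> tuple[float, ...]:
    days = np.arange(1, N_DAYS + 1)
    return tuple(asymptote / (1.0 + np.exp(-rate * (days - midpoint))))


def default_cohort(n_subjects: int = 23, seed: int = 0) -> list[SubjectConfig]:
    """The default synthetic study cohort (23 learners, 10 days).

    Calibrated qualitatively to the study conditions: sequence-specific RT
    improves roughly linearly (~0.35 z/day at the cohort level), accuracy
    saturates quadratically from ~76% to ~94% by the end of week one,
    binding strength follows a sigmoid to ~0.85 asymptoting after day ~5
    (yielding chunk estimates that grow and asymptote around 6-7), and PES
    grows with binding toward ~15 ms.  Between-subject heterogeneity enters
    through learning slopes, binding asymptotes, key biases and noise.
    """
    rng = np.random.default_rng(seed)
    days = np.arange(1, N_DAYS + 1)
    cohort = []
    for i in range(n_subjects):
        slope = float(np.clip(rng.normal(14.0, 5.0), 2.0, 28.0))
        alpha_max = float(np.clip(rng.normal(0.85, 0.05), 0.5, 0.95))
        midpoint = float(rng.normal(3.5, 0.7))
        alphas = tuple(
            float(a) for a in alpha_max / (1.0 + np.exp(-1.1 * (days - midpoint)))
        )
        # accuracy: quadratic rise reaching a ~94% plateau after day ~5,
        # constant for the second week (error = 1 - acc)
        acc_end = float(np.clip(rng.normal(0.94, 0.015), 0.88, 0.985))
        acc_start = float(np.clip(rng.normal(0.76, 0.03), 0.60, acc_end - 0.10))
        vertex = float(rng.uniform(5.0, 7.0))
        acc = acc_end - (acc_end - acc_start) * np.clip((vertex - days) / (vertex - 1.0), 0.0, None) ** 2
        err = tuple(float(e) for e in np.minimum.accumulate(1.0 - acc))
        pes_max = float(np.clip(rng.normal(15.0, 3.0), 5.0, 25.0))
        pes_by_day = tuple(p * pes_max / alpha_max for p in alphas)
        cohort.append(
            SubjectConfig(
                subject=f"S{i + 1:02d}",
                base_rt_ms=float(rng.normal(420.0, 25.0)),
                rt_learning_slope_ms_per_day=slope,
                key_bias_ms=tuple(float(b) for b in rng.normal(0.0, 12.0, size=N_KEYS)),
                binding_alpha_by_day=alphas,
                binding_sd_ms=25.0,
                motor_sd_ms=30.0,
                pes_state_delay_ms=pes_max,
                pes_decay_lags=4,
                pes_delay_by_day=pes_by_day,
                error_rate_by_day=err,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return cohort


def score_questionnaire(
    q1_different: bool,
    q2_keywords: Sequence[str],
    q3_always_present: bool,
    q4_reproduced_4_items: bool,
) -> int:
    """Score the daily awareness questionnaire on the 0-3 scale.

    0: nothing noticed; 1: something noticed but not named as a pattern;
    2: named the pattern but believed it always present; 3: knew it was
    occasional and reproduced >= 4 consecutive items.  A score of 2 marks
    the implicit-to-explicit transition.
    """
    if not q1_different:
        return 0
    if not any(w.strip().lower() in AWARENESS_KEYWORDS for w in q2_keywords):
        return 1
    if q3_always_present:
        return 2
    return 3 if q4_reproduced_4_items else 2
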