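"""Stimulus schedules for the three sleep-session paradigms.

social : 16 auditory trials of 8 s (vocal V / nonvocal N in a fixed
    pseudo-random order) each preceded by a silent baseline jittered
    uniformly on [10, 12] s.
hand   : habituation-and-novelty-detection; 25 spoken-sentence trials of
    8 s, each preceded by a 10 s silent baseline, grouped into five
    5-trial epochs Fam1, Fam2, Fam3, Nov, ReFam.
fc     : functional connectivity; alternating social (70 s) / nonsocial
    (60 s) audio blocks, the pair repeated twice, 260 s total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed pseudo-random condition order of the social paradigm.
SOCIAL_ORDER = tuple("NVVNVNNVNVVNVNNV")

HAND_PHASES = ("Fam1", "Fam2", "Fam3", "Nov", "ReFam")


@dataclass(frozen=True)
class Trial:
    onset: float  # s
    duration: float  # s
    condition: str
    phase: str | None = None

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class StimulusSchedule:
    paradigm: str
    trials: tuple[Trial, ...]
    total_duration: float

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for tr in self.trials:
            if tr.onset < 0 or tr.duration <= 0:
                raise ValueError("trial onsets must be >= 0 and durations > 0")
            if tr.onset < prev_end:
                raise ValueError("trials overlap or are out of order")
            prev_end = tr.offset

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trials])

    def conditions(self) -> list[str]:
        return [t.condition for t in self.trials]

    def phases(self) -> list[str | None]:
        return [t.phase for t in self.trials]


def hand_phase(trial_index: int) -> str:
    """Five-trial epoch label for a 0-based trial index (0-24)."""
    if not 0 <= trial_index < 25:
        raise ValueError("trial index out of range for the 25-trial design")
    return HAND_PHASES[trial_index // 5]


def build_schedule(
    paradigm: str,
    *,
    seed: int = 0,
    trial_duration: float = 8.0,
    jitter_range: tuple[float, float] = (10.0, 12.0),
    hand_baseline: float = 10.0,
    fc_block_durations: tuple[float, float] = (70.0, 60.0),
    condition_order: tuple[str, ...] | None = None,
) -> StimulusSchedule:
    """Build the stimulus schedule for one paradigm.

    The seed drives only the social paradigm's baseline jitter; hand and
    fc schedules are fully deterministic.
    """
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    rng = np.random.default_rng(seed)

    if paradigm == "social":
        order = condition_order or SOCIAL_ORDER
        if set(order) - {"N", "V"}:
            raise ValueError("social conditions must be drawn from {N, V}")
        trials = []
        t = 0.0
        for cond in order:
            t += rng.uniform(*jitter_range)  # preceding silent baseline
            trials.append(Trial(t, trial_duration, cond))
            t += trial_duration
        t += rng.uniform(*jitter_range)  # trailing baseline
        return StimulusSchedule("social", tuple(trials), t)

    if paradigm == "hand":
        trials = []
        t = 0.0
        for i in range(25):
            t += hand_baseline
            trials.append(Trial(t, trial_duration, "sentence", hand_phase(i)))
            t += trial_duration
        return StimulusSchedule("hand", tuple(trials), t + hand_baseline)

    if paradigm == "fc":
        soc, nonsoc = fc_block_durations
        if soc <= 0 or nonsoc <= 0:
            raise ValueError("block durations must be positive")
        trials = []
        t = 0.0
        for _ in range(2):  # sequence repeated twice
            trials.append(Trial(t, soc, "social"))
            t += soc
            trials.append(Trial(t, nonsoc, "nonsocial"))
            t += nonsoc
        return StimulusSchedule("fc", tuple(trials), t)

    raise ValueError(f"unknown paradigm {paradigm!r}")
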