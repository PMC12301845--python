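"""The reward-related coffee-tea (RCT) task.

A hierarchical sequence task: on each trial a cue instructs the subject to
prepare coffee or tea, followed by five decision steps (first ingredient,
stir, second ingredient, stir, serve) and a feedback step.  The rules --
cream goes only with coffee, sugar only with tea, water is required for both,
the step-4 ingredient complements the step-2 choice, the spoon is always
selected for stirring, and the prepared drink is served at step 6 -- yield
exactly four distinct action sequences.  One drink is rewarded (fixed per
subject), so two sequences are rewarded and two are not.  Six steps by four
sequences define the 24 task states used throughout the analyses.

Canonical state ordering (used wherever RDMs are indexed): sequences in the
order rewarded/water-first, rewarded/water-second, non-rewarded/water-first,
non-rewarded/water-second; steps 1-6 within each sequence, so
``index = 6 * sequence_position + (step - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACTIONS = (
    "add-coffee",
    "add-tea",
    "add-cream",
    "add-water",
    "stir",
    "add-sugar",
    "serve-coffee",
    "serve-tea",
)
CUES = ("make-coffee", "make-tea")
DRINKS = ("coffee", "tea")
SEQUENCE_LABELS = ("Rw1", "Rw2", "nRw1", "nRw2")

#: exclusive ingredient per drink (cream with coffee, sugar with tea)
EXCLUSIVE_INGREDIENT = {"coffee": "add-cream", "tea": "add-sugar"}

#: the three displayed items at each decision step (step 2-6)
STEP_OPTIONS = {
    2: ("cream", "sugar", "water"),
    3: ("fork", "spoon", "knife"),
    4: ("sugar", "water", "cream"),
    5: ("spoon", "knife", "fork"),
    6: ("prepared-coffee", "prepared-tea", "orange-juice"),
}

N_SEQUENCES = 4
N_STEPS = 6
N_STATES = N_SEQUENCES * N_STEPS

#: seven equally spaced inter-stimulus jitters, 2.5-4.5 s, mean exactly 3.5 s
JITTER_LEVELS = tuple(2.5 + k / 3.0 for k in range(7))
STIM_DURATION = 1.0
TRIALS_PER_RUN = 18
N_RUNS = 4
STEPS_PER_TRIAL = 7  # 6 task states + feedback

TR = 1.72
N_VOLUMES = 362
#: task onset: the scan is synchronized to begin at the sixth volume
RUN_START_OFFSET = 5 * TR


class ConfigurationError(ValueError):
    """Invalid task configuration (e.g. unknown reward task)."""


@dataclass(frozen=True)
class SequenceDef:
    """One of the four action sequences."""

    label: str
    drink: str  # coffee | tea
    water_first: bool
    rewarded: bool

    @property
    def first_ingredient(self) -> str:
        return "add-water" if self.water_first else EXCLUSIVE_INGREDIENT[self.drink]

    @property
    def second_ingredient(self) -> str:
        return EXCLUSIVE_INGREDIENT[self.drink] if self.water_first else "add-water"

    @property
    def cue(self) -> str:
        return f"make-{self.drink}"

    def actions(self) -> tuple[str, ...]:
        """Correct action at steps 1..6 (step 1 carries the upcoming
        first-ingredient target; the cue itself requires no response)."""
        return (
            self.first_ingredient,
            self.first_ingredient,
            "stir",
            self.second_ingredient,
            "stir",
            f"serve-{self.drink}",
        )


@dataclass(frozen=True)
class TaskState:
    """A (sequence, step) pair with its canonical index 0..23."""

    sequence_id: str
    step: int
    index: int

    def __post_init__(self):
        if not 1 <= self.step <= N_STEPS:
            raise ValueError(f"step must be 1..{N_STEPS}, got {self.step}")


@dataclass(frozen=True)
class TaskSpec:
    """Full task definition for one reward assignment."""

    reward_task: str
    sequences: tuple[SequenceDef, ...]
    actions: tuple[str, ...] = ACTIONS
    cues: tuple[str, ...] = CUES
    step_options: dict = field(default_factory=lambda: dict(STEP_OPTIONS))

    def states(self) -> list[TaskState]:
        return [
            TaskState(seq.label, step, 6 * i + step - 1)
            for i, seq in enumerate(self.sequences)
            for step in range(1, N_STEPS + 1)
        ]

    def state(self, sequence_id: str, step: int) -> TaskState:
        labels = [s.label for s in self.sequences]
        i = labels.index(sequence_id)
        return TaskState(sequence_id, step, 6 * i + step - 1)

    def state_labels(self) -> list[str]:
        return [f"{s.sequence_id}_s{s.step}" for s in self.states()]

    def sequence(self, sequence_id: str) -> SequenceDef:
        for seq in self.sequences:
            if seq.label == sequence_id:
                return seq
        raise KeyError(sequence_id)


def build_task_spec(reward_task: str) -> TaskSpec:
    """Build the task for a given rewarded drink (``"coffee"`` or ``"tea"``).

    The four sequences are ordered canonically: the two rewarded-drink
    sequences first (water-first, then water-second), then the two
    non-rewarded ones.
    """
    if reward_task not in DRINKS:
        raise ConfigurationError(
            f"reward_task must be one of {DRINKS}, got {reward_task!r}"
        )
    other = "tea" if reward_task == "coffee" else "coffee"
    sequences = (
        SequenceDef("Rw1", reward_task, True, True),
        SequenceDef("Rw2", reward_task, False, True),
        SequenceDef("nRw1", other, True, False),
        SequenceDef("nRw2", other, False, False),
    )
    return TaskSpec(reward_task=reward_task, sequences=sequences)


def correct_action(spec: TaskSpec, state: TaskState) -> str:
    """The single correct action for a task state.

    Pure function of the task rules: step 1 returns the sequence's
    first-ingredient target (the cue-consistent upcoming action), steps 3 and
    5 always stir, step 4 is the complementary ingredient to step 2, and step
    6 serves the prepared drink.
    """
    return spec.sequence(state.sequence_id).actions()[state.step - 1]


def generate_session(spec: TaskSpec, seed: int) -> pd.DataFrame:
    """Generate a full 4-run x 18-trial session design (the event table).

    Sequence identities are balanced: each of the four sequences occurs 18
    times over the session (36 rewarded / 36 non-rewarded trials), allocated
    5/5/4/4 per run on a rotating pattern.  Each run's 126 inter-stimulus
    intervals are 18 complete shuffled replicates of the 7-level jitter set,
    so the mean ISI is exactly 3.5 s in every run.  Step 7 (feedback) is
    carried in the table but has no state index.

    Returns a DataFrame with columns ``run, trial, step, onset, duration,
    trial_type, state_index, sequence, condition, jitter``; onsets are in
    seconds from the start of each run's acquisition (task start offset by
    the five discarded volumes).
    """
    rng = np.random.default_rng(seed)
    base_counts = [5, 5, 4, 4]
    rows = []
    for run in range(1, N_RUNS + 1):
        counts = np.roll(base_counts, run - 1)
        seq_ids = np.repeat(np.arange(N_SEQUENCES), counts)
        rng.shuffle(seq_ids)
        jitters = np.tile(JITTER_LEVELS, TRIALS_PER_RUN)
        rng.shuffle(jitters)
        onset = RUN_START_OFFSET
        j = 0
        for trial, si in enumerate(seq_ids, start=1):
            seq = spec.sequences[si]
            for step in range(1, STEPS_PER_TRIAL + 1):
                feedback = step > N_STEPS
                rows.append(
                    {
                        "run": run,
                        "trial": trial,
                        "step": step,
                        "onset": onset,
                        "duration": STIM_DURATION,
                        "trial_type": "feedback"
                        if feedback
                        else f"{seq.label}_s{step}",
                        "state_index": pd.NA if feedback else 6 * si + step - 1,
                        "sequence": seq.label,
                        "condition": "rewarded" if seq.rewarded else "non-rewarded",
                        "jitter": jitters[j],
                    }
                )
                onset += STIM_DURATION + jitters[j]
                j += 1
    events = pd.DataFrame(rows)
    events["state_index"] = events["state_index"].astype("Int64")
    return events


def events_to_tsv(events: pd.DataFrame, path) -> None:
    """Serialize an event table to a BIDS-style events TSV."""
    cols = ["onset", "duration", "trial_type", "run", "condition"]
    events[cols].to_csv(path, sep="\t", index=False)
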