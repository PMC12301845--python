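"""Goal-unit Elman network for the coffee-tea task.

Architecture: 8 input units (6 previous-action units plus the two drink
cues), a 15-unit sigmoid hidden layer with Elman recurrence (the hidden
activations are copied to a context layer that feeds the hidden layer on the
next step), an 8-unit softmax action-output head, and 4 goal units with
softmax output that serve both as inputs to the hidden layer and as an
output head.  Training is plain stochastic gradient descent with
backpropagation through the six steps of one sequence per episode; the loss
is the sum over steps of the action and goal cross-entropies.

After training the weights are frozen and reward is simulated purely by
clamping the executing sequence's goal input at 1 (rewarded) or 0
(non-rewarded); the hidden-layer geometry under those clamps yields the
model RDMs.

Two accuracy conventions are provided (see ``action_accuracy``):

``forced``
    state-conditional accuracy: each step's argmax action is scored against
    the correct action with the *correct* previous action as input, so every
    decision is evaluated from the true task state.  This is the convention
    under which the goal-0 ensemble lands near 80 % correct: without the
    goal unit the water-first/water-second branch is genuinely ambiguous, so
    roughly one first-ingredient decision in two is unrecoverable, while the
    stirring and serving decisions survive.

``free``
    free-running accuracy: the network's own argmax action is fed back as
    the next input.  A wrong branch choice then propagates, so this is the
    stricter criterion; trained networks reach 100 % with the goal unit at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rctrsa.rdm import RDM, euclidean_rdm
from rctrsa.task import (
    ACTIONS,
    DRINKS,
    N_STEPS,
    SequenceDef,
    TaskSpec,
    build_task_spec,
)

N_INPUT = 8
N_GOAL = 4
N_HIDDEN = 15
N_ACTION = 8

#: input vocabulary: the six non-serve actions plus the two cues
INPUT_UNITS = (
    "add-coffee",
    "add-tea",
    "add-cream",
    "add-water",
    "stir",
    "add-sugar",
    "make-coffee",
    "make-tea",
)
_INPUT_INDEX = {name: i for i, name in enumerate(INPUT_UNITS)}
_ACTION_INDEX = {name: i for i, name in enumerate(ACTIONS)}

_WEIGHT_SHAPES = {
    "W_xh": (N_INPUT, N_HIDDEN),
    "W_gh": (N_GOAL, N_HIDDEN),
    "W_ch": (N_HIDDEN, N_HIDDEN),
    "W_ha": (N_HIDDEN, N_ACTION),
    "W_hg": (N_HIDDEN, N_GOAL),
}
_BIAS_SHAPES = {"b_h": (N_HIDDEN,), "b_a": (N_ACTION,), "b_g": (N_GOAL,)}


class TrainingError(RuntimeError):
    """Raised when training diverges (NaN loss)."""


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``learning_rate`` is the one free parameter the study leaves open; the
    default 0.5 brings every network to criterion well inside 5000 episodes.
    """

    episodes: int = 5000
    learning_rate: float = 0.5
    init_sd: float = 0.1
    seed: int = 0
    n_networks: int = 25
    check_every: int = 100  # convergence-probe period, in episodes

    def __post_init__(self):
        if self.episodes < 1:
            raise ValueError("episodes must be >= 1")
        if self.init_sd <= 0:
            raise ValueError("init_sd must be positive")


@dataclass
class NetworkParams:
    W_xh: np.ndarray
    W_gh: np.ndarray
    W_ch: np.ndarray
    W_ha: np.ndarray
    W_hg: np.ndarray
    b_h: np.ndarray
    b_a: np.ndarray
    b_g: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in (*_WEIGHT_SHAPES, *_BIAS_SHAPES)}

    def copy(self) -> "NetworkParams":
        return NetworkParams(**{k: v.copy() for k, v in self.as_dict().items()})

    def check_finite(self) -> None:
        for k, v in self.as_dict().items():
            if not np.all(np.isfinite(v)):
                raise TrainingError(f"non-finite values in {k}")


@dataclass
class EpisodeTrace:
    """Per-step record of one simulated sequence."""

    sequence_id: str
    goal_level: float
    mode: str
    inputs: np.ndarray  # 6 x 8
    goal_inputs: np.ndarray  # 6 x 4
    hidden: np.ndarray  # 6 x 15
    action_probs: np.ndarray  # 6 x 8
    goal_probs: np.ndarray  # 6 x 4
    selected: np.ndarray  # 6 argmax action indices
    correct: np.ndarray  # 6 bools vs correct_action


@dataclass
class ModelRDMPair:
    """Ensemble-average model RDMs under the two reward assignments."""

    rdm_coffee_rewarded: RDM
    rdm_tea_rewarded: RDM
    n_networks_averaged: int

    def for_reward_task(self, reward_task: str) -> RDM:
        if reward_task == "coffee":
            return self.rdm_coffee_rewarded
        if reward_task == "tea":
            return self.rdm_tea_rewarded
        raise KeyError(reward_task)


def init_network(cfg: TrainConfig, rng: np.random.Generator | None = None) -> NetworkParams:
    """All weights i.i.d. normal(0, init_sd); biases zero."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    arrays = {k: rng.normal(0.0, cfg.init_sd, s) for k, s in _WEIGHT_SHAPES.items()}
    arrays.update({k: np.zeros(s) for k, s in _BIAS_SHAPES.items()})
    return NetworkParams(**arrays)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def forward_step(
    params: NetworkParams,
    input8: np.ndarray,
    goal4: np.ndarray,
    context15: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One step: hidden sigmoid, then softmax action and goal heads.

    The returned hidden vector is the context for the next step.
    """
    pre = (
        input8 @ params.W_xh
        + goal4 @ params.W_gh
        + context15 @ params.W_ch
        + params.b_h
    )
    hidden = 1.0 / (1.0 + np.exp(-pre))
    action_probs = _softmax(hidden @ params.W_ha + params.b_a)
    goal_probs = _softmax(hidden @ params.W_hg + params.b_g)
    for v in (hidden, action_probs, goal_probs):
        if not np.all(np.isfinite(v)):
            raise TrainingError("non-finite activation in forward_step")
    return hidden, action_probs, goal_probs


def input_vector(name: str | None) -> np.ndarray:
    """One-hot over the 8 input units; serve actions (no input unit) and
    ``None`` map to the zero vector."""
    x = np.zeros(N_INPUT)
    if name is not None and name in _INPUT_INDEX:
        x[_INPUT_INDEX[name]] = 1.0
    return x


def episode_io(spec: TaskSpec, seq_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Teacher-forced inputs, action targets and goal one-hot for a sequence.

    Step 1's input is the drink cue; steps 2-6 receive the previous correct
    action.  The action target at step 1 is the sequence's first-ingredient
    action (the cue demands no response, but the trained head already
    commits to the upcoming ingredient there).
    """
    seq = spec.sequences[seq_index]
    actions = seq.actions()
    xs = np.zeros((N_STEPS, N_INPUT))
    xs[0] = input_vector(seq.cue)
    for t in range(1, N_STEPS):
        xs[t] = input_vector(actions[t - 1])
    targets = np.array([_ACTION_INDEX[a] for a in actions])
    goal = np.zeros(N_GOAL)
    goal[seq_index] = 1.0
    return xs, targets, goal


def loss_and_gradients(
    params: NetworkParams,
    xs: np.ndarray,
    goal_input: np.ndarray,
    action_targets: np.ndarray,
    goal_target: int,
) -> tuple[float, dict[str, np.ndarray]]:
    """Summed cross-entropy loss and its BPTT gradients for one episode.

    The goal input is clamped for all six steps; the goal head's target is
    the same goal unit at every step.  Gradients flow through the context
    recurrence across all steps.
    """
    n_steps = xs.shape[0]
    hs = np.empty((n_steps, N_HIDDEN))
    d_as = np.empty((n_steps, N_ACTION))
    d_gs = np.empty((n_steps, N_GOAL))
    contexts = np.zeros((n_steps + 1, N_HIDDEN))
    loss = 0.0
    for t in range(n_steps):
        h, pa, pg = forward_step(params, xs[t], goal_input, contexts[t])
        hs[t] = h
        contexts[t + 1] = h
        loss -= np.log(pa[action_targets[t]]) + np.log(pg[goal_target])
        d_as[t] = pa
        d_as[t, action_targets[t]] -= 1.0
        d_gs[t] = pg
        d_gs[t, goal_target] -= 1.0
    if not np.isfinite(loss):
        raise TrainingError("loss is not finite")

    grads = {k: np.zeros(s) for k, s in {**_WEIGHT_SHAPES, **_BIAS_SHAPES}.items()}
    d_next = np.zeros(N_HIDDEN)  # dL/dh_t carried back through the context path
    for t in range(n_steps - 1, -1, -1):
        h = hs[t]
        grads["W_ha"] += np.outer(h, d_as[t])
        grads["b_a"] += d_as[t]
        grads["W_hg"] += np.outer(h, d_gs[t])
        grads["b_g"] += d_gs[t]
        dh = d_as[t] @ params.W_ha.T + d_gs[t] @ params.W_hg.T + d_next
        dz = dh * h * (1.0 - h)
        grads["W_xh"] += np.outer(xs[t], dz)
        grads["W_gh"] += np.outer(goal_input, dz)
        grads["W_ch"] += np.outer(contexts[t], dz)
        grads["b_h"] += dz
        d_next = dz @ params.W_ch.T
    return loss, grads


def episode_loss(
    params: NetworkParams,
    xs: np.ndarray,
    goal_input: np.ndarray,
    action_targets: np.ndarray,
    goal_target: int,
) -> float:
    """Loss only (used as the finite-difference oracle's target)."""
    loss = 0.0
    context = np.zeros(N_HIDDEN)
    for t in range(xs.shape[0]):
        h, pa, pg = forward_step(params, xs[t], goal_input, context)
        loss -= np.log(pa[action_targets[t]]) + np.log(pg[goal_target])
        context = h
    return loss


def train(
    cfg: TrainConfig, spec: TaskSpec | None = None
) -> tuple[NetworkParams, dict]:
    """Train one network; returns the parameters and a training log.

    One episode = one full six-step sequence drawn uniformly from the four,
    teacher-forced, with the sequence's goal input clamped at 1; parameters
    are updated after every episode.  The log records the per-episode loss
    and, probed every ``cfg.check_every`` episodes, the first episode count
    at which the network free-runs all four sequences without error at goal
    level 1 (``converged_at``; None if never reached).
    """
    if spec is None:
        spec = build_task_spec("coffee")
    rng = np.random.default_rng(cfg.seed)
    params = init_network(cfg, rng)
    episodes_io = [episode_io(spec, i) for i in range(len(spec.sequences))]
    losses = np.empty(cfg.episodes)
    converged_at = None
    for ep in range(cfg.episodes):
        si = int(rng.integers(len(spec.sequences)))
        xs, targets, goal = episodes_io[si]
        try:
            loss, grads = loss_and_gradients(params, xs, goal, targets, si)
        except TrainingError as err:
            raise TrainingError(f"training diverged at episode {ep + 1}") from err
        losses[ep] = loss
        for k, g in grads.items():
            arr = getattr(params, k)
            arr -= cfg.learning_rate * g
        if converged_at is None and (ep + 1) % cfg.check_every == 0:
            if action_accuracy(params, spec, 1.0, mode="free", steps="all") == 1.0:
                converged_at = ep + 1
    return params, {"loss": losses, "converged_at": converged_at, "config": cfg}


def train_ensemble(
    cfg: TrainConfig, spec: TaskSpec | None = None
) -> tuple[list[NetworkParams], list[dict]]:
    """Train ``cfg.n_networks`` independently initialized networks.

    Network ``i`` uses seed ``cfg.seed + i``.
    """
    ensemble, logs = [], []
    for i in range(cfg.n_networks):
        cfg_i = TrainConfig(
            episodes=cfg.episodes,
            learning_rate=cfg.learning_rate,
            init_sd=cfg.init_sd,
            seed=cfg.seed + i,
            n_networks=1,
            check_every=cfg.check_every,
        )
        params, log = train(cfg_i, spec)
        ensemble.append(params)
        logs.append(log)
    return ensemble, logs


def simulate_sequence(
    params: NetworkParams,
    spec: TaskSpec,
    sequence_id: str,
    goal_level: float,
    mode: str = "forced",
) -> EpisodeTrace:
    """Run one sequence with the executing sequence's goal input clamped.

    The sequence's goal input is held at ``goal_level`` for all six steps
    (the other three goal inputs stay at 0).  In ``forced`` mode the inputs
    are the correct previous actions; in ``free`` mode the network's own
    argmax action is fed back (serve actions have no input unit and map to a
    zero input).  No learning occurs.
    """
    if mode not in ("free", "forced"):
        raise ValueError(f"mode must be 'free' or 'forced', got {mode!r}")
    params.check_finite()
    seq_index = [s.label for s in spec.sequences].index(sequence_id)
    seq = spec.sequences[seq_index]
    actions = seq.actions()
    goal = np.zeros(N_GOAL)
    goal[seq_index] = goal_level

    xs = np.empty((N_STEPS, N_INPUT))
    hidden = np.empty((N_STEPS, N_HIDDEN))
    a_probs = np.empty((N_STEPS, N_ACTION))
    g_probs = np.empty((N_STEPS, N_GOAL))
    selected = np.empty(N_STEPS, dtype=int)
    correct = np.empty(N_STEPS, dtype=bool)

    x = input_vector(seq.cue)
    context = np.zeros(N_HIDDEN)
    for t in range(N_STEPS):
        xs[t] = x
        h, pa, pg = forward_step(params, x, goal, context)
        hidden[t], a_probs[t], g_probs[t] = h, pa, pg
        selected[t] = int(pa.argmax())
        correct[t] = ACTIONS[selected[t]] == actions[t]
        context = h
        if t < N_STEPS - 1:
            nxt = actions[t] if mode == "forced" else ACTIONS[selected[t]]
            x = input_vector(nxt)
    return EpisodeTrace(
        sequence_id=sequence_id,
        goal_level=goal_level,
        mode=mode,
        inputs=xs,
        goal_inputs=np.tile(goal, (N_STEPS, 1)),
        hidden=hidden,
        action_probs=a_probs,
        goal_probs=g_probs,
        selected=selected,
        correct=correct,
    )


def action_accuracy(
    params: NetworkParams,
    spec: TaskSpec,
    goal_level: float,
    mode: str = "forced",
    steps: str = "decision",
) -> float:
    """Fraction of correct argmax actions over the four sequences.

    ``steps="decision"`` scores the five decision steps 2-6 (the steps on
    which the task demands an action); ``steps="all"`` additionally scores
    the step-1 first-ingredient commitment.
    """
    sl = slice(1, None) if steps == "decision" else slice(None)
    flags = [
        simulate_sequence(params, spec, seq.label, goal_level, mode).correct[sl]
        for seq in spec.sequences
    ]
    return float(np.mean(flags))


def ensemble_accuracy(
    ensemble: list[NetworkParams],
    spec: TaskSpec,
    goal_level: float,
    mode: str = "forced",
    steps: str = "decision",
) -> float:
    return float(
        np.mean([action_accuracy(p, spec, goal_level, mode, steps) for p in ensemble])
    )


def _hidden_states_for_assignment(
    params: NetworkParams, spec: TaskSpec, reward_task: str, mode: str
) -> np.ndarray:
    """24 x 15 hidden states in the canonical order of ``reward_task``.

    Every sequence is executed with its own goal input clamped at 1 if its
    drink is rewarded under the assignment and at 0 otherwise; rows are then
    ordered rewarded/water-first, rewarded/water-second, non-rewarded/
    water-first, non-rewarded/water-second.
    """
    other = "tea" if reward_task == "coffee" else "coffee"
    canonical: list[tuple[str, bool]] = [
        (reward_task, True),
        (reward_task, False),
        (other, True),
        (other, False),
    ]
    by_key = {(s.drink, s.water_first): s for s in spec.sequences}
    blocks = []
    for drink, water_first in canonical:
        seq = by_key[(drink, water_first)]
        level = 1.0 if drink == reward_task else 0.0
        trace = simulate_sequence(params, spec, seq.label, level, mode=mode)
        blocks.append(trace.hidden)
    return np.vstack(blocks)


def build_model_rdms(
    ensemble: list[NetworkParams],
    spec: TaskSpec | None = None,
    mode: str = "forced",
) -> ModelRDMPair:
    """Ensemble-average 24x24 hidden-state Euclidean RDMs for both reward
    assignments (coffee rewarded, tea rewarded).

    Per network: run all four sequences with goal input 1 for the rewarded
    drink and 0 otherwise, collect the 24 hidden vectors (teacher-forced, so
    they correspond to the canonical 24 task states), compute the Euclidean
    distance matrix, then average element-wise across networks.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    if spec is None:
        spec = build_task_spec("coffee")
    rdms = {}
    for reward_task in DRINKS:
        acc = np.zeros((24, 24))
        for params in ensemble:
            H = _hidden_states_for_assignment(params, spec, reward_task, mode)
            acc += euclidean_rdm(H).matrix
        labels = build_task_spec(reward_task).state_labels()
        rdms[reward_task] = RDM(acc / len(ensemble), labels, metric="plain-euclidean")
    return ModelRDMPair(
        rdm_coffee_rewarded=rdms["coffee"],
        rdm_tea_rewarded=rdms["tea"],
        n_networks_averaged=len(ensemble),
    )


def save_ensemble(path, ensemble: list[NetworkParams], cfg: TrainConfig) -> None:
    """Archive trained weights (one NPZ, arrays named ``net{i}_{weight}``)."""
    arrays = {
        f"net{i}_{k}": v
        for i, p in enumerate(ensemble)
        for k, v in p.as_dict().items()
    }
    arrays["n_networks"] = np.array(len(ensemble))
    arrays["config"] = np.array(
        [cfg.episodes, cfg.learning_rate, cfg.init_sd, cfg.seed]
    )
    np.savez(path, **arrays)


def load_ensemble(path) -> list[NetworkParams]:
    with np.load(path) as npz:
        n = int(npz["n_networks"])
        return [
            NetworkParams(
                **{k: npz[f"net{i}_{k}"] for k in (*_WEIGHT_SHAPES, *_BIAS_SHAPES)}
            )
            for i in range(n)
        ]
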