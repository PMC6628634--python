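"""The Michigan Decision-Making (MDM) gamble task.

The task is a series of 126 binary choices between two-outcome gambles
``(x, y, p)``: outcome ``x`` with probability ``p``, outcome ``y``
otherwise.  Outcome values span [-200, 200] points and probabilities come
from five levels {.05, .30, .50, .70, .95}.  Trials are Gain-Only (all
four outcomes >= 0), Loss-Only (all <= 0) or Mixed-Outcome (each gamble
pairs a gain with a loss), 42 of each, randomly intermixed.  A designed
subset of 17 trials presents both gambles at the same probability level;
14 of those are single-domain and isolate value discrimination from
probability weighting, which is what the optimality (delta-EV) analysis
uses.

The published task instrument does not include the concrete gamble pairs,
so :func:`generate_task` synthesises a trial set satisfying every
structural constraint above, deterministically from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional

import numpy as np
import pandas as pd

from .cpt import expected_value

__all__ = [
    "Gamble",
    "Trial",
    "TaskSpec",
    "TaskConfig",
    "TRIAL_TYPES",
    "PROB_LEVELS",
    "generate_task",
    "validate_task",
    "equal_probability_subset",
    "task_to_frame",
    "task_from_frame",
    "write_task_csv",
    "read_task_csv",
]

TRIAL_TYPES = ("GAIN_ONLY", "LOSS_ONLY", "MIXED")
PROB_LEVELS = (0.05, 0.30, 0.50, 0.70, 0.95)


class Gamble(NamedTuple):
    """Two-outcome gamble: ``x`` with probability ``p``, ``y`` with ``1-p``.

    By convention ``x`` is the more extreme outcome (``|x| >= |y|``); in
    mixed gambles ``x`` is the gain and ``y`` the loss.
    """

    x: int
    y: int
    p: float


@dataclass(frozen=True)
class Trial:
    trial_id: int
    trial_type: str
    gamble_a: Gamble
    gamble_b: Gamble


@dataclass
class TaskSpec:
    """An ordered trial set plus provenance metadata."""

    trials: List[Trial]
    seed: int
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaskSpec) and self.trials == other.trials \
            and self.seed == other.seed


@dataclass(frozen=True)
class TaskConfig:
    """Structural constraints for task generation.

    Defaults reproduce the published task structure; counts are
    configurable but must stay mutually consistent
    (``n_trials == 3 * n_per_type``, equal-probability counts split as
    gain/loss/mixed summing to ``n_equal_prob``).
    """

    n_trials: int = 126
    n_per_type: int = 42
    n_equal_prob: int = 17
    n_equal_prob_gain: int = 7
    n_equal_prob_loss: int = 7
    n_equal_prob_mixed: int = 3
    value_max: int = 200
    value_step: int = 5
    prob_levels: tuple = PROB_LEVELS

    def validate(self) -> None:
        if self.n_trials != 3 * self.n_per_type:
            raise ValueError(
                "unsatisfiable config: n_trials must equal 3 * n_per_type "
                f"({self.n_trials} != 3*{self.n_per_type})")
        if self.n_equal_prob_gain + self.n_equal_prob_loss + self.n_equal_prob_mixed \
                != self.n_equal_prob:
            raise ValueError(
                "unsatisfiable config: per-type equal-probability counts must sum "
                f"to n_equal_prob={self.n_equal_prob}")
        for name in ("n_equal_prob_gain", "n_equal_prob_loss", "n_equal_prob_mixed"):
            if getattr(self, name) > self.n_per_type:
                raise ValueError(
                    f"unsatisfiable config: {name} exceeds n_per_type={self.n_per_type}")
        if self.value_max <= 0 or self.value_step <= 0 or self.value_max % self.value_step:
            raise ValueError("unsatisfiable config: value grid must be positive and "
                             "value_step must divide value_max")

    @property
    def n_equal_prob_single_domain(self) -> int:
        return self.n_equal_prob_gain + self.n_equal_prob_loss


def _draw_gamble(rng: np.random.Generator, cfg: TaskConfig, trial_type: str,
                 p: float) -> Gamble:
    grid = np.arange(cfg.value_step, cfg.value_max + 1, cfg.value_step)
    if trial_type == "MIXED":
        # gain carried with probability p; loss magnitude <= gain magnitude
        x = int(rng.choice(grid))
        y = -int(rng.choice(np.arange(cfg.value_step, x + 1, cfg.value_step)))
        return Gamble(x, y, p)
    x = int(rng.choice(grid))
    y = int(rng.choice(np.arange(0, x + 1, cfg.value_step)))
    if trial_type == "LOSS_ONLY":
        x, y = -x, -y
    return Gamble(x, y, p)


def _draw_trial(rng: np.random.Generator, cfg: TaskConfig, trial_type: str,
                equal_prob: bool) -> tuple:
    levels = np.asarray(cfg.prob_levels)
    while True:
        if equal_prob:
            pa = pb = float(rng.choice(levels))
        else:
            pa, pb = (float(v) for v in rng.choice(levels, size=2, replace=False))
        a = _draw_gamble(rng, cfg, trial_type, pa)
        b = _draw_gamble(rng, cfg, trial_type, pb)
        if a == b:
            continue
        # reject EV ties so the optimal choice is always well defined
        if abs(expected_value(a) - expected_value(b)) < 1e-9:
            continue
        return trial_type, a, b


def generate_task(seed: int, config: Optional[TaskConfig] = None) -> TaskSpec:
    """Generate a task specification satisfying all structural invariants.

    The same seed and config always produce the identical trial table.
    Trial order is a seeded uniform shuffle of the full set.  The summed
    optimal delta-EV over the equal-probability single-domain trials (the
    ceiling of the optimality analysis) is recorded in ``metadata``.
    """
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError("seed must be a non-negative integer")
    cfg = config or TaskConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    eq_counts = {"GAIN_ONLY": cfg.n_equal_prob_gain,
                 "LOSS_ONLY": cfg.n_equal_prob_loss,
                 "MIXED": cfg.n_equal_prob_mixed}
    drawn = []
    for ttype in TRIAL_TYPES:
        n_eq = eq_counts[ttype]
        for i in range(cfg.n_per_type):
            drawn.append(_draw_trial(rng, cfg, ttype, equal_prob=i < n_eq))
    order = rng.permutation(len(drawn))
    trials = [Trial(trial_id=i + 1, trial_type=drawn[j][0],
                    gamble_a=drawn[j][1], gamble_b=drawn[j][2])
              for i, j in enumerate(order)]

    task = TaskSpec(trials=trials, seed=int(seed))
    subset = equal_probability_subset(task, single_domain_only=True)
    optimal = sum(abs(expected_value(t.gamble_a) - expected_value(t.gamble_b))
                  for t in subset)
    task.metadata = {
        "seed": int(seed),
        "n_trials": len(trials),
        "optimal_delta_ev_sum": float(optimal),
        "optimal_delta_ev_mean": float(optimal / max(len(subset), 1)),
        "n_equal_prob_single_domain": len(subset),
    }
    return task


def _check_gamble(g: Gamble, cfg: TaskConfig, label: str) -> List[str]:
    issues = []
    if g.p not in cfg.prob_levels:
        issues.append(f"{label}: probability {g.p} not in allowed levels {cfg.prob_levels}")
    if not (-cfg.value_max <= g.x <= cfg.value_max and -cfg.value_max <= g.y <= cfg.value_max):
        issues.append(f"{label}: outcome values outside [-{cfg.value_max}, {cfg.value_max}]")
    if abs(g.x) < abs(g.y):
        issues.append(f"{label}: |x| < |y| (x must be the more extreme outcome)")
    if g.x == 0 and g.y == 0:
        issues.append(f"{label}: degenerate all-zero gamble")
    return issues


def validate_task(task: TaskSpec, config: Optional[TaskConfig] = None) -> List[str]:
    """Check every structural invariant; returns a list of violations.

    An empty list means the task conforms.  Malformed trials are reported,
    never raised.
    """
    cfg = config or TaskConfig()
    report: List[str] = []
    counts = {t: 0 for t in TRIAL_TYPES}
    n_eq = 0
    n_eq_single = 0
    for t in task.trials:
        tag = f"trial {t.trial_id}"
        if t.trial_type not in TRIAL_TYPES:
            report.append(f"{tag}: unknown trial type {t.trial_type!r}")
            continue
        counts[t.trial_type] += 1
        for label, g in (("gamble_a", t.gamble_a), ("gamble_b", t.gamble_b)):
            report.extend(f"{tag} {label[-1]}: {msg}" for msg in _check_gamble(g, cfg, label))
            xs = (g.x, g.y)
            if t.trial_type == "GAIN_ONLY" and any(v < 0 for v in xs):
                report.append(f"{tag}: negative outcome in GAIN_ONLY {label}")
            elif t.trial_type == "LOSS_ONLY" and any(v > 0 for v in xs):
                report.append(f"{tag}: positive outcome in LOSS_ONLY {label}")
            elif t.trial_type == "MIXED" and g.x * g.y >= 0:
                report.append(f"{tag}: MIXED {label} outcomes do not have opposite signs")
        if t.gamble_a == t.gamble_b:
            report.append(f"{tag}: identical gambles")
        if t.gamble_a.p == t.gamble_b.p:
            n_eq += 1
            if t.trial_type != "MIXED":
                n_eq_single += 1
    if len(task.trials) != cfg.n_trials:
        report.append(f"trial count {len(task.trials)} != {cfg.n_trials}")
    for ttype in TRIAL_TYPES:
        if counts[ttype] != cfg.n_per_type:
            report.append(f"{ttype} count {counts[ttype]} != {cfg.n_per_type}")
    if n_eq != cfg.n_equal_prob:
        report.append(f"equal-probability trial count {n_eq} != {cfg.n_equal_prob}")
    if n_eq_single != cfg.n_equal_prob_single_domain:
        report.append(
            f"single-domain equal-probability count {n_eq_single} != "
            f"{cfg.n_equal_prob_single_domain}")
    ids = [t.trial_id for t in task.trials]
    if len(set(ids)) != len(ids):
        report.append("duplicate trial ids")
    return report


def equal_probability_subset(task: TaskSpec, single_domain_only: bool = False) -> List[Trial]:
    """Trials where both gambles carry the same probability.

    With ``single_domain_only`` the mixed-outcome trials are removed,
    leaving the subset on which choice optimality reflects value
    discrimination alone (probability weighting is held constant and loss
    aversion cannot act).
    """
    out = [t for t in task.trials if t.gamble_a.p == t.gamble_b.p]
    if single_domain_only:
        out = [t for t in out if t.trial_type != "MIXED"]
    return out


# ---------------------------------------------------------------------------
# serialization: one CSV row per trial

_COLUMNS = ["trial_id", "trial_type", "ax", "ay", "ap", "bx", "by", "bp"]


def task_to_frame(task: TaskSpec) -> pd.DataFrame:
    rows = [(t.trial_id, t.trial_type,
             t.gamble_a.x, t.gamble_a.y, t.gamble_a.p,
             t.gamble_b.x, t.gamble_b.y, t.gamble_b.p)
            for t in task.trials]
    return pd.DataFrame(rows, columns=_COLUMNS)


def task_from_frame(df: pd.DataFrame, seed: int = -1,
                    metadata: Optional[dict] = None) -> TaskSpec:
    trials = [Trial(trial_id=int(r.trial_id), trial_type=str(r.trial_type),
                    gamble_a=Gamble(int(r.ax), int(r.ay), float(r.ap)),
                    gamble_b=Gamble(int(r.bx), int(r.by), float(r.bp)))
              for r in df.itertuples(index=False)]
    return TaskSpec(trials=trials, seed=seed, metadata=metadata or {})


def write_task_csv(task: TaskSpec, path) -> None:
    df = task_to_frame(task)
    df["ap"] = df["ap"].map(lambda v: f"{v:.2f}")
    df["bp"] = df["bp"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, index=False)


def read_task_csv(path) -> TaskSpec:
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return task_from_frame(df)
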