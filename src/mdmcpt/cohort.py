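"""Synthetic cohorts of CPT decision-makers.

Simulated subjects carry latent parameter quartets drawn log-normally
around group-level means, make Bernoulli choices on each trial according
to the logistic choice rule, and optionally time out on a small fraction
of trials (a timed-out trial records no choice and costs 5 points).  The
default cohort mirrors the clinical study design: four groups — healthy
controls (HC, n=20), generalized anxiety disorder (GAD, n=15), social
anxiety disorder (SAD, n=14) and obsessive-compulsive disorder (OCD,
n=10) — identical in every parameter except value discrimination, where
the OCD group mean sits below the HC mean.  Optional per-subject clinical
severity scores (PHQ-9, GAD-7, BDI, WSAS) are drawn from truncated
normals with configurable correlation to a named model parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cpt import CPTParams, choice_probability
from .task import TaskSpec, read_task_csv, write_task_csv

__all__ = [
    "GroupSpec",
    "ChoiceDataset",
    "default_groups",
    "draw_subject_params",
    "simulate_choices",
    "simulate_cohort",
    "TIMEOUT_PENALTY",
]

#: points lost on a timed-out trial
TIMEOUT_PENALTY = -5

PARAM_NAMES = ("alpha", "lam", "gamma", "delta")
CLINICAL_SCALES = ("PHQ9", "GAD7", "BDI", "WSAS")

# group-level clinical score means/SDs (defaults for the synthetic cohort)
_CLINICAL_DEFAULTS = {
    "HC":  {"PHQ9": (1.3, 2.2), "GAD7": (0.9, 1.4), "BDI": (2.7, 4.9), "WSAS": (0.1, 0.7)},
    "GAD": {"PHQ9": (10.2, 6.6), "GAD7": (14.5, 6.0), "BDI": (22.1, 13.5), "WSAS": (19.1, 11.0)},
    "SAD": {"PHQ9": (10.1, 6.2), "GAD7": (11.8, 5.1), "BDI": (16.4, 8.5), "WSAS": (20.4, 8.1)},
    "OCD": {"PHQ9": (11.6, 8.7), "GAD7": (11.5, 6.6), "BDI": (22.8, 13.9), "WSAS": (22.1, 9.4)},
}


@dataclass(frozen=True)
class GroupSpec:
    """Generating distribution for one participant group."""

    label: str
    n_subjects: int
    param_means: CPTParams = CPTParams(alpha=0.85, lam=1.25, gamma=0.7, delta=0.9)
    param_sds: Dict[str, float] = field(
        default_factory=lambda: {n: 0.15 for n in PARAM_NAMES})
    clinical_means: Optional[Dict[str, float]] = None
    clinical_sds: Optional[Dict[str, float]] = None
    #: (parameter name, scale name, Pearson r) — correlation induced between
    #: the subject's log-parameter deviation and the named clinical scale
    param_clinical_corr: Optional[Tuple[str, str, float]] = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(sd < 0 for sd in self.param_sds.values()):
            raise ValueError("parameter dispersions must be non-negative")
        if self.param_clinical_corr is not None:
            _, _, r = self.param_clinical_corr
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlation must lie in [-1, 1]")


def default_groups(with_clinical: bool = True) -> List[GroupSpec]:
    """The four-group study-shaped cohort.

    All groups share (lam, gamma, delta); the OCD group's value
    discrimination mean (0.55) sits below the HC mean (0.85), the one
    group difference treated as real in the generating model.
    """
    sizes = {"HC": 20, "GAD": 15, "SAD": 14, "OCD": 10}
    groups = []
    for label, n in sizes.items():
        alpha = 0.55 if label == "OCD" else 0.85
        clin = _CLINICAL_DEFAULTS[label] if with_clinical else None
        groups.append(GroupSpec(
            label=label, n_subjects=n,
            param_means=CPTParams(alpha=alpha, lam=1.25, gamma=0.7, delta=0.9),
            clinical_means={k: v[0] for k, v in clin.items()} if clin else None,
            clinical_sds={k: v[1] for k, v in clin.items()} if clin else None,
        ))
    return groups


@dataclass
class ChoiceDataset:
    """Long-format choice records with optional simulation ground truth."""

    task: TaskSpec
    records: pd.DataFrame  # subject_id, group, trial_id, choice, timeout
    true_params: Optional[pd.DataFrame] = None  # subject_id, group, alpha..delta
    clinical_scores: Optional[pd.DataFrame] = None

    def validate(self) -> None:
        dup = self.records.duplicated(subset=["subject_id", "trial_id"])
        if dup.any():
            raise ValueError("duplicate (subject, trial) records")
        known = {t.trial_id for t in self.task.trials}
        bad = set(self.records["trial_id"]) - known
        if bad:
            raise ValueError(f"records reference unknown trial ids: {sorted(bad)[:5]}")

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_task_csv(self.task, path / "task.csv")
        self.records.to_csv(path / "choices.csv", index=False)
        sidecar = {"task_metadata": self.task.metadata}
        if self.true_params is not None:
            sidecar["true_params"] = self.true_params.to_dict(orient="records")
        if self.clinical_scores is not None:
            self.clinical_scores.to_csv(path / "clinical.csv", index=False)
        (path / "truth.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_dir(cls, path) -> "ChoiceDataset":
        path = Path(path)
        task = read_task_csv(path / "task.csv")
        records = pd.read_csv(path / "choices.csv",
                              dtype={"choice": "string"}, keep_default_na=False,
                              na_values=[""])
        records["timeout"] = records["timeout"].astype(bool)
        true_params = None
        sidecar_path = path / "truth.json"
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            task.metadata = sidecar.get("task_metadata", {})
            if "true_params" in sidecar:
                true_params = pd.DataFrame(sidecar["true_params"])
        clinical = None
        if (path / "clinical.csv").exists():
            clinical = pd.read_csv(path / "clinical.csv")
        return cls(task=task, records=records, true_params=true_params,
                   clinical_scores=clinical)


def draw_subject_params(group: GroupSpec, seed: int) -> List[CPTParams]:
    """Draw per-subject parameter quartets for one group.

    Each parameter is log-normal: ``log theta_i ~ N(log mean, sd^2)`` with
    the dispersion given on the log scale, so positivity is guaranteed and
    zero dispersion collapses every subject onto the group mean.
    """
    rng = np.random.default_rng(seed)
    means = group.param_means
    draws = []
    for _ in range(group.n_subjects):
        vals = {}
        for name in PARAM_NAMES:
            mu = np.log(getattr(means, name))
            sd = group.param_sds.get(name, 0.0)
            vals[name] = float(np.exp(rng.normal(mu, sd)))
        draws.append(CPTParams(**vals, k=means.k))
    return draws


def simulate_choices(task: TaskSpec, params_by_subject: Dict[str, CPTParams],
                     seed: int, timeout_rate: float = 0.0,
                     group_by_subject: Optional[Dict[str, str]] = None) -> ChoiceDataset:
    """Simulate Bernoulli choices for each subject on every trial.

    Each non-timeout choice is 'A' with the probability the logistic rule
    assigns to that trial's utility difference under the subject's
    parameters; timeouts occur independently at ``timeout_rate`` and carry
    no choice.
    """
    from .model import task_arrays, trial_utilities  # local import; no cycle at runtime

    rng = np.random.default_rng(seed)
    arrays = task_arrays(task)
    trial_ids = arrays["trial_id"]
    rows = []
    truth_rows = []
    for sid, params in params_by_subject.items():
        group = (group_by_subject or {}).get(sid, "NA")
        f_a, f_b = trial_utilities(arrays, params)
        p_a = choice_probability(f_a, f_b, params)
        chose_a = rng.random(len(trial_ids)) < p_a
        timeout = rng.random(len(trial_ids)) < timeout_rate
        for tid, a, to in zip(trial_ids, chose_a, timeout):
            rows.append((sid, group, int(tid),
                         None if to else ("A" if a else "B"), bool(to)))
        truth_rows.append({"subject_id": sid, "group": group, **params.to_dict()})
    records = pd.DataFrame(rows, columns=["subject_id", "group", "trial_id",
                                          "choice", "timeout"])
    return ChoiceDataset(task=task, records=records,
                         true_params=pd.DataFrame(truth_rows))


def _draw_clinical(group: GroupSpec, z_by_param: Dict[str, np.ndarray],
                   rng: np.random.Generator) -> Optional[pd.DataFrame]:
    if group.clinical_means is None:
        return None
    n = group.n_subjects
    corr_param, corr_scale, corr_r = group.param_clinical_corr or (None, None, 0.0)
    cols = {}
    for scale, mean in group.clinical_means.items():
        sd = (group.clinical_sds or {}).get(scale, 1.0)
        z = rng.standard_normal(n)
        if scale == corr_scale and corr_param in z_by_param:
            zp = z_by_param[corr_param]
            z = corr_r * zp + np.sqrt(1.0 - corr_r ** 2) * z
        # truncation at 0: severity scales cannot be negative
        cols[scale] = np.clip(mean + sd * z, 0.0, None)
    return pd.DataFrame(cols)


def simulate_cohort(groups: Sequence[GroupSpec], task: TaskSpec, seed: int,
                    timeout_rate: float = 0.0) -> ChoiceDataset:
    """Concatenate per-group simulations with disjoint subject ids.

    Per-group seeds are derived deterministically from ``seed``.  Clinical
    scores, when a group configures them, are drawn with the requested
    parameter-scale correlation induced through the subject's standardised
    log-parameter deviation.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2 * len(groups))]
    datasets = []
    clinical_frames = []
    for gi, group in enumerate(groups):
        param_seed, choice_seed = child_seeds[2 * gi], child_seeds[2 * gi + 1]
        params = draw_subject_params(group, param_seed)
        sids = [f"{group.label}_{i + 1:03d}" for i in range(group.n_subjects)]
        ds = simulate_choices(task, dict(zip(sids, params)), seed=choice_seed,
                              timeout_rate=timeout_rate,
                              group_by_subject={s: group.label for s in sids})
        datasets.append(ds)
        # standardised log-parameter deviations drive clinical correlations
        z_by_param = {}
        for name in PARAM_NAMES:
            sd = group.param_sds.get(name, 0.0)
            if sd > 0:
                logs = np.log([getattr(p, name) for p in params])
                z_by_param[name] = (logs - np.log(getattr(group.param_means, name))) / sd
        clin = _draw_clinical(group, z_by_param,
                              np.random.default_rng(choice_seed + 1))
        if clin is not None:
            clin.insert(0, "subject_id", sids)
            clin.insert(1, "group", group.label)
            clinical_frames.append(clin)
    records = pd.concat([d.records for d in datasets], ignore_index=True)
    truth = pd.concat([d.true_params for d in datasets], ignore_index=True)
    clinical = pd.concat(clinical_frames, ignore_index=True) if clinical_frames else None
    out = ChoiceDataset(task=task, records=records, true_params=truth,
                        clinical_scores=clinical)
    out.validate()
    return out
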