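"""Likelihood-based estimation of CPT parameters from binary choices.

The primary workflow is two-stage: each subject's (alpha, lam, gamma,
delta) is estimated by maximum likelihood under the logistic choice rule
(choice sensitivity k fixed at 1), and group inference is then run on the
per-subject estimates.  A penalized hierarchical mode approximates a
nonlinear mixed-effects fit: subject log-parameters are shrunk toward
group-level fixed effects under a Gaussian random-effect penalty whose
standard deviations are profiled on a coarse grid, and group contrasts
are expressed as additive dummy offsets on the log-parameter scale with
Wald-type tests.

Estimation is over log-parameters inside box bounds, with a fixed set of
multi-starts (identity, canonical prospect-theory values, grid corners,
seeded jitter) and a gradient-free local search per start, so fits are
deterministic given the data and the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .cpt import CPTParams, PROB_CLIP_EPS
from .task import TaskSpec, task_to_frame
from .cohort import ChoiceDataset

__all__ = [
    "FitSettings",
    "HierarchicalSettings",
    "SubjectFit",
    "HierarchicalFit",
    "CPTChoiceModel",
    "CPTChoiceResults",
    "TwoStageCohortModel",
    "TwoStageCohortResults",
    "HierarchicalCPTModel",
    "task_arrays",
    "trial_utilities",
    "negative_log_likelihood",
    "fit_subject",
    "fit_cohort_two_stage",
    "fit_cohort_hierarchical",
]

_PARAM_NAMES = ("alpha", "lam", "gamma", "delta")


# ---------------------------------------------------------------------------
# vectorised task evaluation

def task_arrays(task: TaskSpec) -> Dict[str, np.ndarray]:
    """Precompute per-trial arrays used by the vectorised likelihood.

    The result is memoised on the task object, so repeated subject fits
    against the same task share one set of arrays.
    """
    cached = getattr(task, "_arrays_cache", None)
    if cached is not None:
        return cached
    df = task_to_frame(task)
    p_a = df["ap"].to_numpy(float)
    p_b = df["bp"].to_numpy(float)
    arrays = {
        "trial_id": df["trial_id"].to_numpy(int),
        "ax": df["ax"].to_numpy(float), "ay": df["ay"].to_numpy(float),
        "bx": df["bx"].to_numpy(float), "by": df["by"].to_numpy(float),
        # probability levels exclude 0 and 1, so log-odds are finite
        "lo_a": np.log(p_a) - np.log1p(-p_a),
        "lo_b": np.log(p_b) - np.log1p(-p_b),
        "mixed": (df["trial_type"] == "MIXED").to_numpy(bool),
    }
    arrays["row_of"] = {tid: i for i, tid in enumerate(arrays["trial_id"])}
    arrays["X"] = np.ascontiguousarray(
        np.column_stack([arrays["ax"], arrays["ay"], arrays["bx"], arrays["by"]]))
    arrays["LO"] = np.ascontiguousarray(np.column_stack([arrays["lo_a"], arrays["lo_b"]]))
    try:
        object.__setattr__(task, "_arrays_cache", arrays)
    except AttributeError:  # read-only task containers
        pass
    return arrays


def _values(x: np.ndarray, alpha: float, lam: float) -> np.ndarray:
    ax = np.abs(x) ** alpha
    return np.where(x >= 0, ax, -lam * ax)


def trial_utilities(arrays: Dict[str, np.ndarray], params: CPTParams
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """CPT utilities (f_A, f_B) for every trial of a task."""
    a, l, g, d = params.alpha, params.lam, params.gamma, params.delta
    logd = np.log(d)
    mixed = arrays["mixed"]
    out = []
    for side in ("a", "b"):
        lo = arrays[f"lo_{side}"]
        w_x = expit(logd + g * lo)
        # single-domain: complementary weight; mixed: w(1-p) weighted separately
        w_y = np.where(mixed, expit(logd - g * lo), 1.0 - w_x)
        f = w_x * _values(arrays[f"{side}x"], a, l) + w_y * _values(arrays[f"{side}y"], a, l)
        out.append(f)
    return out[0], out[1]


def _p_choose_a(arrays, params) -> np.ndarray:
    f_a, f_b = trial_utilities(arrays, params)
    return np.clip(expit(params.k * (f_a - f_b)), PROB_CLIP_EPS, 1.0 - PROB_CLIP_EPS)


# Optimisation spends nearly all its time in the likelihood, so a compiled
# scalar-loop kernel is used when numba is importable; the numpy path below
# implements the identical arithmetic and is the fallback (and the reference
# the tests compare against).
try:
    from numba import njit as _njit

    @_njit(cache=False, fastmath=False)
    def _nll_kernel(alpha, lam, gamma, logd, k, X, LO, mixed, cnt_a, cnt_b, eps):
        # X[i] = (ax, ay, bx, by); LO[i] = (logodds p_a, logodds p_b)
        total = 0.0
        for i in range(X.shape[0]):
            ca, cb = cnt_a[i], cnt_b[i]
            if ca == 0.0 and cb == 0.0:
                continue
            # weights: w(p) = expit(log d + g * logodds(p)); single-domain
            # gambles use the complement, mixed weigh the 1-p outcome too
            ua = logd + gamma * LO[i, 0]
            wxa = 1.0 / (1.0 + np.exp(-ua)) if ua >= 0 else np.exp(ua) / (1.0 + np.exp(ua))
            ub = logd + gamma * LO[i, 1]
            wxb = 1.0 / (1.0 + np.exp(-ub)) if ub >= 0 else np.exp(ub) / (1.0 + np.exp(ub))
            if mixed[i]:
                uya = logd - gamma * LO[i, 0]
                wya = 1.0 / (1.0 + np.exp(-uya)) if uya >= 0 \
                    else np.exp(uya) / (1.0 + np.exp(uya))
                uyb = logd - gamma * LO[i, 1]
                wyb = 1.0 / (1.0 + np.exp(-uyb)) if uyb >= 0 \
                    else np.exp(uyb) / (1.0 + np.exp(uyb))
            else:
                wya = 1.0 - wxa
                wyb = 1.0 - wxb
            vax = abs(X[i, 0]) ** alpha
            if X[i, 0] < 0:
                vax = -lam * vax
            vay = abs(X[i, 1]) ** alpha
            if X[i, 1] < 0:
                vay = -lam * vay
            vbx = abs(X[i, 2]) ** alpha
            if X[i, 2] < 0:
                vbx = -lam * vbx
            vby = abs(X[i, 3]) ** alpha
            if X[i, 3] < 0:
                vby = -lam * vby
            u = k * ((wxa * vax + wya * vay) - (wxb * vbx + wyb * vby))
            if u >= 0:
                p = 1.0 / (1.0 + np.exp(-u))
            else:
                e = np.exp(u)
                p = e / (1.0 + e)
            if p < eps:
                p = eps
            elif p > 1.0 - eps:
                p = 1.0 - eps
            total -= ca * np.log(p) + cb * np.log(1.0 - p)
        return total

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# per-subject likelihood

def _subject_counts(records: pd.DataFrame, arrays: Dict[str, np.ndarray]
                    ) -> Tuple[np.ndarray, np.ndarray, int]:
    """Aggregate usable records into per-task-row A/B choice counts.

    Timed-out records carry no choice and are excluded.  Aggregation makes
    the likelihood invariant to trial order and fast under task tiling.
    """
    usable = records[~records["timeout"].astype(bool) & records["choice"].notna()]
    row_of = arrays["row_of"]
    mapped = usable["trial_id"].map(row_of)
    if mapped.isna().any():
        raise ValueError("records reference trial ids missing from the task")
    idx = mapped.to_numpy().astype(int)
    chose_a = (usable["choice"] == "A").to_numpy()
    n_rows = len(arrays["trial_id"])
    cnt_a = np.bincount(idx[chose_a], minlength=n_rows).astype(float)
    cnt_b = np.bincount(idx[~chose_a], minlength=n_rows).astype(float)
    return cnt_a, cnt_b, len(usable)


def _nll_counts(cnt_a: np.ndarray, cnt_b: np.ndarray, arrays, params: CPTParams) -> float:
    if _HAVE_NUMBA:
        return float(_nll_kernel(
            params.alpha, params.lam, params.gamma, np.log(params.delta), params.k,
            arrays["X"], arrays["LO"], arrays["mixed"],
            cnt_a, cnt_b, PROB_CLIP_EPS))
    p = _p_choose_a(arrays, params)
    return float(-(cnt_a @ np.log(p) + cnt_b @ np.log1p(-p)))


def negative_log_likelihood(records: pd.DataFrame, task: TaskSpec,
                            params: CPTParams) -> float:
    """Negative log-likelihood (nats) of a subject's usable choices.

    Sums ``-log P(observed choice)`` over non-timeout trials, with the
    choice probability from the logistic rule on the trial's utilities.
    Raises if no usable trials remain.
    """
    arrays = task_arrays(task)
    cnt_a, cnt_b, n = _subject_counts(records, arrays)
    if n == 0:
        raise ValueError("no usable (non-timeout) trials for likelihood evaluation")
    return _nll_counts(cnt_a, cnt_b, arrays, params)


# ---------------------------------------------------------------------------
# settings and fit containers

@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration for per-subject maximum likelihood."""

    n_restarts: int = 8
    bounds: Tuple[float, float] = (0.05, 20.0)  # on the natural parameter scale
    min_trials: int = 50
    seed: int = 0
    jitter_sd: float = 0.5
    xtol: float = 1e-6
    ftol: float = 1e-9
    maxiter: int = 2000
    compute_std_errors: bool = False
    k: float = 1.0  # choice sensitivity; override for sensitivity analysis only


@dataclass(frozen=True)
class HierarchicalSettings:
    """Configuration of the penalized hierarchical approximation."""

    sd_grid: Tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)
    inner_iters: int = 2
    mle_restarts: int = 4
    reference_group: Optional[str] = None  # default: first group encountered


@dataclass
class SubjectFit:
    subject_id: str
    params_hat: CPTParams
    neg_log_lik: float
    n_trials_used: int
    converged: bool
    n_restarts_used: int
    std_errors: Optional[Dict[str, float]] = None
    group: str = "NA"


@dataclass
class HierarchicalFit:
    fixed_effects: Dict[str, CPTParams]          # per-group effective params
    dummy_offsets: pd.DataFrame                  # group, parameter, offset, se, z, p
    random_effect_sds: Dict[str, float]
    subject_blups: pd.DataFrame
    total_neg_log_lik: float
    dof_residual: int
    reference_group: str = ""


# ---------------------------------------------------------------------------
# optimisation

def _start_points(settings: FitSettings) -> np.ndarray:
    lo, hi = np.log(settings.bounds[0]), np.log(settings.bounds[1])
    base = [
        np.zeros(4),                                     # identity parameters
        np.log([0.88, 2.25, 0.65, 1.0]),                 # canonical estimates
        np.full(4, np.log(0.3)),                         # low corner
        np.full(4, np.log(3.0)),                         # high corner
        np.log([0.3, 3.0, 0.3, 3.0]),                    # mixed corner
    ]
    rng = np.random.default_rng(settings.seed)
    while len(base) < settings.n_restarts:
        base.append(rng.normal(0.0, settings.jitter_sd, size=4))
    starts = np.clip(np.array(base[: settings.n_restarts]), lo + 1e-6, hi - 1e-6)
    return starts


def _optimize_nll(objective, settings: FitSettings,
                  extra_starts: Sequence[np.ndarray] = ()) -> Tuple[np.ndarray, float, bool]:
    lo, hi = np.log(settings.bounds[0]), np.log(settings.bounds[1])
    bounds = [(lo, hi)] * 4
    best_z, best_f, any_success = None, np.inf, False
    starts = list(extra_starts) + list(_start_points(settings))
    for z0 in starts:
        res = minimize(objective, z0, method="Powell", bounds=bounds,
                       options={"xtol": settings.xtol, "ftol": settings.ftol,
                                "maxiter": settings.maxiter})
        any_success = any_success or bool(res.success)
        if res.fun < best_f:
            best_f, best_z = float(res.fun), np.asarray(res.x, dtype=float)
    return best_z, best_f, any_success


def _std_errors_from_hessian(objective, z_hat: np.ndarray, theta: np.ndarray,
                             step: float = 1e-4) -> Optional[Dict[str, float]]:
    """Delta-method standard errors on the natural scale from a numerical
    Hessian of the NLL in log-parameters."""
    n = len(z_hat)
    H = np.empty((n, n))
    f0 = objective(z_hat)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            fpp = objective(z_hat + ei + ej)
            fpm = objective(z_hat + ei - ej)
            fmp = objective(z_hat - ei + ej)
            fmm = objective(z_hat - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step ** 2)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        return None
    se_log = np.sqrt(var)
    return {name: float(theta[i] * se_log[i]) for i, name in enumerate(_PARAM_NAMES)}


# ---------------------------------------------------------------------------
# Model / Results objects

class CPTChoiceModel:
    """Maximum-likelihood CPT model for one subject's choices.

    Parameters
    ----------
    records : DataFrame with columns trial_id, choice ('A'/'B'), timeout.
    task : the TaskSpec the trial ids refer to.

    ``fit`` minimises the choice negative log-likelihood over
    log-parameters with multi-start gradient-free local search and returns
    a :class:`CPTChoiceResults`.
    """

    def __init__(self, records: pd.DataFrame, task: TaskSpec,
                 subject_id: str = "subject", group: str = "NA"):
        self.task = task
        self.subject_id = subject_id
        self.group = group
        self._arrays = task_arrays(task)
        self._cnt_a, self._cnt_b, self.n_trials_used = _subject_counts(records, self._arrays)

    @classmethod
    def from_records(cls, records: pd.DataFrame, task: TaskSpec,
                     subject_id: str = "subject", group: str = "NA") -> "CPTChoiceModel":
        return cls(records, task, subject_id=subject_id, group=group)

    def loglike(self, params: CPTParams) -> float:
        return -_nll_counts(self._cnt_a, self._cnt_b, self._arrays, params)

    def _objective(self, k: float):
        cnt_a, cnt_b, arrays = self._cnt_a, self._cnt_b, self._arrays
        if _HAVE_NUMBA:
            X, LO, mixed = arrays["X"], arrays["LO"], arrays["mixed"]

            def nll_z(z: np.ndarray) -> float:
                # z = log(alpha, lam, gamma, delta); z[3] is log delta directly
                return float(_nll_kernel(
                    np.exp(z[0]), np.exp(z[1]), np.exp(z[2]), z[3], k,
                    X, LO, mixed, cnt_a, cnt_b, PROB_CLIP_EPS))
        else:
            def nll_z(z: np.ndarray) -> float:
                p = CPTParams.from_array(np.exp(z), k=k)
                return _nll_counts(cnt_a, cnt_b, arrays, p)

        return nll_z

    def fit(self, settings: Optional[FitSettings] = None,
            extra_starts: Sequence[np.ndarray] = ()) -> "CPTChoiceResults":
        settings = settings or FitSettings()
        if self.n_trials_used < settings.min_trials:
            raise ValueError(
                f"subject {self.subject_id}: {self.n_trials_used} usable trials "
                f"< minimum {settings.min_trials}")
        objective = self._objective(settings.k)
        z_hat, nll, success = _optimize_nll(objective, settings, extra_starts)
        theta = np.exp(z_hat)
        se = None
        if settings.compute_std_errors:
            se = _std_errors_from_hessian(objective, z_hat, theta)
        fit = SubjectFit(
            subject_id=self.subject_id,
            params_hat=CPTParams.from_array(theta, k=settings.k),
            neg_log_lik=nll, n_trials_used=self.n_trials_used,
            converged=success,
            n_restarts_used=settings.n_restarts + len(list(extra_starts)),
            std_errors=se, group=self.group)
        return CPTChoiceResults(self, fit, settings)


class CPTChoiceResults:
    """Estimates, uncertainty and diagnostics for one fitted subject."""

    def __init__(self, model: CPTChoiceModel, fit: SubjectFit, settings: FitSettings):
        self.model = model
        self.subject_fit = fit
        self.settings = settings

    @property
    def params(self) -> CPTParams:
        return self.subject_fit.params_hat

    @property
    def bse(self) -> Optional[Dict[str, float]]:
        return self.subject_fit.std_errors

    @property
    def llf(self) -> float:
        return -self.subject_fit.neg_log_lik

    @property
    def converged(self) -> bool:
        return self.subject_fit.converged

    def summary(self) -> str:
        f = self.subject_fit
        lines = [
            f"CPT choice model — subject {f.subject_id} (group {f.group})",
            f"  trials used: {f.n_trials_used}   NLL: {f.neg_log_lik:.3f}   "
            f"converged: {f.converged}",
            f"  {'param':<8}{'estimate':>10}{'std err':>10}",
        ]
        for name in _PARAM_NAMES:
            est = getattr(f.params_hat, name)
            se = (f.std_errors or {}).get(name)
            lines.append(f"  {name:<8}{est:>10.4f}{(f'{se:.4f}' if se else '—'):>10}")
        return "\n".join(lines)


def fit_subject(records: pd.DataFrame, task: TaskSpec,
                settings: Optional[FitSettings] = None,
                subject_id: str = "subject", group: str = "NA") -> SubjectFit:
    """Functional wrapper: fit one subject, return the :class:`SubjectFit`."""
    res = CPTChoiceModel(records, task, subject_id=subject_id, group=group).fit(settings)
    return res.subject_fit


# ---------------------------------------------------------------------------
# two-stage cohort fit

class TwoStageCohortModel:
    """Stage one of two-stage inference: independent per-subject MLE.

    Subjects with fewer usable trials than the minimum are skipped and
    listed, not fitted.
    """

    def __init__(self, dataset: ChoiceDataset):
        dataset.validate()
        self.dataset = dataset

    def fit(self, settings: Optional[FitSettings] = None) -> "TwoStageCohortResults":
        settings = settings or FitSettings()
        fits: List[SubjectFit] = []
        skipped: List[str] = []
        for sid, sub in self.dataset.records.groupby("subject_id", sort=True):
            group = str(sub["group"].iloc[0])
            model = CPTChoiceModel(sub, self.dataset.task, subject_id=str(sid), group=group)
            if model.n_trials_used < settings.min_trials:
                skipped.append(str(sid))
                continue
            fits.append(model.fit(settings).subject_fit)
        return TwoStageCohortResults(self, fits, skipped, settings)


class TwoStageCohortResults:
    def __init__(self, model: TwoStageCohortModel, fits: List[SubjectFit],
                 skipped: List[str], settings: FitSettings):
        self.model = model
        self.fits = fits
        self.skipped = skipped
        self.settings = settings

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append({"subject_id": f.subject_id, "group": f.group,
                         **{n: getattr(f.params_hat, n) for n in _PARAM_NAMES},
                         "nll": f.neg_log_lik, "n_trials_used": f.n_trials_used,
                         "converged": f.converged})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [f"Two-stage cohort fit: {len(self.fits)} subjects fitted, "
                 f"{len(self.skipped)} skipped"]
        if len(df):
            g = df.groupby("group")[list(_PARAM_NAMES)].mean()
            lines.append(g.round(4).to_string())
        return "\n".join(lines)


def fit_cohort_two_stage(dataset: ChoiceDataset,
                         settings: Optional[FitSettings] = None) -> TwoStageCohortResults:
    return TwoStageCohortModel(dataset).fit(settings)


# ---------------------------------------------------------------------------
# penalized hierarchical fit

class HierarchicalCPTModel:
    """Penalized-likelihood approximation to a nonlinear mixed-effects fit.

    The joint criterion is the sum over subjects of the choice NLL plus a
    Gaussian penalty ``sum_j (z_ij - mu_gj)^2 / (2 sigma_j^2)`` on subject
    log-parameter deviations from their group fixed effect, plus the
    normalisation term ``n log sigma_j`` per parameter.  Random-effect SDs
    are profiled parameter-by-parameter on a coarse grid; within each
    candidate, subject-level modes (BLUP analogues) and group means are
    updated by coordinate ascent.  Group contrasts are additive dummy
    offsets on the log scale with Wald-type tests based on the profiled
    random-effect SD.
    """

    def __init__(self, dataset: ChoiceDataset):
        dataset.validate()
        self.dataset = dataset
        self._arrays = task_arrays(dataset.task)
        self._subjects: List[Tuple[str, str, np.ndarray, np.ndarray, int]] = []
        for sid, sub in dataset.records.groupby("subject_id", sort=True):
            cnt_a, cnt_b, n = _subject_counts(sub, self._arrays)
            if n == 0:
                continue
            self._subjects.append((str(sid), str(sub["group"].iloc[0]), cnt_a, cnt_b, n))
        groups = sorted({s[1] for s in self._subjects})
        counts = {g: sum(1 for s in self._subjects if s[1] == g) for g in groups}
        low = [g for g, c in counts.items() if c < 2]
        if len(self._subjects) and low and len(groups) > 1:
            raise ValueError(f"hierarchical fit needs >= 2 subjects per group; low: {low}")

    def _subject_nll(self, i: int, params: CPTParams) -> float:
        _, _, cnt_a, cnt_b, _ = self._subjects[i]
        return _nll_counts(cnt_a, cnt_b, self._arrays, params)

    def _penalized_refit(self, i: int, z0: np.ndarray, mu: np.ndarray,
                         sigma: np.ndarray, settings: FitSettings) -> Tuple[np.ndarray, float]:
        lo, hi = np.log(settings.bounds[0]), np.log(settings.bounds[1])

        def obj(z):
            p = CPTParams.from_array(np.exp(z), k=settings.k)
            pen = float(np.sum((z - mu) ** 2 / (2.0 * sigma ** 2)))
            return self._subject_nll(i, p) + pen

        res = minimize(obj, np.clip(z0, lo + 1e-6, hi - 1e-6), method="Powell",
                       bounds=[(lo, hi)] * 4,
                       options={"xtol": settings.xtol, "ftol": settings.ftol,
                                "maxiter": settings.maxiter})
        return np.asarray(res.x, float), float(res.fun)

    def _criterion(self, z: np.ndarray, mu_by_group: Dict[str, np.ndarray],
                   sigma: np.ndarray, settings: FitSettings) -> float:
        total = 0.0
        for i, (sid, g, cnt_a, cnt_b, n) in enumerate(self._subjects):
            p = CPTParams.from_array(np.exp(z[i]), k=settings.k)
            total += _nll_counts(cnt_a, cnt_b, self._arrays, p)
            total += float(np.sum((z[i] - mu_by_group[g]) ** 2 / (2.0 * sigma ** 2)))
        total += len(self._subjects) * float(np.sum(np.log(sigma)))
        return total

    def _inner_loop(self, z, mu_by_group, sigma, settings, hset):
        for _ in range(hset.inner_iters):
            for i, (sid, g, *_rest) in enumerate(self._subjects):
                z[i], _ = self._penalized_refit(i, z[i], mu_by_group[g], sigma, settings)
            for g in mu_by_group:
                idx = [i for i, s in enumerate(self._subjects) if s[1] == g]
                mu_by_group[g] = z[idx].mean(axis=0)
        return z, mu_by_group

    def fit(self, settings: Optional[FitSettings] = None,
            hsettings: Optional[HierarchicalSettings] = None) -> HierarchicalFit:
        settings = settings or FitSettings()
        hset = hsettings or HierarchicalSettings()
        if not self._subjects:
            raise ValueError("no usable subjects")

        mle_settings = replace(settings, n_restarts=hset.mle_restarts)
        z = np.empty((len(self._subjects), 4))
        for i, (sid, g, cnt_a, cnt_b, n) in enumerate(self._subjects):
            def obj(zz, _i=i):
                return self._subject_nll(_i, CPTParams.from_array(np.exp(zz), k=settings.k))
            z_hat, _, _ = _optimize_nll(obj, mle_settings)
            z[i] = z_hat

        groups = sorted({s[1] for s in self._subjects})
        mu_by_group = {g: z[[i for i, s in enumerate(self._subjects) if s[1] == g]].mean(axis=0)
                       for g in groups}

        # initial sigma: pooled within-group SD of MLE log-params, snapped to grid
        grid = np.asarray(hset.sd_grid)
        resid = np.vstack([z[i] - mu_by_group[s[1]] for i, s in enumerate(self._subjects)])
        raw_sd = resid.std(axis=0, ddof=0)
        if np.any(raw_sd < grid.min()):
            warnings.warn("near-degenerate random-effect variance; "
                          "flooring at the smallest grid value")
        sigma = grid[np.argmin(np.abs(np.log(np.maximum(raw_sd, grid.min()))[:, None]
                                      - np.log(grid)[None, :]), axis=1)]

        # profile each parameter's random-effect SD on the coarse grid
        for j in range(4):
            best_val, best_crit, best_state = sigma[j], np.inf, None
            for cand in grid:
                sig_try = sigma.copy(); sig_try[j] = cand
                z_try = z.copy()
                mu_try = {g: m.copy() for g, m in mu_by_group.items()}
                z_try, mu_try = self._inner_loop(z_try, mu_try, sig_try, settings, hset)
                crit = self._criterion(z_try, mu_try, sig_try, settings)
                if crit < best_crit:
                    best_crit, best_val, best_state = crit, cand, (z_try, mu_try)
            sigma[j] = best_val
            z, mu_by_group = best_state

        ref = hset.reference_group or ("HC" if "HC" in groups else groups[0])
        fixed_effects = {g: CPTParams.from_array(np.exp(mu_by_group[g]), k=settings.k)
                         for g in groups}
        n_by_group = {g: sum(1 for s in self._subjects if s[1] == g) for g in groups}
        rows = []
        for g in groups:
            if g == ref:
                continue
            for j, name in enumerate(_PARAM_NAMES):
                offset = float(mu_by_group[g][j] - mu_by_group[ref][j])
                se = float(sigma[j] * np.sqrt(1.0 / n_by_group[ref] + 1.0 / n_by_group[g]))
                zstat = offset / se
                rows.append({"group": g, "parameter": name, "offset": offset,
                             "se": se, "z": zstat,
                             "p": float(2 * norm.sf(abs(zstat)))})
        offsets = pd.DataFrame(rows, columns=["group", "parameter", "offset",
                                              "se", "z", "p"])
        blups = pd.DataFrame(
            [{"subject_id": s[0], "group": s[1],
              **dict(zip(_PARAM_NAMES, np.exp(z[i])))}
             for i, s in enumerate(self._subjects)])
        total_nll = sum(
            self._subject_nll(i, CPTParams.from_array(np.exp(z[i]), k=settings.k))
            for i in range(len(self._subjects)))
        n_obs = sum(s[4] for s in self._subjects)
        dof = n_obs - 4 * len(groups) - 4 * len(self._subjects)
        return HierarchicalFit(
            fixed_effects=fixed_effects, dummy_offsets=offsets,
            random_effect_sds=dict(zip(_PARAM_NAMES, (float(v) for v in sigma))),
            subject_blups=blups, total_neg_log_lik=float(total_nll),
            dof_residual=int(dof), reference_group=ref)


def fit_cohort_hierarchical(dataset: ChoiceDataset,
                            settings: Optional[FitSettings] = None,
                            hsettings: Optional[HierarchicalSettings] = None
                            ) -> HierarchicalFit:
    return HierarchicalCPTModel(dataset).fit(settings, hsettings)
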