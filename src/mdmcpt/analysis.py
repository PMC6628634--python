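"""Group-level statistics on fitted parameters and raw choices.

Covers the study's inferential battery: pooled-variance independent t
tests comparing each patient group with controls on each of the four CPT
parameters (Bonferroni-corrected as a family), one-sample t tests of loss
aversion against 1, an expected-value optimality analysis (delta-EV) on
the equal-probability single-domain trial subset with a two-group mixed
ANOVA, Pearson correlations between parameters and clinical severity
scores, and rendering of the group-level value and weighting curves.

Student (pooled-variance) t tests are used rather than Welch so degrees
of freedom follow the n1 + n2 - 2 convention of the original analyses;
Cohen's d uses the pooled SD (two-sample) or the sample SD (one-sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cpt import CPTParams, expected_value, value, weight
from .task import TaskSpec, equal_probability_subset
from .cohort import ChoiceDataset

__all__ = [
    "TTestResult",
    "independent_t_test",
    "one_sample_test_vs_one",
    "bonferroni",
    "group_parameter_tests",
    "delta_ev_analysis",
    "delta_ev_long",
    "mixed_anova",
    "parameter_clinical_correlations",
    "plot_functions",
]

PARAM_NAMES = ("alpha", "lam", "gamma", "delta")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    dof: int
    p_value: float
    mean_diff: float           # mean difference (two-sample) or sample mean (one-sample)
    ci_low: float
    ci_high: float
    cohens_d: float
    corrected_alpha: Optional[float] = None

    def significant(self, alpha: float = 0.05, family_size: int = 1) -> bool:
        return self.p_value < alpha / family_size


def independent_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Two-tailed pooled-variance (Student) t test.

    Degrees of freedom are ``n1 + n2 - 2``; Cohen's d divides the mean
    difference by the pooled SD; the 95% CI is on the mean difference.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    dof = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / dof
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    diff = a.mean() - b.mean()
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    tcrit = stats.t.ppf(0.975, dof)
    d = diff / np.sqrt(sp2)
    return TTestResult(statistic=float(t), dof=dof, p_value=float(p),
                       mean_diff=float(diff), ci_low=float(diff - tcrit * se),
                       ci_high=float(diff + tcrit * se), cohens_d=float(d))


def one_sample_test_vs_one(sample: Sequence[float]) -> TTestResult:
    """One-sample t test of the mean against 1 (the loss-neutral value).

    ``t = (mean - 1) / (sd / sqrt(n))``; ``d = (mean - 1) / sd``; the CI
    is on the mean itself.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("sample needs at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance sample")
    t, p = stats.ttest_1samp(x, popmean=1.0)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return TTestResult(statistic=float(t), dof=n - 1, p_value=float(p),
                       mean_diff=float(x.mean()),
                       ci_low=float(x.mean() - tcrit * se),
                       ci_high=float(x.mean() + tcrit * se),
                       cohens_d=float((x.mean() - 1.0) / sd))


def bonferroni(p_values: Sequence[float], family_size: int) -> pd.DataFrame:
    """Bonferroni decisions: reject iff ``p < 0.05 / family_size``."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    corrected = 0.05 / family_size
    p = np.asarray(p_values, dtype=float)
    return pd.DataFrame({"p_value": p, "corrected_alpha": corrected,
                         "significant": p < corrected})


def group_parameter_tests(fits: pd.DataFrame, reference: str = "HC",
                          family_size: Optional[int] = None,
                          params: Sequence[str] = PARAM_NAMES) -> pd.DataFrame:
    """Every patient group against the reference on every parameter.

    Returns a tidy table (one row per comparison x parameter) with the
    Bonferroni decision at the given family size (defaults to the number
    of tests performed).
    """
    groups = [g for g in fits["group"].unique() if g != reference]
    rows = []
    for g in sorted(groups):
        for name in params:
            a = fits.loc[fits["group"] == reference, name].to_numpy()
            b = fits.loc[fits["group"] == g, name].to_numpy()
            r = independent_t_test(a, b)
            rows.append({"comparison": f"{reference}-vs-{g}", "parameter": name,
                         "t": r.statistic, "dof": r.dof, "p": r.p_value,
                         "d": r.cohens_d, "ci_low": r.ci_low, "ci_high": r.ci_high})
    out = pd.DataFrame(rows)
    fam = family_size or len(out)
    if len(out):
        out["corrected_alpha"] = 0.05 / fam
        out["significant"] = out["p"] < 0.05 / fam
    return out


# ---------------------------------------------------------------------------
# expected-value optimality

def _delta_ev_records(dataset: ChoiceDataset, trials) -> pd.DataFrame:
    info = {t.trial_id: (expected_value(t.gamble_a), expected_value(t.gamble_b),
                         t.trial_type) for t in trials}
    rec = dataset.records
    rec = rec[rec["trial_id"].isin(info) & ~rec["timeout"].astype(bool)
              & rec["choice"].notna()].copy()
    ev_a = rec["trial_id"].map(lambda t: info[t][0])
    ev_b = rec["trial_id"].map(lambda t: info[t][1])
    chose_a = rec["choice"] == "A"
    rec["delta_ev"] = np.where(chose_a, ev_a - ev_b, ev_b - ev_a)
    rec["trial_type"] = rec["trial_id"].map(lambda t: info[t][2])
    return rec


def delta_ev_long(dataset: ChoiceDataset, task: Optional[TaskSpec] = None,
                  single_domain_only: bool = True) -> pd.DataFrame:
    """Per-record delta-EV (EV of chosen minus non-chosen gamble) on the
    equal-probability trial subset, long format for the mixed ANOVA."""
    task = task or dataset.task
    trials = equal_probability_subset(task, single_domain_only=single_domain_only)
    return _delta_ev_records(dataset, trials)[
        ["subject_id", "group", "trial_id", "trial_type", "delta_ev"]]


def delta_ev_analysis(dataset: ChoiceDataset, task: Optional[TaskSpec] = None,
                      single_domain_only: bool = True) -> pd.DataFrame:
    """Per-subject optimality summary on the equal-probability subset.

    Columns: mean delta-EV overall and per trial type, number of usable
    subset trials, and the attainable maximum (mean delta-EV of an agent
    always choosing the higher-EV gamble).  Subjects with no usable
    subset trials are excluded.
    """
    task = task or dataset.task
    trials = equal_probability_subset(task, single_domain_only=single_domain_only)
    max_attainable = float(np.mean(
        [abs(expected_value(t.gamble_a) - expected_value(t.gamble_b)) for t in trials]))
    rec = _delta_ev_records(dataset, trials)
    rows = []
    for sid, sub in rec.groupby("subject_id", sort=True):
        row = {"subject_id": sid, "group": sub["group"].iloc[0],
               "mean_delta_ev": sub["delta_ev"].mean(),
               "n_trials": len(sub), "max_attainable": max_attainable}
        for ttype, tsub in sub.groupby("trial_type"):
            row[f"mean_delta_ev_{ttype.lower()}"] = tsub["delta_ev"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def mixed_anova(long_df: pd.DataFrame, dv: str = "delta_ev",
                within: str = "trial_id", subject: str = "subject_id",
                between: str = "group") -> pd.DataFrame:
    """Two-group mixed ANOVA: within-subject trial factor, between-subject
    group factor.

    Subjects missing any within-factor cell are dropped listwise.  Returns
    the effect table (Source, SS, DF1, DF2, F, p-unc) augmented with
    Cohen's d on the subject means for the between effect.
    """
    import pingouin as pg

    groups = long_df[between].unique()
    if len(groups) != 2:
        raise ValueError("mixed_anova expects exactly two groups")
    # listwise deletion: keep subjects observed in every within cell
    cells = long_df.groupby(subject)[within].nunique()
    full = cells[cells == long_df[within].nunique()].index
    dropped = sorted(set(long_df[subject]) - set(full))
    if dropped:
        import warnings
        warnings.warn(f"dropping {len(dropped)} subject(s) with missing cells")
    df = long_df[long_df[subject].isin(full)]
    # collapse duplicates (repeated presentations of a trial) to cell means
    df = (df.groupby([subject, between, within], as_index=False)[dv].mean())
    aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                         between=between)
    subj_means = df.groupby([subject, between])[dv].mean().reset_index()
    a = subj_means.loc[subj_means[between] == groups[0], dv].to_numpy()
    b = subj_means.loc[subj_means[between] == groups[1], dv].to_numpy()
    if len(a) >= 2 and len(b) >= 2:
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                     / (len(a) + len(b) - 2))
    else:
        sp = np.nan
    aov = aov.copy()
    aov["cohens_d_between"] = np.where(aov["Source"] == between,
                                       (a.mean() - b.mean()) / sp, np.nan)
    return aov


def parameter_clinical_correlations(fits: pd.DataFrame, clinical: pd.DataFrame,
                                    family_size: int = 16,
                                    params: Sequence[str] = PARAM_NAMES
                                    ) -> pd.DataFrame:
    """Pearson correlations between each parameter and each clinical scale.

    Pairs with a constant column are skipped with a warning.  Decisions
    use the Bonferroni threshold ``0.05 / family_size``.
    """
    import warnings

    merged = fits.merge(clinical, on="subject_id", suffixes=("", "_clin"))
    scales = [c for c in clinical.columns if c not in ("subject_id", "group")]
    rows = []
    for pname in params:
        for scale in scales:
            x = merged[pname].to_numpy(float)
            y = merged[scale].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 3:
                warnings.warn(f"{pname}~{scale}: fewer than 3 paired observations; skipped")
                continue
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"{pname}~{scale}: constant column; skipped")
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"parameter": pname, "scale": scale, "n": len(x),
                         "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["corrected_alpha"] = 0.05 / family_size
        out["significant"] = out["p"] < 0.05 / family_size
    return out


# ---------------------------------------------------------------------------
# curves

def plot_functions(params_by_group: Dict[str, CPTParams], out_dir,
                   x_range: Tuple[float, float] = (-200.0, 200.0),
                   n_points: int = 401) -> Dict[str, str]:
    """Render group-level value and weighting curves, with CSV tables.

    Writes ``value_function.png`` / ``weighting_function.png`` and the
    underlying curve tables ``value_curves.csv`` / ``weight_curves.csv``
    (one column per group) to ``out_dir``; returns the paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    xs = np.linspace(x_range[0], x_range[1], n_points)
    ps = np.linspace(0.0, 1.0, n_points)

    vtab = pd.DataFrame({"x": xs})
    wtab = pd.DataFrame({"p": ps})
    fig_v, ax_v = plt.subplots(figsize=(5, 4))
    fig_w, ax_w = plt.subplots(figsize=(5, 4))
    for label, params in params_by_group.items():
        vtab[label] = value(xs, params)
        wtab[label] = weight(ps, params)
        ax_v.plot(xs, vtab[label], label=label)
        ax_w.plot(ps, wtab[label], label=label)
    ax_v.set_xlabel("outcome x (points)"); ax_v.set_ylabel("v(x)"); ax_v.legend()
    ax_w.set_xlabel("probability p"); ax_w.set_ylabel("w(p)"); ax_w.legend()
    ax_w.plot([0, 1], [0, 1], ls=":", c="gray", lw=0.8)
    paths = {
        "value_png": str(out_dir / "value_function.png"),
        "weight_png": str(out_dir / "weighting_function.png"),
        "value_csv": str(out_dir / "value_curves.csv"),
        "weight_csv": str(out_dir / "weight_curves.csv"),
    }
    fig_v.savefig(paths["value_png"], dpi=150, bbox_inches="tight")
    fig_w.savefig(paths["weight_png"], dpi=150, bbox_inches="tight")
    plt.close(fig_v); plt.close(fig_w)
    vtab.to_csv(paths["value_csv"], index=False)
    wtab.to_csv(paths["weight_csv"], index=False)
    return paths
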