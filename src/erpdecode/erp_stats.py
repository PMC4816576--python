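"""Condition ERPs, Ne/Pe quantification, and the accompanying statistics.

The Ne/ERN is quantified as the mean voltage 20–100 ms after the response at
FCz, the Pe as the mean voltage 180–250 ms after the response at Cz (window
endpoints inclusive on the discrete grid).  Condition effects are assessed
with 2x2 repeated-measures ANOVAs (task x response), paired bootstrap
t-tests, repeated-measures Cohen's d, and Benjamini–Yekutieli FDR control
for post-hoc contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .epochs import Epochs

__all__ = [
    "ComponentWindow",
    "NE_WINDOW",
    "PE_WINDOW",
    "ConditionERP",
    "condition_erps",
    "windowed_mean",
    "subject_condition_table",
    "AnovaResult",
    "rm_anova_2x2",
    "bootstrap_ttest_paired",
    "posthoc_ttest",
    "cohens_d_rm",
    "adjust_fdr_by",
    "rt_filter",
    "erp_image",
]


@dataclass(frozen=True)
class ComponentWindow:
    """A named measurement window at a single channel."""

    name: str  # "Ne" or "Pe"
    channel: str
    window: tuple[float, float]  # ms post-response, endpoints inclusive


NE_WINDOW = ComponentWindow("Ne", "FCz", (20.0, 100.0))
PE_WINDOW = ComponentWindow("Pe", "Cz", (180.0, 250.0))


@dataclass
class ConditionERP:
    """Across-trial average for one (task, response) cell."""

    task: str
    response: str
    data: np.ndarray  # (n_channels, n_samples), μV
    times: np.ndarray
    channel_names: tuple[str, ...]
    n_trials: int

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


def condition_erps(epochs: Epochs) -> dict[tuple[str, str], ConditionERP]:
    """Arithmetic-mean ERP per (task, response) condition present in the data."""
    out: dict[tuple[str, str], ConditionERP] = {}
    meta = epochs.trial_meta
    for (task, response), idx in meta.groupby(["task", "response"], observed=True).groups.items():
        idx = np.asarray(idx)
        out[(task, response)] = ConditionERP(
            task=task,
            response=response,
            data=epochs.data[idx].mean(axis=0),
            times=epochs.times,
            channel_names=epochs.montage.channel_names,
            n_trials=len(idx),
        )
    if not out:
        raise ValueError("no trials to average")
    return out


def windowed_mean(values, times, channel_names, cw: ComponentWindow):
    """Mean voltage in ``cw``'s window at its channel.

    ``values`` may be ``(n_channels, n_samples)`` (returns a scalar) or
    ``(n_trials, n_channels, n_samples)`` (returns one value per trial).
    Samples with ``start <= t <= end`` are included.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    names = list(channel_names)
    if cw.channel not in names:
        raise KeyError(f"channel {cw.channel!r} not present")
    lo, hi = cw.window
    if lo < times[0] or hi > times[-1]:
        raise ValueError(f"window {cw.window} outside the time axis")
    mask = (times >= lo) & (times <= hi)
    ch = names.index(cw.channel)
    return values[..., ch, :][..., mask].mean(axis=-1)


def erp_windowed_mean(erp: ConditionERP, cw: ComponentWindow) -> float:
    return float(windowed_mean(erp.data, erp.times, erp.channel_names, cw))


def epochs_windowed_mean(epochs: Epochs, cw: ComponentWindow) -> np.ndarray:
    """Single-trial windowed means (one value per trial)."""
    return windowed_mean(epochs.data, epochs.times, epochs.montage.channel_names, cw)


def subject_condition_table(
    cohort: list[dict[str, Epochs]], cw: ComponentWindow
) -> pd.DataFrame:
    """Tidy subject x task x response table of ERP windowed-mean amplitudes.

    Columns: subject, task, response, value (μV), n_trials.  Input is a list
    of per-subject ``{task: Epochs}`` dicts as produced by the simulator.
    """
    rows = []
    for subject, tasks in enumerate(cohort):
        for task, epochs in tasks.items():
            for (t, response), erp in condition_erps(epochs).items():
                rows.append(
                    {
                        "subject": subject,
                        "task": t,
                        "response": response,
                        "value": erp_windowed_mean(erp, cw),
                        "n_trials": erp.n_trials,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float
    eta_p2: float


def _contrast_f(values: np.ndarray) -> tuple[float, float, float, int]:
    """Paired-t-on-contrast F test: returns (F, p, eta_p2, df2)."""
    n = len(values)
    t = float(values.mean() / (values.std(ddof=1) / np.sqrt(n)))
    F = t * t
    df2 = n - 1
    p = float(stats.f.sf(F, 1, df2))
    eta = F / (F + df2)
    return F, p, eta, df2


def rm_anova_2x2(table: pd.DataFrame, value_col: str = "value") -> list[AnovaResult]:
    """2x2 fully-within repeated-measures ANOVA (task x response).

    Exploits the equivalence, exact in the 2x2 within design, between each
    effect's F statistic and the squared paired t on the corresponding
    orthogonal contrast.  Returns task, response, and interaction effects
    with F, (1, n-1) degrees of freedom, p, and partial eta squared.
    """
    wide = table.pivot_table(index="subject", columns=["task", "response"], values=value_col)
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("incomplete 2x2 cell structure")
    if len(wide) < 3:
        raise ValueError("need at least 3 subjects")
    tasks = sorted({c[0] for c in wide.columns})
    responses = sorted({c[1] for c in wide.columns})
    a1, a2 = tasks
    b1, b2 = responses
    cells = {k: wide[k].to_numpy() for k in wide.columns}
    contrasts = {
        "task": (cells[(a1, b1)] + cells[(a1, b2)] - cells[(a2, b1)] - cells[(a2, b2)]) / 2,
        "response": (cells[(a1, b1)] - cells[(a1, b2)] + cells[(a2, b1)] - cells[(a2, b2)]) / 2,
        "interaction": (cells[(a1, b1)] - cells[(a1, b2)] - cells[(a2, b1)] + cells[(a2, b2)]) / 2,
    }
    out = []
    for effect, c in contrasts.items():
        if np.allclose(c, 0):
            n = len(c)
            out.append(AnovaResult(effect, 0.0, (1, n - 1), 1.0, 0.0))
            continue
        F, p, eta, df2 = _contrast_f(c)
        out.append(AnovaResult(effect, F, (1, df2), p, eta))
    return out


def bootstrap_ttest_paired(
    x, y, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Paired t-test with a bootstrap null distribution.

    The observed statistic is the ordinary paired t.  The null is formed by
    resampling the mean-centred paired differences with replacement
    ``n_boot`` times; the two-sided p uses the add-one estimator
    ``p = (1 + #{|t*| >= |t_obs|}) / (n_boot + 1)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D samples of size >= 3")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance paired differences")
    n = len(d)
    t_obs = float(d.mean() / (sd / np.sqrt(n)))
    centred = d - d.mean()
    rng = np.random.default_rng(seed)
    samples = rng.choice(centred, size=(n_boot, n), replace=True)
    sds = samples.std(ddof=1, axis=1)
    sds[sds == 0] = np.inf  # degenerate resamples contribute t* = 0
    t_star = samples.mean(axis=1) / (sds / np.sqrt(n))
    p = (1 + int(np.sum(np.abs(t_star) >= abs(t_obs)))) / (n_boot + 1)
    return t_obs, float(p)


def posthoc_ttest(x, y, alternative: str = "two-sided") -> tuple[float, float, float]:
    """Paired t-test with selectable sidedness; returns (t, p, d_rm)."""
    res = stats.ttest_rel(np.asarray(x, float), np.asarray(y, float), alternative=alternative)
    return float(res.statistic), float(res.pvalue), cohens_d_rm(x, y)


def cohens_d_rm(x, y) -> float:
    """Repeated-measures Cohen's d: mean difference over SD of differences."""
    d = np.asarray(x, float) - np.asarray(y, float)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero SD of paired differences; d undefined")
    return float(d.mean() / sd)


def adjust_fdr_by(pvalues) -> np.ndarray:
    """Benjamini–Yekutieli step-up FDR adjustment (arbitrary dependence)."""
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be a 1-D array within [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_by")[1]


def rt_filter(epochs: Epochs, low_ms: float = 100.0, high_ms: float = 1000.0) -> Epochs:
    """Keep trials with ``low < RT < high`` (strict exclusion at the bounds)."""
    rts = epochs.rts
    return epochs.subset((rts > low_ms) & (rts < high_ms))


def erp_image(
    epochs: Epochs, channel: str, ma_window: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """RT-sorted, smoothed single-trial image of one channel.

    Each subject's trials are scaled to [-1, 1] by the subject's maximum
    absolute value; all trials are then sorted by ascending RT and a boxcar
    moving average of ``ma_window`` trials is run down the trial axis
    (output has ``n_trials - ma_window + 1`` rows).  Returns the smoothed
    matrix and the RT sort order (trial indices).
    """
    if ma_window < 1:
        raise ValueError("ma_window must be >= 1")
    if epochs.n_trials < ma_window:
        raise ValueError("fewer trials than the moving-average window")
    x = epochs.get_channel(channel).copy()
    for _, idx in epochs.trial_meta.groupby("subject_id").groups.items():
        idx = np.asarray(idx)
        peak = np.abs(x[idx]).max()
        if peak > 0:
            x[idx] = x[idx] / peak
    order = np.argsort(epochs.rts, kind="stable")
    x = x[order]
    kernel = np.ones(ma_window) / ma_window
    smoothed = np.apply_along_axis(lambda col: np.convolve(col, kernel, mode="valid"), 0, x)
    return smoothed, order
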