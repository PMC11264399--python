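"""Descriptive statistics for ordinal symptom panels.

Covers the standard reporting block for a multi-wave questionnaire study:
per-item moment tables, scale totals, Cronbach's alpha with a Feldt
confidence interval, prevalence at a clinical cut-off, and the attrition
t-test comparing baseline totals of completers vs. dropouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_data import PanelDataError, PanelDataset

__all__ = [
    "item_moments",
    "scale_total",
    "cronbach_alpha",
    "cutoff_prevalence",
    "attrition_comparison",
]


def item_moments(ds: PanelDataset, *, bias_corrected: bool = True) -> pd.DataFrame:
    """Per item x wave: n, mean, SD (n-1), skewness, excess kurtosis.

    With ``bias_corrected`` (default) skewness is the adjusted Fisher-Pearson
    coefficient and kurtosis the adjusted G2 (excess); set False for raw
    moment-based estimators.  Kurtosis needs n >= 4 and skewness n >= 3;
    below that (or at zero variance) NaN is reported.
    """
    rows = []
    for t, wave in enumerate(ds.schema.wave_labels):
        for j, item in enumerate(ds.schema.item_ids):
            vals = ds.scores[:, t, j][~ds.missing_mask[:, t, j]]
            n = vals.size
            mean = vals.mean() if n else np.nan
            sd = vals.std(ddof=1) if n > 1 else np.nan
            skew = kurt = np.nan
            if n > 1 and sd > 0:
                if n >= 3:
                    skew = stats.skew(vals, bias=not bias_corrected)
                if n >= 4 or not bias_corrected:
                    kurt = stats.kurtosis(vals, fisher=True, bias=not bias_corrected)
            rows.append(
                {"wave": wave, "item": item, "n": n, "mean": mean, "sd": sd,
                 "skewness": skew, "kurtosis": kurt}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TotalSummary:
    totals: np.ndarray
    person_ids: tuple
    n: int
    mean: float
    sd: float


def scale_total(ds: PanelDataset, wave: int) -> TotalSummary:
    """Sum-score totals at a wave, for persons with all items non-missing there."""
    comp = ds.complete_at_wave(wave)
    totals = ds.scores[comp, wave, :].sum(axis=1)
    n = int(comp.sum())
    return TotalSummary(
        totals=totals,
        person_ids=tuple(pid for pid, c in zip(ds.person_ids, comp) if c),
        n=n,
        mean=float(totals.mean()) if n else float("nan"),
        sd=float(totals.std(ddof=1)) if n > 1 else float("nan"),
    )


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    ci_low: float
    ci_high: float
    n: int
    k: int


def cronbach_alpha(ds: PanelDataset, wave: int, ci_level: float = 0.95) -> AlphaResult:
    """Cronbach's alpha at a wave (complete cases) with a Feldt F-based CI.

    alpha = k/(k-1) * (1 - sum item variances / variance of total).  The
    confidence interval uses Feldt's method: (1 - alpha) scaled by F quantiles
    with df1 = n-1 and df2 = (n-1)(k-1).
    """
    k = ds.n_items
    if k < 2:
        raise PanelDataError("alpha needs >= 2 items")
    comp = ds.complete_at_wave(wave)
    X = ds.scores[comp, wave, :]
    n = X.shape[0]
    if n < 3:
        raise PanelDataError("alpha needs >= 3 complete cases")
    total_var = X.sum(axis=1).var(ddof=1)
    if not total_var > 0:
        raise PanelDataError("zero total variance")
    item_var = X.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1 - item_var / total_var)
    gamma = 1 - ci_level
    df1, df2 = n - 1, (n - 1) * (k - 1)
    lo = 1 - (1 - alpha) * stats.f.ppf(1 - gamma / 2, df1, df2)
    hi = 1 - (1 - alpha) * stats.f.ppf(gamma / 2, df1, df2)
    return AlphaResult(float(alpha), float(lo), float(hi), n, k)


def cutoff_prevalence(
    ds: PanelDataset, wave: int, cutoff: int, *, strict: bool = False
) -> tuple[int, float]:
    """Count and percentage of complete cases whose total meets the cut-off.

    Default is total >= cutoff ("at or above clinically significant level");
    ``strict=True`` uses >.  Percentage uses the complete-case n as the
    denominator, rounded to 2 decimals.
    """
    summ = scale_total(ds, wave)
    if summ.n == 0:
        return 0, 0.0
    count = int((summ.totals > cutoff).sum() if strict else (summ.totals >= cutoff).sum())
    return count, round(100.0 * count / summ.n, 2)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_completers: float
    mean_dropouts: float
    n_completers: int
    n_dropouts: int


def attrition_comparison(ds: PanelDataset, outcome_wave: int = 0, final_wave: int = -1) -> TTestResult:
    """Pooled-variance two-sample t-test of baseline totals: completers vs dropouts.

    Completers are persons observed (>= 1 item) at ``final_wave``; dropouts the
    rest.  Totals come from ``outcome_wave`` complete cases.  Sign convention:
    completers minus dropouts, so attrition of the more symptomatic gives t < 0.
    """
    final_wave = final_wave % ds.n_waves
    completer = ds.observed_at_wave(final_wave)
    summ = scale_total(ds, outcome_wave)
    pid_to_completer = dict(zip(ds.person_ids, completer))
    is_comp = np.array([pid_to_completer[p] for p in summ.person_ids], dtype=bool)
    a = summ.totals[is_comp]
    b = summ.totals[~is_comp]
    if a.size < 2 or b.size < 2:
        raise PanelDataError("both completer and dropout groups need >= 2 members")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(t), df=a.size + b.size - 2, p=float(p),
        mean_completers=float(a.mean()), mean_dropouts=float(b.mean()),
        n_completers=int(a.size), n_dropouts=int(b.size),
    )
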