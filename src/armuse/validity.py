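"""Feasibility and validity statistics on the daily and window datasets.

Two model families, matching the repeated-measures structure of a
multi-day, multi-prompt monitoring study:

* :func:`rm_anova_days` — repeated-measures ANOVA with day (1..5) as the
  within-subject factor and Bonferroni-corrected pairwise day contrasts,
  for wearing time, response rates and the accumulative-reactivity test
  on the daily time-metric percentages.
* :func:`response_bias_test` / :func:`immediate_reactivity_test` —
  two-level hierarchical linear models (random intercept per participant,
  REML, Wald tests) on the 10-min-window metrics, which tolerate the
  unequal numbers of prompts per participant.

Outcomes are log-transformed (``log(x + 1)``) when a Shapiro-Wilk test
rejects normality of the raw values at alpha = 0.05; the applied
transform is always recorded in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelResult",
    "RMAnovaResult",
    "log_transform",
    "needs_log_transform",
    "rm_anova_days",
    "response_bias_test",
    "immediate_reactivity_test",
    "percent_to_duration",
    "WINDOW_OUTCOMES",
    "DAILY_OUTCOMES",
]

logger = logging.getLogger(__name__)

WINDOW_OUTCOMES = ("time_r_s", "time_l_s", "time_b_s")
DAILY_OUTCOMES = ("time_r_pct", "time_l_pct", "time_b_pct")

#: Offset added before the log: window metrics and daily percents can be
#: exactly zero.  One unit of the outcome's scale (1 s or 1 percent point).
LOG_OFFSET = 1.0


@dataclass
class ModelResult:
    """One fixed-effect test from a random-intercept model."""

    outcome: str
    term: str
    estimate: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    group_var: float
    n_obs: int
    n_groups: int
    transform: str  # "log" or "none"


@dataclass
class RMAnovaResult:
    """Within-subject day effect plus Bonferroni pairwise contrasts."""

    outcome: str
    f: float
    df1: float
    df2: float
    pvalue: float
    pairwise: pd.DataFrame
    transform: str
    n_participants: int
    anova_table: pd.DataFrame


def log_transform(values: np.ndarray, offset: float = LOG_OFFSET) -> np.ndarray:
    """Natural log of (value + offset); rejects negative input."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("log_transform requires non-negative values")
    return np.log(values + offset)


def needs_log_transform(values: np.ndarray, alpha: float = 0.05) -> bool:
    """True when a Shapiro-Wilk test rejects normality of the raw values.

    Shapiro-Wilk is computed on at most 5000 values (deterministic
    thinning for longer series, within the test's validated range).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 3 or np.ptp(values) == 0:
        return False
    if len(values) > 5000:
        values = values[:: len(values) // 5000 + 1]
    return bool(stats.shapiro(values).pvalue < alpha)


def _apply_transform(values: np.ndarray, transform: str) -> tuple[np.ndarray, str]:
    if transform == "auto":
        transform = "log" if needs_log_transform(values) else "none"
    if transform == "log":
        return log_transform(values), "log"
    if transform == "none":
        return np.asarray(values, dtype=float), "none"
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA over days


def rm_anova_days(
    data: pd.DataFrame,
    outcome: str,
    n_days: int = 5,
    transform: str = "auto",
    sphericity_correction: bool = False,
) -> RMAnovaResult:
    """Within-subject day effect on a daily outcome, complete cases only.

    ``data`` needs columns ``participant_id``, ``day`` (1..n_days) and the
    outcome.  Participants missing any day are dropped (the
    repeated-measures layout requires a full panel); at least two complete
    participants are required.  All ``n_days * (n_days - 1) / 2`` pairwise
    day contrasts are returned with Bonferroni-adjusted p-values.
    Greenhouse-Geisser correction of the F test is available behind
    ``sphericity_correction``.
    """
    if n_days < 2:
        raise ValueError("a within-subject day factor needs >= 2 days")
    df = data[["participant_id", "day", outcome]].dropna()
    if df.duplicated(["participant_id", "day"]).any():
        raise ValueError("more than one row per participant-day")
    counts = df.groupby("participant_id")["day"].nunique()
    complete = counts[counts == n_days].index
    df = df[df["participant_id"].isin(complete)].copy()
    n = len(complete)
    if n < 2:
        raise ValueError(
            f"need >= 2 participants with complete {n_days}-day data, have {n}"
        )
    values, applied = _apply_transform(df[outcome].to_numpy(), transform)
    df["_y"] = values
    df = df.sort_values(["participant_id", "day"])

    aov = pg.rm_anova(
        data=df, dv="_y", within="day", subject="participant_id",
        correction=sphericity_correction, detailed=True,
    )
    aov = aov.rename(columns=lambda c: c.replace("-", "_"))
    row = aov[aov["Source"] == "day"].iloc[0]
    if sphericity_correction and "p_GG_corr" in aov.columns and pd.notna(row.get("p_GG_corr")):
        pval = float(row["p_GG_corr"])
    else:
        pval = float(row["p_unc"])
    pairwise = pg.pairwise_tests(
        data=df, dv="_y", within="day", subject="participant_id",
        padjust="bonf",
    )
    return RMAnovaResult(
        outcome=outcome,
        f=float(row["F"]),
        df1=float(row["DF"]),
        df2=float(aov[aov["Source"] == "Error"].iloc[0]["DF"]),
        pvalue=pval,
        pairwise=pairwise,
        transform=applied,
        n_participants=int(n),
        anova_table=aov,
    )


# ---------------------------------------------------------------------------
# two-level random-intercept models


def _fit_random_intercept(
    df: pd.DataFrame,
    outcome: str,
    indicator: np.ndarray,
    term: str,
    transform: str,
) -> ModelResult:
    """REML random-intercept fit: outcome ~ indicator + (1 | participant)."""
    y_raw = df[outcome].to_numpy(dtype=float)
    groups, _ = pd.factorize(df["participant_id"], sort=True)
    n_groups = int(groups.max()) + 1
    if n_groups < 2:
        raise ValueError(
            "random-intercept model needs >= 2 participants "
            f"(insufficient grouping: {n_groups})"
        )
    y, applied = _apply_transform(y_raw, transform)
    x = np.asarray(indicator, dtype=float)
    if np.ptp(y) == 0:
        # degenerate constant outcome: no effect, by construction
        return ModelResult(outcome, term, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0,
                           len(y), n_groups, applied)
    exog = sm.add_constant(x)
    model = sm.MixedLM(y, exog, groups=groups)
    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with _warnings.catch_warnings(), np.errstate(all="ignore"):
        # a truly zero between-participant variance legitimately sits on
        # the boundary; the Wald test for the fixed effect is unaffected
        _warnings.simplefilter("ignore", ConvergenceWarning)
        _warnings.simplefilter("ignore", UserWarning)
        res = model.fit(reml=True)
    est = float(res.params[1])
    se = float(res.bse[1])
    ci = res.conf_int()
    return ModelResult(
        outcome=outcome, term=term, estimate=est, se=se,
        pvalue=float(res.pvalues[1]),
        ci_low=float(ci[1][0]), ci_high=float(ci[1][1]),
        group_var=float(res.cov_re.iloc[0, 0]) if hasattr(res.cov_re, "iloc")
        else float(np.asarray(res.cov_re)[0, 0]),
        n_obs=len(y), n_groups=n_groups, transform=applied,
    )


def _check_levels(df: pd.DataFrame, mask: np.ndarray, names: tuple[str, str]) -> None:
    for level, sel in zip(names, (~mask, mask)):
        part = df.loc[sel, "participant_id"].nunique()
        if part == 0:
            raise ValueError(f"contrast level {level!r} is absent from the data")
        if part < 2:
            raise ValueError(
                f"contrast level {level!r} present in only {part} participant(s)"
            )


def _valid_rows(data: pd.DataFrame) -> pd.DataFrame:
    df = data
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    # deterministic fit regardless of the caller's row order
    return df.sort_values(["participant_id", "prompt_id", "phase"],
                          kind="stable").reset_index(drop=True)


def response_bias_test(
    data: pd.DataFrame,
    contrast: str = "answered_vs_unanswered",
    outcomes: tuple[str, ...] = WINDOW_OUTCOMES,
    transform: str = "auto",
) -> dict[str, ModelResult]:
    """Does pre-prompt arm use predict whether/how a prompt was answered?

    ``answered_vs_unanswered`` compares the pre-window metrics of answered
    vs unanswered *scheduled* prompts (coefficient: answered minus
    unanswered); ``scheduled_vs_selftriggered`` compares answered
    scheduled prompts with self-triggered prompts (coefficient:
    self-triggered minus scheduled).  One random-intercept model per
    outcome.
    """
    df = _valid_rows(data)
    df = df[df["phase"] == "pre"]
    if contrast == "answered_vs_unanswered":
        df = df[df["prompt_type"] == "scheduled"]
        mask = df["answered"].astype(bool).to_numpy()
        names = ("unanswered", "answered")
    elif contrast == "scheduled_vs_selftriggered":
        df = df[df["answered"].astype(bool)]
        mask = (df["prompt_type"] == "self_triggered").to_numpy()
        names = ("scheduled", "self_triggered")
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    df = df.reset_index(drop=True)
    _check_levels(df, mask, names)
    return {
        out: _fit_random_intercept(df, out, mask.astype(float), contrast, transform)
        for out in outcomes
    }


def immediate_reactivity_test(
    data: pd.DataFrame,
    outcomes: tuple[str, ...] = WINDOW_OUTCOMES,
    transform: str = "auto",
) -> dict[str, ModelResult]:
    """Did arm use change right after answering a prompt?

    Uses answered prompts with valid pre *and* post windows; the fixed
    effect is the post-vs-pre phase indicator (coefficient: post minus
    pre) in a random-intercept model per outcome.
    """
    df = _valid_rows(data)
    df = df[df["answered"].astype(bool)]
    have_both = df.groupby("prompt_id")["phase"].transform("nunique") == 2
    df = df[have_both].reset_index(drop=True)
    if df.empty:
        raise ValueError("no prompt has both a valid pre and post window")
    mask = (df["phase"] == "post").to_numpy()
    _check_levels(df, mask, ("pre", "post"))
    return {
        out: _fit_random_intercept(df, out, mask.astype(float), "post_vs_pre", transform)
        for out in outcomes
    }


def percent_to_duration(
    percent: float, wearing_hours: float = 13.7
) -> tuple[float, float]:
    """Convert a percent-of-wearing-time metric back to (minutes, hours).

    Uses the group-average daily wearing time as the reference
    denominator, for interpreting normalised daily percentages in
    absolute time units.
    """
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    hours = percent / 100.0 * wearing_hours
    return hours * 60.0, hours
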