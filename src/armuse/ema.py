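"""EMA prompt-log parsing, duplicate removal and response-rate analytics.

A prompt log holds one row per logged smartphone prompt: scheduled
prompts carry a notification time; answered prompts carry start and
completion times plus the 17 item responses; self-triggered prompts have
no notification (the participant initiated them).  Scheduled prompts that
were never delivered (phone off, technical failure) do not appear in the
log and therefore never enter the response-rate denominator.

Duplicate rule: two adjacent prompts from the same participant are
duplicates when their start times are less than one minute apart *and*
their close-ended item responses are identical; the later record is
removed (it is the re-submission), chained through bursts so only the
first of k near-simultaneous identical submissions survives.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from armuse.synthetic_data import ITEM_COLUMNS, DEFAULT_CLOSE_ENDED

__all__ = [
    "REQUIRED_COLUMNS",
    "parse_prompt_log",
    "dedup_prompts",
    "response_rates",
    "scheduled_selftrigger_correlation",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "participant_id", "prompt_id", "type",
    "notify_time", "start_time", "completion_time",
] + ITEM_COLUMNS

_TIME_COLUMNS = ("notify_time", "start_time", "completion_time")


def parse_prompt_log(path: str | Path | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a prompt-log CSV into a validated DataFrame.

    Returns ``(records, rejects)``.  Malformed rows (completion before
    start, scheduled prompt without a notification time, unparseable
    timestamps) are moved to ``rejects`` with a ``reject_reason`` column
    rather than silently dropped.  A missing required column raises.
    """
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        df = pd.read_csv(path, dtype={"participant_id": str, "prompt_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prompt log is missing required columns: {missing}")
    if df.empty:
        logger.warning("prompt log is empty")
        return df, df.assign(reject_reason=pd.Series(dtype=str))

    bad_time = pd.Series(False, index=df.index)
    for col in _TIME_COLUMNS:
        raw = df[col]
        # keep the log's local offset (day boundaries are local); fall back
        # to UTC only when a column mixes offsets
        try:
            parsed = pd.to_datetime(raw, errors="coerce")
        except (ValueError, TypeError):
            parsed = pd.to_datetime(raw, errors="coerce", utc=True)
        if not pd.api.types.is_datetime64_any_dtype(parsed):
            parsed = pd.to_datetime(raw, errors="coerce", utc=True)
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        bad_time |= parsed.isna() & ~blank
        df[col] = parsed
    # unify time zones so the columns are mutually comparable (an all-empty
    # column parses as naive NaT)
    tzs = [df[c].dt.tz for c in _TIME_COLUMNS if df[c].dt.tz is not None]
    if tzs:
        for col in _TIME_COLUMNS:
            if df[col].dt.tz is None:
                df[col] = df[col].dt.tz_localize(tzs[0])

    reasons = pd.Series("", index=df.index)
    reasons[bad_time] = "unparseable timestamp"
    inverted = (
        df["completion_time"].notna()
        & df["start_time"].notna()
        & (df["completion_time"] < df["start_time"])
    )
    reasons[inverted & (reasons == "")] = "completion before start"
    half_answered = df["start_time"].notna() ^ df["completion_time"].notna()
    reasons[half_answered & (reasons == "")] = "started but not completed"
    no_notify = (df["type"] == "scheduled") & df["notify_time"].isna()
    reasons[no_notify & (reasons == "")] = "scheduled prompt without notify_time"

    bad = reasons != ""
    rejects = df[bad].assign(reject_reason=reasons[bad])
    records = df[~bad].copy()
    records["answered"] = records["start_time"].notna() & records["completion_time"].notna()
    if bad.any():
        logger.warning("rejected %d malformed prompt rows", int(bad.sum()))
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def dedup_prompts(
    records: pd.DataFrame,
    close_ended_items: tuple[int, ...] = DEFAULT_CLOSE_ENDED,
    max_gap_s: float = 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove duplicate submissions, keeping the first of each burst.

    A record is a duplicate of its predecessor (same participant, ordered
    by start time) when the start-time gap is strictly below ``max_gap_s``
    *and* all close-ended item responses match.  Comparison chains through
    already-removed records, so k identical submissions in quick
    succession keep only the first.  Returns ``(kept, removed)``; the two
    partition the input and ``removed`` gains a ``duplicate_of`` column.
    """
    cols = [f"item_{i}" for i in close_ended_items]
    order_key = records["start_time"].fillna(records["notify_time"])
    df = records.assign(_t=order_key).sort_values(
        ["participant_id", "_t"], kind="stable"
    )
    removed_idx: list = []
    dup_of: dict = {}
    for _, grp in df.groupby("participant_id", sort=False):
        prev = None
        for idx, row in grp.iterrows():
            if prev is not None and pd.notna(row["start_time"]) and pd.notna(prev["start_time"]):
                gap = (row["start_time"] - prev["start_time"]).total_seconds()
                same = all(_eq(row[c], prev[c]) for c in cols)
                if gap < max_gap_s and same:
                    removed_idx.append(idx)
                    dup_of[idx] = prev["prompt_id"]
            prev = row
    removed_mask = df.index.isin(removed_idx)
    kept = df[~removed_mask].drop(columns="_t")
    removed = df[removed_mask].drop(columns="_t")
    removed = removed.assign(
        duplicate_of=[dup_of[i] for i in removed.index]
    )
    return (
        kept.sort_index().reset_index(drop=True),
        removed.sort_index().reset_index(drop=True),
    )


def _eq(a, b) -> bool:
    if pd.isna(a) and pd.isna(b):
        return True
    return a == b


def response_rates(
    records: pd.DataFrame,
    n_days: int = 5,
    scheduled_per_day: int = 6,
) -> pd.DataFrame:
    """Per-participant response-rate summary (duplicates must already be
    removed).

    ``provided`` counts the scheduled prompts present in the log (prompts
    the phone actually delivered); the overall rate is answered/provided
    as a percentage and is missing, not zero, for a participant with no
    provided prompts.  Per-day rates use the local calendar day of the
    notification.  Self-triggered prompts are tallied separately and
    never enter the scheduled denominator.
    """
    out = []
    for pid, grp in records.groupby("participant_id", sort=True):
        sched = grp[grp["type"] == "scheduled"]
        selftrig = grp[grp["type"] == "self_triggered"]
        provided = len(sched)
        answered = int(sched["answered"].sum())
        row = {
            "participant_id": pid,
            "provided": provided,
            "answered": answered,
            "response_rate_pct": (100.0 * answered / provided) if provided else np.nan,
            "self_triggered": int(selftrig["answered"].sum()),
            "mean_completion_min": _mean_completion_min(grp),
        }
        if provided:
            days = sched["notify_time"].dt.tz_convert(
                sched["notify_time"].dt.tz
            ).dt.date
            first = days.min()
            for d in range(1, n_days + 1):
                day_mask = days.map(lambda x: (x - first).days + 1) == d
                n_prov = int(day_mask.sum())
                n_ans = int(sched.loc[day_mask, "answered"].sum())
                row[f"rate_day{d}_pct"] = (
                    100.0 * n_ans / n_prov if n_prov else np.nan
                )
        else:
            for d in range(1, n_days + 1):
                row[f"rate_day{d}_pct"] = np.nan
        out.append(row)
    df = pd.DataFrame(out)
    if not df.empty and (df["provided"] > scheduled_per_day * n_days).any():
        logger.warning("some participants have more scheduled prompts than the protocol provides")
    return df


def _mean_completion_min(grp: pd.DataFrame) -> float:
    answered = grp[grp["answered"]] if "answered" in grp else grp
    if answered.empty:
        return np.nan
    dur = (answered["completion_time"] - answered["start_time"]).dt.total_seconds()
    return float(dur.mean() / 60.0)


def scheduled_selftrigger_correlation(
    answered_counts: np.ndarray | pd.Series,
    selftrigger_counts: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Spearman rank correlation between completed scheduled prompts and
    self-triggered prompts across participants (average ranks for ties).

    Returns ``(rho, p)``; both are NaN when either vector is constant
    (the correlation is undefined).
    """
    x = np.asarray(answered_counts, dtype=float)
    y = np.asarray(selftrigger_counts, dtype=float)
    if len(x) != len(y):
        raise ValueError("count vectors differ in length")
    if len(x) < 4:
        raise ValueError("need at least 4 participants for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant counts: correlation undefined")
        return np.nan, np.nan
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
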