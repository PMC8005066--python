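"""Synchronize EMA prompts with the epoch grid: 10-min pre/post windows.

For every deduplicated prompt, the 10 minutes of accelerometry right
before the participant started the response (for unanswered prompts:
before the notification, the moment they had the opportunity to respond)
and right after they completed it are summarised with the TimeR / TimeL /
TimeB metrics.  Windows are snapped to whole 2-s epochs; a window that
reaches outside the recording or touches any non-wear epoch is marked
invalid with a reason and is excluded from model fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from armuse.accelerometry import Category, EPOCH_LENGTH_S, time_metrics

__all__ = ["extract_windows"]


def extract_windows(
    prompts: pd.DataFrame,
    classification: np.ndarray,
    epoch_times: pd.DatetimeIndex,
    window_minutes: float = 10.0,
    epoch_length: float = EPOCH_LENGTH_S,
) -> pd.DataFrame:
    """Extract pre/post-prompt windows and their time metrics.

    Parameters
    ----------
    prompts : DataFrame
        Deduplicated prompt records (``prompt_id``, ``type``, ``answered``,
        ``notify_time``, ``start_time``, ``completion_time``).
    classification : ndarray
        Per-epoch :class:`~armuse.accelerometry.Category` codes covering
        the monitoring span.
    epoch_times : DatetimeIndex
        Start time of each epoch (contiguous within recordings; may be a
        concatenation of per-day recordings).

    Returns
    -------
    DataFrame
        One row per prompt and phase (``pre`` always; ``post`` only for
        answered prompts) with ``time_r_s``/``time_l_s``/``time_b_s``,
        ``wearing_s``, ``valid`` and ``invalid_reason``.

    Notes
    -----
    The pre window is the ``window_minutes`` ending at the epoch boundary
    at or before the anchor (so it closes strictly before the response
    began); the post window starts at the boundary at or after the
    completion.  Both are exactly ``window_minutes`` long.  Adjacent
    prompts' windows may overlap; no exclusivity is enforced.
    """
    codes = np.asarray(classification)
    if len(codes) != len(epoch_times):
        raise ValueError("classification and epoch_times lengths differ")
    if len(codes) == 0:
        raise ValueError("empty classification")
    n_epochs_win = int(round(window_minutes * 60.0 / epoch_length))
    # positions on the (possibly non-contiguous) grid via searchsorted
    times = epoch_times.asi8
    step_ns = int(epoch_length * 1e9)

    rows = []
    for _, p in prompts.iterrows():
        answered = bool(p.get("answered", pd.notna(p.get("start_time"))))
        pre_anchor = p["start_time"] if answered else p["notify_time"]
        phases = [("pre", pre_anchor)]
        if answered:
            phases.append(("post", p["completion_time"]))
        for phase, anchor in phases:
            row = {
                "participant_id": p.get("participant_id"),
                "prompt_id": p["prompt_id"],
                "prompt_type": p["type"],
                "answered": answered,
                "phase": phase,
            }
            if pd.isna(anchor):
                rows.append({**row, **_empty_metrics(), "valid": False,
                             "invalid_reason": "missing anchor time"})
                continue
            anchor_ns = pd.Timestamp(anchor).as_unit("ns").tz_convert(
                epoch_times.tz
            ).value
            if phase == "pre":
                # last epoch boundary <= anchor closes the window
                end_pos = int(np.searchsorted(times, anchor_ns - step_ns + 1))
                sl = slice(end_pos - n_epochs_win, end_pos)
            else:
                # first epoch boundary >= anchor opens the window
                start_pos = int(np.searchsorted(times, anchor_ns))
                sl = slice(start_pos, start_pos + n_epochs_win)
            if sl.start < 0 or sl.stop > len(codes):
                rows.append({**row, **_empty_metrics(), "valid": False,
                             "invalid_reason": "out of range"})
                continue
            win_codes = codes[sl]
            win_times = times[sl]
            contiguous = bool(np.all(np.diff(win_times) == step_ns))
            if not contiguous:
                rows.append({**row, **_empty_metrics(), "valid": False,
                             "invalid_reason": "out of range"})
                continue
            if np.any(win_codes == Category.INVALID):
                m = time_metrics(win_codes, epoch_length=epoch_length)
                rows.append({**row, **_as_cols(m), "valid": False,
                             "invalid_reason": "non-wear in window"})
                continue
            m = time_metrics(win_codes, epoch_length=epoch_length)
            rows.append({**row, **_as_cols(m), "valid": True,
                         "invalid_reason": ""})
    return pd.DataFrame(rows)


def _as_cols(m) -> dict:
    return {"time_r_s": m.time_r, "time_l_s": m.time_l, "time_b_s": m.time_b,
            "wearing_s": m.wearing_time_s}


def _empty_metrics() -> dict:
    return {"time_r_s": np.nan, "time_l_s": np.nan, "time_b_s": np.nan,
            "wearing_s": np.nan}
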