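"""Shared fixtures and brute-force reference implementations.

The reference functions here deliberately re-derive the pipeline's
operations sample by sample / cell by cell, independent of the vectorised
implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from armuse.accelerometry import Category


# ---------------------------------------------------------------------------
# brute-force references


def reference_counts(signal: np.ndarray, sample_rate: float = 30.0,
                     epoch_length: float = 2.0, step_g: float = 0.01664) -> np.ndarray:
    """Per-sample loop implementation of the count conversion."""
    n_per = int(round(sample_rate * epoch_length))
    n_epochs = signal.shape[0] // n_per
    out = np.zeros((n_epochs, 3), dtype=np.int64)
    for e in range(n_epochs):
        for ax in range(3):
            total = 0.0
            for i in range(n_per):
                total += abs(signal[e * n_per + i, ax])
            out[e, ax] = math.floor(total / (n_per * step_g) + 1e-9)
    return out


def reference_classify(right_counts: np.ndarray, left_counts: np.ndarray,
                       wear_right: np.ndarray, wear_left: np.ndarray,
                       threshold: float = 2.0) -> np.ndarray:
    """Epoch-by-epoch loop implementation of the movement classification."""
    n = right_counts.shape[0]
    out = np.empty(n, dtype=np.int8)
    for e in range(n):
        if not (wear_right[e] and wear_left[e]):
            out[e] = Category.INVALID
            continue
        r = math.sqrt(sum(float(c) ** 2 for c in right_counts[e]))
        l = math.sqrt(sum(float(c) ** 2 for c in left_counts[e]))
        r_mov, l_mov = r >= threshold, l >= threshold
        if r_mov and l_mov:
            out[e] = Category.BIMANUAL
        elif r_mov:
            out[e] = Category.UNI_RIGHT
        elif l_mov:
            out[e] = Category.UNI_LEFT
        else:
            out[e] = Category.NO_MOVEMENT
    return out


def reference_rm_anova(table: np.ndarray) -> tuple[float, float]:
    """Textbook sums-of-squares one-way repeated-measures ANOVA.

    ``table`` is (n_subjects, k_levels); returns (F, p).
    """
    from scipy import stats

    n, k = table.shape
    grand = table.mean()
    ss_day = n * sum((table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((table[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((table[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_day - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    f = (ss_day / df1) / (ss_err / df2)
    return f, float(stats.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def tz_start() -> pd.Timestamp:
    return pd.Timestamp("2024-03-04 09:00:00-08:00")


@pytest.fixture
def prompt_log_columns() -> list[str]:
    from armuse.ema import REQUIRED_COLUMNS

    return list(REQUIRED_COLUMNS)


def make_prompt_row(pid: str, prompt_id: str, ptype: str = "scheduled",
                    notify: str | None = None, start: str | None = None,
                    completion: str | None = None,
                    items: dict | None = None) -> dict:
    from armuse.synthetic_data import ITEM_COLUMNS

    row = {
        "participant_id": pid, "prompt_id": prompt_id, "type": ptype,
        "notify_time": notify, "start_time": start, "completion_time": completion,
    }
    base_items = {c: 1 for c in ITEM_COLUMNS}
    base_items["item_17"] = ""
    if items:
        base_items.update(items)
    row.update(base_items)
    return row
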